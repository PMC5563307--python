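"""EEG and event-table I/O.

EDF/EDF+ recordings are read through :func:`mne.io.read_raw_edf`; a minimal
16-bit EDF writer is provided so that synthetic recordings can round-trip
through the same on-disk format clinical data arrives in.  Discharge event
tables are plain CSV with a ``peak_time_s`` column (seconds from recording
start) and an optional ``label`` column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError, FormatError

__all__ = [
    "Recording",
    "DischargeEvent",
    "read_edf",
    "write_edf",
    "read_events",
    "write_events",
    "SEGMENT_MARGIN_S",
]

logger = logging.getLogger(__name__)

#: Half-width of the analysis epoch in seconds; events closer than this to a
#: recording edge cannot yield a full segment and are dropped.
SEGMENT_MARGIN_S = 3.0


@dataclass
class Recording:
    """A multichannel EEG recording in microvolts.

    Parameters
    ----------
    channel_labels
        Ordered montage names (e.g. ``Fp1`` ... ``T6``); must be unique.
    fs
        Sampling rate in Hz.
    data
        Array of shape ``(n_channels, n_samples)`` in microvolts.
    reference
        Free-text description of the reference scheme.
    """

    channel_labels: list[str]
    fs: float
    data: np.ndarray
    reference: str = "as recorded"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_labels = list(self.channel_labels)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def select(self, labels: Sequence[str]) -> "Recording":
        """Return a new Recording restricted to ``labels`` (in that order)."""
        missing = [l for l in labels if l not in self.channel_labels]
        if missing:
            raise ConfigError(f"requested channel(s) not in recording: {missing}")
        idx = [self.channel_labels.index(l) for l in labels]
        return Recording(list(labels), self.fs, self.data[idx].copy(), self.reference)

    def copy(self) -> "Recording":
        return Recording(
            list(self.channel_labels), self.fs, self.data.copy(), self.reference
        )


@dataclass(frozen=True)
class DischargeEvent:
    """A manually labeled inter-ictal discharge peak.

    ``peak_time`` is in seconds from the start of the recording; the peak
    defines time "0" of the extracted analysis epoch.
    """

    peak_time: float
    label: str | None = None


# ---------------------------------------------------------------------------
# EDF reading (mne) with a direct header check for per-signal sampling rates
# ---------------------------------------------------------------------------


def _edf_header_rates(path: Path) -> dict[str, float]:
    """Parse the ASCII EDF header and return label -> sampling rate.

    mne silently resamples mixed-rate EDF files onto a common grid, so the
    per-signal rates must be checked against the raw header.
    """
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise FormatError(f"{path}: truncated EDF header")
        try:
            record_dur = float(head[244:252].decode("ascii"))
            ns = int(head[252:256].decode("ascii"))
        except (UnicodeDecodeError, ValueError) as exc:
            raise FormatError(f"{path}: malformed EDF header") from exc
        sig = fh.read(ns * 256)
        if len(sig) < ns * 256:
            raise FormatError(f"{path}: truncated EDF signal header")
    labels = [
        sig[16 * i : 16 * (i + 1)].decode("ascii", "replace").strip()
        for i in range(ns)
    ]
    off = ns * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80)
    rates = {}
    for i, lab in enumerate(labels):
        n_per_rec = int(sig[off + 8 * i : off + 8 * (i + 1)].decode("ascii"))
        rates[lab] = n_per_rec / record_dur
    return rates


def read_edf(path: str | Path, channels: Sequence[str] | None = None) -> Recording:
    """Read an EDF/EDF+ file into a :class:`Recording` (microvolts).

    Parameters
    ----------
    path
        EDF file path.
    channels
        Labels of the EEG channels to keep, in the desired order.  ``None``
        keeps every channel in file order.  Auxiliary channels (ECG, EMG, ...)
        are excluded simply by not listing them.

    Raises
    ------
    FileNotFoundError, FormatError, ConfigError
        For a missing file, mixed sampling rates among the selected channels,
        or a requested label absent from the file.
    """
    import mne

    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    rates = _edf_header_rates(path)
    if channels is not None:
        missing = [c for c in channels if c not in rates]
        if missing:
            raise ConfigError(f"{path}: channel(s) not present in EDF: {missing}")
        sel_rates = {c: rates[c] for c in channels}
    else:
        sel_rates = rates
    if len(set(sel_rates.values())) > 1:
        raise FormatError(
            f"{path}: selected channels have mixed sampling rates: {sel_rates}"
        )

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    if channels is not None:
        raw = raw.pick(list(channels))
        raw = raw.reorder_channels(list(channels))
    data_uv = raw.get_data() * 1e6  # mne returns volts for uV-dimensioned signals
    return Recording(list(raw.ch_names), fs, data_uv, reference="as recorded")


# ---------------------------------------------------------------------------
# Minimal 16-bit EDF writer
# ---------------------------------------------------------------------------


def _ascii_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(
    path: str | Path,
    rec: Recording,
    *,
    patient_id: str = "X X X X",
    recording_id: str = "Startdate 01-JAN-2000 X X X",
) -> Path:
    """Write ``rec`` to ``path`` as a 16-bit EDF file with 1-s data records.

    The physical range is set per signal from the data, so quantization error
    is at most (peak amplitude)/32767.  The recording length must be an
    integer number of seconds and the sampling rate an integer.
    """
    path = Path(path)
    fs = rec.fs
    if fs != int(fs):
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(fs)
    if rec.n_samples % fs != 0:
        raise ValueError("EDF writer requires a whole number of 1-s records")
    n_records = rec.n_samples // fs
    ns = rec.n_channels

    phys_max = np.maximum(np.abs(rec.data).max(axis=1), 1e-6)
    dig_max = 32767
    scale = phys_max / dig_max
    digital = np.round(rec.data / scale[:, None]).astype("<i2")

    header = b"".join(
        [
            _ascii_field("0", 8),
            _ascii_field(patient_id, 80),
            _ascii_field(recording_id, 80),
            _ascii_field("01.01.00", 8),
            _ascii_field("00.00.00", 8),
            _ascii_field(256 * (1 + ns), 8),
            _ascii_field("", 44),
            _ascii_field(n_records, 8),
            _ascii_field(1, 8),
            _ascii_field(ns, 4),
        ]
    )

    def per_signal(fmt, width):
        return b"".join(_ascii_field(fmt(i), width) for i in range(ns))

    header += per_signal(lambda i: rec.channel_labels[i], 16)
    header += per_signal(lambda i: "", 80)  # transducer
    header += per_signal(lambda i: "uV", 8)
    header += per_signal(lambda i: f"{-phys_max[i]:.6g}"[:8], 8)
    header += per_signal(lambda i: f"{phys_max[i]:.6g}"[:8], 8)
    header += per_signal(lambda i: -dig_max, 8)
    header += per_signal(lambda i: dig_max, 8)
    header += per_signal(lambda i: "", 80)  # prefiltering
    header += per_signal(lambda i: fs, 8)
    header += per_signal(lambda i: "", 32)

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            block = digital[:, r * fs : (r + 1) * fs]
            fh.write(block.tobytes())  # C order: signal-major within record
    return path


# ---------------------------------------------------------------------------
# Event tables
# ---------------------------------------------------------------------------


def read_events(
    path: str | Path,
    duration: float | None = None,
    margin: float = SEGMENT_MARGIN_S,
) -> list[DischargeEvent]:
    """Read a discharge-event CSV into a sorted list of :class:`DischargeEvent`.

    The CSV must have a ``peak_time_s`` column (seconds) and may have a
    ``label`` column.  Events closer than ``margin`` seconds to either
    recording edge (when ``duration`` is given) are dropped with a warning so
    that every retained event admits a full epoch.

    Raises
    ------
    FormatError
        If the header is missing or a row does not parse as a number; the
        error names the offending line.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"label": "string"})
    except pd.errors.EmptyDataError:
        logger.warning("%s: empty event file", path)
        return []
    if "peak_time_s" not in df.columns:
        raise FormatError(f"{path}: missing required column 'peak_time_s'")
    times = pd.to_numeric(df["peak_time_s"], errors="coerce")
    bad = times.index[times.isna()]
    if len(bad):
        # +2: 1-based line numbers plus the header line
        raise FormatError(f"{path}: unparseable peak_time_s on line {bad[0] + 2}")
    labels = df["label"] if "label" in df.columns else pd.Series([None] * len(df))
    events = []
    for t, lab in zip(times, labels):
        lab = None if pd.isna(lab) else str(lab)
        if t < margin or (duration is not None and t > duration - margin):
            logger.warning(
                "dropping event at %.3f s: within %.1f s of a recording edge", t, margin
            )
            continue
        events.append(DischargeEvent(float(t), lab))
    events.sort(key=lambda e: e.peak_time)
    if not events:
        logger.warning("%s: no usable events", path)
    return events


def write_events(path: str | Path, events: Sequence[DischargeEvent]) -> Path:
    """Write events as CSV in the dialect :func:`read_events` accepts."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "peak_time_s": [e.peak_time for e in events],
            "label": [e.label if e.label is not None else "" for e in events],
        }
    )
    df.to_csv(path, index=False)
    return path
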