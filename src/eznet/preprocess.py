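"""Preprocessing and epoching.

The analysis chain is: common-average reference -> zero-phase band-pass
(0.5-30 Hz by default) -> extraction of 6-s epochs centered on each labeled
discharge peak -> anti-aliased decimation to the analysis rate (factor 8, so
256 Hz recordings become 32 Hz / 192-sample segments).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .exceptions import ConfigError
from .io import DischargeEvent, Recording, SEGMENT_MARGIN_S

__all__ = [
    "Segment",
    "average_reference",
    "bandpass",
    "extract_segments",
    "decimate_segment",
    "preprocess_recording",
]


@dataclass
class Segment:
    """A discharge-centered epoch (channels x samples, microvolts).

    ``t0_index`` is the sample corresponding to the labeled discharge peak
    (time "0"); the time axis spans [-t0_index/fs, (n-t0_index)/fs).
    """

    data: np.ndarray
    fs: float
    t0_index: int
    event: DischargeEvent | None = None
    channel_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 1:
            self.data = self.data[None, :]
        if not 0 <= self.t0_index < self.data.shape[1]:
            raise ValueError("t0_index outside segment")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to the discharge peak."""
        return (np.arange(self.n_samples) - self.t0_index) / self.fs


def average_reference(rec: Recording) -> Recording:
    """Re-reference to the common average (per-sample mean across channels).

    After this, the instantaneous mean across channels is zero.
    """
    if rec.n_channels < 2:
        raise ValueError("average reference requires at least 2 channels")
    out = rec.copy()
    out.data -= out.data.mean(axis=0, keepdims=True)
    out.reference = "common average"
    return out


def bandpass(
    rec: Recording, low: float = 0.5, high: float = 30.0, order: int = 4
) -> Recording:
    """Zero-phase Butterworth band-pass (forward-backward, ``order`` per pass)."""
    nyq = rec.fs / 2.0
    if not 0 < low < high < nyq:
        raise ConfigError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < fs/2 = {nyq}"
        )
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    out = rec.copy()
    out.data = signal.sosfiltfilt(sos, out.data, axis=1)
    return out


def extract_segments(
    rec: Recording,
    events: list[DischargeEvent],
    half_width: float = SEGMENT_MARGIN_S,
) -> list[Segment]:
    """Extract one ``2*half_width``-second epoch per event, peak at the center.

    Sample windows are half-open ``[start, start + 2*half_width*fs)`` with the
    peak index ``round(peak_time * fs)``; events must respect the edge margin
    (see :func:`eznet.io.read_events`).
    """
    half = int(round(half_width * rec.fs))
    segments = []
    for ev in events:
        peak = int(round(ev.peak_time * rec.fs))
        start, stop = peak - half, peak + half
        if start < 0 or stop > rec.n_samples:
            raise ValueError(
                f"event at {ev.peak_time} s does not fit the recording; "
                "filter events with read_events(duration=...)"
            )
        segments.append(
            Segment(
                rec.data[:, start:stop].copy(),
                rec.fs,
                t0_index=half,
                event=ev,
                channel_labels=list(rec.channel_labels),
            )
        )
    return segments


def decimate_segment(seg: Segment, factor: int = 8) -> Segment:
    """Anti-aliased decimation by an integer ``factor``.

    A zero-phase low-pass (scipy's Chebyshev design) is applied before sample
    selection; fs, sample count and ``t0_index`` are all divided by ``factor``.
    """
    if factor == 1:
        return Segment(
            seg.data.copy(), seg.fs, seg.t0_index, seg.event,
            list(seg.channel_labels) if seg.channel_labels else None,
        )
    if factor < 1 or seg.n_samples % factor != 0 or seg.t0_index % factor != 0:
        raise ConfigError(
            f"decimation factor {factor} must divide the segment length "
            f"({seg.n_samples}) and t0_index ({seg.t0_index})"
        )
    data = signal.decimate(seg.data, factor, axis=1, zero_phase=True)
    return Segment(
        data,
        seg.fs / factor,
        seg.t0_index // factor,
        seg.event,
        list(seg.channel_labels) if seg.channel_labels else None,
    )


def preprocess_recording(
    rec: Recording,
    events: list[DischargeEvent],
    *,
    band: tuple[float, float] = (0.5, 30.0),
    filter_order: int = 4,
    decim: int = 8,
    half_width: float = SEGMENT_MARGIN_S,
) -> list[Segment]:
    """Full preprocessing chain: average reference -> band-pass -> epoch -> decimate."""
    rec = bandpass(average_reference(rec), *band, order=filter_order)
    segs = extract_segments(rec, events, half_width=half_width)
    return [decimate_segment(s, decim) for s in segs]
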