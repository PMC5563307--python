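"""Synthetic EEG with planted time-varying directed structure.

Recordings are generated from a piecewise-stationary multichannel
autoregressive process: every channel carries its own resonant AR(2)
background (a ~6 Hz rhythm, innovation SD 5 microvolts), and directed
coupling terms are switched on and off on a schedule.  The planted
epileptogenic source starts driving its neighbors a fixed lead time (0.5 s
by default) before each spike-shaped transient, emulating a focus that
activates before the discharge and propagates to other regions; optional
background sources drive their neighbors throughout the recording.  The
cross-channel coupling acts at lag 8 of the 256 Hz process so that it
survives the factor-8 decimation as a lag-1 interaction at 32 Hz.

Ground truth (source, background drivers, coupling windows, spike times)
is carried alongside the recording so every pipeline stage can be scored.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import ConfigError
from .io import DischargeEvent, Recording, write_edf, write_events

__all__ = [
    "TEN_TWENTY_16",
    "SimulationConfig",
    "GroundTruth",
    "simulate_tv_mvar",
    "inject_spikes",
    "make_fixture",
    "PRESETS",
]

logger = logging.getLogger(__name__)

#: The 16-electrode extended 10-20 montage used for the default fixtures.
TEN_TWENTY_16 = [
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4",
    "O1", "O2", "F7", "F8", "T3", "T4", "T5", "T6",
]

COUPLING_LAG = 8  # samples at the raw rate; = 1 sample after factor-8 decimation


@dataclass
class SimulationConfig:
    """Parameters of one synthetic recording.

    ``coefficient_schedule`` is a list of ``(t_start, t_end, A)`` entries with
    ``A`` of shape (p, M, M); later entries override earlier ones where they
    overlap, and every tensor must be stable (companion spectral radius < 1).
    Spike transients are biphasic spike-and-slow-wave shapes added on top of
    the AR background; ``coupling_lead`` seconds before each spike peak the
    source's outgoing coupling switches on.
    """

    n_channels: int = 16
    channel_labels: list[str] = field(default_factory=lambda: list(TEN_TWENTY_16))
    fs: float = 256.0
    duration: float = 20.0
    coefficient_schedule: list[tuple[float, float, np.ndarray]] = field(
        default_factory=list
    )
    noise_sd: float = 5.0  # innovation SD, microvolts
    noise_cov: np.ndarray | None = None
    source_channel: str | None = None
    spike_times: list[float] = field(default_factory=list)
    coupling_lead: float = 0.5
    coupling_tail: float = 1.0  # coupling stays on this long after the peak
    spike_amplitude_uv: float = 120.0
    spike_width_ms: float = 70.0
    wave_width_ms: float = 200.0
    wave_amplitude_frac: float = 0.5
    propagation_delays_ms: np.ndarray | None = None
    spike_attenuation: float = 0.6
    background_sources: list[str] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.channel_labels) != self.n_channels:
            raise ConfigError("channel_labels length must equal n_channels")
        margin = 3.0
        for t in self.spike_times:
            if t < margin or t > self.duration - margin:
                raise ConfigError(
                    f"spike at {t} s violates the {margin}-s segment margin"
                )
        for i, (t0, t1, A) in enumerate(self.coefficient_schedule):
            A = np.asarray(A, dtype=float)
            rho = companion_spectral_radius(A)
            if rho >= 1.0:
                raise ConfigError(
                    f"schedule interval {i} [{t0}, {t1}) s is unstable "
                    f"(companion spectral radius {rho:.4f} >= 1)"
                )


def companion_spectral_radius(A: np.ndarray) -> float:
    """Spectral radius of the VAR companion matrix of coefficients (p, M, M)."""
    A = np.asarray(A, dtype=float)
    p, M, _ = A.shape
    comp = np.zeros((M * p, M * p))
    comp[:M] = A.transpose(1, 0, 2).reshape(M, M * p)
    if p > 1:
        comp[M:, :-M] = np.eye(M * (p - 1))
    return float(np.abs(np.linalg.eigvals(comp)).max())


@dataclass
class GroundTruth:
    """What was planted: source, drivers, coupling windows, true edges."""

    source_channel: str | None
    background_sources: list[str]
    spike_times: list[float]
    coupling_windows: list[tuple[float, float]]
    edges: list[dict]  # {"t_start","t_end","sender","receiver"}

    def to_json(self, path: str | Path) -> Path:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, default=list))
        return Path(path)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        d["coupling_windows"] = [tuple(w) for w in d["coupling_windows"]]
        return cls(**d)


def _ar2_background(fs: float, f0: float = 6.0, r: float = 0.95) -> tuple[float, float]:
    """AR(2) coefficients with a resonance at f0 Hz and pole radius r."""
    theta = 2.0 * np.pi * f0 / fs
    return 2.0 * r * np.cos(theta), -(r * r)


def _base_tensor(cfg: SimulationConfig, p: int) -> np.ndarray:
    a1, a2 = _ar2_background(cfg.fs)
    A = np.zeros((p, cfg.n_channels, cfg.n_channels))
    np.fill_diagonal(A[0], a1)
    np.fill_diagonal(A[1], a2)
    return A


def _add_coupling(
    A: np.ndarray, labels: list[str], sender: str, receivers: list[str], c: float
) -> np.ndarray:
    A = A.copy()
    j = labels.index(sender)
    for r in receivers:
        A[COUPLING_LAG - 1, labels.index(r), j] = c
    return A


def simulate_tv_mvar(cfg: SimulationConfig) -> tuple[Recording, GroundTruth]:
    """Generate a recording sample-by-sample from the scheduled coefficients.

    Gaussian innovations, deterministic under ``cfg.seed``.  A 2-s burn-in
    under the t=0 dynamics is discarded so segments near the start are
    stationary.
    """
    if not cfg.coefficient_schedule:
        raise ConfigError("coefficient_schedule must contain at least one entry")
    rng = np.random.default_rng(cfg.seed)
    M = cfg.n_channels
    fs = cfg.fs
    n = int(round(cfg.duration * fs))
    p = max(np.asarray(A).shape[0] for _, _, A in cfg.coefficient_schedule)

    # per-sample index into the schedule (later entries override earlier)
    tensor_idx = np.full(n, -1, dtype=int)
    flats = []
    for i, (t0, t1, A) in enumerate(cfg.coefficient_schedule):
        A = np.asarray(A, dtype=float)
        if A.shape[0] < p:  # pad to the common order
            A = np.concatenate([A, np.zeros((p - A.shape[0], M, M))])
        flats.append(A.transpose(1, 0, 2).reshape(M, M * p))
        lo, hi = max(0, int(round(t0 * fs))), min(n, int(round(t1 * fs)))
        tensor_idx[lo:hi] = i
    if np.any(tensor_idx < 0):
        raise ConfigError("coefficient_schedule does not cover the full duration")

    if cfg.noise_cov is not None:
        L = np.linalg.cholesky(np.asarray(cfg.noise_cov, dtype=float))
    else:
        L = cfg.noise_sd * np.eye(M)

    burn = int(round(2.0 * fs))
    innov = L @ rng.standard_normal((M, burn + n))
    x = np.zeros((M, burn + n))
    z = np.zeros(M * p)  # [x(t-1); x(t-2); ...; x(t-p)]
    for t in range(burn + n):
        i = tensor_idx[0] if t < burn else tensor_idx[t - burn]
        xt = flats[i] @ z + innov[:, t]
        x[:, t] = xt
        z = np.concatenate((xt, z[:-M]))
    data = x[:, burn:]

    windows = [
        (t - cfg.coupling_lead, t + cfg.coupling_tail) for t in cfg.spike_times
    ]
    edges = []
    labels = cfg.channel_labels
    for t0, t1, A in cfg.coefficient_schedule:
        A = np.asarray(A)
        recv_i, send_j = np.nonzero(np.any(np.abs(A) > 0, axis=0) & ~np.eye(M, dtype=bool))
        for i, j in zip(recv_i, send_j):
            edges.append(
                {"t_start": t0, "t_end": t1, "sender": labels[j], "receiver": labels[i]}
            )
    truth = GroundTruth(
        source_channel=cfg.source_channel,
        background_sources=list(cfg.background_sources),
        spike_times=list(cfg.spike_times),
        coupling_windows=windows,
        edges=edges,
    )
    rec = Recording(list(labels), fs, data, reference="simulated, common ground")
    return rec, truth


def _spike_template(cfg: SimulationConfig) -> tuple[np.ndarray, int]:
    """Biphasic spike-and-slow-wave; returns (template, index of its peak)."""
    fs = cfg.fs
    n_spike = max(int(round(cfg.spike_width_ms / 1000.0 * fs)) | 1, 3)  # odd: peak == amplitude
    n_wave = max(int(round(cfg.wave_width_ms / 1000.0 * fs)), 3)
    spike = cfg.spike_amplitude_uv * np.hanning(n_spike)
    wave = -cfg.wave_amplitude_frac * cfg.spike_amplitude_uv * np.hanning(n_wave)
    template = np.concatenate((spike, wave))
    return template, int(np.argmax(spike))


def inject_spikes(rec: Recording, cfg: SimulationConfig) -> Recording:
    """Add the spike-and-wave template at each spike time.

    The template peak lands on the source channel at the spike time exactly;
    every other channel receives it after its propagation delay, scaled by
    ``spike_attenuation``.
    """
    out = rec.copy()
    if cfg.spike_amplitude_uv == 0.0 or not cfg.spike_times:
        return out
    template, peak_off = _spike_template(cfg)
    fs = rec.fs
    src = (
        rec.channel_labels.index(cfg.source_channel)
        if cfg.source_channel in rec.channel_labels
        else 0
    )
    delays = cfg.propagation_delays_ms
    if delays is None:
        delays = np.zeros(rec.n_channels)
    delays = np.asarray(delays, dtype=float)
    for t_spike in cfg.spike_times:
        peak = int(round(t_spike * fs))
        for ch in range(rec.n_channels):
            d = 0 if ch == src else int(round(delays[ch] / 1000.0 * fs))
            gain = 1.0 if ch == src else cfg.spike_attenuation
            start = peak + d - peak_off
            stop = start + template.size
            if start < 0 or stop > rec.n_samples:
                raise ConfigError(
                    f"spike at {t_spike} s overlaps the recording edge"
                )
            out.data[ch, start:stop] += gain * template
    return out


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------


def _preset_null_independent(seed: int) -> SimulationConfig:
    cfg = SimulationConfig(
        duration=20.0,
        spike_times=[10.0],
        spike_amplitude_uv=0.0,  # events mark epochs; no transient, no coupling
        seed=seed,
    )
    cfg.coefficient_schedule = [(0.0, cfg.duration, _base_tensor(cfg, COUPLING_LAG))]
    cfg.__post_init__()
    return cfg


def _preset_two_channel_driver(seed: int) -> SimulationConfig:
    cfg = SimulationConfig(
        n_channels=2,
        channel_labels=["CH1", "CH2"],
        duration=16.0,
        source_channel="CH1",
        spike_times=[8.0],
        propagation_delays_ms=np.array([0.0, 30.0]),
        seed=seed,
    )
    base = _base_tensor(cfg, COUPLING_LAG)
    coupled = _add_coupling(base, cfg.channel_labels, "CH1", ["CH2"], 0.45)
    cfg.coefficient_schedule = [(0.0, cfg.duration, base)] + [
        (t - cfg.coupling_lead, t + cfg.coupling_tail, coupled)
        for t in cfg.spike_times
    ]
    cfg.__post_init__()
    return cfg


SOURCE_TARGETS_16 = {"F7": ["F3", "T3", "Fp1", "C3", "T5"]}
BACKGROUND_TARGETS_16 = {"O1": ["O2", "P3", "T6", "P4", "C4"]}


def _preset_full16_planted_source(seed: int) -> SimulationConfig:
    cfg = SimulationConfig(
        duration=52.0,
        source_channel="F7",
        spike_times=[8.0, 18.0, 28.0, 38.0, 48.0],
        background_sources=list(BACKGROUND_TARGETS_16),
        propagation_delays_ms=20.0 + 2.5 * np.arange(16),
        seed=seed,
    )
    base = _base_tensor(cfg, COUPLING_LAG)
    for bg, targets in BACKGROUND_TARGETS_16.items():
        base = _add_coupling(base, cfg.channel_labels, bg, targets, 0.25)
    coupled = base
    for src, targets in SOURCE_TARGETS_16.items():
        coupled = _add_coupling(coupled, cfg.channel_labels, src, targets, 0.45)
    cfg.coefficient_schedule = [(0.0, cfg.duration, base)] + [
        (t - cfg.coupling_lead, t + cfg.coupling_tail, coupled)
        for t in cfg.spike_times
    ]
    cfg.__post_init__()
    return cfg


PRESETS = {
    "null_independent": _preset_null_independent,
    "two_channel_driver": _preset_two_channel_driver,
    "full16_planted_source": _preset_full16_planted_source,
}


def make_fixture(
    preset: str, seed: int, outdir: str | Path
) -> tuple[Path, Path, Path, GroundTruth]:
    """Write a self-contained synthetic dataset (EDF, event CSV, truth JSON).

    Returns the three file paths and the in-memory :class:`GroundTruth`.
    """
    if preset not in PRESETS:
        raise ConfigError(
            f"unknown preset {preset!r}; choose from {sorted(PRESETS)}"
        )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = PRESETS[preset](seed)
    rec, truth = simulate_tv_mvar(cfg)
    rec = inject_spikes(rec, cfg)
    edf = write_edf(outdir / f"{preset}_seed{seed}.edf", rec)
    events = write_events(
        outdir / f"{preset}_seed{seed}_events.csv",
        [DischargeEvent(t, "simulated") for t in cfg.spike_times],
    )
    truth_path = truth.to_json(outdir / f"{preset}_seed{seed}_truth.json")
    return edf, events, truth_path, truth
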