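"""Adaptive directed transfer function (ADTF) connectivity.

From tv-MVAR coefficients the frequency-domain coefficient matrix is

    A(f, t) = I - sum_{k=1..p} A_k(t) exp(-j 2 pi f dt k),

whose inverse H(f, t) = A(f, t)^-1 is the time-resolved transfer matrix.
The normalized ADTF from sender j to receiver i,

    gamma2_ij(f, t) = |H_ij(f, t)|^2 / sum_m |H_im(f, t)|^2,

is normalized over senders for each receiver, so each receiver row sums to
one.  Band integration averages gamma2 over the frequency bins inside the
band of interest (0.5-14.5 Hz by default), giving Q2_ij(t) in [0, 1]; the
total outflow of node j is the mean of Q2_kj(t) over receivers k != j.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .var import TimeVaryingVARResults

__all__ = [
    "SpectralTransfer",
    "DynamicConnectivity",
    "default_freq_grid",
    "coeff_to_spectrum",
    "normalized_adtf",
    "integrated_adtf",
    "total_outflow",
    "compute_connectivity",
]

logger = logging.getLogger(__name__)

#: Condition-number ceiling beyond which A(f,t) is treated as singular.
COND_LIMIT = 1e12

BAND_DEFAULT = (0.5, 14.5)


def default_freq_grid(fs: float, step: float = 0.5, f_max: float = 15.5) -> np.ndarray:
    """0.5 Hz-spaced grid from ``step`` up to min(f_max, just below Nyquist)."""
    top = min(f_max, fs / 2.0 - step / 2.0)
    return np.arange(step, top + 1e-9, step)


@dataclass
class SpectralTransfer:
    """Frequency-domain tv-MVAR quantities on the valid time grid.

    ``H[t, f]`` is the transfer matrix (receiver x sender) at valid time point
    t and frequency ``freqs[f]``; ``A_f`` is its inverse-side coefficient
    spectrum.  ``flagged`` marks (t, f) points where A(f,t) was singular or
    ill-conditioned; H is NaN there.
    """

    freqs: np.ndarray
    H: np.ndarray
    A_f: np.ndarray
    dt: float
    times: np.ndarray
    time_indices: np.ndarray
    flagged: np.ndarray
    channel_labels: list[str] | None = None

    @property
    def n_channels(self) -> int:
        return self.H.shape[-1]


def coeff_to_spectrum(
    model: TimeVaryingVARResults, freqs: np.ndarray
) -> SpectralTransfer:
    """Evaluate A(f,t) and H(f,t) = A(f,t)^-1 on a frequency grid.

    Frequencies must lie strictly inside (0, fs/2).  Points where A(f,t) is
    singular or has 1-norm condition number above :data:`COND_LIMIT` are
    flagged and carry NaN in H.
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.ndim != 1 or np.any(np.diff(freqs) <= 0):
        raise ConfigError("frequency grid must be 1-D and strictly increasing")
    if np.any(freqs <= 0) or np.any(freqs >= model.fs / 2):
        raise ConfigError(
            f"frequencies must lie in (0, {model.fs / 2}) Hz for fs={model.fs}"
        )
    dt = 1.0 / model.fs
    valid_idx = np.flatnonzero(model.valid)
    coeffs = model.coeffs[valid_idx]  # (T, p, M, M)
    T, p, M, _ = coeffs.shape
    F = freqs.size
    # phase[f, k] = exp(-j 2 pi f dt (k+1))
    phase = np.exp(-2j * np.pi * np.outer(freqs, dt * np.arange(1, p + 1)))
    A_f = np.tile(np.eye(M, dtype=complex), (T, F, 1, 1))
    A_f -= np.einsum("tkij,fk->tfij", coeffs, phase)

    H = np.full_like(A_f, np.nan)
    flagged = np.zeros((T, F), dtype=bool)
    try:
        H_all = np.linalg.inv(A_f)
    except np.linalg.LinAlgError:
        H_all = None
    if H_all is None:
        for t in range(T):
            for f in range(F):
                try:
                    H[t, f] = np.linalg.inv(A_f[t, f])
                except np.linalg.LinAlgError:
                    flagged[t, f] = True
    else:
        H = H_all
    # cheap 1-norm condition estimate on the (possibly batched) inverses
    with np.errstate(invalid="ignore", over="ignore"):
        norm_a = np.abs(A_f).sum(axis=-2).max(axis=-1)
        norm_h = np.abs(H).sum(axis=-2).max(axis=-1)
        cond = norm_a * norm_h
    bad = ~np.isfinite(cond) | (cond > COND_LIMIT)
    if bad.any():
        flagged |= bad
        H[flagged] = np.nan
        logger.warning("%d (time, freq) points flagged as ill-conditioned", bad.sum())
    return SpectralTransfer(
        freqs=freqs,
        H=H,
        A_f=A_f,
        dt=dt,
        times=model.times[valid_idx],
        time_indices=valid_idx,
        flagged=flagged,
        channel_labels=model.channel_labels,
    )


def normalized_adtf(st: SpectralTransfer) -> np.ndarray:
    """Receiver-normalized ADTF gamma2, shape (T, F, receiver, sender).

    Each receiver row sums to 1 over senders; degenerate all-zero rows (and
    flagged points) are NaN.
    """
    power = np.abs(st.H) ** 2
    denom = power.sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma2 = power / denom
    zero_rows = denom[..., 0] == 0
    if zero_rows.any():
        logger.warning("%d all-zero transfer rows set unavailable", zero_rows.sum())
        gamma2[zero_rows] = np.nan
    return gamma2


def band_mask(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    f1, f2 = band
    mask = (freqs >= f1 - 1e-9) & (freqs <= f2 + 1e-9)
    if not mask.any():
        raise ConfigError(f"band {band} contains no grid frequencies")
    return mask


def integrated_adtf(
    gamma2: np.ndarray, freqs: np.ndarray, band: tuple[float, float] = BAND_DEFAULT
) -> np.ndarray:
    """Average gamma2 over the in-band frequency bins -> Q2, shape (T, M, M).

    The divisor is the number of in-band bins, which keeps Q2 in [0, 1] on
    any grid (and coincides with a literal (f2 - f1) divisor on a 1 Hz grid).
    """
    mask = band_mask(freqs, band)
    return gamma2[:, mask].mean(axis=1)


def total_outflow(Q2: np.ndarray) -> np.ndarray:
    """Normalized total outflow per sender: mean of Q2[:, k, j] over k != j.

    Shape (T, M); values in [0, 1].
    """
    n = Q2.shape[-1]
    if n < 2:
        raise ValueError("outflow requires at least 2 nodes")
    diag = Q2[:, np.arange(n), np.arange(n)]
    return (Q2.sum(axis=1) - diag) / (n - 1)


@dataclass
class DynamicConnectivity:
    """Normalized and band-integrated ADTF over time.

    ``gamma2[t, f, i, j]`` is flow j -> i at valid time point t; ``Q2`` is its
    in-band average and ``outflow[t, j]`` the mean outgoing Q2 of node j.
    The on-disk container persists only the band-integrated quantities, so
    ``gamma2`` is None on objects restored with :meth:`load`.
    """

    gamma2: np.ndarray
    Q2: np.ndarray
    outflow: np.ndarray
    freqs: np.ndarray
    band: tuple[float, float]
    times: np.ndarray
    time_indices: np.ndarray
    channel_labels: list[str] | None = None

    @property
    def n_nodes(self) -> int:
        return self.Q2.shape[-1]

    def _labels(self) -> list[str]:
        if self.channel_labels is not None:
            return list(self.channel_labels)
        return [f"ch{i}" for i in range(self.n_nodes)]

    def q2_to_csv(self, path: str | Path) -> Path:
        """Long-format export: time_s, sender, receiver, value."""
        labels = self._labels()
        n, T = self.n_nodes, len(self.times)
        recv, send = np.meshgrid(range(n), range(n), indexing="ij")
        rows = {
            "time_s": np.repeat(self.times, n * n),
            "sender": np.tile([labels[j] for j in send.ravel()], T),
            "receiver": np.tile([labels[i] for i in recv.ravel()], T),
            "value": self.Q2.reshape(T, -1).ravel(),
        }
        pd.DataFrame(rows).to_csv(path, index=False)
        return Path(path)

    def outflow_to_csv(self, path: str | Path) -> Path:
        labels = self._labels()
        df = pd.DataFrame(self.outflow, columns=labels)
        df.insert(0, "time_s", self.times)
        df.to_csv(path, index=False)
        return Path(path)

    def save(self, path: str | Path) -> Path:
        """Serialize to ``<path>.npz`` plus a ``<path>.json`` sidecar."""
        import json

        path = Path(path)
        np.savez_compressed(
            path.with_suffix(".npz"),
            Q2=self.Q2, outflow=self.outflow, freqs=self.freqs,
            times=self.times, time_indices=self.time_indices,
        )
        sidecar = {"band": list(self.band), "channel_labels": self._labels()}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
        return path.with_suffix(".npz")

    @classmethod
    def load(cls, path: str | Path) -> "DynamicConnectivity":
        import json

        path = Path(path)
        arrays = np.load(path.with_suffix(".npz"))
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            gamma2=None, Q2=arrays["Q2"], outflow=arrays["outflow"],
            freqs=arrays["freqs"], band=tuple(meta["band"]),
            times=arrays["times"], time_indices=arrays["time_indices"],
            channel_labels=meta["channel_labels"],
        )


def compute_connectivity(
    model: TimeVaryingVARResults,
    freqs: np.ndarray | None = None,
    band: tuple[float, float] = BAND_DEFAULT,
) -> DynamicConnectivity:
    """tv-MVAR results -> spectral transfer -> gamma2 -> Q2 -> outflow."""
    if freqs is None:
        freqs = default_freq_grid(model.fs)
    st = coeff_to_spectrum(model, np.asarray(freqs, dtype=float))
    gamma2 = normalized_adtf(st)
    Q2 = integrated_adtf(gamma2, st.freqs, band)
    outflow = total_outflow(Q2)
    return DynamicConnectivity(
        gamma2=gamma2,
        Q2=Q2,
        outflow=outflow,
        freqs=st.freqs,
        band=band,
        times=st.times,
        time_indices=st.time_indices,
        channel_labels=st.channel_labels,
    )
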