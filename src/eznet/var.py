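"""Time-varying multivariate autoregressive (tv-MVAR) modeling.

Each channel of a segment is modeled as a lagged linear combination of all
channels plus innovation noise,

    X(t) = sum_{k=1..p} A_k(t) X(t-k) + E(t),

with the coefficient matrices A_k(t) tracked through time by a Kalman filter
in the classic recursive "update constant" (UC) parameterization: the state
is the vectorized coefficient set, the state transition is a random walk
whose process noise is a UC-scaled copy of the state covariance, and the
measurement noise variance is tracked adaptively from the innovations.
Because every channel shares the same lagged regressor vector, the filter
factorizes into independent scalar-observation filters per target channel,
which is what :meth:`TimeVaryingVAR.fit` runs (batched over channels).

The model order p is chosen per segment by the Akaike information criterion
computed from a stationary least-squares pre-fit,

    AIC(p) = ln det(chi) + 2 M^2 p / N,

with chi the residual covariance, M the channel count and N the segment
length, searched over 2..20 (clamped to the largest identifiable order).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import ConfigError, NumericalError
from .preprocess import Segment

__all__ = [
    "AICResult",
    "TimeVaryingVAR",
    "TimeVaryingVARResults",
    "select_order",
    "fit_kalman",
    "ols_var",
]

logger = logging.getLogger(__name__)

ORDER_MIN_DEFAULT = 2
ORDER_MAX_DEFAULT = 20
UC_DEFAULT = 1e-3


def _lag_matrix(data: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Return (Y, Z): Y[t] = X(t), Z[t] = [X(t-1); ...; X(t-p)] for t = p..N-1."""
    M, N = data.shape
    Y = data[:, p:].T  # (N-p, M)
    Z = np.empty((N - p, M * p))
    for k in range(1, p + 1):
        Z[:, (k - 1) * M : k * M] = data[:, p - k : N - k].T
    return Y, Z


def ols_var(data: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Stationary least-squares VAR fit (no intercept, first p samples presample).

    Returns
    -------
    coeffs : ndarray, shape (p, M, M)
        ``coeffs[k-1][i, j]`` multiplies channel j at lag k in the prediction
        of channel i.
    resid_cov : ndarray, shape (M, M)
        Unbiased residual covariance (divisor = residual degrees of freedom,
        (N - p) - M p).
    """
    M, N = data.shape
    if N <= p:
        raise ConfigError(f"segment of {N} samples cannot fit order {p}")
    Y, Z = _lag_matrix(data, p)
    B, _, _, _ = np.linalg.lstsq(Z, Y, rcond=None)  # (M*p, M)
    resid = Y - Z @ B
    df = (N - p) - M * p  # residual degrees of freedom per equation
    if df < 1:
        raise NumericalError(f"singular regression at order {p}: no residual df")
    resid_cov = resid.T @ resid / df
    coeffs = B.T.reshape(M, p, M).transpose(1, 0, 2)
    return coeffs, resid_cov


@dataclass
class AICResult:
    """Order-selection outcome.

    ``scores`` maps candidate order -> AIC value; ``selected`` is the
    minimizer (smallest order on ties).  ``p_max_effective`` records any clamp
    applied to keep the least-squares pre-fit identifiable (N - p > M p).
    """

    scores: dict[int, float]
    selected: int
    n_samples: int
    n_channels: int
    residual_cov_by_order: dict[int, np.ndarray]
    p_max_effective: int = 0


def select_order(
    seg: Segment | np.ndarray,
    p_min: int = ORDER_MIN_DEFAULT,
    p_max: int = ORDER_MAX_DEFAULT,
) -> AICResult:
    """Choose the MVAR order by AIC over ``p_min..p_max``.

    For each candidate p a stationary VAR is fitted by multichannel least
    squares; AIC(p) = ln det(chi) + 2 M^2 p / N with chi the unbiased
    residual covariance.  The search ceiling is clamped so the covariance
    keeps at least 4M residual degrees of freedom (an underdetermined or
    rank-deficient pre-fit makes the log-determinant meaningless); ties go
    to the smaller order.
    """
    data = seg.data if isinstance(seg, Segment) else np.asarray(seg, dtype=float)
    M, N = data.shape
    # the residual covariance needs df = N - p - M*p degrees of freedom; with
    # df < a few times M its log-determinant is biased far downward and AIC
    # degenerates toward the ceiling, so keep df >= 4M (and always >= 1)
    feasible = (N - max(4 * M, 1)) // (M + 1)
    if feasible < p_min:
        raise ConfigError(
            f"segment too short for order selection: N={N}, M={M} "
            f"admits p <= {feasible} < p_min={p_min}"
        )
    p_hi = min(p_max, feasible)
    if p_hi < p_max:
        logger.info(
            "order search clamped to %d (N=%d, M=%d cannot identify p > %d)",
            p_hi, N, M, p_hi,
        )
    scores: dict[int, float] = {}
    covs: dict[int, np.ndarray] = {}
    for p in range(p_min, p_hi + 1):
        _, chi = ols_var(data, p)
        # floor the spectrum so a rank-deficient montage (e.g. common-average
        # referenced data) yields a finite, p-comparable log-determinant
        ridge = 1e-12 * max(np.trace(chi) / M, 1e-30)
        sign, logdet = np.linalg.slogdet(chi + ridge * np.eye(M))
        aic = logdet + 2.0 * M * M * p / N
        if sign <= 0 or not np.isfinite(aic):
            raise NumericalError(f"singular residual covariance at order {p}")
        scores[p] = float(aic)
        covs[p] = chi
    selected = min(scores, key=lambda p: (scores[p], p))
    return AICResult(scores, selected, N, M, covs, p_max_effective=p_hi)


@dataclass
class TimeVaryingVARResults:
    """Kalman-tracked tv-MVAR estimates for one segment.

    Attributes
    ----------
    coeffs : ndarray, shape (N, p, M, M)
        ``coeffs[t, k-1, i, j]`` is the estimate of A_k(t)[i, j]; NaN for
        t < p where no estimate exists (the first p samples are regressors
        only).
    residual_cov : ndarray, shape (N, M, M)
        Adaptive innovation-covariance estimate (symmetric PSD); NaN early.
    valid : ndarray of bool, shape (N,)
        True where estimates are defined (t >= p).
    """

    order: int
    uc: float
    fs: float
    coeffs: np.ndarray
    residual_cov: np.ndarray
    valid: np.ndarray
    channel_labels: list[str] | None = None
    t0_index: int = 0
    innovations: np.ndarray | None = None

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[2]

    @property
    def n_samples(self) -> int:
        return self.coeffs.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Seconds relative to the discharge peak, full sample grid."""
        return (np.arange(self.n_samples) - self.t0_index) / self.fs

    # -- connectivity front-ends (implemented in eznet.connectivity) --------

    def spectral_transfer(self, freqs: np.ndarray | None = None):
        from .connectivity import coeff_to_spectrum, default_freq_grid

        if freqs is None:
            freqs = default_freq_grid(self.fs)
        return coeff_to_spectrum(self, np.asarray(freqs, dtype=float))

    def connectivity(
        self,
        freqs: np.ndarray | None = None,
        band: tuple[float, float] = (0.5, 14.5),
    ):
        from .connectivity import compute_connectivity

        return compute_connectivity(self, freqs=freqs, band=band)

    # -- reporting / persistence -------------------------------------------

    def summary(self) -> str:
        nval = int(self.valid.sum())
        mean_abs = float(np.nanmean(np.abs(self.coeffs[self.valid])))
        resid_tr = float(np.nanmean(np.trace(self.residual_cov[self.valid], axis1=1, axis2=2)))
        lines = [
            "Time-varying MVAR (Kalman) results",
            "=" * 40,
            f"channels:          {self.n_channels}",
            f"model order p:     {self.order}",
            f"update constant:   {self.uc:g}",
            f"sampling rate:     {self.fs:g} Hz",
            f"samples (valid):   {self.n_samples} ({nval})",
            f"mean |coeff|:      {mean_abs:.4f}",
            f"mean tr(resid cov): {resid_tr:.4f}",
        ]
        return "\n".join(lines)

    def save(self, path: str | Path) -> Path:
        """Serialize to ``<path>.npz`` plus a ``<path>.json`` sidecar."""
        path = Path(path)
        np.savez_compressed(
            path.with_suffix(".npz"),
            coeffs=self.coeffs,
            residual_cov=self.residual_cov,
            valid=self.valid,
        )
        sidecar = {
            "order": self.order,
            "uc": self.uc,
            "fs": self.fs,
            "t0_index": self.t0_index,
            "channel_labels": self.channel_labels,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
        return path.with_suffix(".npz")

    @classmethod
    def load(cls, path: str | Path) -> "TimeVaryingVARResults":
        path = Path(path)
        arrays = np.load(path.with_suffix(".npz"))
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            order=meta["order"],
            uc=meta["uc"],
            fs=meta["fs"],
            coeffs=arrays["coeffs"],
            residual_cov=arrays["residual_cov"],
            valid=arrays["valid"],
            channel_labels=meta["channel_labels"],
            t0_index=meta["t0_index"],
        )


class TimeVaryingVAR:
    """Time-varying MVAR model of one segment or an ensemble of segments.

    Parameters
    ----------
    segment
        A :class:`~eznet.preprocess.Segment` (or plain channels-x-samples
        array), or a list of peak-aligned segments treated as repeated trials
        of the same time-locked process.  Reliable time-varying networks need
        several discharge epochs; with an ensemble, every trial contributes
        an update at each latency, so coefficient noise shrinks roughly with
        the trial count.
    order
        Model order p; ``None`` selects it by AIC on construction (lower
        median across trials for an ensemble).
    uc
        Kalman update constant in (0, 1); larger tracks faster but noisier.
    leak
        Optional ridge-type shrinkage of the coefficient state toward zero
        per step (bounds coefficient variance along weakly excited regressor
        directions, at the price of downward bias on true coefficients).
        Default 0 (off).
    """

    def __init__(
        self,
        segment: Segment | np.ndarray | list,
        order: int | None = None,
        uc: float = UC_DEFAULT,
        fs: float | None = None,
        leak: float | None = None,
    ) -> None:
        if isinstance(segment, (list, tuple)):
            if not segment:
                raise ConfigError("empty trial list")
            first = segment[0]
            if not isinstance(first, Segment):
                raise ConfigError("trial lists must contain Segment objects")
            shapes = {s.data.shape for s in segment}
            if len(shapes) > 1 or any(s.fs != first.fs for s in segment):
                raise ConfigError("all trials must share shape and sampling rate")
            self.trials = np.stack([s.data for s in segment])
            self.fs = first.fs
            self.channel_labels = first.channel_labels
            self.t0_index = first.t0_index
        elif isinstance(segment, Segment):
            self.trials = segment.data[None, :, :]
            self.fs = segment.fs
            self.channel_labels = segment.channel_labels
            self.t0_index = segment.t0_index
        else:
            self.trials = np.asarray(segment, dtype=float)[None, :, :]
            self.fs = float(fs) if fs is not None else 1.0
            self.channel_labels = None
            self.t0_index = 0
        if not 0.0 < uc < 1.0:
            raise ConfigError(f"update constant must lie in (0, 1), got {uc}")
        self.uc = float(uc)
        if order is None:
            sels = [select_order(tr).selected for tr in self.trials]
            order = sorted(sels)[(len(sels) - 1) // 2]
        if order < 1 or order >= self.trials.shape[2]:
            raise ConfigError(
                f"order {order} invalid for {self.trials.shape[2]} samples"
            )
        self.order = int(order)
        self.leak = 0.0 if leak is None else float(leak)
        if not 0.0 <= self.leak < 1.0:
            raise ConfigError(f"leak must lie in [0, 1), got {self.leak}")
        self.aic_result: AICResult | None = None

    @property
    def data(self) -> np.ndarray:
        """Channels-x-samples data of the (first) trial."""
        return self.trials[0]

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @classmethod
    def from_segment(
        cls, seg: Segment, order: int | None = None, uc: float = UC_DEFAULT
    ) -> "TimeVaryingVAR":
        return cls(seg, order=order, uc=uc)

    @classmethod
    def from_segments(
        cls, segs: list, order: int | None = None, uc: float = UC_DEFAULT,
        leak: float | None = None,
    ) -> "TimeVaryingVAR":
        """Build an ensemble (multi-trial) model from peak-aligned segments."""
        return cls(list(segs), order=order, uc=uc, leak=leak)

    def fit(self) -> TimeVaryingVARResults:
        """Run the Kalman coefficient tracker and return the results object."""
        from ._kalman import kalman_filter

        trials = self.trials
        K, M, N = trials.shape
        p, uc = self.order, self.uc
        var0 = np.maximum(trials.var(axis=2).mean(axis=0), 1e-12)
        coeffs_flat, resid_cov, innov, t_div = kalman_filter(
            np.ascontiguousarray(trials, dtype=float), p, uc, self.leak, var0
        )
        if t_div >= 0:
            raise NumericalError(f"Kalman filter diverged at sample {t_div}")
        # (N, M, M*p) -> (N, p, M, M): state row i holds [A_1 ... A_p][i, :]
        coeffs = coeffs_flat.reshape(N, M, p, M).transpose(0, 2, 1, 3)
        valid = np.zeros(N, dtype=bool)
        valid[p:] = True
        innovations = innov[:, 0, :] if K == 1 else innov
        return TimeVaryingVARResults(
            order=p,
            uc=uc,
            fs=self.fs,
            coeffs=coeffs,
            residual_cov=resid_cov,
            valid=valid,
            channel_labels=self.channel_labels,
            t0_index=self.t0_index,
            innovations=innovations,
        )


def fit_kalman(
    seg: Segment | np.ndarray,
    p: int,
    uc: float = UC_DEFAULT,
    leak: float | None = None,
) -> TimeVaryingVARResults:
    """Functional front-end: Kalman-track a tv-MVAR of order ``p`` on ``seg``."""
    return TimeVaryingVAR(seg, order=p, uc=uc, leak=leak).fit()
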