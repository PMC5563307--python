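"""Epileptogenic-zone localization from binary dynamic networks.

The out-degree of each electrode at each time point counts its significant
outgoing edges; the out-degree matrix is binarized at a threshold (default:
1 iff out-degree > 3) and the epileptogenic-zone electrode is identified as
the earliest electrode to show sustained strong outflow, excluding the
electrodes whose outflow is already part of the pre-discharge background
pattern.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .surrogate import BinaryDynamicNetwork

__all__ = [
    "OutDegreeMatrix",
    "BinarizedOutDegree",
    "LocalizationResult",
    "PatientLocalization",
    "out_degree_matrix",
    "binarize",
    "identify_background",
    "locate_ez",
    "aggregate_patient",
]

logger = logging.getLogger(__name__)

OUT_DEGREE_THRESHOLD_DEFAULT = 3
BASELINE_S_DEFAULT = 1.0
BASELINE_FRACTION_DEFAULT = 0.5
MIN_DURATION_DEFAULT = 2


@dataclass
class OutDegreeMatrix:
    """Integer out-degree per (node, time); times relative to the peak."""

    k: np.ndarray  # (n_nodes, n_times)
    channel_labels: list[str]
    times: np.ndarray

    def to_csv(self, path: str | Path) -> Path:
        df = pd.DataFrame(self.k.T, columns=self.channel_labels)
        df.insert(0, "time_s", self.times)
        df.to_csv(path, index=False)
        return Path(path)


@dataclass
class BinarizedOutDegree:
    """Thresholded out-degree matrix (same layout as :class:`OutDegreeMatrix`)."""

    b: np.ndarray
    threshold: int
    comparison: str
    channel_labels: list[str]
    times: np.ndarray
    source: OutDegreeMatrix | None = None

    def to_csv(self, path: str | Path) -> Path:
        df = pd.DataFrame(self.b.T.astype(int), columns=self.channel_labels)
        df.insert(0, "time_s", self.times)
        df.to_csv(path, index=False)
        return Path(path)


@dataclass
class LocalizationResult:
    """Identified epileptogenic-zone electrode for one segment."""

    electrode: str | None
    onset_index: int | None
    onset_time: float | None
    background: set[str]
    ties: list[str] = field(default_factory=list)

    @property
    def localizable(self) -> bool:
        return self.electrode is not None

    def to_dict(self) -> dict:
        return {
            "electrode": self.electrode,
            "onset_index": self.onset_index,
            "onset_time_s": self.onset_time,
            "background": sorted(self.background),
            "ties": list(self.ties),
            "localizable": self.localizable,
        }


def out_degree_matrix(net: BinaryDynamicNetwork) -> OutDegreeMatrix:
    """Count outgoing edges per node and time (self-edges excluded)."""
    k = net.adj.sum(axis=2).T.astype(int)  # (sender, time)
    labels = net.channel_labels or [f"ch{i}" for i in range(net.n_nodes)]
    return OutDegreeMatrix(k=k, channel_labels=list(labels), times=net.times)


def binarize(
    k: OutDegreeMatrix,
    threshold: int = OUT_DEGREE_THRESHOLD_DEFAULT,
    comparison: str = "greater",
) -> BinarizedOutDegree:
    """Binarize the out-degree matrix.

    ``comparison="greater"`` sets 1 iff k > threshold (the strict reading of
    the localization procedure); ``"greater_equal"`` sets 1 iff k >= threshold.
    """
    if threshold < 0:
        raise ConfigError("threshold must be >= 0")
    if comparison == "greater":
        b = k.k > threshold
    elif comparison == "greater_equal":
        b = k.k >= threshold
    else:
        raise ConfigError(f"unknown comparison {comparison!r}")
    return BinarizedOutDegree(
        b=b, threshold=threshold, comparison=comparison,
        channel_labels=list(k.channel_labels), times=k.times, source=k,
    )


def _default_baseline(times: np.ndarray, baseline_s: float) -> np.ndarray:
    """Indices of the first ``baseline_s`` seconds of the available grid."""
    return np.flatnonzero(times < times[0] + baseline_s)


def identify_background(
    b: BinarizedOutDegree,
    baseline_window: np.ndarray | tuple[int, int] | None = None,
    min_fraction: float = BASELINE_FRACTION_DEFAULT,
    baseline_s: float = BASELINE_S_DEFAULT,
) -> set[str]:
    """Electrodes whose strong outflow is already part of the baseline pattern.

    A channel is background iff its binarized out-degree is 1 in at least
    ``min_fraction`` of the baseline-window time points (default: the first
    second of the segment's analyzed grid, which precedes the discharge peak).
    """
    if baseline_window is None:
        idx = _default_baseline(b.times, baseline_s)
    elif isinstance(baseline_window, tuple):
        idx = np.arange(*baseline_window)
    else:
        idx = np.asarray(baseline_window, dtype=int)
    if idx.size == 0:
        raise ConfigError("baseline window is empty")
    if b.times[idx].max() >= 0:
        raise ConfigError("baseline window must precede the discharge peak")
    frac = b.b[:, idx].mean(axis=1)
    return {lab for lab, f in zip(b.channel_labels, frac) if f >= min_fraction}


def _first_run(row: np.ndarray, start: int, min_duration: int) -> tuple[int, int] | None:
    """First (onset, run_length) with run_length >= min_duration at or after start."""
    active = np.flatnonzero(row[start:]) + start
    if active.size == 0:
        return None
    # split into consecutive runs
    breaks = np.flatnonzero(np.diff(active) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [active.size - 1]))
    for s, e in zip(starts, ends):
        if e - s + 1 >= min_duration:
            return int(active[s]), int(e - s + 1)
    return None


def locate_ez(
    b: BinarizedOutDegree,
    background: set[str],
    min_duration: int = MIN_DURATION_DEFAULT,
    scan_start: int | None = None,
    baseline_s: float = BASELINE_S_DEFAULT,
    anchor_time: float | None = None,
    onset_tolerance: int = 0,
) -> LocalizationResult:
    """Earliest non-background electrode with sustained strong outflow.

    Scanning forward from the end of the baseline window, the first
    non-background channel whose binarized out-degree stays 1 for at least
    ``min_duration`` consecutive points wins.  Channels whose onsets fall
    within ``onset_tolerance`` samples of the earliest onset count as
    co-earliest: they are reported in ``ties`` and broken by longer sustained
    activation, then by larger total out-degree over the activation run
    (``onset_tolerance=0`` keeps only exact ties).

    With ``anchor_time`` set (seconds on the segment's time axis, normally
    0.0 = the labeled discharge peak), only activation runs still active at
    that instant qualify: the electrode sought is the source *of the labeled
    discharge*, so an outflow episode that dies out before the discharge is
    treated as unrelated background fluctuation.
    """
    candidates = [lab for lab in b.channel_labels if lab not in background]
    if not candidates:
        raise ConfigError("no non-background channel to localize from")
    if scan_start is None:
        base = _default_baseline(b.times, baseline_s)
        scan_start = int(base[-1]) + 1 if base.size else 0
    anchor_idx = None
    if anchor_time is not None:
        anchor_idx = int(np.searchsorted(b.times, anchor_time))
    hits = []  # (onset, -run, -total_k, label)
    for lab in candidates:
        ch = b.channel_labels.index(lab)
        start = scan_start
        while True:
            run = _first_run(b.b[ch], start, min_duration)
            if run is None:
                break
            onset, length = run
            if anchor_idx is not None and onset + length <= anchor_idx:
                start = onset + length  # run dies before the anchor; skip it
                continue
            total_k = (
                int(b.source.k[ch, onset : onset + length].sum())
                if b.source is not None
                else length
            )
            hits.append((onset, -length, -total_k, lab))
            break
    if not hits:
        logger.info("no channel ever shows sustained strong outflow")
        return LocalizationResult(None, None, None, set(background))
    hits.sort()
    first_onset = hits[0][0]
    window = [h for h in hits if h[0] <= first_onset + onset_tolerance]
    best = min(window, key=lambda h: (h[1], h[2], h[0], h[3]))
    co_earliest = [h[3] for h in window]
    return LocalizationResult(
        electrode=best[3],
        onset_index=best[0],
        onset_time=float(b.times[best[0]]),
        background=set(background),
        ties=co_earliest if len(co_earliest) > 1 else [],
    )


@dataclass
class PatientLocalization:
    """Majority-vote aggregation of per-segment localizations."""

    electrode: str | None
    votes: dict[str, int]
    ties: list[str]
    n_segments: int
    segment_results: list[LocalizationResult]

    @property
    def localizable(self) -> bool:
        return self.electrode is not None

    def to_dict(self) -> dict:
        return {
            "electrode": self.electrode,
            "votes": dict(sorted(self.votes.items())),
            "ties": list(self.ties),
            "n_segments": self.n_segments,
            "localizable": self.localizable,
            "segments": [r.to_dict() for r in self.segment_results],
        }

    def to_json(self, path: str | Path) -> Path:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))
        return Path(path)

    def summary(self) -> str:
        """Human-readable per-patient localization report."""
        lines = ["Epileptogenic-zone localization", "=" * 40]
        if self.electrode is not None:
            lines.append(f"identified electrode:  {self.electrode}")
        elif self.ties:
            lines.append(f"tied candidates:       {', '.join(self.ties)}")
        else:
            lines.append("identified electrode:  (not localizable)")
        lines.append(f"discharge epochs:      {self.n_segments}")
        if self.votes:
            votes = ", ".join(f"{k}: {v}" for k, v in sorted(self.votes.items()))
            lines.append(f"votes:                 {votes}")
        for i, r in enumerate(self.segment_results):
            onset = f"{r.onset_time:+.3f} s" if r.onset_time is not None else "-"
            bg = ", ".join(sorted(r.background)) or "(none)"
            lines.append(
                f"  result {i}: electrode {r.electrode or '-'}, onset {onset}, "
                f"background [{bg}]"
            )
        return "\n".join(lines)

    def to_text(self, path: str | Path) -> Path:
        Path(path).write_text(self.summary() + "\n")
        return Path(path)


def aggregate_patient(results: list[LocalizationResult]) -> PatientLocalization:
    """Majority vote over segment-level electrodes; ties reported, not broken."""
    if not results:
        raise ValueError("need at least one segment result")
    votes = Counter(r.electrode for r in results if r.electrode is not None)
    if not votes:
        return PatientLocalization(None, {}, [], len(results), list(results))
    top = max(votes.values())
    leaders = sorted(lab for lab, c in votes.items() if c == top)
    electrode = leaders[0] if len(leaders) == 1 else None
    return PatientLocalization(
        electrode=electrode,
        votes=dict(votes),
        ties=leaders if len(leaders) > 1 else [],
        n_segments=len(results),
        segment_results=list(results),
    )
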