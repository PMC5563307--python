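"""Shared fixtures: deterministic RNGs and small synthetic datasets."""

from __future__ import annotations

import numpy as np
import pytest

from eznet import Segment, make_fixture
from eznet.simulate import companion_spectral_radius


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def stable_var(rng: np.random.Generator, m: int, p: int, scale: float = 0.3,
               target_radius: float = 0.9) -> np.ndarray:
    """Random VAR coefficient tensor rescaled to a stable companion radius."""
    A = rng.normal(scale=scale, size=(p, m, m))
    rho = companion_spectral_radius(A)
    if rho >= target_radius:
        A *= target_radius / rho
    return A


def simulate_var(A: np.ndarray, n: int, rng: np.random.Generator,
                 burn: int = 200) -> np.ndarray:
    """Direct VAR simulation (channels x samples), unit-variance innovations."""
    p, m, _ = A.shape
    x = np.zeros((m, n + burn))
    e = rng.standard_normal((m, n + burn))
    for t in range(p, n + burn):
        acc = e[:, t].copy()
        for k in range(p):
            acc += A[k] @ x[:, t - k - 1]
        x[:, t] = acc
    return x[:, burn:]


@pytest.fixture(scope="session")
def null_fixture(tmp_path_factory):
    """Files of the 16-channel independent-noise preset (seed 0)."""
    outdir = tmp_path_factory.mktemp("nullfx")
    edf, events, truth, gt = make_fixture("null_independent", 0, outdir)
    return {"edf": edf, "events": events, "truth": truth, "gt": gt}


@pytest.fixture(scope="session")
def planted_fixture(tmp_path_factory):
    """Files of the 16-channel planted-source preset (seed 0)."""
    outdir = tmp_path_factory.mktemp("plantedfx")
    edf, events, truth, gt = make_fixture("full16_planted_source", 0, outdir)
    return {"edf": edf, "events": events, "truth": truth, "gt": gt}


def make_segment(data: np.ndarray, fs: float = 32.0,
                 labels: list | None = None) -> Segment:
    data = np.asarray(data, dtype=float)
    return Segment(data, fs, data.shape[-1] // 2, channel_labels=labels)
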