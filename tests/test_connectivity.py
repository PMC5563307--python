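"""Spectral transfer, ADTF normalization, band integration, outflow."""

import numpy as np
import pytest

from eznet import (
    TimeVaryingVAR,
    coeff_to_spectrum,
    fit_kalman,
    integrated_adtf,
    normalized_adtf,
    total_outflow,
)
from eznet.connectivity import default_freq_grid
from eznet.exceptions import ConfigError
from eznet.var import TimeVaryingVARResults

from conftest import make_segment, simulate_var, stable_var


def results_from_coeffs(A, fs=32.0, n_t=4):
    """Wrap constant true coefficients as a results object (no fitting)."""
    A = np.asarray(A, dtype=float)
    p, m, _ = A.shape
    coeffs = np.tile(A, (n_t + p, 1, 1, 1))
    coeffs[:p] = np.nan
    valid = np.ones(n_t + p, dtype=bool)
    valid[:p] = False
    return TimeVaryingVARResults(
        order=p, uc=1e-3, fs=fs, coeffs=coeffs,
        residual_cov=np.tile(np.eye(m), (n_t + p, 1, 1)), valid=valid,
    )


class TestSpectralTransfer:
    def test_zero_coefficient_gives_identity_transfer(self):
        st = results_from_coeffs(np.zeros((1, 1, 1))).spectral_transfer()
        assert np.allclose(st.A_f, 1.0)
        assert np.allclose(st.H, 1.0)

    @pytest.mark.parametrize("f", [1.0, 8.0, 15.0])
    def test_scalar_ar1_matches_closed_form(self, f):
        st = results_from_coeffs(np.full((1, 1, 1), 0.5), fs=32.0).spectral_transfer(
            np.array([f])
        )
        expect = 1.0 / abs(1.0 - 0.5 * np.exp(-2j * np.pi * f / 32.0)) ** 2
        assert np.allclose(np.abs(st.H[0, 0, 0, 0]) ** 2, expect, rtol=1e-12)

    def test_diagonal_var_gives_diagonal_transfer(self, rng):
        A = np.zeros((2, 3, 3))
        A[0] = np.diag([0.5, -0.3, 0.2])
        A[1] = np.diag([0.2, 0.1, -0.4])
        st = results_from_coeffs(A).spectral_transfer()
        off = ~np.eye(3, dtype=bool)
        assert np.abs(st.H[..., off]).max() < 1e-12

    def test_frequency_grid_validated(self):
        res = results_from_coeffs(np.zeros((1, 2, 2)))
        with pytest.raises(ConfigError):
            res.spectral_transfer(np.array([20.0]))  # above Nyquist for fs=32
        with pytest.raises(ConfigError):
            res.spectral_transfer(np.array([3.0, 2.0]))


class TestNormalizedADTF:
    def test_diagonal_transfer_gives_identity_rows(self):
        A = np.zeros((1, 3, 3))
        np.fill_diagonal(A[0], [0.5, 0.2, -0.3])
        st = results_from_coeffs(A).spectral_transfer()
        g = normalized_adtf(st)
        eye = np.eye(3)
        assert np.allclose(g, np.broadcast_to(eye, g.shape), atol=1e-12)

    def test_equal_magnitudes_split_half(self):
        # receiver row with two equal |H| entries -> 0.5 each
        A = np.zeros((1, 2, 2))
        A[0, 1, 0] = 0.5  # flow 0 -> 1
        st = results_from_coeffs(A).spectral_transfer(np.array([8.0]))
        H = st.H.copy()
        H[..., 1, 0] = H[..., 1, 1]  # force equal magnitudes in row 1
        st.H = H
        g = normalized_adtf(st)
        assert np.allclose(g[..., 1, 0], 0.5) and np.allclose(g[..., 1, 1], 0.5)

    def test_rowsums_one_over_random_stable_models(self, rng):
        for _ in range(20):
            res = results_from_coeffs(stable_var(rng, 3, 2))
            g = normalized_adtf(res.spectral_transfer())
            assert np.abs(g.sum(axis=-1) - 1.0).max() < 1e-10


class TestBandIntegration:
    def test_constant_gamma_integrates_to_itself(self):
        freqs = default_freq_grid(32.0)
        g = np.full((3, freqs.size, 2, 2), 0.37)
        q = integrated_adtf(g, freqs, (0.5, 14.5))
        assert np.allclose(q, 0.37)

    def test_diagonal_gamma_stays_diagonal(self):
        freqs = default_freq_grid(32.0)
        g = np.zeros((2, freqs.size, 3, 3))
        g[..., np.arange(3), np.arange(3)] = 1.0
        q = integrated_adtf(g, freqs, (0.5, 14.5))
        assert np.allclose(q, np.eye(3))

    def test_bin_count_divisor_matches_literal_on_1hz_grid(self, rng):
        freqs = np.arange(1.0, 15.0 + 1e-9, 1.0)  # 1 Hz spacing, 14 bins in band
        res = results_from_coeffs(stable_var(rng, 2, 2))
        g = normalized_adtf(coeff_to_spectrum(res, freqs))
        band = (1.0, 15.0)
        q_bins = integrated_adtf(g, freqs, band)
        mask = (freqs >= band[0]) & (freqs <= band[1])
        q_literal = g[:, mask].sum(axis=1) / (band[1] - band[0])
        n_bins = mask.sum()
        assert np.allclose(q_bins * n_bins, q_literal * (band[1] - band[0]))
        # within one part in the bin count of each other
        assert np.abs(q_bins - q_literal).max() <= q_literal.max() / n_bins + 1e-12

    def test_empty_band_rejected(self):
        with pytest.raises(ConfigError):
            integrated_adtf(np.zeros((1, 3, 2, 2)), np.array([1.0, 2.0, 3.0]),
                            (20.0, 30.0))


class TestOutflow:
    def test_no_offdiagonal_flow_means_zero_outflow(self):
        q = np.broadcast_to(np.eye(4), (5, 4, 4))
        assert np.allclose(total_outflow(q), 0.0)

    def test_column_mean_arithmetic(self):
        q = np.zeros((1, 3, 3))
        q[0, 1, 0], q[0, 2, 0] = 0.4, 0.2  # node 0 sends 0.4 and 0.2
        assert np.isclose(total_outflow(q)[0, 0], 0.3)

    def test_single_node_rejected(self):
        with pytest.raises(ValueError):
            total_outflow(np.ones((2, 1, 1)))

    def test_driver_has_largest_outflow(self, rng):
        A = np.zeros((1, 3, 3))
        A[0] = np.diag([0.4, 0.3, 0.3])
        A[0, 1, 0] = 0.5
        A[0, 2, 0] = 0.5  # channel 0 drives 1 and 2
        x = simulate_var(A, 1500, rng)
        res = fit_kalman(make_segment(x), 1, uc=5e-3)
        conn = res.connectivity()
        mean_out = np.nanmean(conn.outflow[750:], axis=0)
        assert mean_out[0] > mean_out[1] and mean_out[0] > mean_out[2]


class TestDecoupledAndStationary:
    def test_block_diagonal_model_has_zero_cross_block_values(self, rng):
        A = np.zeros((2, 3, 3))
        A[:, :2, :2] = stable_var(rng, 2, 2)
        A[0, 2, 2] = 0.5  # singleton block
        conn = results_from_coeffs(A).connectivity()
        assert np.abs(conn.gamma2[..., :2, 2]).max() < 1e-12
        assert np.abs(conn.gamma2[..., 2, :2]).max() < 1e-12
        assert np.abs(conn.Q2[..., :2, 2]).max() < 1e-12
        assert np.abs(conn.outflow[..., 2]).max() < 1e-12

    def test_fitted_adtf_approaches_truth_on_stationary_data(self, rng):
        A = np.zeros((1, 2, 2))
        A[0] = [[0.5, 0.0], [0.5, 0.3]]
        x = simulate_var(A, 3000, rng)
        res = fit_kalman(make_segment(x), 1, uc=2e-3)
        fitted = res.connectivity()
        truth = results_from_coeffs(A).connectivity()
        est = np.nanmean(fitted.Q2[1500:], axis=0)
        assert np.abs(est - truth.Q2[-1]).max() < 0.1


class TestExports:
    def test_q2_long_csv_round_trips_values(self, rng, tmp_path):
        import pandas as pd

        conn = results_from_coeffs(stable_var(rng, 2, 1), n_t=3).connectivity()
        path = conn.q2_to_csv(tmp_path / "q2.csv")
        df = pd.read_csv(path)
        assert set(df.columns) == {"time_s", "sender", "receiver", "value"}
        row = df[(df.sender == "ch0") & (df.receiver == "ch1")].iloc[0]
        assert np.isclose(row.value, conn.Q2[0, 1, 0])

    def test_container_round_trips_band_integrated_values(self, rng, tmp_path):
        from eznet import DynamicConnectivity

        conn = results_from_coeffs(stable_var(rng, 2, 1), n_t=3).connectivity()
        conn.save(tmp_path / "conn")
        back = DynamicConnectivity.load(tmp_path / "conn")
        assert np.allclose(back.Q2, conn.Q2)
        assert np.allclose(back.outflow, conn.outflow)
        assert back.band == conn.band
        assert back.gamma2 is None
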