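"""Out-degree, binarization, background exclusion and EZ identification."""

import numpy as np
import pytest

from eznet import (
    BinaryDynamicNetwork,
    LocalizationResult,
    aggregate_patient,
    binarize,
    identify_background,
    locate_ez,
    out_degree_matrix,
)
from eznet.exceptions import ConfigError
from eznet.localize import BinarizedOutDegree, OutDegreeMatrix

LABELS16 = [
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4",
    "O1", "O2", "F7", "F8", "T3", "T4", "T5", "T6",
]


def net_from_adj(adj, labels=None):
    adj = np.asarray(adj, dtype=np.int8)
    n_t = adj.shape[0]
    labels = labels or [f"ch{i}" for i in range(adj.shape[1])]
    times = (np.arange(n_t) - n_t // 2) / 32.0
    return BinaryDynamicNetwork(
        adj=adj, alpha=0.01, times=times,
        time_indices=np.arange(n_t), channel_labels=labels,
    )


def binarized(b, times=None, k=None, labels=None):
    b = np.asarray(b, dtype=bool)
    n_ch, n_t = b.shape
    labels = labels or LABELS16[:n_ch]
    if times is None:
        times = (np.arange(n_t) - n_t // 2) / 32.0
    src = None
    if k is not None:
        src = OutDegreeMatrix(np.asarray(k), list(labels), times)
    return BinarizedOutDegree(b, 3, "greater", list(labels), np.asarray(times), src)


class TestOutDegree:
    def test_complete_network_gives_n_minus_1(self):
        adj = np.ones((4, 16, 16), dtype=np.int8)
        adj[:, np.arange(16), np.arange(16)] = 0
        k = out_degree_matrix(net_from_adj(adj))
        assert (k.k == 15).all()

    def test_empty_network_gives_zero(self):
        assert out_degree_matrix(net_from_adj(np.zeros((3, 5, 5)))).k.sum() == 0

    def test_counts_outgoing_edges(self):
        adj = np.zeros((8, 6, 6), dtype=np.int8)
        adj[7, 2, [1, 3, 5]] = 1
        k = out_degree_matrix(net_from_adj(adj))
        assert k.k[2, 7] == 3 and k.k.sum() == 3

    def test_degree_sum_equals_edge_count(self, rng):
        adj = (rng.random((10, 8, 8)) < 0.3).astype(np.int8)
        adj[:, np.arange(8), np.arange(8)] = 0
        k = out_degree_matrix(net_from_adj(adj))
        assert np.array_equal(k.k.sum(axis=0), adj.sum(axis=(1, 2)))


class TestBinarize:
    def test_boundary_value_three(self):
        k = OutDegreeMatrix(np.array([[3]]), ["A"], np.array([0.0]))
        assert binarize(k, 3, "greater").b[0, 0] == False  # noqa: E712
        assert binarize(k, 3, "greater_equal").b[0, 0] == True  # noqa: E712

    def test_large_value_passes_either_comparison(self):
        k = OutDegreeMatrix(np.array([[15]]), ["A"], np.array([0.0]))
        assert binarize(k, 3, "greater").b[0, 0]
        assert binarize(k, 3, "greater_equal").b[0, 0]

    def test_raising_threshold_is_monotone(self, rng):
        k = OutDegreeMatrix(
            rng.integers(0, 10, size=(6, 40)), LABELS16[:6],
            np.arange(40) / 32.0,
        )
        lo = binarize(k, 2).b
        hi = binarize(k, 5).b
        assert np.all(hi <= lo)

    def test_unknown_comparison_rejected(self):
        k = OutDegreeMatrix(np.zeros((1, 1), int), ["A"], np.array([0.0]))
        with pytest.raises(ConfigError):
            binarize(k, 3, "less")


class TestBackground:
    def test_channel_active_through_baseline_is_background(self):
        b = np.zeros((3, 96), dtype=bool)
        b[0, :] = True  # active everywhere, including baseline
        b[1, 60:] = True  # active only later
        bg = identify_background(binarized(b))
        assert bg == {"Fp1"}

    def test_all_silent_baseline_gives_empty_set(self):
        bg = identify_background(binarized(np.zeros((4, 96), dtype=bool)))
        assert bg == set()

    def test_window_must_precede_peak(self):
        b = binarized(np.zeros((2, 10), dtype=bool),
                      times=np.linspace(0.5, 1.0, 10))
        with pytest.raises(ConfigError):
            identify_background(b)

    def test_fraction_threshold_respected(self):
        b = np.zeros((2, 96), dtype=bool)
        base = 32  # baseline = first second = 32 samples
        b[0, : base // 2 + 2] = True  # just above half
        b[1, : base // 2 - 2] = True  # just below half
        bg = identify_background(binarized(b), min_fraction=0.5)
        assert bg == {"Fp1"}


class TestLocateEZ:
    def test_earliest_activating_channel_wins(self):
        b = np.zeros((16, 192), dtype=bool)
        b[LABELS16.index("O1"), :] = True  # background throughout
        b[LABELS16.index("F7"), 140:160] = True
        b[LABELS16.index("T3"), 150:170] = True
        mat = binarized(b)
        bg = identify_background(mat)
        res = locate_ez(mat, bg)
        assert bg == {"O1"}
        assert res.electrode == "F7"
        assert res.onset_index == 140
        assert res.ties == []

    def test_constructed_onset_at_index_40(self):
        b = np.zeros((16, 192), dtype=bool)
        b[LABELS16.index("O1"), :] = True
        b[LABELS16.index("F7"), 40:60] = True
        mat = binarized(b)
        res = locate_ez(mat, {"O1"}, scan_start=0)
        assert res.electrode == "F7" and res.onset_index == 40

    def test_same_onset_longer_run_wins_and_both_reported(self):
        b = np.zeros((4, 192), dtype=bool)
        b[1, 100:102] = True  # 2 points
        b[2, 100:110] = True  # 10 points
        mat = binarized(b, labels=["A", "B", "C", "D"])
        res = locate_ez(mat, set())
        assert res.electrode == "C"
        assert set(res.ties) == {"B", "C"}

    def test_equal_runs_broken_by_total_out_degree(self):
        b = np.zeros((3, 192), dtype=bool)
        b[0, 100:105] = True
        b[1, 100:105] = True
        k = np.zeros((3, 192), dtype=int)
        k[0, 100:105] = 4
        k[1, 100:105] = 9
        mat = binarized(b, k=k, labels=["A", "B", "C"])
        assert locate_ez(mat, set()).electrode == "B"

    def test_short_blips_are_ignored(self):
        b = np.zeros((2, 192), dtype=bool)
        b[0, 100] = True  # single-sample blip
        b[1, 120:130] = True
        mat = binarized(b, labels=["A", "B"])
        res = locate_ez(mat, set(), min_duration=2)
        assert res.electrode == "B"

    def test_never_active_yields_not_localizable(self):
        mat = binarized(np.zeros((3, 192), dtype=bool), labels=["A", "B", "C"])
        res = locate_ez(mat, set())
        assert not res.localizable and res.electrode is None

    def test_all_background_is_an_error(self):
        mat = binarized(np.ones((2, 192), dtype=bool), labels=["A", "B"])
        with pytest.raises(ConfigError):
            locate_ez(mat, {"A", "B"})

    def test_anchored_search_skips_runs_that_die_before_peak(self):
        b = np.zeros((2, 192), dtype=bool)
        b[0, 40:60] = True  # early run, dies long before the peak (index 96)
        b[0, 100:140] = True  # later run, after the peak
        b[1, 90:130] = True  # spans the peak
        mat = binarized(b, labels=["A", "B"])
        free = locate_ez(mat, set(), scan_start=0)
        anchored = locate_ez(mat, set(), scan_start=0, anchor_time=0.0)
        assert free.electrode == "A" and free.onset_index == 40
        assert anchored.electrode == "B" and anchored.onset_index == 90

    def test_onset_tolerance_prefers_stronger_near_tie(self):
        b = np.zeros((2, 192), dtype=bool)
        b[0, 100:110] = True  # earlier but short
        b[1, 104:180] = True  # 4 samples later, much longer
        mat = binarized(b, labels=["A", "B"])
        strict = locate_ez(mat, set())
        lenient = locate_ez(mat, set(), onset_tolerance=6)
        assert strict.electrode == "A"
        assert lenient.electrode == "B"
        assert set(lenient.ties) == {"A", "B"}

    def test_result_invariant_under_channel_permutation(self, rng):
        b = rng.random((6, 192)) < 0.1
        b[3, 120:160] = True
        labels = ["A", "B", "C", "D", "E", "F"]
        mat = binarized(b, labels=labels)
        res = locate_ez(mat, set(), min_duration=8)
        perm = rng.permutation(6)
        mat2 = binarized(b[perm], labels=[labels[i] for i in perm])
        res2 = locate_ez(mat2, set(), min_duration=8)
        assert res.electrode == res2.electrode


class TestAggregation:
    def _loc(self, lab):
        return LocalizationResult(lab, 10, 0.1, set())

    def test_majority_vote(self):
        pat = aggregate_patient([self._loc("F7"), self._loc("F7"), self._loc("T3")])
        assert pat.electrode == "F7"
        assert pat.votes == {"F7": 2, "T3": 1}

    def test_single_segment_passes_through(self):
        assert aggregate_patient([self._loc("T4")]).electrode == "T4"

    def test_tie_reported_not_broken(self):
        pat = aggregate_patient([self._loc("F7"), self._loc("T3")])
        assert pat.electrode is None
        assert pat.ties == ["F7", "T3"]

    def test_summary_names_electrode_and_votes(self):
        pat = aggregate_patient([self._loc("F7"), self._loc("F7")])
        text = pat.summary()
        assert "F7" in text and "votes" in text

    def test_all_unlocalizable(self):
        pat = aggregate_patient([LocalizationResult(None, None, None, set())])
        assert not pat.localizable and pat.votes == {}
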