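import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from unfoldmap import (
    MIParams,
    ScalarSeries,
    block_scores,
    mi_matrix_direct,
    mi_matrix_rate,
    mutual_information,
    normalize_matrix,
    pairwise_distance_series,
    permutation_null,
    rate_of_change,
    rmsd_from_initial,
    select_pairs,
)
from unfoldmap.mi import MIMatrix, auto_bins, discretize, write_matrix_tsv


def exhaustive_plugin_mi(lx, ly):
    """Independent oracle: dictionary-based plug-in MI over occupied cells."""
    n = len(lx)
    joint = Counter(zip(lx, ly))
    px = Counter(lx)
    py = Counter(ly)
    mi = 0.0
    for (a, b), c in joint.items():
        pj = c / n
        mi += pj * math.log2(pj * n * n / (px[a] * py[b]))
    return mi


PREBINNED = MIParams(n_bins=4, binning="equal_width")


class TestEstimator:
    def test_self_information_of_k_symbols(self):
        x = np.tile([0, 1, 2, 3], 25).astype(float)
        assert mutual_information(x, x, PREBINNED) == pytest.approx(2.0, abs=1e-12)

    def test_perfect_two_symbol_dependence(self):
        x = np.array([0.0] * 5 + [1.0] * 5)
        assert mutual_information(x, x, MIParams(n_bins=2)) == pytest.approx(1.0, abs=1e-12)

    def test_matches_exhaustive_oracle_on_prebinned_data(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            lx = rng.integers(0, 5, size=200)
            ly = (lx + rng.integers(0, 3, size=200)) % 5
            got = mutual_information(lx.astype(float), ly.astype(float), MIParams(n_bins=5, binning="equal_width"))
            assert got == pytest.approx(exhaustive_plugin_mi(lx, ly), abs=1e-12)

    def test_matches_sklearn_on_prebinned_data(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(7)
        lx = rng.integers(0, 6, size=500)
        ly = rng.integers(0, 4, size=500) + (lx > 3)
        got = mutual_information(lx.astype(float), ly.astype(float), MIParams(n_bins=8, binning="equal_width"))
        expected = sklearn_metrics.mutual_info_score(lx, ly) / math.log(2)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_independent_series_near_zero(self):
        rng = np.random.default_rng(123)
        x = rng.random(10_000)
        y = rng.random(10_000)
        assert mutual_information(x, y) < 0.05

    def test_symmetry_and_nonnegativity(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=300)
        y = x + rng.normal(size=300)
        a = mutual_information(x, y)
        b = mutual_information(y, x)
        assert a == b
        assert a >= 0

    def test_constant_series_gives_zero(self):
        x = np.ones(100)
        y = np.arange(100.0)
        assert mutual_information(x, y) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            mutual_information(np.ones(10), np.ones(11))

    @pytest.mark.parametrize("t,expected", [(80, 4), (500, 10), (1000, 14), (5000, 16)])
    def test_auto_bin_rule(self, t, expected):
        assert auto_bins(t) == expected

    def test_equal_frequency_bins_balance_occupancy(self):
        rng = np.random.default_rng(1)
        x = rng.exponential(size=1000)  # heavily skewed
        labels = discretize(x, 10, "equal_frequency")
        counts = np.bincount(labels)
        assert counts.min() >= 90 and counts.max() <= 110


class TestMonotoneInvariance:
    def test_direct_mi_stable_under_monotone_transform_of_order(self, tiny_run):
        traj, _ = tiny_run
        ds = pairwise_distance_series(traj)
        order = rmsd_from_initial(traj)
        warped = ScalarSeries(values=np.exp(order.values / order.values.max()), kind="external")
        m1 = mi_matrix_direct(ds, order).values
        m2 = mi_matrix_direct(ds, warped).values
        # Rank-based binning: identical up to quantile-edge ties.
        mask = m1 > 0
        assert np.all(np.abs(m1[mask] - m2[mask]) / m1[mask] < 0.10)


class TestPermutationNull:
    def test_independent_pair_falls_inside_null(self):
        hits = 0
        reps = 50
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            x = rng.random(500)
            y = rng.random(500)
            obs = mutual_information(x, y)
            null = permutation_null(x, y, MIParams(n_permutations=99, seed=seed))
            if obs < np.quantile(null, 0.95):
                hits += 1
        assert hits >= 0.9 * reps


def _matrix(values, ids=None, normalized=False):
    values = np.asarray(values, dtype=float)
    ids = np.arange(1, len(values) + 1) if ids is None else np.asarray(ids)
    return MIMatrix(values=values, residue_ids=ids, mode="direct_vs_order", normalized=normalized)


class TestMatrixAssembly:
    def test_zero_rates_give_zero_matrix(self, tiny_run):
        traj, _ = tiny_run
        ds = pairwise_distance_series(traj)
        rates = rate_of_change(ds)
        rates.values[:] = 0.0
        act = ScalarSeries(values=np.linspace(0, 1, ds.n_frames), kind="external")
        m = mi_matrix_rate(rates, act)
        np.testing.assert_array_equal(m.values, 0.0)

    def test_planted_rate_pair_attains_maximum(self, tiny_run):
        traj, _ = tiny_run
        ds = pairwise_distance_series(traj)
        rates = rate_of_change(ds)
        rng = np.random.default_rng(0)
        act_values = rng.random(ds.n_frames)
        rates.values[:] = rng.random(rates.values.shape)
        rates.values[3] = act_values[: rates.values.shape[1]]  # plant a dependent pair
        m = mi_matrix_rate(rates, ScalarSeries(values=act_values, kind="external"))
        i, j = rates.pairs[3]
        assert m.values[i, j] == m.values.max()

    def test_matrix_symmetry(self, tiny_run):
        traj, _ = tiny_run
        ds = pairwise_distance_series(traj)
        m = mi_matrix_direct(ds, rmsd_from_initial(traj))
        np.testing.assert_array_equal(m.values, m.values.T)
        assert np.all(np.diag(m.values) == 0)

    def test_constant_distances_give_zero_matrix(self, tiny_run):
        traj, _ = tiny_run
        ds = pairwise_distance_series(traj)
        ds.values[:] = 7.0
        m = mi_matrix_direct(ds, rmsd_from_initial(traj))
        np.testing.assert_array_equal(m.values, 0.0)

    def test_constant_order_parameter_gives_zero_matrix(self, tiny_run):
        traj, _ = tiny_run
        ds = pairwise_distance_series(traj)
        order = ScalarSeries(values=np.ones(ds.n_frames), kind="external")
        np.testing.assert_array_equal(mi_matrix_direct(ds, order).values, 0.0)

    def test_rate_mode_truncates_activity(self, tiny_run):
        traj, _ = tiny_run
        ds = pairwise_distance_series(traj)
        rates = rate_of_change(ds)
        act = ScalarSeries(values=np.linspace(0, 1, ds.n_frames), kind="external")
        m = mi_matrix_rate(rates, act)  # length T works, trimmed to T-1
        assert m.values.shape == (10, 10)
        short = ScalarSeries(values=act.values[: ds.n_frames - 2], kind="external")
        with pytest.raises(ValueError, match="shorter"):
            mi_matrix_rate(rates, short)


class TestNormalizeSelect:
    def test_normalize_scales_max_to_one(self):
        m = _matrix([[0, 0.8], [0.8, 0]])
        norm = normalize_matrix(m)
        assert norm.values.max() == 1.0
        assert norm.normalized

    def test_normalize_all_zero_unchanged(self):
        norm = normalize_matrix(_matrix(np.zeros((3, 3))))
        np.testing.assert_array_equal(norm.values, 0.0)
        assert norm.normalized

    def test_normalize_idempotent(self):
        m = _matrix([[0, 0.4, 0.8], [0.4, 0, 0.2], [0.8, 0.2, 0]])
        once = normalize_matrix(m)
        twice = normalize_matrix(once)
        np.testing.assert_array_equal(once.values, twice.values)

    def test_selection_strictly_above_threshold(self):
        values = np.zeros((40, 40))
        values[8, 35] = values[35, 8] = 0.71
        values[0, 5] = values[5, 0] = 0.2
        values[1, 2] = values[2, 1] = 1.0
        m = _matrix(values, ids=np.arange(1, 41), normalized=True)
        sel = select_pairs(m, 0.7)
        assert sel.pairs == [(2, 3), (9, 36)]
        assert sel.residues == [2, 3, 9, 36]

    def test_threshold_one_gives_empty_selection(self):
        m = normalize_matrix(_matrix([[0, 0.5], [0.5, 0]]))
        assert select_pairs(m, 1.0).pairs == []

    def test_unnormalized_matrix_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            select_pairs(_matrix([[0, 2.0], [2.0, 0]]))


class TestBlockScores:
    def test_identity_block(self):
        values = np.zeros((4, 4))
        values[0, 1] = values[1, 0] = 1.0
        df = block_scores(_matrix(values), [(1, 2), (3, 4)])
        by = {(r.segment_a, r.segment_b): r.mean_mi for r in df.itertuples()}
        assert by[("1-2", "1-2")] == 1.0
        assert by[("3-4", "3-4")] == 0.0
        assert by[("1-2", "3-4")] == 0.0

    def test_uniform_matrix(self):
        values = np.full((4, 4), 0.3)
        df = block_scores(_matrix(values), [(1, 2), (3, 4)])
        assert np.allclose(df["mean_mi"], 0.3)

    def test_cross_interface_exceeds_intra_on_planted_fixture(self, tiny_run):
        traj, _ = tiny_run
        ds = pairwise_distance_series(traj)
        m = normalize_matrix(mi_matrix_direct(ds, rmsd_from_initial(traj)))
        df = block_scores(m, [(1, 5), (6, 10)])
        by = {(r.segment_a, r.segment_b): r.mean_mi for r in df.itertuples()}
        assert by[("1-5", "6-10")] > by[("1-5", "1-5")]
        assert by[("1-5", "6-10")] > by[("6-10", "6-10")]

    @pytest.mark.parametrize("segments", [[(1, 3), (3, 10)], [(1, 4), (7, 10)]])
    def test_bad_partition_rejected(self, segments):
        with pytest.raises(ValueError):
            block_scores(_matrix(np.zeros((10, 10))), segments)


def test_matrix_tsv_header_and_values(tmp_path):
    m = normalize_matrix(_matrix([[0, 0.5], [0.5, 0]], ids=[3, 94]))
    path = tmp_path / "m.tsv"
    write_matrix_tsv(m, path, ["prov"])
    lines = [l for l in path.read_text().splitlines() if not l.startswith("#")]
    assert lines[0].split("\t") == ["residue", "3", "94"]
    assert lines[1].split("\t") == ["3", "0", "1"]


@settings(max_examples=30, derandomize=True)
@given(st.lists(st.floats(-100, 100), min_size=10, max_size=60), st.integers(0, 10))
def test_mi_nonnegative_and_symmetric_property(xs, seed):
    rng = np.random.default_rng(seed)
    x = np.asarray(xs)
    y = rng.normal(size=len(x))
    mi_xy = mutual_information(x, y, MIParams(n_bins=4))
    assert mi_xy >= 0
    assert mi_xy == mutual_information(y, x, MIParams(n_bins=4))
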