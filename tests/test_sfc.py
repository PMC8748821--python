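import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import stepconn as sc
from stepconn import sfc as sfc_mod
from stepconn.errors import DegenerateGraphError, InputError

from _oracles import dfs_walk_counts

PATH_ABC = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
TRIANGLE = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]])


class TestThresholdBinarize:
    def test_single_strongest_edge_survives(self, rng):
        w = rng.uniform(0, 0.5, size=(5, 5))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        w[1, 3] = w[3, 1] = 0.99
        g = sc.threshold_binarize(w, percentile=95)
        assert g.adjacency.sum() == 2
        assert g.adjacency[1, 3] == g.adjacency[3, 1] == 1

    def test_edge_count_at_study_scale(self, rng):
        w = rng.standard_normal((246, 246))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        g = sc.threshold_binarize(w, percentile=95)
        n_pairs = 246 * 245 // 2
        kept = g.adjacency.sum() // 2
        assert abs(kept - round(0.05 * n_pairs)) <= 1

    def test_percentile_zero_gives_complete_graph(self, rng):
        w = rng.random((6, 6))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        g = sc.threshold_binarize(w, percentile=0)
        expected = np.ones((6, 6), dtype=int) - np.eye(6, dtype=int)
        # the minimum-weight edge falls at the cutoff and is dropped
        assert (expected.sum() - g.adjacency.sum()) == 2

    def test_all_equal_weights_degenerate(self):
        w = np.full((4, 4), 0.3)
        np.fill_diagonal(w, 0)
        # off-diagonal all equal: there is no top 5% to keep
        with pytest.raises(DegenerateGraphError):
            sc.threshold_binarize(np.full((4, 4), 0.3) - 0.3 * np.eye(4), percentile=95)

    def test_absolute_ranking_keeps_strong_negative_edges(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = -0.9
        w[2, 3] = w[3, 2] = 0.4
        g_signed = sc.threshold_binarize(w, percentile=80, edge_rank="signed")
        g_abs = sc.threshold_binarize(w, percentile=80, edge_rank="absolute")
        assert g_signed.adjacency[0, 1] == 0
        assert g_abs.adjacency[0, 1] == 1


class TestWalkCounts:
    def test_path_graph_hand_counts(self):
        counts = sc.sfc_walk_counts(PATH_ABC, seeds=[0], max_step=3)
        assert counts.tolist() == [[0, 1, 0], [1, 0, 1], [0, 2, 0]]

    def test_triangle_step_two(self):
        counts = sc.sfc_walk_counts(TRIANGLE, seeds=[0], max_step=2)
        assert counts[1].tolist() == [2, 1, 1]

    def test_step_one_is_sum_of_seed_rows(self, rng):
        a = (rng.random((8, 8)) < 0.4).astype(int)
        a = ((a + a.T) > 0).astype(int)
        np.fill_diagonal(a, 0)
        seeds = [1, 4, 6]
        counts = sc.sfc_walk_counts(a, seeds, max_step=1)
        assert np.array_equal(counts[0], a[seeds].sum(axis=0))

    def test_recursion_a_times_previous(self, rng):
        a = (rng.random((10, 10)) < 0.3).astype(int)
        a = ((a + a.T) > 0).astype(int)
        np.fill_diagonal(a, 0)
        counts = sc.sfc_walk_counts(a, [0, 2], max_step=5)
        for k in range(1, 5):
            assert np.array_equal(counts[k], a @ counts[k - 1])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_exhaustive_enumeration(self, data):
        r = data.draw(st.integers(3, 8))
        density = data.draw(st.floats(0.15, 0.8))
        seed = data.draw(st.integers(0, 2**31 - 1))
        rng = np.random.default_rng(seed)
        a = (rng.random((r, r)) < density).astype(int)
        a = ((a + a.T) > 0).astype(int)
        np.fill_diagonal(a, 0)
        n_seeds = data.draw(st.integers(1, r))
        seeds = rng.permutation(r)[:n_seeds]
        k = data.draw(st.integers(1, 5))
        got = sc.sfc_walk_counts(a, seeds, max_step=k)
        want = dfs_walk_counts(a, seeds, k)
        assert np.array_equal(got.astype(object), want)

    def test_permutation_equivariance(self, rng):
        a = (rng.random((9, 9)) < 0.4).astype(int)
        a = ((a + a.T) > 0).astype(int)
        np.fill_diagonal(a, 0)
        perm = rng.permutation(9)
        seeds = np.array([0, 3])
        base = sc.sfc_walk_counts(a, seeds, max_step=4)
        inv = np.argsort(perm)
        permuted = sc.sfc_walk_counts(a[np.ix_(perm, perm)], inv[seeds], max_step=4)
        assert np.array_equal(permuted, base[:, perm])

    def test_complete_graph_closed_form_beyond_int_range(self):
        """K_n walk counts match the eigenvalue closed form with exact ints."""
        n, k_max = 12, 20
        a = np.ones((n, n), dtype=int) - np.eye(n, dtype=int)
        counts = sc.sfc_walk_counts(a, [0], max_step=k_max)
        for k in range(1, k_max + 1):
            same = ((n - 1) ** k + (n - 1) * (-1) ** k) // n
            other = ((n - 1) ** k - (-1) ** k) // n
            assert counts[k - 1][0] == same
            assert all(counts[k - 1][j] == other for j in range(1, n))
        assert int(counts[-1].max()) > 2**53  # exact-integer path exercised

    def test_empty_seed_set_rejected(self):
        with pytest.raises(InputError, match="empty"):
            sc.sfc_walk_counts(PATH_ABC, [], max_step=2)

    def test_isolated_seed_gives_zero_rows(self):
        a = np.zeros((4, 4), dtype=int)
        a[1, 2] = a[2, 1] = 1
        counts = sc.sfc_walk_counts(a, [0], max_step=3)
        assert np.all(counts == 0)


class TestZNormalize:
    def test_hand_example_population_sd(self):
        z, degenerate = sc.z_normalize_steps(np.array([[0, 1, 2]]))
        assert np.allclose(z, [[-1.22474487, 0.0, 1.22474487]])
        assert degenerate == []

    def test_constant_step_flagged(self):
        z, degenerate = sc.z_normalize_steps(np.array([[1, 1, 1], [0, 1, 2]]))
        assert degenerate == [1]
        assert np.all(z[0] == 0)

    def test_mean_zero_sd_one(self, rng):
        raw = rng.integers(0, 50, size=(5, 30))
        z, _ = sc.z_normalize_steps(raw)
        assert np.allclose(z.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(z.std(axis=1), 1, atol=1e-12)


class TestHubs:
    def test_hand_example(self):
        hubs = sc.detect_hubs(np.array([1.0, 1, 1, 1, 6]), multiplier=1.5)
        assert hubs.tolist() == [4]

    def test_all_equal_degrees_no_hubs(self):
        assert sc.detect_hubs(np.full(6, 2.0)).size == 0

    def test_zero_multiplier_marks_positive_degrees(self):
        hubs = sc.detect_hubs(np.array([0.0, 1.0, 0.0, 2.0]), multiplier=0)
        assert hubs.tolist() == [1, 3]

    def test_negative_degrees_rejected(self):
        with pytest.raises(InputError, match="non-negative"):
            sc.detect_hubs(np.array([-1.0, 2.0]))


class TestRunSFC:
    def _random_fc(self, rng, r=20):
        w = rng.standard_normal((r, r))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        return w

    def test_identical_subjects_identical_results(self, rng):
        w = self._random_fc(rng)
        results, failures = sc.run_sfc_cohort({"a": w, "b": w.copy()}, [0, 1])
        assert not failures
        assert np.array_equal(results["a"].raw_counts, results["b"].raw_counts)
        assert np.array_equal(results["a"].z_counts, results["b"].z_counts)

    def test_step_one_equals_thresholded_seed_connectivity(self, rng):
        """The first step reproduces conventional binarised seed connectivity."""
        w = self._random_fc(rng)
        seeds = [2, 5]
        res = sc.run_sfc_subject(w, seeds, percentile=90, max_step=1)
        graph = sc.threshold_binarize(w, percentile=90)
        assert np.array_equal(res.raw_counts[0], graph.adjacency[seeds].sum(axis=0))

    def test_longer_run_preserves_prefix(self, rng):
        w = self._random_fc(rng)
        r5 = sc.run_sfc_subject(w, [0], max_step=5)
        r6 = sc.run_sfc_subject(w, [0], max_step=6)
        assert np.array_equal(r6.raw_counts[:5], r5.raw_counts)

    def test_per_subject_failures_collected(self, rng):
        degenerate = np.zeros((6, 6))
        results, failures = sc.run_sfc_cohort(
            {"ok": self._random_fc(rng, 6), "bad": degenerate}, [0]
        )
        assert "ok" in results
        assert "bad" in failures and "DegenerateGraphError" in failures["bad"]

    def test_hub_basis_shifted_z(self, rng):
        res = sc.run_sfc_subject(self._random_fc(rng), [0, 1], max_step=3)
        hubs = res.hubs(step=1)
        d = res.z_counts[0] - res.z_counts[0].min()
        assert np.array_equal(hubs, np.flatnonzero(d > 1.5 * d.mean()))
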