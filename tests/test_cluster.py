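"""Cluster-permutation engine against independent oracles, plus effect sizes."""

import numpy as np
import pytest
from scipy import stats

from somnolearn import cluster as cl
from somnolearn import simulate as sim

import _oracles


def _times(n):
    return np.arange(float(n))


class TestEngineVsBruteForce:
    @pytest.mark.parametrize("seed", range(4))
    def test_exact_enumeration_matches_loop_oracle(self, seed):
        """For n <= 7 the engine's exhaustive sign-flip p equals a naive
        loop-based enumeration, cluster by cluster, to machine precision."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 8))
        X = rng.normal(0.35, 1.0, (n, int(rng.integers(20, 65))))
        cfg = cl.ClusterTestConfig(n_permutations=1000, seed=0)
        res = cl.one_sample_cluster_test(X, _times(X.shape[1]), cfg)
        assert res.exact and res.n_null == 2 ** n
        mine = sorted(((c.time_slice[0], c.time_slice[1] - 1), c.mass, c.p_perm)
                      for c in res.clusters)
        oracle = sorted(_oracles.brute_force_cluster_p(X))
        assert len(mine) == len(oracle)
        for (ext_a, m_a, p_a), (ext_b, m_b, p_b) in zip(mine, oracle):
            assert ext_a == ext_b
            assert m_a == pytest.approx(m_b, abs=1e-9)
            assert p_a == pytest.approx(p_b, abs=1e-12)

    def test_positive_tail_matches_oracle(self):
        rng = np.random.default_rng(9)
        X = rng.normal(0.4, 1.0, (6, 30))
        cfg = cl.ClusterTestConfig(tail="pos", n_permutations=1000)
        res = cl.one_sample_cluster_test(X, _times(30), cfg)
        oracle = sorted(_oracles.brute_force_cluster_p(X, tail="pos"))
        mine = sorted(((c.time_slice[0], c.time_slice[1] - 1), c.mass, c.p_perm)
                      for c in res.clusters)
        for a, b in zip(mine, oracle):
            assert a[0] == b[0] and a[2] == pytest.approx(b[2], abs=1e-12)

    def test_cross_check_against_mne(self):
        """Same clusters and masses as MNE's implementation of this test
        family (threshold and mass conventions aligned)."""
        from mne.stats import permutation_cluster_1samp_test

        rng = np.random.default_rng(4)
        X = rng.normal(0.3, 1.0, (10, 60))
        thr = stats.t.ppf(1 - 0.025, 9)
        t_obs, clusters, pvals, _ = permutation_cluster_1samp_test(
            X, threshold=thr, tail=0, n_permutations=1024, seed=0, verbose=False)
        cfg = cl.ClusterTestConfig(n_permutations=1024)
        res = cl.one_sample_cluster_test(X, _times(60), cfg)
        mne_masses = sorted(round(float(t_obs[c[0]].sum()), 6) for c in clusters)
        my_masses = sorted(round(c.mass, 6) for c in res.clusters)
        assert my_masses == mne_masses
        for c in res.clusters:
            mne_idx = [i for i, cc in enumerate(clusters)
                       if round(float(t_obs[cc[0]].sum()), 6) == round(c.mass, 6)]
            assert abs(c.p_perm - float(pvals[mne_idx[0]])) < 0.02


class TestEngineBehaviour:
    def test_all_zero_maps_give_empty_cluster_list(self):
        cfg = cl.ClusterTestConfig(n_permutations=100)
        res = cl.one_sample_cluster_test(np.zeros((8, 40)), _times(40), cfg)
        assert res.clusters == []

    def test_single_participant_rejected(self):
        with pytest.raises(ValueError, match="2 participants"):
            cl.one_sample_cluster_test(np.ones((1, 10)), _times(10),
                                       cl.ClusterTestConfig())

    def test_p_value_floor(self):
        rng = np.random.default_rng(1)
        X = rng.normal(3.0, 0.5, (12, 30))  # overwhelming effect
        cfg = cl.ClusterTestConfig(n_permutations=200, seed=0)
        res = cl.one_sample_cluster_test(X, _times(30), cfg)
        assert res.clusters
        assert min(c.p_perm for c in res.clusters) == 1 / (res.n_null + 1)

    def test_determinism_under_fixed_seed(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0.3, 1.0, (15, 50))
        cfg = cl.ClusterTestConfig(n_permutations=300, seed=7)
        r1 = cl.one_sample_cluster_test(X, _times(50), cfg)
        r2 = cl.one_sample_cluster_test(X, _times(50), cfg)
        assert [(c.mass, c.p_perm) for c in r1.clusters] == \
            [(c.mass, c.p_perm) for c in r2.clusters]

    def test_2d_adjacency_is_4_neighbour(self):
        """Two suprathreshold blobs touching only diagonally stay separate."""
        rng = np.random.default_rng(3)
        X = rng.normal(0.0, 1.0, (10, 6, 6))
        X[:, 1:3, 1:3] += 3.0
        X[:, 3:5, 3:5] += 3.0
        cfg = cl.ClusterTestConfig(n_permutations=64, adjacency="time-frequency")
        res = cl.one_sample_cluster_test(X, _times(6), cfg,
                                         freqs=np.arange(6.0))
        pos = [c for c in res.clusters if c.sign == "+"]
        assert len(pos) >= 2

    def test_planted_offset_recovered_with_overlap(self):
        """1.5-pooled-SD offset over 1000-2000 ms, n=12: a significant
        cluster overlaps the planted window with Jaccard >= 0.5 in >= 90 %
        of 50 replicates (0.1-s correlated noise field)."""
        from scipy.ndimage import gaussian_filter1d

        times = np.arange(0, 3000, 10.0)
        window = (1000.0, 2000.0)
        hits = 0
        for rep in range(50):
            rng = np.random.default_rng(100 + rep)

            def draw():
                x = gaussian_filter1d(rng.standard_normal((12, times.size)),
                                      10.0, axis=-1, mode="reflect")
                return x / x.std(axis=-1, keepdims=True)

            a = draw() + 1.5 * ((times >= window[0]) & (times <= window[1]))
            cfg = cl.ClusterTestConfig(n_permutations=300, seed=rep,
                                       test_window_ms=(0, 2990))
            res = cl.paired_condition_cluster_test(a, draw(), times, cfg)
            sig = [c for c in res.significant if c.sign == "+"]
            if not sig:
                continue
            c = max(sig, key=lambda c: c.mass)
            inter = max(0.0, min(c.end_ms, window[1]) - max(c.start_ms, window[0]))
            union = (c.end_ms - c.start_ms) + (window[1] - window[0]) - inter
            hits += inter / union >= 0.5
        assert hits >= 45


class TestBaselineCorrection:
    def test_constant_map_zeroed(self):
        times = np.arange(-5500, 5001, 1.0)
        out = cl.baseline_correct(np.full((3, times.size), 7.0), times)
        assert np.allclose(out, 0.0)

    def test_printed_window_has_5001_samples_at_1ms(self):
        times = np.arange(-5500, 5001, 1.0)
        assert int(cl.window_mask(times, (-5500, -500)).sum()) == 5001

    def test_step_signal_keeps_post_onset_level(self):
        times = np.arange(-5500, 5001, 1.0)
        x = np.where(times >= 0, 1.0, 0.0)[None, :]
        out = cl.baseline_correct(x, times)
        assert np.allclose(out[0, times >= 0], 1.0)


class TestPairedAndTwoStage:
    def test_identical_conditions_give_no_clusters(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(8, 40))
        res = cl.paired_condition_cluster_test(a, a.copy(), _times(40),
                                               cl.ClusterTestConfig(n_permutations=50),
                                               window_ms=(0, 39))
        assert res.clusters == []

    def test_argument_swap_negates_masses_same_p(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0.5, 1, (9, 45))
        b = rng.normal(0.0, 1, (9, 45))
        cfg = cl.ClusterTestConfig(n_permutations=200, seed=11)
        r_ab = cl.paired_condition_cluster_test(a, b, _times(45), cfg,
                                                window_ms=(0, 44))
        r_ba = cl.paired_condition_cluster_test(b, a, _times(45), cfg,
                                                window_ms=(0, 44))
        assert [(c.mass, c.p_perm) for c in r_ab.clusters] == \
            [(-c.mass, c.p_perm) for c in r_ba.clusters]

    def test_nan_rows_dropped_as_incomplete(self):
        rng = np.random.default_rng(7)
        a = rng.normal(1.0, 0.3, (6, 30))
        b = rng.normal(0.0, 0.3, (6, 30))
        a[2] = np.nan
        res = cl.paired_condition_cluster_test(a, b, _times(30),
                                               cl.ClusterTestConfig(n_permutations=64),
                                               window_ms=(0, 29))
        assert res.n == 5

    def test_pooled_window_covers_planted_response(self):
        """Evoked bump in all cells -> positive-tail window overlapping it."""
        times = np.arange(-2000, 3001, 10.0)
        rng = np.random.default_rng(8)
        bump = np.exp(-0.5 * ((times - 800) / 300.0) ** 2)
        cells = {}
        for c in ("CSu", "CSp"):
            for ph in ("early", "late"):
                noise, _ = sim.simulate_envelope_pair(10, times, "delta", rng)
                cells[(c, ph)] = 0.3 * noise + 2.0 * bump
        cfg = cl.ClusterTestConfig(n_permutations=200, seed=0,
                                   baseline_ms=(-2000, -500),
                                   test_window_ms=(0, 3000))
        out = cl.pooled_window(cells, times, cfg)
        assert out["status"] == "ok"
        lo, hi = out["window_ms"]
        assert lo < 800 < hi

    def test_pooled_window_untestable_under_null(self):
        times = np.arange(-2000, 3001, 10.0)
        rng = np.random.default_rng(12)
        cells = {(c, ph): sim.simulate_envelope_pair(10, times, "delta", rng)[0]
                 for c in ("CSu", "CSp") for ph in ("early", "late")}
        cfg = cl.ClusterTestConfig(n_permutations=200, seed=1,
                                   baseline_ms=(-2000, -500),
                                   test_window_ms=(0, 3000))
        out = cl.pooled_window(cells, times, cfg)
        if out["status"] == "ok":  # a rare false positive is possible
            assert out["result"].significant[0].p_perm <= 0.05
        else:
            assert out["window_ms"] is None

    def test_restricted_test_skipped_for_untestable_band(self):
        res, effects = cl.restricted_condition_test(
            np.ones((4, 10)), np.zeros((4, 10)), _times(10),
            {"status": "untestable", "window_ms": None},
            cl.ClusterTestConfig())
        assert res is None and effects == []

    def test_single_point_window_matches_sign_test_enumeration(self):
        """A length-1 window degenerates to a sign-flip test on one value;
        the exact p equals direct enumeration of the t statistic."""
        rng = np.random.default_rng(13)
        diffs = rng.normal(0.8, 1.0, 7)
        a = np.tile(diffs[:, None], (1, 3))
        b = np.zeros_like(a)
        cfg = cl.ClusterTestConfig(n_permutations=1000)
        res = cl.paired_condition_cluster_test(a, b, _times(3), cfg,
                                               window_ms=(1, 1))
        oracle = _oracles.brute_force_cluster_p(diffs[:, None])
        assert len(res.clusters) == len(oracle)
        if res.clusters:
            assert res.clusters[0].p_perm == pytest.approx(oracle[0][2])

    def test_phase_interaction_antisymmetry_and_null(self):
        rng = np.random.default_rng(14)
        d_early = rng.normal(1.0, 0.5, (8, 30))
        d_late = rng.normal(0.0, 0.5, (8, 30))
        cfg = cl.ClusterTestConfig(n_permutations=128, seed=2)
        r1 = cl.phase_interaction_test(d_early, d_late, _times(30), cfg,
                                       window_ms=(0, 29))
        r2 = cl.phase_interaction_test(d_late, d_early, _times(30), cfg,
                                       window_ms=(0, 29))
        assert [(c.mass, c.p_perm) for c in r1.clusters] == \
            [(-c.mass, c.p_perm) for c in r2.clusters]
        same = cl.phase_interaction_test(d_early, d_early.copy(), _times(30),
                                         cfg, window_ms=(0, 29))
        assert same.clusters == []


class TestEffectSize:
    def test_printed_formula_arithmetic(self):
        assert cl.r_from_z(3.70, 38) == pytest.approx(0.600, abs=5e-4)

    def test_zero_z_gives_zero_r(self):
        es = cl.effect_size_r(np.array([1.0, -1.0, 2.0, -2.0]))
        assert es.z == 0.0 and es.r == 0.0

    def test_all_zero_diffs_explicit_status(self):
        es = cl.effect_size_r(np.zeros(6))
        assert es.status == "undefined" and np.isnan(es.r)

    @pytest.mark.parametrize("n", [6, 8, 10])
    def test_normal_approximation_matches_exact_enumeration(self, n):
        """z is built from the exact W+ mean/variance, and the approximate
        p stays within 0.02 of the fully enumerated signed-rank p."""
        rng = np.random.default_rng(n)
        diffs = rng.normal(0.8, 1.0, n)
        diffs = np.where(diffs == 0, 0.1, diffs)
        es = cl.effect_size_r(diffs)
        d = diffs[diffs != 0]
        m = d.size
        ranks = stats.rankdata(np.abs(d))
        w = ranks[d > 0].sum()
        mu = m * (m + 1) / 4
        sigma = np.sqrt(m * (m + 1) * (2 * m + 1) / 24)
        assert abs(es.z) == pytest.approx(
            (abs(w - mu) - 0.5) / sigma if w != mu else 0.0, abs=1e-12)
        assert es.p == pytest.approx(_oracles.exact_signed_rank_p(diffs),
                                     abs=0.02)

    def test_all_positive_six_matches_table_and_scipy(self):
        es = cl.effect_size_r(np.array([1.0, 2, 3, 4, 5, 6]))
        ref = stats.wilcoxon(np.array([1.0, 2, 3, 4, 5, 6]),
                             method="approx", correction=True)
        assert es.p == pytest.approx(float(ref.pvalue), abs=1e-12)
        assert es.r == pytest.approx(es.z / np.sqrt(6))
        assert _oracles.exact_signed_rank_p([1, 2, 3, 4, 5, 6]) == \
            pytest.approx(2 / 64)

    def test_sign_follows_median_difference(self):
        up = cl.effect_size_r(np.array([0.5, 1.0, 2.0, 3.0, -0.1]))
        down = cl.effect_size_r(-np.array([0.5, 1.0, 2.0, 3.0, -0.1]))
        assert up.r > 0 > down.r
        assert up.r == pytest.approx(-down.r)
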