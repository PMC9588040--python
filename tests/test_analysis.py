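"""Population-coding measures: rates, Q, MI, dimensionality, stability,
readout."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from stcnet import SpikeRaster
from stcnet.analysis import (fit_ridge_readout, gaussian_random_walk,
                             mutual_information_MI, pattern_completion_Q,
                             pca_dimensionality, readout_connectivity_curve,
                             shuffle_raster, sliding_rate,
                             spike_time_stability,
                             stability_weight_correlation)
from stcnet.fixtures import low_rank_raster


class TestSlidingRate:
    def test_count_over_window(self):
        r = SpikeRaster([0] * 5, np.linspace(0.6, 0.9, 5), 2)
        rates = sliding_rate(r, 1.0)
        assert rates[0] == 10.0 and rates[1] == 0.0

    def test_window_boundary_convention(self):
        """Trailing half-open window (t - w, t]: a spike exactly at t - w is
        excluded, one exactly at t is included."""
        r = SpikeRaster([0, 1], [0.5, 1.0], 2)
        rates = sliding_rate(r, 1.0)
        assert rates[0] == 0.0 and rates[1] == 2.0

    def test_rates_are_multiples_of_two_hz(self, rng):
        r = SpikeRaster(rng.integers(0, 20, 200),
                        rng.uniform(0, 1.0, 200), 20)
        rates = sliding_rate(r, 1.0)
        assert np.allclose(rates % 2.0, 0.0)

    def test_uncovered_window_rejected(self):
        with pytest.raises(ValueError):
            sliding_rate(SpikeRaster([0], [0.1], 1), 0.3)


class TestPatternCompletionQ:
    def test_perfect_completion(self):
        rates = np.array([10.0, 10.0, 0.0])
        assert pattern_completion_Q(rates, [0], [1], [2]) == pytest.approx(1.0)

    def test_no_completion_when_ans_matches_control(self):
        rates = np.array([10.0, 3.0, 3.0])
        assert pattern_completion_Q(rates, [0], [1], [2]) == pytest.approx(0.0)

    def test_intermediate_value(self):
        rates = np.array([10.0, 6.0, 2.0])
        assert pattern_completion_Q(rates, [0], [1], [2]) == pytest.approx(0.4)

    def test_silent_recall_population_undefined(self):
        rates = np.array([0.0, 5.0, 1.0])
        assert np.isnan(pattern_completion_Q(rates, [0], [1], [2]))

    @given(st.floats(0.1, 50.0))
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_invariant_to_uniform_rate_rescaling(self, scale):
        rates = np.array([12.0, 7.0, 4.0, 1.0])
        q1 = pattern_completion_Q(rates, [0], [1, 2], [3])
        q2 = pattern_completion_Q(scale * rates, [0], [1, 2], [3])
        assert q1 == pytest.approx(q2)


def _mi_bruteforce(x, y):
    """Plug-in MI from the explicit joint probability table."""
    pairs = list(zip(x, y))
    n = len(pairs)
    mi = 0.0
    for vx in set(x):
        for vy in set(y):
            pxy = pairs.count((vx, vy)) / n
            if pxy:
                px = list(x).count(vx) / n
                py = list(y).count(vy) / n
                mi += pxy * np.log2(pxy / (px * py))
    return mi


class TestMutualInformation:
    def test_identical_distributions_give_entropy(self):
        x = np.array([0.0, 2.0, 2.0, 8.0])
        h = -(0.25 * np.log2(0.25) * 2 + 0.5 * np.log2(0.5))
        assert mutual_information_MI(x, x) == pytest.approx(h)

    def test_constant_recall_carries_no_information(self):
        x = np.array([0.0, 2.0, 4.0, 8.0])
        assert mutual_information_MI(x, np.full(4, 6.0)) == pytest.approx(0.0)

    def test_four_neuron_toy_matches_bruteforce_table(self):
        x = np.array([0.0, 0.0, 2.0, 4.0])
        y = np.array([2.0, 0.0, 2.0, 2.0])
        assert mutual_information_MI(x, y) == pytest.approx(_mi_bruteforce(x, y))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mutual_information_MI(np.zeros(3), np.zeros(4))

    @given(st.integers(0, 2 ** 30))
    @settings(deadline=None, derandomize=True, max_examples=25)
    def test_symmetry_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 4, 30) * 2.0
        y = rng.integers(0, 4, 30) * 2.0
        mi = mutual_information_MI(x, y)
        assert mi == pytest.approx(mutual_information_MI(y, x))
        h_x = mutual_information_MI(x, x)
        h_y = mutual_information_MI(y, y)
        assert -1e-9 <= mi <= min(h_x, h_y) + 1e-9


class TestPCADimensionality:
    def test_rank_one_matrix_needs_one_component(self, rng):
        profile = rng.random(100)
        amps = rng.uniform(0.5, 2.0, 50)
        m = np.outer(amps, profile)
        assert pca_dimensionality(m) == 1

    def test_iid_noise_matches_eigenvalue_oracle(self, rng):
        m = rng.standard_normal((50, 100))
        centered = m - m.mean(axis=0)
        evals = np.sort(np.linalg.eigvalsh(centered.T @ centered))[::-1]
        cum = np.cumsum(evals) / evals.sum()
        expect = int(np.searchsorted(cum, 0.7 - 1e-12) + 1)
        assert pca_dimensionality(m, 0.7) == expect

    def test_full_variance_returns_rank(self, rng):
        m = low_rank_raster(40, 60, rank=3, seed=0)
        assert pca_dimensionality(m, 1.0) == 3

    def test_zero_matrix_has_dimension_zero(self):
        assert pca_dimensionality(np.zeros((10, 20))) == 0

    def test_invariant_to_row_permutation(self, rng):
        m = (rng.random((30, 50)) < 0.2).astype(float)
        perm = rng.permutation(30)
        assert pca_dimensionality(m) == pca_dimensionality(m[perm])


class TestSpikeTimeStability:
    def test_identical_rasters_fully_stable(self, rng):
        m = (rng.random((20, 100)) < 0.1).astype(np.int8)
        assert spike_time_stability(m, m) == pytest.approx(1.0)

    def test_disjoint_rasters_unstable(self):
        a = np.zeros((3, 100), dtype=np.int8)
        b = np.zeros((3, 100), dtype=np.int8)
        a[:, :10] = 1
        b[:, 50:60] = 1
        assert spike_time_stability(a, b) == 0.0

    def test_partial_overlap_fraction(self):
        a = np.zeros((1, 100), dtype=np.int8)
        b = np.zeros((1, 100), dtype=np.int8)
        a[0, [3, 10, 40]] = 1
        b[0, [10, 40, 77]] = 1
        assert spike_time_stability(a, b) == pytest.approx(2.0 / 3.0)

    def test_neurons_without_learning_spikes_excluded(self):
        a = np.zeros((2, 100), dtype=np.int8)
        b = np.ones((2, 100), dtype=np.int8)
        a[0, 5] = 1
        scores = spike_time_stability(a, b, per_neuron=True)
        assert scores[0] == 1.0 and np.isnan(scores[1])
        assert spike_time_stability(a, b) == 1.0


class TestShuffleRaster:
    def test_per_neuron_counts_preserved(self, rng):
        m = (rng.random((30, 100)) < 0.15).astype(np.int8)
        sh = shuffle_raster(m, seed=0)
        np.testing.assert_array_equal(m.sum(axis=1), sh.sum(axis=1))

    def test_shuffled_stability_matches_hypergeometric_mean(self, rng):
        """With k learning and m recall spikes in B bins, expected matches
        are k m / B, so the normalized score has mean m / B."""
        k, m_spk, B, n_rep = 12, 20, 100, 1500
        a = np.zeros((n_rep, B), dtype=np.int8)
        b = np.zeros((n_rep, B), dtype=np.int8)
        a[:, :k] = 1
        b[:, :m_spk] = 1
        scores = spike_time_stability(shuffle_raster(a, 1),
                                      shuffle_raster(b, 2), per_neuron=True)
        expect = m_spk / B
        var = (k * (m_spk / B) * (1 - m_spk / B) * (B - k) / (B - 1)) / k ** 2
        se = np.sqrt(var / n_rep)
        assert abs(scores.mean() - expect) < 3 * se

    def test_rows_shuffled_independently(self):
        m = np.zeros((2, 100), dtype=np.int8)
        m[:, :50] = 1
        sh = shuffle_raster(m, seed=3)
        assert not np.array_equal(sh[0], sh[1])  # permutations differ


class TestStabilityWeightCorrelation:
    def test_monotone_relation_gives_unit_correlation(self):
        stab = np.array([0.1, 0.2, 0.3, 0.5, 0.9])
        w = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        rho, _ = stability_weight_correlation(stab, w)
        assert rho == pytest.approx(1.0)

    def test_independent_permutation_near_zero(self, rng):
        stab = rng.random(400)
        w = rng.random(400)
        rho, p = stability_weight_correlation(stab, w)
        assert abs(rho) < 0.15

    def test_toy_matches_rank_formula(self):
        stab = np.array([0.3, 0.1, 0.9, 0.4, 0.2])
        w = np.array([2.0, 1.0, 4.0, 5.0, 3.0])
        rho, _ = stability_weight_correlation(stab, w)
        rs = stats.rankdata(stab)
        rw = stats.rankdata(w)
        d2 = ((rs - rw) ** 2).sum()
        assert rho == pytest.approx(1 - 6 * d2 / (5 * 24))

    def test_nan_scores_excluded_and_min_points_enforced(self):
        with pytest.raises(ValueError):
            stability_weight_correlation(np.array([0.1, np.nan, np.nan]),
                                         np.array([1.0, 2.0, 3.0]))


class TestGaussianRandomWalk:
    def test_starts_at_one(self):
        assert gaussian_random_walk(100, seed=0)[0] == 1.0

    def test_increments_standard_normal(self):
        y = gaussian_random_walk(20000, seed=1)
        inc = np.diff(y)
        assert abs(inc.mean()) < 3 / np.sqrt(len(inc))
        assert inc.std() == pytest.approx(1.0, abs=0.03)

    def test_variance_grows_linearly(self):
        ys = np.array([gaussian_random_walk(101, seed=s) for s in range(800)])
        d = ys[:, 50] - ys[:, 0]
        assert d.var() == pytest.approx(50.0, rel=0.25)

    def test_minimum_length(self):
        assert len(gaussian_random_walk(1, seed=0)) == 1
        with pytest.raises(ValueError):
            gaussian_random_walk(0)


class TestRidgeReadout:
    def _rasters(self, rng, n_neurons=12, n_bins=40):
        learn = [(rng.random((n_neurons, n_bins)) < 0.3).astype(np.int8)
                 for _ in range(3)]
        recall = (rng.random((n_neurons, n_bins)) < 0.3).astype(np.int8)
        return learn, recall

    def test_solution_matches_normal_equations(self, rng):
        """Ridge coefficients equal (X^T X + a I)^{-1} X^T y with the
        intercept column penalized like every other weight."""
        learn, recall = self._rasters(rng)
        target = gaussian_random_walk(40, seed=5)
        res = fit_ridge_readout(learn, recall, target, p_out=1.0,
                                alpha_ridge=0.1, seed=0)
        X = np.vstack([seg.T for seg in learn + [recall]]).astype(float)
        X = np.hstack([X, np.ones((X.shape[0], 1))])
        y = np.concatenate([target] * 4)
        w = np.linalg.solve(X.T @ X + 0.1 * np.eye(X.shape[1]), X.T @ y)
        np.testing.assert_allclose(res.weights, w, atol=1e-8)

    def test_interpolation_limit_without_regularization(self, rng):
        """With identical full-rank segments and alpha -> 0 the readout
        interpolates the target exactly (R^2 -> 1)."""
        seg = (rng.random((30, 25)) < 0.4).astype(np.int8)
        target = gaussian_random_walk(25, seed=11)
        res = fit_ridge_readout([seg, seg, seg], seg, target, p_out=1.0,
                                alpha_ridge=1e-10, seed=0)
        assert res.r2_recall > 0.999

    def test_infinite_shrinkage_kills_fit(self, rng):
        learn, recall = self._rasters(rng)
        target = gaussian_random_walk(40, seed=2)
        res = fit_ridge_readout(learn, recall, target, alpha_ridge=1e9, seed=0)
        assert np.abs(res.weights).max() < 1e-3
        assert res.r2_recall <= 0.0

    def test_subsample_size_and_empty_subsample(self, rng):
        learn, recall = self._rasters(rng, n_neurons=20)
        target = gaussian_random_walk(40, seed=3)
        res = fit_ridge_readout(learn, recall, target, p_out=0.5, seed=1)
        assert len(res.neuron_subset) == 10
        assert len(res.weights) == 11  # subsample + intercept
        with pytest.raises(ValueError):
            fit_ridge_readout(learn, recall, target, p_out=0.01, seed=1)

    def test_core_pool_design_width(self, rng):
        """A 150-neuron pool at full connectivity gives 151 columns."""
        learn = [(rng.random((200, 30)) < 0.2).astype(np.int8)
                 for _ in range(3)]
        recall = (rng.random((200, 30)) < 0.2).astype(np.int8)
        target = gaussian_random_walk(30, seed=4)
        res = fit_ridge_readout(learn, recall, target, p_out=1.0,
                                neuron_pool=np.arange(150), seed=0)
        assert len(res.weights) == 151


class TestReadoutCurve:
    def test_identical_seed_identical_table(self, rng):
        learn = [(rng.random((15, 30)) < 0.3).astype(np.int8)] * 3
        recall = (rng.random((15, 30)) < 0.3).astype(np.int8)
        t1 = readout_connectivity_curve(learn, recall, p_out_grid=[0.5, 1.0],
                                        n_targets=3, seed=7)
        t2 = readout_connectivity_curve(learn, recall, p_out_grid=[0.5, 1.0],
                                        n_targets=3, seed=7)
        assert t1.equals(t2)

    def test_r2_improves_with_connectivity_on_average(self, rng):
        """Nested designs at the same penalty: mean R^2 grows with p_out
        (checked on structured rasters where recall repeats learning)."""
        base = (rng.random((60, 50)) < 0.25).astype(np.int8)
        learn = [base, base, base]
        tab = readout_connectivity_curve(learn, base,
                                         p_out_grid=[0.1, 1.0],
                                         n_targets=8, seed=3)
        mean = tab.groupby("p_out")["r2"].mean()
        assert mean[1.0] > mean[0.1]
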