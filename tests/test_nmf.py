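"""Staged constrained KL-NMF: stage-by-stage correctness, monotonicity,
rescaling, genome-wide extension, and recovery of simulated ground truth."""

import dataclasses

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from chipdeconv.genome import BinnedTracks, GenomeBins
from chipdeconv.nmf import (
    FactorizationConfig,
    assemble_matrix,
    deconvolve,
    extend_genomewide,
    fit_background_coefficients,
    fit_control_stage,
    fit_specific_stage,
    kl_divergence,
    multiplicative_update_K,
    multiplicative_update_W,
    regularized_loss,
    relax_and_alternate,
    rescale_result,
    select_training_bins,
)
from chipdeconv.samples import SampleInfo

from conftest import make_toy_tracks, plain_kl_nmf_reference


class TestAssemble:
    def test_two_treatment_conditions_plus_control_give_l3(self):
        tracks = make_toy_tracks(30, 2, [("A", 3), ("B", 3)], seed=0)
        V, conditions, l = assemble_matrix(tracks)
        assert V.shape == (30, 8)
        assert l == 3
        assert conditions[0] == "control"

    def test_single_pair_gives_l2(self):
        tracks = make_toy_tracks(30, 1, [("A", 1)], seed=0)
        _, _, l = assemble_matrix(tracks)
        assert l == 2

    def test_no_control_rejected(self):
        bins = GenomeBins({"c": 2000}, 200)
        tracks = BinnedTracks(
            bins, np.ones((10, 1)), [SampleInfo("t", "A", False, 1)]
        )
        with pytest.raises(ValueError, match="control"):
            assemble_matrix(tracks)

    def test_replicate_permutation_leaves_W_invariant(self):
        tracks = make_toy_tracks(200, 1, [("A", 2)], seed=2)
        swapped = BinnedTracks(
            tracks.bins,
            tracks.values[:, [0, 2, 1]],
            [tracks.samples[0], tracks.samples[2], tracks.samples[1]],
        )
        cfg = FactorizationConfig(n_train_bins=200)
        r1 = deconvolve(tracks, cfg, seed=0)
        r2 = deconvolve(swapped, cfg, seed=0)
        np.testing.assert_allclose(r1.W, r2.W, rtol=1e-8)
        np.testing.assert_allclose(r1.K[:, [0, 2, 1]], r2.K, rtol=1e-8)


class TestTrainingBins:
    def test_threshold_zero_full_size_is_identity(self):
        V = np.random.default_rng(0).gamma(2, 2, (50, 3))
        cfg = FactorizationConfig(n_train_bins=50, min_mean_coverage=0.0)
        idx = select_training_bins(V, cfg, np.random.default_rng(0))
        np.testing.assert_array_equal(idx, np.arange(50))

    def test_simulated_preset_returns_5000_bins(self, default_sim):
        _, tracks = default_sim
        cfg = FactorizationConfig(n_train_bins=5000)
        idx = select_training_bins(tracks.values, cfg, np.random.default_rng(1))
        assert len(idx) == 5000
        assert len(np.unique(idx)) == 5000

    def test_coverage_threshold_excludes_low_bins(self):
        V = np.vstack([np.full((20, 2), 0.5), np.full((30, 2), 5.0)])
        cfg = FactorizationConfig(n_train_bins=30, min_mean_coverage=1.0)
        idx = select_training_bins(V, cfg, np.random.default_rng(0))
        assert idx.min() >= 20

    def test_inclusion_is_uniform_over_eligible_bins(self):
        """Chi-square test of inclusion counts across 200 seeds."""
        from scipy.stats import chisquare

        V = np.random.default_rng(3).gamma(2, 2, (80, 2))
        cfg = FactorizationConfig(n_train_bins=20, min_mean_coverage=0.0)
        counts = np.zeros(80)
        for seed in range(200):
            counts[select_training_bins(V, cfg, np.random.default_rng(seed))] += 1
        _, p = chisquare(counts)
        assert p > 0.01


class TestControlStage:
    CFG = FactorizationConfig(max_iter=2000, tol=1e-12)

    def test_identical_columns_give_proportional_x_and_equal_coeffs(self):
        c = np.random.default_rng(0).gamma(2, 2, 60)
        x, k, _ = fit_control_stage(np.column_stack([c, c]), self.CFG)
        assert k[0] == pytest.approx(k[1], rel=1e-6)
        np.testing.assert_allclose(np.outer(x, k), np.column_stack([c, c]), rtol=5e-3)

    def test_scaled_column_doubles_coefficient(self):
        c = np.random.default_rng(1).gamma(2, 2, 60) + 0.5
        x, k, _ = fit_control_stage(np.column_stack([c, 2 * c]), self.CFG)
        assert k[1] / k[0] == pytest.approx(2.0, rel=1e-3)

    def test_matches_multi_restart_reference_on_poisson_block(self):
        rng = np.random.default_rng(2)
        base = rng.gamma(3, 2, 50)
        block = np.column_stack(
            [rng.poisson(base * 0.8), rng.poisson(base * 1.4)]
        ).astype(float)
        cfg = FactorizationConfig(max_iter=50_000, tol=1e-14)
        x, k, _ = fit_control_stage(block, cfg)
        mine = regularized_loss(block, x[:, None], k[None, :], cfg.lambda_W, cfg.lambda_K)
        ref = plain_kl_nmf_reference(
            block, 1, self.CFG.lambda_W, self.CFG.lambda_K, n_restarts=500, seed=99
        )
        assert mine <= ref + 1e-6

    def test_all_zero_block_rejected(self):
        with pytest.raises(ValueError, match="all zero"):
            fit_control_stage(np.zeros((10, 2)), self.CFG)


class TestBackgroundCoefficients:
    def test_exact_multiple_recovered(self):
        x = np.random.default_rng(0).gamma(2, 2, 40)
        beta = fit_background_coefficients(3 * x[:, None], x, lambda_K=0.0)
        assert beta[0] == pytest.approx(3.0)

    def test_orthogonal_support_gives_zero(self):
        x = np.zeros(40)
        x[:20] = 1.0
        v = np.zeros(40)
        v[20:] = 5.0
        beta = fit_background_coefficients(v[:, None], x, lambda_K=0.0)
        # KL(V || beta*x) on disjoint support is minimized by beta -> 0
        assert beta[0] == pytest.approx(5.0 * 20 / 20)  # unpenalized mass ratio
        beta_pen = fit_background_coefficients(v[:, None], x, lambda_K=0.001)
        assert beta_pen[0] < beta[0]

    def test_matches_1d_numerical_minimizer(self):
        rng = np.random.default_rng(3)
        x = rng.gamma(2, 2, 80) + 0.1
        v = rng.gamma(2, 2, 80)
        lam = 0.001
        beta = fit_background_coefficients(v[:, None], x, lambda_K=lam)[0]

        def objective(b):
            return kl_divergence(v[:, None], b * x[:, None]) + lam * b**2

        res = minimize_scalar(objective, bounds=(1e-6, 50), method="bounded",
                              options={"xatol": 1e-10})
        assert beta == pytest.approx(res.x, abs=1e-6)

    def test_all_zero_x_rejected(self):
        with pytest.raises(ValueError):
            fit_background_coefficients(np.ones((5, 1)), np.zeros(5))


class TestSpecificStage:
    CFG = FactorizationConfig(max_iter=2000, tol=1e-12)

    def test_noiseless_construction_recovered_in_peaks(self):
        rng = np.random.default_rng(4)
        G = 300
        x = rng.gamma(3, 2, G)
        y = np.zeros(G)
        y[::7] = rng.gamma(4, 3, len(y[::7]))
        V = np.column_stack([0.6 * x + 1.0 * y, 0.9 * x + 1.3 * y])
        beta = np.array([0.6, 0.9])
        Y, coeffs, _ = fit_specific_stage(V, x, beta, [np.array([0, 1])], self.CFG)
        recon = Y[:, 0]
        peaks = y > 0
        r = np.corrcoef(recon[peaks], y[peaks])[0, 1]
        assert r > 0.99

    def test_single_replicate_is_normalized_residual(self):
        rng = np.random.default_rng(5)
        x = rng.gamma(2, 2, 50)
        v = 0.5 * x + rng.gamma(1, 1, 50)
        beta = np.array([0.5])
        cfg = FactorizationConfig(lambda_W=0.0, lambda_K=0.0, max_iter=5000, tol=1e-14)
        Y, coeffs, _ = fit_specific_stage(v[:, None], x, beta, [np.array([0])], cfg)
        residual = np.maximum(v - 0.5 * x, 0)
        np.testing.assert_allclose(Y[:, 0] * coeffs[0][0], residual, rtol=1e-3, atol=1e-6)

    def test_exact_multiples_factor_with_zero_kl(self):
        rng = np.random.default_rng(6)
        x = np.zeros(50)
        y = rng.gamma(2, 2, 50)
        V = np.column_stack([y, 2 * y])
        cfg = FactorizationConfig(lambda_W=0.0, lambda_K=0.0, max_iter=5000, tol=1e-14)
        Y, coeffs, traces = fit_specific_stage(V, x + 1e-9, np.zeros(2), [np.array([0, 1])], cfg)
        recon = np.outer(Y[:, 0], coeffs[0])
        assert kl_divergence(V, recon) < 1e-4

    def test_zero_residual_warns_and_returns_zero(self, caplog):
        x = np.ones(20)
        V = 0.5 * x[:, None]
        Y, coeffs, _ = fit_specific_stage(V, x, np.array([1.0]), [np.array([0])], self.CFG)
        assert np.all(Y == 0)


class TestRelaxation:
    def test_exact_factorization_is_fixed_point_without_penalty(self):
        rng = np.random.default_rng(7)
        W0 = rng.gamma(2, 1, (30, 2)) + 0.1
        K0 = rng.gamma(2, 1, (2, 4)) + 0.1
        V = W0 @ K0
        cfg = FactorizationConfig(lambda_W=0.0, lambda_K=0.0, max_iter=50, tol=1e-15)
        W, K, trace = relax_and_alternate(V, W0, K0, cfg)
        assert trace[0] == pytest.approx(0.0, abs=1e-8)
        assert trace[-1] <= trace[0] + 1e-10
        np.testing.assert_allclose(W @ K, V, rtol=1e-6)

    def test_loss_monotone_nonincreasing(self):
        tracks = make_toy_tracks(100, 2, [("A", 2), ("B", 2)], seed=8)
        cfg = FactorizationConfig(n_train_bins=100, max_iter=300)
        rng = np.random.default_rng(0)
        W0 = rng.uniform(0.5, 2, (100, 3))
        K0 = rng.uniform(0.5, 2, (3, 6))
        _, _, trace = relax_and_alternate(tracks.values, W0, K0, cfg)
        diffs = np.diff(trace)
        assert np.all(diffs <= 1e-10 + 1e-8 * np.abs(trace[:-1]))

    @pytest.mark.parametrize("shape,rank", [((25, 5), 2), ((40, 3), 3)])
    def test_mu_updates_never_increase_penalized_loss(self, shape, rank):
        rng = np.random.default_rng(hash(shape) % 2**31)
        V = rng.gamma(2, 2, shape)
        W = rng.uniform(0.1, 2, (shape[0], rank))
        K = rng.uniform(0.1, 2, (rank, shape[1]))
        lw, lk = 0.01, 0.001
        prev = regularized_loss(V, W, K, lw, lk)
        for _ in range(100):
            W = multiplicative_update_W(V, W, K, lw)
            loss = regularized_loss(V, W, K, lw, lk)
            assert loss <= prev + 1e-10 + 1e-8 * abs(prev)
            prev = loss
            K = multiplicative_update_K(V, W, K, lk)
            loss = regularized_loss(V, W, K, lw, lk)
            assert loss <= prev + 1e-10 + 1e-8 * abs(prev)
            prev = loss

    def test_plain_mu_matches_sklearn_on_unregularized_toy(self):
        """Cross-check of the multiplicative-update core against scikit-learn's
        KL NMF ('mu' solver) on a small unpenalized problem."""
        from sklearn.decomposition import NMF

        rng = np.random.default_rng(9)
        V = rng.gamma(2, 2, (40, 5)) + 0.01
        W = rng.uniform(0.5, 1.5, (40, 2))
        K = rng.uniform(0.5, 1.5, (2, 5))
        for _ in range(3000):
            W = multiplicative_update_W(V, W, K, 0.0)
            K = multiplicative_update_K(V, W, K, 0.0)
        mine = kl_divergence(V, W @ K)
        best_sk = np.inf
        for seed in range(10):
            model = NMF(
                n_components=2, solver="mu", beta_loss="kullback-leibler",
                init="random", random_state=seed, max_iter=3000, tol=1e-10,
            )
            Wsk = model.fit_transform(V)
            best_sk = min(best_sk, kl_divergence(V, Wsk @ model.components_))
        assert mine <= best_sk * (1 + 1e-3) + 1e-6


class TestRescale:
    def test_constant_column_unchanged(self):
        W = np.ones((50, 1))
        K = np.full((1, 2), 3.0)
        W2, K2 = rescale_result(W, K)
        np.testing.assert_array_equal(W2, W)
        np.testing.assert_array_equal(K2, K)

    def test_reconstruction_identical_to_machine_precision(self):
        rng = np.random.default_rng(10)
        W = rng.gamma(2, 2, (100, 3))
        K = rng.gamma(2, 2, (3, 7))
        W2, K2 = rescale_result(W, K)
        np.testing.assert_allclose(W2 @ K2, W @ K, rtol=1e-12)

    def test_98th_percentile_becomes_one(self):
        rng = np.random.default_rng(11)
        W = rng.gamma(2, 2, (500, 4))
        K = rng.gamma(2, 2, (4, 6))
        W2, _ = rescale_result(W, K, percentile=98.0)
        np.testing.assert_allclose(np.percentile(W2, 98, axis=0), 1.0, atol=1e-12)

    def test_zero_column_left_unscaled(self):
        W = np.zeros((10, 1))
        K = np.ones((1, 2))
        W2, K2 = rescale_result(W, K)
        np.testing.assert_array_equal(W2, W)
        np.testing.assert_array_equal(K2, K)


class TestExtendGenomewide:
    def test_all_zero_bin_gives_zero_row(self):
        rng = np.random.default_rng(12)
        V = rng.gamma(2, 2, (30, 4))
        V[7] = 0.0
        K = rng.gamma(2, 2, (2, 4))
        cfg = FactorizationConfig(max_iter=500)
        W = extend_genomewide(V, K, cfg)
        np.testing.assert_array_equal(W[7], 0.0)
        assert np.all(W >= 0)

    def test_chunked_equals_whole(self):
        rng = np.random.default_rng(13)
        V = rng.gamma(2, 2, (90, 4))
        K = rng.gamma(2, 2, (2, 4))
        whole = extend_genomewide(V, K, FactorizationConfig(extend_chunk=1000))
        chunked = extend_genomewide(V, K, FactorizationConfig(extend_chunk=17))
        # rows are solved independently; chunking only changes BLAS blocking,
        # so agreement is to the last few ulp
        np.testing.assert_allclose(whole, chunked, rtol=1e-12, atol=1e-300)

    def test_training_rows_agree_with_training_solve(self):
        rng = np.random.default_rng(14)
        V = rng.gamma(2, 2, (60, 4))
        K = rng.gamma(2, 2, (2, 4))
        cfg = FactorizationConfig(max_iter=5000, tol=1e-13)
        full = extend_genomewide(V, K, cfg)
        subset = extend_genomewide(V[10:30], K, cfg)
        np.testing.assert_allclose(full[10:30], subset, rtol=1e-4)


class TestRecovery:
    def test_bias_signal_recovers_true_chromatin_bias(self, default_sim):
        """Pearson r(log x, log a*m*n) >= 0.9 on the default simulation."""
        truth, tracks = default_sim
        cfg = FactorizationConfig(n_train_bins=5000)
        result = deconvolve(tracks, cfg, seed=1)
        x = result.bias
        ok = x > 0
        r = np.corrcoef(np.log(x[ok]), np.log(truth.bias[ok]))[0, 1]
        assert r >= 0.9

    def test_nonnegativity_throughout(self, default_sim):
        _, tracks = default_sim
        result = deconvolve(tracks, FactorizationConfig(n_train_bins=5000), seed=2)
        assert np.all(result.W >= 0)
        assert np.all(result.K >= 0)

    def test_low_specificity_sample_has_higher_background_weight(self):
        """The mixing matrix separates good from poor antibodies."""
        from chipdeconv.simulate import SimulationConfig, simulate_experiment

        marks = (
            dataclasses.replace(
                SimulationConfig().marks[0], name="good_ab", specificity=2.0
            ),
            dataclasses.replace(
                SimulationConfig().marks[1], name="poor_ab", specificity=0.3
            ),
        )
        cfg = SimulationConfig(genome_length=400_000, marks=marks, seed=3,
                               specificity_jitter_sd=0.0)
        _, tracks = simulate_experiment(cfg)
        result = deconvolve(tracks, FactorizationConfig(n_train_bins=2000), seed=3)
        frac = result.background_fraction()
        good = [j for j, s in enumerate(tracks.samples) if s.condition == "good_ab"]
        poor = [j for j, s in enumerate(tracks.samples) if s.condition == "poor_ab"]
        assert frac[poor].mean() > frac[good].mean()
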