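import numpy as np
import pytest
from scipy.stats import kstest

import tumortwin as tt
from tumortwin.calibrate import (
    PosteriorEnsemble,
    abc_rejection,
    default_priors,
    epsilon_floor,
    lm_fit,
    posterior_predict,
    reduced_mse,
)


class TestPriors:
    def test_truncation_respected(self, reference_priors, rng):
        s = reference_priors.sample(rng, 100_000)
        assert s["D"].min() >= 1e-6 and s["D"].max() <= 1e-3
        assert s["alpha"].min() >= 1e-6 and s["alpha"].max() <= 1.0
        assert s["beta_A"].min() >= 0.35 and s["beta_A"].max() <= 0.85
        assert s["beta_C"].min() >= 1.0 and s["beta_C"].max() <= 5.5
        lo, hi = reference_priors.k_bounds
        assert np.all(s["Kr"] >= lo - 1e-12) and np.all(s["Kr"] <= hi + 1e-12)

    def test_beta_c_moments_match_truncated_normal(self, reference_priors, rng):
        s = reference_priors.beta["C"].rvs(size=100_000, random_state=rng)
        se = reference_priors.beta["C"].std() / np.sqrt(s.size)
        assert abs(s.mean() - reference_priors.beta["C"].mean()) < 3 * se

    def test_logpdf_finite_inside_support(self, reference_priors, rng):
        s = reference_priors.sample(rng, 3)
        from tumortwin.calibrate import _samples_to_flat

        for row in _samples_to_flat(s):
            assert np.isfinite(reference_priors.logpdf(row))


class TestLMFit:
    def test_fit_respects_bounds_and_beats_noise_floor(self, reference_rom, reference_data, reference_priors):
        theta, eps, _ = lm_fit(reference_rom, reference_data, reference_priors, seed=0)
        b = theta.__class__.BOUNDS
        assert b["D"][0] <= theta.D <= b["D"][1]
        assert b["alpha"][0] <= theta.alpha <= b["alpha"][1]
        assert b["beta_A"][0] <= theta.beta["A"] <= b["beta_A"][1]
        assert b["beta_C"][0] <= theta.beta["C"] <= b["beta_C"][1]
        # zero-noise synthetic patient: the fit reaches (numerically) zero misfit
        assert eps < epsilon_floor(reference_data)

    def test_fit_error_is_minimum_of_sampled_distances(
        self, reference_rom, reference_data, reference_priors, rng
    ):
        _, eps, _ = lm_fit(reference_rom, reference_data, reference_priors, seed=0)
        d = reduced_mse(reference_rom, reference_data, reference_priors.sample(rng, 500))
        assert eps <= d.min()


class TestRejectionABC:
    def test_accept_all_limit_reproduces_priors(self, reference_rom, reference_data, reference_priors):
        ens = abc_rejection(
            reference_rom, reference_data, reference_priors, epsilon=np.inf, n_accept=500, seed=11
        )
        assert len(ens) == 500
        assert ens.attempts >= 500  # whole batches are simulated at once
        for arr, dist in ((ens.D, reference_priors.D), (ens.beta_A, reference_priors.beta["A"]),
                          (ens.beta_C, reference_priors.beta["C"]), (ens.alpha, reference_priors.alpha)):
            assert kstest(arr, dist.cdf).pvalue > 0.01

    def test_accepted_distances_below_epsilon(self, reference_rom, reference_data, reference_priors):
        eps = 0.5  # permissive enough for plain rejection
        ens = abc_rejection(
            reference_rom, reference_data, reference_priors, epsilon=eps, n_accept=50,
            batch_size=500, seed=2,
        )
        assert np.all(ens.distances <= eps)
        assert len(ens) == 50

    def test_deterministic_under_seed(self, reference_rom, reference_data, reference_priors):
        kw = dict(epsilon=np.inf, n_accept=40, seed=7)
        a = abc_rejection(reference_rom, reference_data, reference_priors, **kw)
        b = abc_rejection(reference_rom, reference_data, reference_priors, **kw)
        np.testing.assert_array_equal(a.Kr, b.Kr)
        np.testing.assert_array_equal(a.alpha, b.alpha)

    def test_unreachable_tolerance_aborts(self, reference_rom, reference_data, reference_priors):
        with pytest.raises(RuntimeError):
            abc_rejection(
                reference_rom, reference_data, reference_priors, epsilon=1e-12,
                n_accept=10, max_attempts=4000, batch_size=1000, rate_floor=1e-2, seed=0,
            )


class TestSequentialABC:
    def test_reaches_target_and_matches_tolerance(self, reference_ensemble, reference_data):
        assert len(reference_ensemble) == 500
        assert np.all(reference_ensemble.distances <= reference_ensemble.epsilon + 1e-15)
        assert reference_ensemble.epsilon <= epsilon_floor(reference_data) + 1e-15

    def test_posterior_explains_data_better_than_prior(
        self, reference_ensemble, reference_rom, reference_data, reference_priors, rng
    ):
        prior_d = reduced_mse(reference_rom, reference_data, reference_priors.sample(rng, 500))
        assert np.median(reference_ensemble.distances) < 0.01 * np.median(prior_d)


class TestPosteriorPredict:
    def test_degenerate_ensemble_zero_iqr(self, reference_rom, reference_data, reference_priors, responder):
        s = reference_priors.sample(np.random.default_rng(0), 1)
        from tumortwin.calibrate import _samples_to_flat, _flat_to_samples

        flat = np.repeat(_samples_to_flat(s), 8, axis=0)
        ens = PosteriorEnsemble.from_samples(_flat_to_samples(flat), np.zeros(8), 1.0, 8)
        pred = posterior_predict(
            reference_rom, ens, reference_data.regimen, reference_data.auc_assign,
            reference_data.u0, (0, 28), store_every=7.0,
        )
        np.testing.assert_allclose(pred.cells_iqr[0], pred.cells_iqr[1])

    def test_median_invariant_to_sample_order(self, reference_rom, reference_data, reference_ensemble):
        e = reference_ensemble
        perm = np.random.default_rng(3).permutation(len(e))
        shuffled = PosteriorEnsemble(
            D=e.D[perm], alpha=e.alpha[perm], beta_A=e.beta_A[perm], beta_C=e.beta_C[perm],
            Kr=e.Kr[perm], distances=e.distances[perm], epsilon=e.epsilon, attempts=e.attempts,
        )
        kw = dict(store_every=14.0)
        a = posterior_predict(reference_rom, e, reference_data.regimen, reference_data.auc_assign,
                              reference_data.u0, (0, 28), **kw)
        b = posterior_predict(reference_rom, shuffled, reference_data.regimen, reference_data.auc_assign,
                              reference_data.u0, (0, 28), **kw)
        np.testing.assert_allclose(a.cells_median, b.cells_median)

    def test_v2_prediction_error_bounded_by_tolerance(
        self, reference_rom, reference_data, reference_ensemble, responder
    ):
        """Every accepted sample satisfies MSE <= epsilon in reduced
        coordinates, which bounds the bulk-cell misfit at V2 through
        Cauchy-Schwarz: |total - measured| <= theta * ||w|| * sqrt(r*eps)
        with w the reduced total-cells functional.  (The predictive IQR
        itself need not cover the measurement: the prior concentrates
        the posterior on the over-predicting side of the tolerance
        ball.)"""
        pred = posterior_predict(
            reference_rom, reference_ensemble, reference_data.regimen, reference_data.auc_assign,
            reference_data.u0, (0, 28), store_every=28.0,
        )
        # the guarantee is relative to the projected V2 data: the basis
        # truncation itself shifts the raw measurement's total mass
        projected_total = reference_rom.theta_cap * float(
            reference_rom.cells_weights @ reference_data.data_v2
        )
        r = reference_rom.rank
        bound = reference_rom.theta_cap * np.linalg.norm(reference_rom.cells_weights) * np.sqrt(
            r * reference_ensemble.epsilon
        )
        # clipping the lifted fields can only add a bounded positive margin
        assert np.all(np.abs(pred.cells[:, -1] - projected_total) <= 1.3 * bound)
        assert abs(pred.cells_median[-1] - projected_total) <= 1.3 * bound
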