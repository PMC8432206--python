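"""Folded-plane likelihood: evaluation, simulation and fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from sgascreen import (
    REFERENCE_RATIO,
    REFERENCE_SFLT1,
    FitConfig,
    FoldedPlaneParams,
    fit_folded_plane,
    folded_mean,
    marker_loglik,
    plane_value,
    simulate_observations,
)


class TestPlaneValue:
    def test_reference_ratio_at_term_origin(self, ratio_params):
        # intercept alone: Z = 0 and GA at the transform centre
        assert plane_value(ratio_params, 0.0, 40.0) == pytest.approx(-0.25555636, abs=1e-10)

    def test_reference_ratio_small_preterm(self, ratio_params):
        # -0.25555636 + (-0.12802946)(-3) + (-0.01624357)(28-40)
        assert plane_value(ratio_params, -3.0, 28.0) == pytest.approx(0.32345486, abs=1e-8)

    def test_zero_coefficients_give_zero_everywhere(self):
        p = FoldedPlaneParams(0.0, 0.0, 0.0, 1.0, "linear_offset", 40.0, "none")
        for z, g in [(-4, 25), (0, 40), (3, 42.5)]:
            assert plane_value(p, z, g) == 0.0

    def test_reciprocal_singularity_raises(self):
        p = FoldedPlaneParams(0.0, 0.0, 1.0, 1.0, "reciprocal_offset", 33.0,
                              "max_at_zero", ga_applicability_cutoff=32.0)
        with pytest.raises(ValueError, match="singular"):
            plane_value(p, 0.0, 33.0)


class TestFoldedMean:
    def test_negative_plane_folds_up_to_zero(self, ratio_params):
        assert folded_mean(ratio_params, 0.0, 40.0) == 0.0

    def test_positive_plane_is_unchanged(self, ratio_params):
        assert folded_mean(ratio_params, -3.0, 28.0) == pytest.approx(0.32345486, abs=1e-8)

    def test_ga_cutoff_forces_zero_mean(self, sflt1_params):
        # past the applicability cut-off the marker carries no information
        assert folded_mean(sflt1_params, -5.0, 35.0) == 0.0

    @settings(deadline=None, derandomize=True)
    @given(z=st.floats(-6, 5), ga=st.floats(24, 43))
    def test_max_fold_geometry(self, z, ga):
        p = REFERENCE_RATIO
        m = folded_mean(p, z, ga)
        assert m >= 0.0
        pv = plane_value(p, z, ga)
        if pv > 0:
            assert m == pytest.approx(pv, abs=1e-12)


class TestMarkerLoglik:
    def test_single_observation_at_its_mean(self, ratio_params):
        # Gaussian log-density at the mode, sd = 0.31564903
        expected = norm.logpdf(0.0, 0.0, ratio_params.sd)
        ll = marker_loglik(ratio_params, [0.32345486], [-3.0], [28.0])
        assert ll == pytest.approx(expected, abs=1e-7)
        assert ll == pytest.approx(0.2342, abs=5e-4)

    def test_additivity_over_observations(self, ratio_params):
        one = marker_loglik(ratio_params, [0.1], [-2.0], [30.0])
        two = marker_loglik(ratio_params, [0.4], [0.5], [40.0])
        both = marker_loglik(ratio_params, [0.1, 0.4], [-2.0, 0.5], [30.0, 40.0])
        assert both == pytest.approx(one + two, abs=1e-10)

    def test_shifting_away_from_mean_decreases_loglik(self, ratio_params):
        base = marker_loglik(ratio_params, [0.32345486], [-3.0], [28.0])
        for shift in (0.1, 0.5, 2.0):
            assert marker_loglik(ratio_params, [0.32345486 + shift], [-3.0], [28.0]) < base

    def test_empty_observations_contribute_zero(self, ratio_params):
        assert marker_loglik(ratio_params, [], [], []) == 0.0

    def test_agrees_with_naive_density_summation(self, rng):
        """Brute-force oracle: per-observation scipy logpdf summation."""
        for _ in range(100):
            params = FoldedPlaneParams(
                intercept=rng.normal(0, 0.3),
                slope_z=rng.normal(0, 0.2),
                slope_ga=rng.normal(0, 0.02),
                sd=rng.uniform(0.1, 0.5),
                fold=rng.choice(["max_at_zero", "min_at_zero", "none"]),
            )
            n = rng.integers(1, 8)
            z = rng.normal(0, 2, n)
            ga = rng.uniform(24, 43, n)
            y = rng.normal(0, 0.5, n)
            naive = sum(
                norm.logpdf(yi, folded_mean(params, zi, gi), params.sd)
                for yi, zi, gi in zip(y, z, ga)
            )
            assert marker_loglik(params, y, z, ga) == pytest.approx(naive, abs=1e-10)


class TestSimulateObservations:
    def test_tiny_sd_reproduces_folded_means(self, ratio_params, rng):
        p = FoldedPlaneParams(**{**ratio_params.to_dict(), "sd": 1e-12})
        z = rng.normal(0, 1, 50)
        ga = rng.uniform(25, 42, 50)
        y = simulate_observations(p, z, ga, rng)
        assert np.allclose(y, folded_mean(p, z, ga), atol=1e-9)

    def test_sample_sd_matches_parameter(self, ratio_params):
        n = 100_000
        y = simulate_observations(ratio_params, np.full(n, -3.0), np.full(n, 28.0), 5)
        se_sd = ratio_params.sd / math.sqrt(2 * n)
        assert abs(np.std(y, ddof=1) - ratio_params.sd) < 3 * se_sd
        assert np.mean(y) == pytest.approx(0.32345486, abs=3 * ratio_params.sd / math.sqrt(n))

    def test_same_seed_identical_draws(self, ratio_params):
        z, ga = np.array([-1.0, 0.5]), np.array([30.0, 40.0])
        a = simulate_observations(ratio_params, z, ga, 99)
        b = simulate_observations(ratio_params, z, ga, 99)
        assert np.array_equal(a, b)


class TestValidation:
    def test_sd_must_be_positive(self):
        with pytest.raises(ValueError, match="sd"):
            FoldedPlaneParams(0.0, 0.0, 0.0, 0.0)

    def test_reciprocal_requires_cutoff_below_center(self):
        with pytest.raises(ValueError, match="cutoff"):
            FoldedPlaneParams(0.0, 0.0, 0.0, 1.0, "reciprocal_offset", 33.0, "max_at_zero")

    def test_fit_requires_50_observations(self, ratio_params):
        with pytest.raises(ValueError, match="50"):
            fit_folded_plane([0.0] * 10, [0.0] * 10, [40.0] * 10,
                             FitConfig(structure=ratio_params))


class TestFitting:
    def test_noiseless_unfolded_plane_recovered_exactly(self, rng):
        truth = FoldedPlaneParams(0.12, -0.08, -0.02, 1e-8, "linear_offset", 40.0, "none")
        z = rng.normal(0, 1.5, 400)
        ga = rng.uniform(25, 42, 400)
        y = np.asarray(folded_mean(truth, z, ga))
        res = fit_folded_plane(y, z, ga, FitConfig(structure=truth))
        assert res.estimates["intercept"] == pytest.approx(0.12, abs=1e-6)
        assert res.estimates["slope_z"] == pytest.approx(-0.08, abs=1e-6)
        assert res.estimates["slope_ga"] == pytest.approx(-0.02, abs=1e-6)

    def test_sd_mle_matches_rms_residual(self, ratio_params, rng):
        """Profile likelihood in the SD is maximized at the RMS residual."""
        z = rng.normal(0, 1, 5000)
        ga = rng.uniform(25, 42, 5000)
        y = simulate_observations(ratio_params, z, ga, rng)
        res = fit_folded_plane(y, z, ga, FitConfig(structure=ratio_params))
        resid = y - folded_mean(res.params, z, ga)
        rms = math.sqrt(np.mean(resid**2))
        assert res.estimates["sd"] == pytest.approx(rms, rel=1e-4)

    def test_mle_and_mcmc_agree_on_identified_parameters(self, ratio_params):
        from sgascreen.protocols import parameter_recovery

        mle = parameter_recovery(ratio_params, 30_000, 3, method="mle")
        mcmc = parameter_recovery(
            ratio_params, 30_000, 3, method="mcmc", n_walkers=12, n_steps=700, n_burn=250
        )
        # sd and slope_ga are well identified; posterior mean ~ MLE
        assert mcmc.estimates["sd"] == pytest.approx(mle.estimates["sd"], abs=3 * mcmc.se["sd"])
        assert mcmc.estimates["slope_ga"] == pytest.approx(
            mle.estimates["slope_ga"], abs=3 * mcmc.se["slope_ga"]
        )

    def test_mcmc_is_seed_deterministic(self, ratio_params):
        from sgascreen.protocols import parameter_recovery

        a = parameter_recovery(ratio_params, 5_000, 5, method="mcmc",
                               n_walkers=8, n_steps=200, n_burn=50)
        b = parameter_recovery(ratio_params, 5_000, 5, method="mcmc",
                               n_walkers=8, n_steps=200, n_burn=50)
        assert a.estimates == b.estimates

    def test_non_identified_directions_flagged_not_silent(self, sflt1_params):
        """With no fold-active data the slopes must come back non-identified."""
        rng = np.random.default_rng(8)
        n = 5000
        z = rng.normal(0, 1, n)
        ga = rng.uniform(33, 42, n)  # all past the 32-week cut-off
        y = rng.normal(0, sflt1_params.sd, n)
        res = fit_folded_plane(y, z, ga, FitConfig(structure=sflt1_params))
        assert not res.identified["slope_z"]
        assert res.intervals["slope_z"] == (-math.inf, math.inf)
        assert res.identified["sd"]
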