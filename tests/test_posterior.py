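"""Bayes grid engine: likelihood surfaces, posteriors, orthant risks."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from sgascreen import (
    REFERENCE_RATIO,
    FoldedPlaneParams,
    OutcomeCutoff,
    PosteriorSurface,
    PriorParams,
    cohort_risks,
    likelihood_surface,
    posterior_surface,
    prior_risk,
    risk_from_posterior,
)
from sgascreen.grids import Grid2D
from sgascreen.prior import prior_density_on_grid


@pytest.fixture(scope="module")
def grid():
    return Grid2D.default()


@pytest.fixture(scope="module")
def prior_surface(grid):
    prior = PriorParams.independent()
    return PosteriorSurface(grid, prior_density_on_grid(prior, {}, grid), normalized=True)


def conjugate_posterior(prior: PriorParams, params: FoldedPlaneParams, y: float):
    """Closed-form Gaussian update for an unfolded linear-GA likelihood.

    x = (GA, Z); the likelihood mean is h.x + offset with h = (slope_ga,
    slope_z); returns posterior mean vector and marginal SDs.
    """
    s = prior.z_on_ga_slope
    lam = np.array(
        [
            [1 / prior.ga_sd**2 + s**2 / prior.z_sd**2, -s / prior.z_sd**2],
            [-s / prior.z_sd**2, 1 / prior.z_sd**2],
        ]
    )
    mu = np.array([prior.ga_mean_base, prior.z_mean_base + s * prior.ga_mean_base])
    h = np.array([params.slope_ga, params.slope_z])
    offset = params.intercept - params.slope_ga * params.ga_center
    lam_post = lam + np.outer(h, h) / params.sd**2
    rhs = lam @ mu + h * (y - offset) / params.sd**2
    mean = np.linalg.solve(lam_post, rhs)
    cov = np.linalg.inv(lam_post)
    return mean, np.sqrt(np.diag(cov))


class TestPosteriorSurface:
    def test_flat_likelihood_is_bayes_identity(self, grid, prior_surface):
        flat = np.ones(grid.shape)
        post = posterior_surface(prior_surface, flat)
        assert np.max(np.abs(post.density - prior_surface.density)) < 1e-10

    def test_two_flat_likelihoods_still_prior(self, grid, prior_surface):
        flat = np.ones(grid.shape)
        post = posterior_surface(prior_surface, flat, 0.5 * flat)
        assert np.max(np.abs(post.density - prior_surface.density)) < 1e-10

    def test_posterior_normalizes_to_unit_mass(self, grid, prior_surface):
        lik = likelihood_surface(0.3, REFERENCE_RATIO, grid)
        post = posterior_surface(prior_surface, lik)
        assert post.mass() == pytest.approx(1.0, abs=1e-6)

    def test_underflowing_product_raises_helpfully(self, grid, prior_surface):
        with pytest.raises(ValueError, match="underflow"):
            posterior_surface(prior_surface, np.zeros(grid.shape))

    def test_conjugate_gaussian_oracle(self, grid):
        """Fold disabled: grid posterior matches the closed-form update."""
        prior = PriorParams(38.0, 0.7, 0.2, 0.0, 0.7)
        params = FoldedPlaneParams(0.1, -0.2, -0.02, 0.35, "linear_offset", 40.0, "none")
        y = 0.25
        surface = PosteriorSurface(
            grid, prior_density_on_grid(prior, {}, grid), normalized=True
        )
        post = posterior_surface(surface, likelihood_surface(y, params, grid))
        mean_ga, mean_z = post.mean()
        sd_ga, sd_z = post.sd()
        (exp_ga, exp_z), (esd_ga, esd_z) = conjugate_posterior(prior, params, y)
        assert mean_ga == pytest.approx(exp_ga, abs=1e-4)
        assert mean_z == pytest.approx(exp_z, abs=1e-4)
        assert sd_ga == pytest.approx(esd_ga, abs=1e-4)
        assert sd_z == pytest.approx(esd_z, abs=1e-4)


class TestLikelihoodSurface:
    def test_zero_coefficients_give_flat_surface(self, grid):
        p = FoldedPlaneParams(0.0, 0.0, 0.0, 0.3, "linear_offset", 40.0, "none")
        s = likelihood_surface(0.1, p, grid)
        assert np.allclose(s, s.flat[0])

    def test_value_at_mode_is_gaussian_peak_density(self, grid):
        y = 0.32345486
        s = likelihood_surface(y, REFERENCE_RATIO, grid)
        i = int(np.argmin(np.abs(grid.ga - 28.0)))
        j = int(np.argmin(np.abs(grid.z - (-3.0))))
        peak = 1.0 / (REFERENCE_RATIO.sd * math.sqrt(2 * math.pi))
        assert s[i, j] == pytest.approx(peak, rel=1e-6)


class TestRiskFromPosterior:
    def test_cutoff_at_grid_maxima_gives_one(self, prior_surface, grid):
        r = risk_from_posterior(prior_surface, OutcomeCutoff(grid.z[-1], grid.ga[-1]))
        assert r == pytest.approx(1.0, abs=1e-6)

    def test_independent_gaussian_product_cdf(self, grid):
        prior = PriorParams.independent(ga_support=(24.0, 47.0))
        g = Grid2D.default(ga_range=(24.0, 47.0))
        surf = PosteriorSurface(g, prior_density_on_grid(prior, {}, g), normalized=True)
        r = risk_from_posterior(surf, OutcomeCutoff(-1.2815515655, 37.0))
        assert r == pytest.approx(norm.cdf(-1.2815515655) * norm.cdf(-1.25), abs=1e-4)

    def test_nested_cutoffs_give_nested_risks(self, prior_surface):
        r_small = risk_from_posterior(prior_surface, OutcomeCutoff(-1.8808, 32.0))
        r_big = risk_from_posterior(prior_surface, OutcomeCutoff(-1.2816, 37.0))
        assert 0.0 <= r_small <= r_big <= 1.0


class TestCohortRisks:
    def test_no_markers_equals_prior_risk(self, small_cohort):
        prior = PriorParams.independent()
        grid = Grid2D.default(step=0.1)
        cut = OutcomeCutoff(-1.2816, 37.0)
        risks = cohort_risks(small_cohort.head(5), prior, {}, cut, grid=grid)
        expected = prior_risk(prior, {}, cut.z_cut, cut.ga_cut, grid=grid)
        assert np.allclose(risks, expected, atol=1e-12)

    def test_record_order_does_not_matter(self, small_cohort):
        prior = PriorParams.independent()
        grid = Grid2D.default(step=0.1)
        cut = OutcomeCutoff(-1.2816, 37.0)
        head = small_cohort.head(20)
        fwd = cohort_risks(head, prior, {"ratio": REFERENCE_RATIO}, cut, grid=grid)
        rev = cohort_risks(
            head.iloc[::-1].reset_index(drop=True),
            prior,
            {"ratio": REFERENCE_RATIO},
            cut,
            grid=grid,
        )
        assert np.allclose(fwd, rev[::-1], atol=1e-14)

    def test_informative_marker_raises_risk_of_affected_typical_record(self):
        """A high ratio MoM (elevated sFlt-1 relative to PlGF) must raise risk."""
        prior = PriorParams.independent()
        grid = Grid2D.default(step=0.1)
        cut = OutcomeCutoff(-1.2816, 32.0)
        rec = pd.DataFrame(
            {"ga_delivery": [30.0], "z_bw": [-2.5], "pe": [0], "mom_ratio": [10**0.5]}
        )
        base = cohort_risks(rec, prior, {}, cut, grid=grid)[0]
        with_marker = cohort_risks(rec, prior, {"ratio": REFERENCE_RATIO}, cut, grid=grid)[0]
        assert with_marker > base

    def test_missing_marker_column_raises(self, small_cohort):
        df = small_cohort.drop(columns=["mom_ratio"])
        with pytest.raises(KeyError, match="mom_ratio"):
            cohort_risks(
                df, PriorParams.independent(), {"ratio": REFERENCE_RATIO},
                OutcomeCutoff(-1.2816, 37.0),
            )

    def test_risk_decile_calibration(self, study_cohort):
        """Observed outcome frequency should rise with modelled risk decile."""
        from scipy.stats import spearmanr

        from sgascreen.cohort import default_prior

        cut = OutcomeCutoff(-1.2816, 37.0)
        grid = Grid2D.default(step=0.1)
        risks = cohort_risks(
            study_cohort, default_prior(), {"ratio": REFERENCE_RATIO}, cut, grid=grid
        )
        outcome = (
            (study_cohort.z_bw < cut.z_cut) & (study_cohort.ga_delivery < cut.ga_cut)
        ).to_numpy()
        decile = pd.qcut(risks, 10, labels=False, duplicates="drop")
        freq = pd.Series(outcome).groupby(decile).mean()
        rho = spearmanr(freq.index, freq.values).statistic
        assert rho > 0.9
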