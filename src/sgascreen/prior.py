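"""Maternal-factor prior for (GA at delivery, birth-weight Z score).

The prior is a bivariate Gaussian factorized as a GA marginal times a Z | GA
conditional whose mean is linear in GA; maternal covariates shift both means
linearly.  GA is truncated to a configurable support (default [24, 43] weeks,
the livebirth registration range) and renormalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.special import ndtr

from .grids import Grid2D, orthant_mass

__all__ = ["PriorParams", "profile_shifted_means", "prior_density_on_grid", "prior_risk"]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class PriorParams:
    """Bivariate-Gaussian joint prior with linear maternal-factor shifts.

    GA_Delivery ~ Normal(ga_mean, ga_sd) truncated to ``ga_support``;
    Z_BW | GA = g ~ Normal(z_mean_base + z_on_ga_slope * g + shifts, z_sd),
    where each mean is shifted by the dot product of the profile covariates
    with the corresponding shift coefficients.
    """

    ga_mean_base: float
    ga_sd: float
    z_mean_base: float
    z_on_ga_slope: float
    z_sd: float
    ga_shift_coefficients: Mapping[str, float] = field(default_factory=dict)
    z_shift_coefficients: Mapping[str, float] = field(default_factory=dict)
    ga_support: tuple[float, float] = (24.0, 43.0)

    def __post_init__(self) -> None:
        if not self.ga_sd > 0:
            raise ValueError("ga_sd must be > 0")
        if not self.z_sd > 0:
            raise ValueError("z_sd must be > 0")
        lo, hi = self.ga_support
        if not lo < hi:
            raise ValueError("ga_support must satisfy low < high")

    # -- simple constructors -------------------------------------------------

    @classmethod
    def independent(
        cls,
        ga_mean: float = 39.5,
        ga_sd: float = 2.0,
        z_mean: float = 0.0,
        z_sd: float = 1.0,
        ga_support: tuple[float, float] = (24.0, 43.0),
    ) -> "PriorParams":
        """A prior with no GA–Z coupling and no covariate shifts.

        This is the simple reference prior used by the parameter-recovery
        protocols: GA ~ Normal(39.5, 2.0) truncated to the support,
        independent of Z ~ Normal(0, 1).
        """
        return cls(
            ga_mean_base=ga_mean,
            ga_sd=ga_sd,
            z_mean_base=z_mean,
            z_on_ga_slope=0.0,
            z_sd=z_sd,
            ga_support=ga_support,
        )

    def to_dict(self) -> dict:
        return {
            "ga_mean_base": self.ga_mean_base,
            "ga_sd": self.ga_sd,
            "z_mean_base": self.z_mean_base,
            "z_on_ga_slope": self.z_on_ga_slope,
            "z_sd": self.z_sd,
            "ga_shift_coefficients": dict(self.ga_shift_coefficients),
            "z_shift_coefficients": dict(self.z_shift_coefficients),
            "ga_support": list(self.ga_support),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PriorParams":
        d = dict(d)
        d["ga_support"] = tuple(d.get("ga_support", (24.0, 43.0)))
        return cls(**d)


def _shift(coeffs: Mapping[str, float], profile: Mapping[str, float]) -> float:
    missing = [k for k in coeffs if k not in profile]
    if missing:
        raise KeyError(f"profile is missing covariates required by the prior: {missing}")
    return float(sum(c * float(profile[k]) for k, c in coeffs.items()))


def profile_shifted_means(
    prior: PriorParams, profile: Mapping[str, float]
) -> tuple[float, float]:
    """(GA mean, Z-conditional intercept) for one maternal profile.

    The Z mean at gestation g is ``z_intercept + z_on_ga_slope * g`` where
    ``z_intercept`` is the second returned value.
    """
    ga_mean = prior.ga_mean_base + _shift(prior.ga_shift_coefficients, profile)
    z_intercept = prior.z_mean_base + _shift(prior.z_shift_coefficients, profile)
    return ga_mean, z_intercept


def prior_log_density_on_grid(
    prior: PriorParams, profile: Mapping[str, float], grid: Grid2D
) -> np.ndarray:
    """Unnormalized log prior density on the grid (GA rows, Z columns)."""
    lo, hi = prior.ga_support
    if grid.ga[0] < lo - 1e-9 or grid.ga[-1] > hi + 1e-9:
        raise ValueError(
            f"grid GA range [{grid.ga[0]}, {grid.ga[-1]}] outside prior support [{lo}, {hi}]"
        )
    ga_mean, z_intercept = profile_shifted_means(prior, profile)
    g = grid.ga[:, None]
    z = grid.z[None, :]
    log_ga = -0.5 * ((g - ga_mean) / prior.ga_sd) ** 2 - np.log(prior.ga_sd) - _LOG_SQRT_2PI
    z_mean = z_intercept + prior.z_on_ga_slope * g
    log_z = -0.5 * ((z - z_mean) / prior.z_sd) ** 2 - np.log(prior.z_sd) - _LOG_SQRT_2PI
    return log_ga + log_z


def prior_density_on_grid(
    prior: PriorParams, profile: Mapping[str, float], grid: Grid2D
) -> np.ndarray:
    """Normalized prior density on the grid (unit trapezoidal mass).

    Truncation to the GA support is implicit: the grid must lie inside the
    support, and renormalization makes the gridded mass 1.
    """
    logd = prior_log_density_on_grid(prior, profile, grid)
    d = np.exp(logd - logd.max())
    return d / grid.mass(d)


def prior_risk(
    prior: PriorParams,
    profile: Mapping[str, float],
    z_cut: float,
    ga_cut: float,
    grid: Grid2D | None = None,
) -> float:
    """P(Z_BW < z_cut, GA_Delivery < ga_cut) under the truncated prior.

    Computed on the same grid engine as the posterior risks so that a flat
    likelihood reproduces these values exactly.  Cut-offs beyond the grid are
    clamped to its edges (a cut above the support top asks for total mass).
    """
    if grid is None:
        grid = Grid2D.default(ga_range=prior.ga_support)
    density = prior_density_on_grid(prior, profile, grid)
    z_cut = float(np.clip(z_cut, grid.z[0], grid.z[-1]))
    ga_cut = float(np.clip(ga_cut, grid.ga[0], grid.ga[-1]))
    return orthant_mass(grid, density, z_cut, ga_cut)


def truncated_ga_moments(prior: PriorParams) -> tuple[float, float]:
    """Mean and SD of the truncated GA marginal (no covariate shifts)."""
    lo, hi = prior.ga_support
    a = (lo - prior.ga_mean_base) / prior.ga_sd
    b = (hi - prior.ga_mean_base) / prior.ga_sd
    phi = lambda x: np.exp(-0.5 * x * x) / np.sqrt(2 * np.pi)
    zmass = ndtr(b) - ndtr(a)
    m = (phi(a) - phi(b)) / zmass
    v = 1.0 + (a * phi(a) - b * phi(b)) / zmass - m * m
    return prior.ga_mean_base + prior.ga_sd * m, prior.ga_sd * float(np.sqrt(v))
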