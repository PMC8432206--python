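"""Bayes' theorem on the (GA, Z) grid: prior x likelihoods -> orthant risks.

The personalized joint posterior of (GA_Delivery, Z_BW) is the pointwise
product of the maternal-factor prior surface with one Gaussian
likelihood surface per observed marker, renormalized to unit mass.  The risk
for an outcome cut-off (z_cut, ga_cut) is the posterior mass of the
lower-left orthant.  All products are computed in log space with a single
max-subtraction before exponentiation, so likelihoods that would underflow a
direct product are handled exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .folded_plane import FoldedPlaneParams, folded_mean
from .grids import Grid2D, orthant_mass
from .prior import PriorParams, prior_log_density_on_grid

__all__ = [
    "OutcomeCutoff",
    "PosteriorSurface",
    "likelihood_surface",
    "log_likelihood_surface",
    "posterior_surface",
    "risk_from_posterior",
    "cohort_risks",
    "Z_CUT_10TH",
    "Z_CUT_3RD",
]

#: Standard-normal quantiles for the 10th and 3rd birth-weight percentiles.
Z_CUT_10TH = -1.2815515655446004
Z_CUT_3RD = -1.8807936081512509

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


@dataclass(frozen=True)
class OutcomeCutoff:
    """An SGA outcome definition: Z below z_cut and delivery before ga_cut."""

    z_cut: float
    ga_cut: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.z_cut) or not np.isfinite(self.ga_cut):
            raise ValueError("cut-offs must be finite")

    def label(self) -> str:
        pct = {round(Z_CUT_10TH, 4): "10th", round(Z_CUT_3RD, 4): "3rd"}.get(
            round(self.z_cut, 4), f"Z<{self.z_cut:g}"
        )
        return f"SGA<{pct}, GA<{self.ga_cut:g}w"


@dataclass
class PosteriorSurface:
    """A (possibly normalized) joint density on a Grid2D."""

    grid: Grid2D
    density: np.ndarray
    normalized: bool = False

    def mass(self) -> float:
        return self.grid.mass(self.density)

    def normalize(self) -> "PosteriorSurface":
        m = self.mass()
        if not np.isfinite(m) or m <= 0:
            raise ValueError("cannot normalize a surface with non-positive mass")
        return PosteriorSurface(self.grid, self.density / m, normalized=True)

    def mean(self) -> tuple[float, float]:
        """Posterior means (GA, Z) by trapezoidal moments."""
        d = self.density if self.normalized else self.normalize().density
        g, z = self.grid.mesh()
        return self.grid.mass(g * d), self.grid.mass(z * d)

    def sd(self) -> tuple[float, float]:
        d = self.density if self.normalized else self.normalize().density
        g, z = self.grid.mesh()
        mg, mz = self.mean()
        return (
            math.sqrt(max(self.grid.mass((g - mg) ** 2 * d), 0.0)),
            math.sqrt(max(self.grid.mass((z - mz) ** 2 * d), 0.0)),
        )


def log_likelihood_surface(
    log10_mom: float, params: FoldedPlaneParams, grid: Grid2D
) -> np.ndarray:
    """Log Gaussian density of one observed log10 MoM at every grid node."""
    if not np.isfinite(log10_mom):
        raise ValueError("marker log10 MoM must be finite")
    g, z = grid.mesh()
    mean = folded_mean(params, z, g)
    r = (log10_mom - mean) / params.sd
    return -0.5 * r * r - math.log(params.sd) - _LOG_SQRT_2PI


def likelihood_surface(
    log10_mom: float, params: FoldedPlaneParams, grid: Grid2D
) -> np.ndarray:
    """Likelihood surface on the natural scale (not normalized over the grid)."""
    return np.exp(log_likelihood_surface(log10_mom, params, grid))


def posterior_surface(
    prior_surface: PosteriorSurface, *likelihoods: np.ndarray
) -> PosteriorSurface:
    """Pointwise product of prior and likelihood surfaces, renormalized.

    Likelihood surfaces may be passed on the natural scale; the product is
    formed in log space to avoid underflow.
    """
    grid = prior_surface.grid
    with np.errstate(divide="ignore"):
        logpost = np.log(prior_surface.density)
        for lik in likelihoods:
            lik = np.asarray(lik, dtype=float)
            if lik.shape != grid.shape:
                raise ValueError("likelihood surface not on the prior's grid")
            logpost = logpost + np.log(lik)
    peak = logpost.max()
    if not np.isfinite(peak):
        raise ValueError(
            "posterior underflowed everywhere; prior and likelihoods have no "
            "common support on this grid"
        )
    d = np.exp(logpost - peak)
    m = grid.mass(d)
    if m <= 0:
        raise ValueError("posterior has zero mass on the grid")
    return PosteriorSurface(grid, d / m, normalized=True)


def risk_from_posterior(posterior: PosteriorSurface, cutoff: OutcomeCutoff) -> float:
    """Posterior mass of {Z < z_cut, GA < ga_cut} (trapezoid + cut interpolation)."""
    if not posterior.normalized:
        posterior = posterior.normalize()
    return orthant_mass(posterior.grid, posterior.density, cutoff.z_cut, cutoff.ga_cut)


def _marker_column(name: str) -> str:
    return f"mom_{name}"


def cohort_risks(
    records: pd.DataFrame,
    prior: PriorParams,
    marker_models: Mapping[str, FoldedPlaneParams],
    cutoff: OutcomeCutoff,
    grid: Grid2D | None = None,
    covariates: Sequence[str] | None = None,
) -> np.ndarray:
    """Per-pregnancy posterior risks for one outcome cut-off.

    ``marker_models`` maps marker names to their folded-plane likelihoods;
    records must carry a ``mom_<name>`` column (MoM scale) for each.  An
    empty map gives maternal-factor-only risks (the prior alone).  The result
    is independent of record order.

    For speed, the folded-mean surface of each marker and the prior surface
    of each distinct shifted profile are computed once and reused.
    """
    if grid is None:
        grid = Grid2D.default(ga_range=prior.ga_support)
    for name in marker_models:
        col = _marker_column(name)
        if col not in records.columns:
            raise KeyError(f"records are missing marker column {col!r}")

    cov_names = set(prior.ga_shift_coefficients) | set(prior.z_shift_coefficients)
    if covariates is not None:
        cov_names |= set(covariates)
    cov_names = sorted(cov_names)
    missing = [c for c in cov_names if c not in records.columns]
    if missing:
        raise KeyError(f"records are missing prior covariates: {missing}")

    # per-marker precomputation: folded-mean surface and observed log10 MoMs
    g_mesh, z_mesh = grid.mesh()
    marker_pre = {}
    for name, params in marker_models.items():
        mean = folded_mean(params, z_mesh, g_mesh)
        y = np.log10(records[_marker_column(name)].to_numpy(dtype=float))
        if not np.all(np.isfinite(y)):
            raise ValueError(f"non-positive or missing MoM values for marker {name!r}")
        marker_pre[name] = (mean, params.sd, y)

    prior_cache: dict[tuple, np.ndarray] = {}
    n = len(records)
    risks = np.empty(n)
    z_cut = float(np.clip(cutoff.z_cut, grid.z[0], grid.z[-1]))
    ga_cut = float(np.clip(cutoff.ga_cut, grid.ga[0], grid.ga[-1]))
    cov_values = {c: records[c].to_numpy(dtype=float) for c in cov_names}
    for i in range(n):
        profile = {c: cov_values[c][i] for c in cov_names}
        key = tuple(profile[c] for c in cov_names)
        logprior = prior_cache.get(key)
        if logprior is None:
            logprior = prior_log_density_on_grid(prior, profile, grid)
            prior_cache[key] = logprior
        logpost = logprior
        for mean, sd, y in marker_pre.values():
            r = (y[i] - mean) / sd
            logpost = logpost - 0.5 * r * r
        d = np.exp(logpost - logpost.max())
        m = grid.mass(d)
        risks[i] = orthant_mass(grid, d, z_cut, ga_cut) / m
    return risks
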