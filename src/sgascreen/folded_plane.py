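"""Folded-plane likelihood for log10 MoM biomarkers.

The mean of a marker's log10 MoM is modelled as a plane in the birth-weight
Z score and a transform of gestational age at delivery, *folded* at zero:
unaffected pregnancies sit at MoM 1 (log10 MoM 0) while affected ones — small
and/or preterm babies — deviate on one side of the plane.  Residuals about
the folded mean are Gaussian with constant SD.

Two GA transforms are supported: ``(GA - center)^-1`` (reciprocal offset,
used with an applicability cut-off that both reflects the marker losing its
association with birth weight at later gestations and guards the
singularity) and ``GA - center`` (linear offset).

Fitting is by maximum likelihood (Nelder–Mead on the exact folded-plane
log-likelihood, observed-information Wald intervals) or by MCMC (emcee
ensemble sampler with diffuse Gaussian priors on the plane coefficients and
a half-Gaussian prior on the residual SD), with equal-tailed 95% intervals
and convergence diagnostics in both cases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "FoldedPlaneParams",
    "FitConfig",
    "FitResult",
    "plane_value",
    "folded_mean",
    "marker_loglik",
    "simulate_observations",
    "fit_folded_plane",
    "REFERENCE_SFLT1",
    "REFERENCE_RATIO",
    "SYNTHETIC_PLGF",
]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)

GATransform = Literal["reciprocal_offset", "linear_offset"]
Fold = Literal["max_at_zero", "min_at_zero", "none"]

#: Parameter names in the order used by the fitting routines.
PARAM_NAMES = ("intercept", "slope_z", "slope_ga", "sd")


@dataclass(frozen=True)
class FoldedPlaneParams:
    """Coefficients and structure of one marker's folded-plane model.

    ``intercept + slope_z * Z + slope_ga * t(GA)`` is the plane, where
    ``t(GA)`` is ``(GA - ga_center)^-1`` or ``GA - ga_center``; the mean of
    log10 MoM is the plane folded at zero per ``fold`` and forced to zero for
    ``GA >= ga_applicability_cutoff`` when a cut-off is set.
    """

    intercept: float
    slope_z: float
    slope_ga: float
    sd: float
    ga_transform: GATransform = "linear_offset"
    ga_center: float = 40.0
    fold: Fold = "max_at_zero"
    ga_applicability_cutoff: float | None = None

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError(f"residual sd must be > 0, got {self.sd}")
        if self.ga_transform not in ("reciprocal_offset", "linear_offset"):
            raise ValueError(f"unknown ga_transform {self.ga_transform!r}")
        if self.fold not in ("max_at_zero", "min_at_zero", "none"):
            raise ValueError(f"unknown fold {self.fold!r}")
        if self.ga_transform == "reciprocal_offset":
            cut = self.ga_applicability_cutoff
            if cut is None or not cut < self.ga_center:
                raise ValueError(
                    "reciprocal_offset requires ga_applicability_cutoff strictly "
                    "below ga_center (singularity guard)"
                )

    def to_dict(self) -> dict:
        d = {
            "intercept": self.intercept,
            "slope_z": self.slope_z,
            "slope_ga": self.slope_ga,
            "sd": self.sd,
            "ga_transform": self.ga_transform,
            "ga_center": self.ga_center,
            "fold": self.fold,
            "ga_applicability_cutoff": self.ga_applicability_cutoff,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FoldedPlaneParams":
        return cls(**d)


#: Reference second-trimester sFlt-1 likelihood: reciprocal GA transform
#: centred at 33 weeks, 32-week applicability cut-off, upward fold.
REFERENCE_SFLT1 = FoldedPlaneParams(
    intercept=-0.028181411,
    slope_z=-0.011182582,
    slope_ga=0.001131449,
    sd=0.233381804,
    ga_transform="reciprocal_offset",
    ga_center=33.0,
    fold="max_at_zero",
    ga_applicability_cutoff=32.0,
)

#: Reported standard errors of the sFlt-1 coefficients (same order as
#: PARAM_NAMES), from the 40241-pregnancy fit the reference values come from.
REFERENCE_SFLT1_SE = {
    "intercept": 0.034100921,
    "slope_z": 0.011519052,
    "slope_ga": 0.001472069,
    "sd": 0.009013250,
}

#: Reference log10 (sFlt-1 MoM / PlGF MoM) ratio likelihood: linear GA - 40
#: transform, upward fold, no applicability cut-off.
REFERENCE_RATIO = FoldedPlaneParams(
    intercept=-0.25555636,
    slope_z=-0.12802946,
    slope_ga=-0.01624357,
    sd=0.31564903,
    ga_transform="linear_offset",
    ga_center=40.0,
    fold="max_at_zero",
    ga_applicability_cutoff=None,
)

REFERENCE_RATIO_SE = {
    "intercept": 0.04816489,
    "slope_z": 0.01262894,
    "slope_ga": 0.00319910,
    "sd": 0.00111485,
}

#: Synthetic PlGF-like likelihood for demonstrations only: a mirror image of
#: the ratio plane with a downward fold (PlGF falls in placental dysfunction).
#: Not an estimate from any cohort.
SYNTHETIC_PLGF = FoldedPlaneParams(
    intercept=0.25555636,
    slope_z=0.12802946,
    slope_ga=0.01624357,
    sd=0.25,
    ga_transform="linear_offset",
    ga_center=40.0,
    fold="min_at_zero",
    ga_applicability_cutoff=None,
)


def _transform_ga(params: FoldedPlaneParams, ga: np.ndarray) -> np.ndarray:
    if params.ga_transform == "reciprocal_offset":
        diff = ga - params.ga_center
        if np.any(diff == 0.0):
            raise ValueError(
                f"GA transform singular at GA == {params.ga_center} weeks"
            )
        return 1.0 / diff
    return ga - params.ga_center


def plane_value(params: FoldedPlaneParams, z_bw, ga_delivery) -> np.ndarray | float:
    """Linear predictor ``intercept + slope_z*Z + slope_ga*t(GA)`` (unfolded)."""
    z = np.asarray(z_bw, dtype=float)
    ga = np.asarray(ga_delivery, dtype=float)
    out = params.intercept + params.slope_z * z + params.slope_ga * _transform_ga(params, ga)
    return out if out.ndim else float(out)


def folded_mean(params: FoldedPlaneParams, z_bw, ga_delivery) -> np.ndarray | float:
    """Mean log10 MoM: the plane folded at zero, with the GA cut-off rule."""
    z = np.atleast_1d(np.asarray(z_bw, dtype=float))
    ga = np.atleast_1d(np.asarray(ga_delivery, dtype=float))
    z, ga = np.broadcast_arrays(z, ga)
    mean = np.zeros(z.shape, dtype=float)
    if params.ga_applicability_cutoff is not None:
        active = ga < params.ga_applicability_cutoff
    else:
        active = np.ones(ga.shape, dtype=bool)
    if np.any(active):
        plane = (
            params.intercept
            + params.slope_z * z[active]
            + params.slope_ga * _transform_ga(params, ga[active])
        )
        if params.fold == "max_at_zero":
            plane = np.maximum(plane, 0.0)
        elif params.fold == "min_at_zero":
            plane = np.minimum(plane, 0.0)
        mean[active] = plane
    if np.isscalar(z_bw) and np.isscalar(ga_delivery):
        return float(mean[0])
    return mean


def marker_loglik(params: FoldedPlaneParams, log10_mom, z_bw, ga_delivery) -> float:
    """Gaussian log-likelihood of observed log10 MoM about the folded mean.

    An empty observation set contributes 0 by convention.
    """
    y = np.atleast_1d(np.asarray(log10_mom, dtype=float))
    if y.size == 0:
        return 0.0
    mean = np.atleast_1d(folded_mean(params, z_bw, ga_delivery))
    r = (y - mean) / params.sd
    return float(-(y.size) * (math.log(params.sd) + _LOG_SQRT_2PI) - 0.5 * np.sum(r * r))


def simulate_observations(
    params: FoldedPlaneParams,
    z_bw: np.ndarray,
    ga_delivery: np.ndarray,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Draw log10 MoM observations about the folded means (seed-deterministic)."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    mean = np.atleast_1d(folded_mean(params, z_bw, ga_delivery))
    return mean + params.sd * rng.standard_normal(mean.shape)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitConfig:
    """Settings for fit_folded_plane.

    ``structure`` carries the fixed structural choices (GA transform and
    centre, fold direction, applicability cut-off); its coefficient values are
    ignored.  ``method`` selects maximum likelihood (default) or the emcee
    ensemble sampler.  MCMC priors: Normal(0, prior_scale) on the plane
    coefficients, half-Normal(prior_scale) on the residual SD.
    """

    structure: FoldedPlaneParams
    method: Literal["mle", "mcmc"] = "mle"
    seed: int = 0
    n_walkers: int = 16
    n_steps: int = 1500
    n_burn: int = 500
    prior_scale: float = 10.0
    maxiter: int = 4000


@dataclass
class FitResult:
    """Point estimates, equal-tailed 95% intervals and diagnostics."""

    params: FoldedPlaneParams
    estimates: dict[str, float]
    intervals: dict[str, tuple[float, float]]
    se: dict[str, float]
    identified: dict[str, bool]
    converged: bool
    method: str
    diagnostics: dict = field(default_factory=dict)

    def covers(self, truth: FoldedPlaneParams, name: str) -> bool:
        lo, hi = self.intervals[name]
        return lo <= getattr(truth, name) <= hi


def _nll_factory(structure: FoldedPlaneParams, y, z, ga):
    """Negative log-likelihood in theta = (intercept, slope_z, slope_ga, log sd).

    The GA transform and applicability mask are precomputed; only the plane
    coefficients vary across evaluations.
    """
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    ga = np.asarray(ga, dtype=float)
    n = y.size
    if structure.ga_applicability_cutoff is not None:
        active = ga < structure.ga_applicability_cutoff
    else:
        active = np.ones(n, dtype=bool)
    t_active = _transform_ga(structure, ga[active])
    z_active = z[active]
    y_active = y[active]
    sq_inactive = float(np.sum(y[~active] ** 2))
    fold = structure.fold

    def nll(theta: np.ndarray) -> float:
        a, b, c, log_sd = theta
        if not np.isfinite(log_sd) or abs(log_sd) > 20:
            return np.inf
        sd = math.exp(log_sd)
        plane = a + b * z_active + c * t_active
        if fold == "max_at_zero":
            plane = np.maximum(plane, 0.0)
        elif fold == "min_at_zero":
            plane = np.minimum(plane, 0.0)
        r = y_active - plane
        ss = float(r @ r) + sq_inactive
        return n * (log_sd + _LOG_SQRT_2PI) + 0.5 * ss / (sd * sd)

    return nll, active, t_active


def _numeric_hessian(f, x: np.ndarray, rel_step: float = 1e-3) -> np.ndarray:
    k = x.size
    h = np.maximum(np.abs(x) * rel_step, 1e-4)
    hess = np.empty((k, k))
    with np.errstate(over="ignore", invalid="ignore"):
        f0 = f(x)
        for i in range(k):
            ei = np.zeros(k)
            ei[i] = h[i]
            hess[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
            for j in range(i + 1, k):
                ej = np.zeros(k)
                ej[j] = h[j]
                fpp = f(x + ei + ej)
                fpm = f(x + ei - ej)
                fmp = f(x - ei + ej)
                fmm = f(x - ei - ej)
                hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return hess


def _initial_points(structure, y, z, ga, active, t_active) -> list[np.ndarray]:
    """Heuristic starts: OLS on the active subset (fold ignored) and zeros."""
    sd0 = float(np.std(y)) or 1.0
    starts = [np.array([0.0, 0.0, 0.0, math.log(sd0)])]
    if active.sum() >= 10:
        X = np.column_stack([np.ones(int(active.sum())), z[active], t_active])
        beta, *_ = np.linalg.lstsq(X, y[active], rcond=None)
        starts.append(np.array([beta[0], beta[1], beta[2], math.log(sd0)]))
        # a deliberately steeper start helps escape the flat folded region
        starts.append(np.array([2 * beta[0], 2 * beta[1], 2 * beta[2], math.log(sd0)]))
    return starts


def _fit_mle(config: FitConfig, y, z, ga) -> FitResult:
    structure = config.structure
    nll, active, t_active = _nll_factory(structure, y, z, ga)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    ga = np.asarray(ga, dtype=float)

    best = None
    for x0 in _initial_points(structure, y, z, ga, active, t_active):
        res = optimize.minimize(
            nll,
            x0,
            method="Nelder-Mead",
            options={
                "xatol": 1e-7,
                "fatol": 1e-9,
                "maxiter": config.maxiter,
                "maxfev": config.maxiter,
            },
        )
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x
    hess = _numeric_hessian(nll, theta)

    # Observed-information covariance; flat or numerically degenerate
    # directions are reported as non-identified with unbounded intervals
    # rather than spurious precision.
    if not np.all(np.isfinite(hess)):
        variances = np.full(4, np.inf)
    else:
        scale = max(float(np.max(np.abs(np.diag(hess)))), 1.0)
        eigvals = np.linalg.eigvalsh(hess)
        if np.all(eigvals > 1e-10 * scale):
            variances = np.diag(np.linalg.inv(hess))
        else:
            cov = np.linalg.pinv(hess, rcond=1e-10)
            variances = np.where(
                np.abs(np.diag(hess)) > 1e-10 * scale, np.diag(cov), np.inf
            )

    sd_hat = math.exp(theta[3])
    ests = {"intercept": theta[0], "slope_z": theta[1], "slope_ga": theta[2], "sd": sd_hat}
    ses, ivals, ident = {}, {}, {}
    zq = 1.959963984540054
    for i, name in enumerate(PARAM_NAMES):
        var = variances[i]
        ok = np.isfinite(var) and 0 <= var < 1e6
        point = theta[i]
        se = math.sqrt(var) if ok else math.inf
        if name == "sd":  # delta method from log scale
            point = sd_hat
            se = sd_hat * se if ok else math.inf
        ident[name] = bool(ok)
        ses[name] = se
        ivals[name] = (point - zq * se, point + zq * se) if ok else (-math.inf, math.inf)

    fitted = replace(
        structure,
        intercept=ests["intercept"],
        slope_z=ests["slope_z"],
        slope_ga=ests["slope_ga"],
        sd=ests["sd"],
    )
    return FitResult(
        params=fitted,
        estimates=ests,
        intervals=ivals,
        se=ses,
        identified=ident,
        converged=bool(best.success),
        method="mle",
        diagnostics={"nll": float(best.fun), "n_eval": int(best.nfev)},
    )


def _fit_mcmc(config: FitConfig, y, z, ga) -> FitResult:
    import emcee

    structure = config.structure
    nll, _, _ = _nll_factory(structure, y, z, ga)
    s = config.prior_scale

    def log_prob(theta: np.ndarray) -> float:
        neg = nll(theta)
        if not np.isfinite(neg):
            return -np.inf
        sd = math.exp(theta[3])
        # diffuse Normal(0, s) on coefficients, half-Normal(s) on sd
        # (+ log-Jacobian for sampling on the log-sd scale)
        lp = -0.5 * (theta[0] ** 2 + theta[1] ** 2 + theta[2] ** 2) / s**2
        lp += -0.5 * (sd / s) ** 2 + theta[3]
        return lp - neg

    mle = _fit_mle(replace(config, method="mle"), y, z, ga)
    center = np.array(
        [
            mle.estimates["intercept"],
            mle.estimates["slope_z"],
            mle.estimates["slope_ga"],
            math.log(mle.estimates["sd"]),
        ]
    )
    rng = np.random.default_rng(config.seed)
    p0 = center + 1e-3 * rng.standard_normal((config.n_walkers, 4)) * np.maximum(
        np.abs(center), 0.05
    )
    sampler = emcee.EnsembleSampler(config.n_walkers, 4, log_prob)
    state = emcee.State(p0, random_state=np.random.RandomState(config.seed).get_state())
    sampler.run_mcmc(state, config.n_steps, progress=False)
    chain = sampler.get_chain()[config.n_burn :]  # (steps, walkers, 4)
    flat = chain.reshape(-1, 4)
    flat_nat = flat.copy()
    flat_nat[:, 3] = np.exp(flat[:, 3])

    # Gelman–Rubin across walkers on each parameter (post burn-in)
    m = chain.shape[1]
    nsteps = chain.shape[0]
    wmeans = chain.mean(axis=0)
    wvars = chain.var(axis=0, ddof=1)
    B = nsteps * wmeans.var(axis=0, ddof=1)
    W = wvars.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(((nsteps - 1) / nsteps * W + B / nsteps) / W)
    accept = float(np.mean(sampler.acceptance_fraction))
    converged = bool(np.all(np.nan_to_num(rhat, nan=np.inf) < 1.1) and 0.1 < accept < 0.8)

    ests = dict(zip(PARAM_NAMES, flat_nat.mean(axis=0)))
    lo = np.percentile(flat_nat, 2.5, axis=0)
    hi = np.percentile(flat_nat, 97.5, axis=0)
    ses = dict(zip(PARAM_NAMES, flat_nat.std(axis=0, ddof=1)))
    ivals = {name: (float(lo[i]), float(hi[i])) for i, name in enumerate(PARAM_NAMES)}
    ident = {name: True for name in PARAM_NAMES}

    fitted = replace(
        structure,
        intercept=ests["intercept"],
        slope_z=ests["slope_z"],
        slope_ga=ests["slope_ga"],
        sd=ests["sd"],
    )
    return FitResult(
        params=fitted,
        estimates={k: float(v) for k, v in ests.items()},
        intervals=ivals,
        se={k: float(v) for k, v in ses.items()},
        identified=ident,
        converged=converged,
        method="mcmc",
        diagnostics={"rhat": rhat.tolist(), "acceptance_fraction": accept},
    )


def fit_folded_plane(
    log10_mom: Sequence[float],
    z_bw: Sequence[float],
    ga_delivery: Sequence[float],
    config: FitConfig,
) -> FitResult:
    """Fit a folded-plane marker model by MLE or MCMC.

    The structural choices (GA transform, fold direction, applicability
    cut-off) are fixed inputs carried by ``config.structure``; only the plane
    coefficients and the residual SD are estimated.  The SD is estimated on
    the log scale internally and reported on the natural scale.  Requires at
    least 50 observations.  Non-convergence is flagged on the result, never
    silent.
    """
    y = np.asarray(log10_mom, dtype=float)
    if y.size < 50:
        raise ValueError(f"need >= 50 observations to fit, got {y.size}")
    if config.method == "mle":
        return _fit_mle(config, y, z_bw, ga_delivery)
    if config.method == "mcmc":
        return _fit_mcmc(config, y, z_bw, ga_delivery)
    raise ValueError(f"unknown fit method {config.method!r}")
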