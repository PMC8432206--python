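"""Synthetic second-trimester screening cohorts.

Generates pregnancies with the statistical structure the risk model assumes:
maternal covariates from configured distributions; (GA at delivery,
birth-weight Z score) from the maternal-factor bivariate-Gaussian prior
truncated to the GA support; a pre-eclampsia label from a logistic model in
(-Z_BW, 40 - GA_Delivery); and log10 MoM marker values about folded-plane
means.  PE is a stratification label only — it never feeds the risk model.

The default configuration emulates a large UK-style routine-care population
screened at 19+0 to 24+6 weeks: ~10% of neonates below the 10th birth-weight
percentile, roughly 3.3 per thousand both SGA<10th and delivered before 32
weeks, PE in ~3% overall and ~7.4% of SGA pregnancies.  The default prior
and PE coefficients were calibrated once, by simulation at n = 2,000,000,
to hit those anchors and are frozen below.

Randomness: one global seed; per-stage substreams (profiles, outcomes,
markers) are spawned deterministically from it, so adding markers does not
perturb outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr, ndtri

from .folded_plane import (
    REFERENCE_RATIO,
    REFERENCE_SFLT1,
    FoldedPlaneParams,
    folded_mean,
)
from .prior import PriorParams

__all__ = [
    "CohortConfig",
    "default_prior",
    "default_config",
    "generate_profiles",
    "draw_outcomes",
    "draw_markers",
    "generate_cohort",
    "simulate_outcome_pairs",
]

#: Columns every cohort frame carries besides covariates and markers.
OUTCOME_COLUMNS = ("ga_measurement", "ga_delivery", "z_bw", "pe")

# ---------------------------------------------------------------------------
# Default calibration (frozen; see docs/methods.md for the derivation)
# ---------------------------------------------------------------------------

#: GA-at-delivery marginal SD (weeks) of the default cohort prior.  Wider
#: than a term-only population so that the preterm tail carries realistic
#: mass once coupled to Z_BW.
_GA_SD = 3.0
#: Z_BW mean slope on GA (per week): earlier deliveries have smaller babies.
_Z_ON_GA = 0.149
#: Residual SD of Z_BW given GA, chosen so the Z marginal has unit variance.
_Z_SD = 0.9091
#: Z intercept making the marginal P(Z_BW < -1.2816) equal 0.10.
_Z_BASE = -5.6481

#: Covariate shift coefficients (applied to the Z_BW and GA means) for the
#: covariates with the strongest reported SGA associations.
_Z_SHIFTS = {
    "smoker": -0.42,
    "previous_sga": -0.56,
    "nulliparous": -0.11,
    "chronic_hypertension": -0.45,
}
_GA_SHIFTS = {"chronic_hypertension": -1.5}

#: Logistic PE-assignment coefficients: intercept, weight on -Z_BW, weight on
#: (40 - GA_Delivery).  Calibrated to ~3.0% PE overall, ~7.4% among SGA<10th
#: and ~33% among SGA<10th delivered <32 weeks.
_PE_MODEL = (-4.3691, 0.2573, 0.3434)


def default_prior() -> PriorParams:
    """The calibrated default cohort prior (correlated GA–Z, covariate shifts)."""
    return PriorParams(
        ga_mean_base=39.5,
        ga_sd=_GA_SD,
        z_mean_base=_Z_BASE,
        z_on_ga_slope=_Z_ON_GA,
        z_sd=_Z_SD,
        ga_shift_coefficients=dict(_GA_SHIFTS),
        z_shift_coefficients=dict(_Z_SHIFTS),
        ga_support=(24.0, 43.0),
    )


#: Default covariate sampling specs (continuous specs are normal
#: approximations to reported median/IQR, probabilities are the reported
#: population prevalences).
DEFAULT_COVARIATES: dict[str, dict] = {
    "maternal_age": {"kind": "normal", "loc": 31.7, "scale": 5.6},
    "maternal_weight": {"kind": "normal", "loc": 69.0, "scale": 13.5},
    "maternal_height": {"kind": "normal", "loc": 165.0, "scale": 6.7},
    "racial_origin": {
        "kind": "categorical",
        "levels": ["white", "black", "south_asian", "east_asian", "mixed"],
        "probs": [0.775, 0.130, 0.048, 0.020, 0.027],
    },
    "conception": {
        "kind": "categorical",
        "levels": ["natural", "ovulation_induction", "ivf"],
        "probs": [0.955, 0.007, 0.038],
    },
    "smoker": {"kind": "bernoulli", "p": 0.075},
    "nulliparous": {"kind": "bernoulli", "p": 0.471},
    "previous_sga": {"kind": "bernoulli", "p": 0.070},
    "chronic_hypertension": {"kind": "bernoulli", "p": 0.011},
}

#: GA at the biomarker measurement (weeks); clipped to the 19+0..24+6 window.
_GA_MEAS = {"loc": 21.6, "scale": 0.67, "low": 19.0, "high": 24.857}


@dataclass(frozen=True)
class CohortConfig:
    """Everything needed to generate one synthetic cohort."""

    n_pregnancies: int
    seed: int = 0
    prior: PriorParams = field(default_factory=default_prior)
    marker_models: Mapping[str, FoldedPlaneParams] = field(
        default_factory=lambda: {"sflt1": REFERENCE_SFLT1, "ratio": REFERENCE_RATIO}
    )
    pe_model: tuple[float, float, float] = _PE_MODEL
    covariate_distributions: Mapping[str, dict] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATES)
    )

    def __post_init__(self) -> None:
        if self.n_pregnancies < 1:
            raise ValueError("n_pregnancies must be >= 1")
        for name, spec in self.covariate_distributions.items():
            kind = spec.get("kind")
            if kind == "categorical":
                probs = np.asarray(spec["probs"], dtype=float)
                if abs(probs.sum() - 1.0) > 1e-9 or np.any(probs < 0):
                    raise ValueError(
                        f"categorical probabilities for {name!r} must be "
                        f"non-negative and sum to 1 (got sum {probs.sum()!r})"
                    )
            elif kind == "bernoulli":
                p = float(spec["p"])
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"bernoulli p for {name!r} must be in [0,1]")
            elif kind == "normal":
                if float(spec["scale"]) <= 0:
                    raise ValueError(f"normal scale for {name!r} must be > 0")
            else:
                raise ValueError(f"unknown covariate kind {kind!r} for {name!r}")
        for name, m in self.marker_models.items():
            if not m.sd > 0:
                raise ValueError(f"marker model {name!r} has non-positive sd")


def default_config(n_pregnancies: int = 40241, seed: int = 0) -> CohortConfig:
    """Default study-scale configuration (40241 pregnancies)."""
    return CohortConfig(n_pregnancies=n_pregnancies, seed=seed)


def _substreams(seed: int) -> tuple[np.random.Generator, ...]:
    ss = np.random.SeedSequence(seed)
    return tuple(np.random.default_rng(s) for s in ss.spawn(3))


def generate_profiles(
    config: CohortConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Sample maternal covariates and the GA at measurement for each pregnancy."""
    if rng is None:
        rng = _substreams(config.seed)[0]
    n = config.n_pregnancies
    cols: dict[str, np.ndarray] = {}
    for name, spec in config.covariate_distributions.items():
        kind = spec["kind"]
        if kind == "normal":
            cols[name] = spec["loc"] + spec["scale"] * rng.standard_normal(n)
        elif kind == "bernoulli":
            cols[name] = (rng.random(n) < float(spec["p"])).astype(int)
        elif kind == "categorical":
            cols[name] = rng.choice(spec["levels"], size=n, p=spec["probs"])
    # truncated-normal GA at measurement via inverse CDF
    lo = ndtr((_GA_MEAS["low"] - _GA_MEAS["loc"]) / _GA_MEAS["scale"])
    hi = ndtr((_GA_MEAS["high"] - _GA_MEAS["loc"]) / _GA_MEAS["scale"])
    u = lo + (hi - lo) * rng.random(n)
    cols["ga_measurement"] = _GA_MEAS["loc"] + _GA_MEAS["scale"] * ndtri(u)
    return pd.DataFrame(cols)


def draw_outcomes(
    profiles: pd.DataFrame,
    prior: PriorParams,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Attach (GA_Delivery, Z_BW) from the profile-shifted prior and a PE label."""
    if rng is None:
        rng = _substreams(config.seed)[1]
    n = len(profiles)
    ga_mean = np.full(n, prior.ga_mean_base, dtype=float)
    for name, coef in prior.ga_shift_coefficients.items():
        ga_mean += coef * profiles[name].to_numpy(dtype=float)
    z_intercept = np.full(n, prior.z_mean_base, dtype=float)
    for name, coef in prior.z_shift_coefficients.items():
        z_intercept += coef * profiles[name].to_numpy(dtype=float)

    lo, hi = prior.ga_support
    a = ndtr((lo - ga_mean) / prior.ga_sd)
    b = ndtr((hi - ga_mean) / prior.ga_sd)
    u = a + (b - a) * rng.random(n)
    ga = ga_mean + prior.ga_sd * ndtri(u)
    z = z_intercept + prior.z_on_ga_slope * ga + prior.z_sd * rng.standard_normal(n)

    c0, c_z, c_ga = config.pe_model
    p_pe = expit(c0 + c_z * (-z) + c_ga * (40.0 - ga))
    pe = (rng.random(n) < p_pe).astype(int)

    out = profiles.copy()
    out["ga_delivery"] = ga
    out["z_bw"] = z
    out["pe"] = pe
    return out


def draw_markers(
    records: pd.DataFrame,
    marker_models: Mapping[str, FoldedPlaneParams],
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Draw MoM values about the folded-plane means, one column per marker.

    Markers are conditionally independent given (Z_BW, GA_Delivery); each
    ``mom_<name>`` column is 10 to the power of a Gaussian draw about the
    marker's folded mean.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out = records.copy()
    z = records["z_bw"].to_numpy(dtype=float)
    ga = records["ga_delivery"].to_numpy(dtype=float)
    for name, params in marker_models.items():
        mean = np.atleast_1d(folded_mean(params, z, ga))
        out[f"mom_{name}"] = 10.0 ** (mean + params.sd * rng.standard_normal(len(records)))
    return out


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Full generator: profiles -> outcomes -> markers, one row per pregnancy."""
    r_prof, r_out, r_mark = _substreams(config.seed)
    profiles = generate_profiles(config, r_prof)
    records = draw_outcomes(profiles, config.prior, config, r_out)
    return draw_markers(records, config.marker_models, r_mark)


def simulate_outcome_pairs(
    n: int, prior: PriorParams, rng: np.random.Generator | int
) -> tuple[np.ndarray, np.ndarray]:
    """(GA_Delivery, Z_BW) pairs from a prior with no covariate shifts.

    Convenience for the parameter-recovery protocols, which draw outcome
    pairs directly from the simple independent prior.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    lo, hi = prior.ga_support
    a = ndtr((lo - prior.ga_mean_base) / prior.ga_sd)
    b = ndtr((hi - prior.ga_mean_base) / prior.ga_sd)
    u = a + (b - a) * rng.random(n)
    ga = prior.ga_mean_base + prior.ga_sd * ndtri(u)
    z = (
        prior.z_mean_base
        + prior.z_on_ga_slope * ga
        + prior.z_sd * rng.standard_normal(n)
    )
    return ga, z
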