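"""End-to-end screening pipeline: simulate -> likelihoods -> risks -> table.

``run_pipeline`` orchestrates the whole analysis from one RunConfig:
generate (or load) a cohort, take the marker likelihoods (reference values
or refit from the cohort), compute per-pregnancy posterior risks per method
and cut-off, and evaluate detection at the fixed FPR.  Every stage logs its
seed and problem size; results are fully reproducible given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortConfig, default_config, generate_cohort
from .folded_plane import (
    REFERENCE_RATIO,
    REFERENCE_SFLT1,
    SYNTHETIC_PLGF,
    FoldedPlaneParams,
)
from .grids import Grid2D
from .posterior import Z_CUT_3RD, Z_CUT_10TH, OutcomeCutoff, cohort_risks
from .screening import screening_table

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "DEFAULT_METHODS"]

log = logging.getLogger("sgascreen")

#: Method name -> marker names combined with maternal factors.
DEFAULT_METHODS: dict[str, tuple[str, ...]] = {
    "MF": (),
    "MF+sFlt-1": ("sflt1",),
    "MF+ratio": ("ratio",),
}

DEFAULT_CUTOFFS = (
    OutcomeCutoff(Z_CUT_10TH, 32.0),
    OutcomeCutoff(Z_CUT_3RD, 32.0),
    OutcomeCutoff(Z_CUT_10TH, 37.0),
    OutcomeCutoff(Z_CUT_3RD, 37.0),
)

REFERENCE_LIKELIHOODS: dict[str, FoldedPlaneParams] = {
    "sflt1": REFERENCE_SFLT1,
    "ratio": REFERENCE_RATIO,
    "plgf": SYNTHETIC_PLGF,
}


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full pipeline run."""

    seed: int = 0
    n_pregnancies: int = 40241
    methods: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_METHODS)
    )
    cutoffs: Sequence[OutcomeCutoff] = DEFAULT_CUTOFFS
    fpr: float = 0.10
    grid_step: float = 0.05
    cohort_config: CohortConfig | None = None
    likelihoods: Mapping[str, FoldedPlaneParams] | None = None

    def resolved_cohort_config(self) -> CohortConfig:
        if self.cohort_config is not None:
            return self.cohort_config
        return default_config(self.n_pregnancies, self.seed)

    def resolved_likelihoods(self) -> dict[str, FoldedPlaneParams]:
        lik = dict(REFERENCE_LIKELIHOODS)
        if self.likelihoods:
            lik.update(self.likelihoods)
        needed = {m for markers in self.methods.values() for m in markers}
        missing = needed - set(lik)
        if missing:
            raise KeyError(f"no likelihood parameters for markers: {sorted(missing)}")
        return lik


@dataclass
class PipelineResult:
    config: RunConfig
    cohort: pd.DataFrame
    risks: dict[str, dict[OutcomeCutoff, np.ndarray]]
    table: pd.DataFrame


def run_pipeline(config: RunConfig, cohort: pd.DataFrame | None = None) -> PipelineResult:
    """Run simulate -> risks -> screening evaluation, logging each stage."""
    cc = config.resolved_cohort_config()
    if cohort is None:
        log.info("stage=simulate seed=%d n=%d", cc.seed, cc.n_pregnancies)
        cohort = generate_cohort(cc)
    else:
        log.info("stage=load n=%d", len(cohort))
    likelihoods = config.resolved_likelihoods()
    grid = Grid2D.default(ga_range=cc.prior.ga_support, step=config.grid_step)

    risks: dict[str, dict[OutcomeCutoff, np.ndarray]] = {}
    for method, markers in config.methods.items():
        models = {m: likelihoods[m] for m in markers}
        risks[method] = {}
        for cutoff in config.cutoffs:
            log.info("stage=risks method=%s cutoff=%s", method, cutoff.label())
            risks[method][cutoff] = cohort_risks(
                cohort, cc.prior, models, cutoff, grid=grid
            )

    pairs = []
    methods = list(config.methods)
    if "MF" in methods:
        pairs = [("MF", m) for m in methods if m != "MF"]
    log.info("stage=screen fpr=%.3f cutoffs=%d", config.fpr, len(config.cutoffs))
    table = screening_table(risks, cohort, config.cutoffs, pairs, fpr=config.fpr)
    return PipelineResult(config=config, cohort=cohort, risks=risks, table=table)
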