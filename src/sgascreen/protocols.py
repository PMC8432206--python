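"""Simulation-and-refit protocols for the folded-plane likelihoods.

The recovery protocol asks: if log10 MoM values are generated from a
folded-plane model with known coefficients over a reference outcome
distribution, does refitting recover those coefficients?  Outcome pairs are
drawn from the simple independent prior (GA ~ Normal(39.5, 2.0) truncated to
[24, 43], Z ~ Normal(0, 1)); marker values are drawn about the folded means;
the model is then refit with the structural choices fixed at truth.

Per-stage random streams (outcomes, marker noise) are spawned from the one
protocol seed, mirroring the cohort generator's seeding scheme.
"""

from __future__ import annotations

import numpy as np

from .cohort import simulate_outcome_pairs
from .folded_plane import FitConfig, FitResult, FoldedPlaneParams, fit_folded_plane, simulate_observations
from .prior import PriorParams

__all__ = ["parameter_recovery"]


def parameter_recovery(
    truth: FoldedPlaneParams,
    n: int,
    seed: int,
    method: str = "mle",
    prior: PriorParams | None = None,
    **fit_kwargs,
) -> FitResult:
    """Simulate ``n`` pregnancies from ``truth`` and refit the folded plane."""
    if prior is None:
        prior = PriorParams.independent()
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(2)]
    ga, z = simulate_outcome_pairs(n, prior, streams[0])
    y = simulate_observations(truth, z, ga, streams[1])
    config = FitConfig(structure=truth, method=method, seed=seed, **fit_kwargs)
    return fit_folded_plane(y, z, ga, config)
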