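#!/usr/bin/env python
"""Refit the folded-plane marker likelihoods to the simulated cohort.

Fits the sFlt-1 model (reciprocal GA-33 transform, 32-week applicability
cut-off) and the sFlt-1/PlGF ratio model (linear GA-40 transform) to the
cohort's log10 MoM values by maximum likelihood, then draws MCMC credibility
intervals for the ratio fit.  Writes the fitted parameter JSONs and prints
estimates next to the generating (reference) coefficients.
"""

import argparse
from pathlib import Path

import numpy as np

from sgascreen import REFERENCE_RATIO, REFERENCE_SFLT1, FitConfig, fit_folded_plane
from sgascreen.io import read_cohort, write_folded_plane


def report(label, res, truth):
    print(f"\n{label} ({res.method}, converged={res.converged})")
    for name in ("intercept", "slope_z", "slope_ga", "sd"):
        lo, hi = res.intervals[name]
        span = f"({lo: .5f} to {hi: .5f})" if res.identified[name] else "(not identified)"
        print(f"  {name:>9s}  est {res.estimates[name]: .6f}  95% {span}"
              f"   generating {getattr(truth, name): .6f}")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort.csv"))
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    cohort = read_cohort(args.cohort)
    z = cohort.z_bw.to_numpy()
    ga = cohort.ga_delivery.to_numpy()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    for marker, truth in (("sflt1", REFERENCE_SFLT1), ("ratio", REFERENCE_RATIO)):
        y = np.log10(cohort[f"mom_{marker}"].to_numpy())
        mle = fit_folded_plane(y, z, ga, FitConfig(structure=truth, seed=args.seed))
        report(f"{marker}: maximum likelihood", mle, truth)
        write_folded_plane(mle.params, args.out_dir / f"likelihood_{marker}.json")

    # MCMC credibility intervals for the ratio model (the identified block)
    y = np.log10(cohort.mom_ratio.to_numpy())
    mcmc = fit_folded_plane(
        y, z, ga,
        FitConfig(structure=REFERENCE_RATIO, method="mcmc", seed=args.seed,
                  n_walkers=16, n_steps=1200, n_burn=400),
    )
    report("ratio: MCMC posterior", mcmc, REFERENCE_RATIO)


if __name__ == "__main__":
    main()
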