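#!/usr/bin/env python
"""Generate the synthetic screening cohort and report its calibration anchors.

Writes the cohort CSV and prints the population-level quantities the
generator is calibrated to: SGA<10th prevalence, the count of SGA<10th
deliveries before 32 weeks, and PE prevalence overall / within SGA.
"""

import argparse
from pathlib import Path

from sgascreen.cohort import default_config, generate_cohort
from sgascreen.io import write_cohort
from sgascreen.posterior import Z_CUT_10TH


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--n", type=int, default=40241)
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    cohort = generate_cohort(default_config(args.n, args.seed))
    args.out_dir.mkdir(parents=True, exist_ok=True)
    out = args.out_dir / "cohort.csv"
    write_cohort(cohort, out)

    sga = cohort.z_bw < Z_CUT_10TH
    early_sga = sga & (cohort.ga_delivery < 32)
    pe = cohort.pe.astype(bool)
    print(f"cohort: n={len(cohort)} seed={args.seed} -> {out}")
    print(f"SGA<10th prevalence:          {sga.mean():.4f}  (target ~0.10)")
    print(f"SGA<10th delivered <32w:      {int(early_sga.sum())}  "
          f"(~131 per 40241 expected at study scale)")
    print(f"PE prevalence:                {pe.mean():.4f}  (target ~0.030)")
    print(f"PE among SGA<10th:            {pe[sga].mean():.4f}  (target ~0.074)")
    print(f"smokers among SGA / non-SGA:  "
          f"{cohort.smoker[sga].mean():.3f} / {cohort.smoker[~sga].mean():.3f}")


if __name__ == "__main__":
    main()
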