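"""Screening performance at a fixed false-positive rate.

Detection rates are empirical: a risk threshold is set on the unaffected
group so that the false-positive rate does not exceed the nominal value
(ties resolved conservatively), and the detection rate is the fraction of
affected pregnancies above that threshold.  Methods are compared on the same
affected individuals, so differences are paired: the confidence interval for
the difference in detection uses the paired (discordant-count) Wald method
and the p-value is the exact McNemar binomial test on discordant pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .posterior import OutcomeCutoff

__all__ = [
    "ScreeningResult",
    "PairedComparison",
    "threshold_at_fpr",
    "detection_rate",
    "paired_comparison",
    "screening_table",
]


@dataclass(frozen=True)
class ScreeningResult:
    method: str
    n_affected: int
    n_detected: int
    detection_rate: float
    fpr_fixed: float
    threshold: float


@dataclass(frozen=True)
class PairedComparison:
    """Difference in detection between two methods on the same individuals."""

    method_a: str
    method_b: str
    diff_detected: int          # B detected minus A detected
    diff_percentage_points: float
    ci_low: float               # 95% CI for the difference, percentage points
    ci_high: float
    p_value: float              # exact McNemar on discordant pairs
    n_discordant_a_only: int
    n_discordant_b_only: int


def threshold_at_fpr(unaffected_risks: Sequence[float], fpr: float) -> float:
    """Smallest threshold t with fraction(unaffected risk > t) <= fpr.

    With ties the threshold is conservative: the empirical FPR never exceeds
    the nominal rate.
    """
    risks = np.asarray(unaffected_risks, dtype=float)
    if risks.size < 10:
        raise ValueError(f"need >= 10 unaffected risks, got {risks.size}")
    if not 0.0 < fpr < 1.0:
        raise ValueError("fpr must lie strictly between 0 and 1")
    k = int(np.floor(fpr * risks.size))  # max allowed false positives
    desc = np.sort(risks)[::-1]
    if k >= risks.size:
        return float(desc[-1])
    return float(desc[k])


def detection_rate(
    affected_risks: Sequence[float],
    threshold: float,
    method: str = "",
    fpr_fixed: float = 0.10,
) -> ScreeningResult:
    """Fraction of affected pregnancies with risk above the threshold."""
    risks = np.asarray(affected_risks, dtype=float)
    if risks.size < 1:
        raise ValueError("affected set is empty")
    detected = int(np.sum(risks > threshold))
    return ScreeningResult(
        method=method,
        n_affected=int(risks.size),
        n_detected=detected,
        detection_rate=detected / risks.size,
        fpr_fixed=fpr_fixed,
        threshold=float(threshold),
    )


def paired_comparison(
    detected_a: Sequence[bool],
    detected_b: Sequence[bool],
    method_a: str = "A",
    method_b: str = "B",
) -> PairedComparison:
    """Paired difference in detection (B minus A) over the same individuals."""
    a = np.asarray(detected_a, dtype=bool)
    b = np.asarray(detected_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"flag vectors differ in length: {a.size} vs {b.size}")
    n = a.size
    n10 = int(np.sum(a & ~b))  # detected by A only
    n01 = int(np.sum(~a & b))  # detected by B only
    diff = n01 - n10
    pp = 100.0 * diff / n
    # paired Wald SE for the difference of marginal proportions
    se = np.sqrt(max(n10 + n01 - diff * diff / n, 0.0)) / n
    zq = 1.959963984540054
    ci = (pp - 100.0 * zq * se, pp + 100.0 * zq * se)
    n_disc = n10 + n01
    p = 1.0 if n_disc == 0 else binomtest(min(n10, n01), n_disc, 0.5).pvalue
    return PairedComparison(
        method_a=method_a,
        method_b=method_b,
        diff_detected=diff,
        diff_percentage_points=pp,
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p_value=float(min(p, 1.0)),
        n_discordant_a_only=n10,
        n_discordant_b_only=n01,
    )


def screening_table(
    risks_by_method: Mapping[str, Mapping[OutcomeCutoff, np.ndarray]],
    outcomes: pd.DataFrame,
    cutoffs: Sequence[OutcomeCutoff],
    method_pairs: Sequence[tuple[str, str]] = (),
    fpr: float = 0.10,
) -> pd.DataFrame:
    """Detection table over cut-offs, PE strata and method pairs.

    ``risks_by_method[method][cutoff]`` holds one risk per cohort row.
    ``outcomes`` must carry ``z_bw``, ``ga_delivery`` and ``pe``.  For each
    cut-off, the FPR threshold of every method is anchored on the pregnancies
    that are *not* affected at that cut-off (SGA delivered at or after the GA
    cut count as unaffected for its rows); the same threshold then serves all
    PE strata of the block.  Strata with no affected pregnancies produce a
    row with NaN rates and zero counts.
    """
    z = outcomes["z_bw"].to_numpy(dtype=float)
    ga = outcomes["ga_delivery"].to_numpy(dtype=float)
    pe = outcomes["pe"].to_numpy(dtype=bool)
    rows = []
    for cutoff in cutoffs:
        affected = (z < cutoff.z_cut) & (ga < cutoff.ga_cut)
        thresholds = {}
        flags = {}
        for method, per_cut in risks_by_method.items():
            risks = np.asarray(per_cut[cutoff], dtype=float)
            if risks.size != len(outcomes):
                raise ValueError(f"risk vector for {method!r} has wrong length")
            thresholds[method] = threshold_at_fpr(risks[~affected], fpr)
            flags[method] = risks > thresholds[method]
        strata = {
            "all": affected,
            "with_pe": affected & pe,
            "no_pe": affected & ~pe,
        }
        for stratum, mask in strata.items():
            n_aff = int(mask.sum())
            for method in risks_by_method:
                if n_aff == 0:
                    rows.append(
                        {
                            "cutoff": cutoff.label(),
                            "z_cut": cutoff.z_cut,
                            "ga_cut": cutoff.ga_cut,
                            "stratum": stratum,
                            "kind": "method",
                            "method": method,
                            "n_affected": 0,
                            "n_detected": 0,
                            "detection_rate": np.nan,
                            "threshold": thresholds[method],
                            "empty": True,
                        }
                    )
                    continue
                res = detection_rate(
                    np.where(flags[method][mask], 1.0, 0.0), 0.5, method, fpr
                )
                rows.append(
                    {
                        "cutoff": cutoff.label(),
                        "z_cut": cutoff.z_cut,
                        "ga_cut": cutoff.ga_cut,
                        "stratum": stratum,
                        "kind": "method",
                        "method": method,
                        "n_affected": res.n_affected,
                        "n_detected": res.n_detected,
                        "detection_rate": res.detection_rate,
                        "threshold": thresholds[method],
                        "empty": False,
                    }
                )
            for ma, mb in method_pairs:
                if n_aff == 0:
                    rows.append(
                        {
                            "cutoff": cutoff.label(),
                            "z_cut": cutoff.z_cut,
                            "ga_cut": cutoff.ga_cut,
                            "stratum": stratum,
                            "kind": "comparison",
                            "method": f"{ma} vs {mb}",
                            "n_affected": 0,
                            "empty": True,
                        }
                    )
                    continue
                cmp_ = paired_comparison(flags[ma][mask], flags[mb][mask], ma, mb)
                rows.append(
                    {
                        "cutoff": cutoff.label(),
                        "z_cut": cutoff.z_cut,
                        "ga_cut": cutoff.ga_cut,
                        "stratum": stratum,
                        "kind": "comparison",
                        "method": f"{ma} vs {mb}",
                        "n_affected": n_aff,
                        "diff_detected": cmp_.diff_detected,
                        "diff_pp": cmp_.diff_percentage_points,
                        "ci_low": cmp_.ci_low,
                        "ci_high": cmp_.ci_high,
                        "p_value": cmp_.p_value,
                        "empty": False,
                    }
                )
    return pd.DataFrame(rows)
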