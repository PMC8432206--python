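"""Multiples-of-the-median (MoM) normalization of raw biomarker values.

A marker's expected median is modelled as a linear regression of log10(raw
concentration) on normalization covariates (GA at measurement, maternal
weight, analyzer indicator, ... — the covariate set is configurable).  A
measurement's MoM is its raw value divided by the predicted median, so that
unaffected pregnancies have median MoM ~ 1 and log10 MoM ~ 0.  Synthetic
cohorts may bypass this module: their markers are generated on the MoM scale
directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["MedianModel", "fit_median_model", "to_mom", "log10_ratio_mom"]


@dataclass(frozen=True)
class MedianModel:
    """Linear model of log10(raw concentration) on normalization covariates."""

    marker: str
    covariate_names: tuple[str, ...]
    coefficients: np.ndarray  # intercept first, then one per covariate
    coefficient_se: np.ndarray

    def __post_init__(self) -> None:
        if len(self.coefficients) != len(self.covariate_names) + 1:
            raise ValueError("coefficient vector length must be 1 + #covariates")

    def predict_log10_median(self, covariates: Mapping[str, np.ndarray] | pd.DataFrame) -> np.ndarray:
        pred = np.full(self._n(covariates), self.coefficients[0], dtype=float)
        for name, coef in zip(self.covariate_names, self.coefficients[1:]):
            pred += coef * np.asarray(covariates[name], dtype=float)
        return pred

    def _n(self, covariates) -> int:
        if self.covariate_names:
            return len(np.atleast_1d(np.asarray(covariates[self.covariate_names[0]])))
        if isinstance(covariates, pd.DataFrame):
            return max(len(covariates), 1)
        for v in covariates.values():
            return len(np.atleast_1d(np.asarray(v)))
        return 1

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "marker": self.marker,
                    "covariate_names": list(self.covariate_names),
                    "coefficients": self.coefficients.tolist(),
                    "coefficient_se": self.coefficient_se.tolist(),
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "MedianModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            marker=d["marker"],
            covariate_names=tuple(d["covariate_names"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            coefficient_se=np.asarray(d["coefficient_se"], dtype=float),
        )


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Greedy identification of columns that break full column rank."""
    bad = []
    kept: list[int] = []
    for j in range(X.shape[1]):
        cols = kept + [j]
        if np.linalg.matrix_rank(X[:, cols]) == len(cols):
            kept.append(j)
        else:
            bad.append(names[j])
    return bad


def fit_median_model(
    raw_values: Sequence[float],
    covariates: pd.DataFrame | Mapping[str, Sequence[float]],
    spec: Sequence[str],
    marker: str = "marker",
) -> MedianModel:
    """Least-squares fit of log10(raw) on the covariates named in ``spec``."""
    raw = np.asarray(raw_values, dtype=float)
    if raw.size < 10:
        raise ValueError(f"need >= 10 observations, got {raw.size}")
    if np.any(raw <= 0):
        raise ValueError("raw concentrations must be strictly positive")
    cov = pd.DataFrame(covariates) if not isinstance(covariates, pd.DataFrame) else covariates
    missing = [c for c in spec if c not in cov.columns]
    if missing:
        raise KeyError(f"covariates missing columns: {missing}")
    X = np.column_stack([np.ones(raw.size)] + [cov[c].to_numpy(dtype=float) for c in spec])
    names = ["intercept"] + list(spec)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = _collinear_columns(X, names)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    fit = sm.OLS(np.log10(raw), X).fit()
    return MedianModel(
        marker=marker,
        covariate_names=tuple(spec),
        coefficients=np.asarray(fit.params, dtype=float),
        coefficient_se=np.asarray(fit.bse, dtype=float),
    )


def to_mom(
    raw, median_model: MedianModel, covariates: pd.DataFrame | Mapping
) -> np.ndarray | float:
    """MoM = raw / 10^(predicted log10 median); strictly positive."""
    raw_arr = np.atleast_1d(np.asarray(raw, dtype=float))
    if np.any(raw_arr <= 0):
        raise ValueError("raw concentrations must be strictly positive")
    cov = pd.DataFrame(covariates) if not isinstance(covariates, pd.DataFrame) else covariates
    mom = raw_arr / 10.0 ** median_model.predict_log10_median(cov)
    return float(mom[0]) if np.isscalar(raw) else mom


def log10_ratio_mom(sflt1_mom, plgf_mom) -> np.ndarray | float:
    """log10 of the sFlt-1 MoM to PlGF MoM ratio.

    Antisymmetric in its arguments: swapping them negates the result.
    """
    a = np.asarray(sflt1_mom, dtype=float)
    b = np.asarray(plgf_mom, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("MoM values must be strictly positive")
    out = np.log10(a) - np.log10(b)
    return out if out.ndim else float(out)
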