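"""Covariate regressions on the battery score.

Two analyses: one ordinary-least-squares fit of the score on all covariates
jointly (age, sex, education, employment, ethnicity, reference exam, and
cognitive status), and a per-covariate interaction series regressing the
score on {covariate, status, covariate x status}.  Categorical covariates are
expanded to indicator terms against the most frequent level as reference; no
multiplicity adjustment is applied across the interaction series.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

CATEGORICAL = ("sex", "education", "employment", "ethnicity", "exam", "status")
NUMERIC = ("age",)
ALL_COVARIATES = ("age", "ethnicity", "sex", "education", "employment", "exam")


class CollinearityError(ValueError):
    """The design matrix is rank-deficient; names the involved terms."""


@dataclass(frozen=True)
class RegressionTerm:
    name: str
    coef: float
    se: float
    p_value: float


@dataclass(frozen=True)
class RegressionResult:
    terms: tuple[RegressionTerm, ...]
    n: int
    r_squared: float
    resid_var: float
    degenerate: bool  # constant outcome: slopes forced to zero, R^2 undefined

    def term(self, name: str) -> RegressionTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(f"no term named {name!r}; have {[t.name for t in self.terms]}")

    def coef(self, name: str) -> float:
        return self.term(name).coef


def _indicator_columns(df: pd.DataFrame, name: str) -> pd.DataFrame:
    """Reference-level dummies: most frequent level dropped."""
    counts = df[name].value_counts()
    if len(counts) < 2:
        raise ValueError(f"covariate {name!r} has a single level "
                         f"({counts.index[0]!r}); cannot be used as a predictor")
    reference = counts.index[0]
    levels = [lv for lv in counts.index if lv != reference]
    out = pd.DataFrame(index=df.index)
    for lv in levels:
        out[f"{name}[{lv}]"] = (df[name] == lv).astype(float)
    return out


def _check_rank(x: pd.DataFrame) -> None:
    mat = x.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # columns with weight in the null space are the collinear ones
        _, s, vt = np.linalg.svd(mat, full_matrices=False)
        null = vt[rank:]
        involved = sorted({x.columns[j] for row in null
                           for j in np.flatnonzero(np.abs(row) > 1e-8)})
        raise CollinearityError(f"design matrix is rank-deficient; "
                                f"collinear terms: {involved}")


def _fit(x: pd.DataFrame, y: pd.Series) -> RegressionResult:
    x = sm.add_constant(x, prepend=True).rename(columns={"const": "intercept"})
    _check_rank(x)
    if float(np.var(y)) == 0.0:
        terms = [RegressionTerm("intercept", float(y.iloc[0]), 0.0, 0.0)]
        terms += [RegressionTerm(c, 0.0, 0.0, 1.0) for c in x.columns[1:]]
        return RegressionResult(tuple(terms), len(y), float("nan"), 0.0, True)
    fit = sm.OLS(y.to_numpy(dtype=float), x.to_numpy(dtype=float)).fit()
    terms = tuple(RegressionTerm(name, float(b), float(se), float(p))
                  for name, b, se, p in zip(x.columns, fit.params, fit.bse, fit.pvalues))
    return RegressionResult(terms, int(fit.nobs), float(fit.rsquared),
                            float(fit.mse_resid), False)


def _design_for(df: pd.DataFrame, names: Sequence[str]) -> pd.DataFrame:
    parts = []
    for name in names:
        if name in NUMERIC:
            parts.append(df[[name]].astype(float))
        else:
            parts.append(_indicator_columns(df, name))
    return pd.concat(parts, axis=1)


def fit_all_covariates(cohort: pd.DataFrame) -> RegressionResult:
    """OLS of score on all demographic covariates and cognitive status jointly."""
    x = _design_for(cohort, list(ALL_COVARIATES) + ["status"])
    return _fit(x, cohort["score"])


def fit_interaction(cohort: pd.DataFrame, covariate: str) -> RegressionResult:
    """OLS of score on {covariate, status, covariate x status}.

    Interaction terms are named ``"<term>:<status term>"``; run once per
    covariate to ask whether that factor compounds the effect of impairment.
    """
    if covariate not in ALL_COVARIATES:
        raise ValueError(f"unknown covariate {covariate!r}; one of {ALL_COVARIATES}")
    cov = _design_for(cohort, [covariate])
    status = _design_for(cohort, ["status"])
    x = pd.concat([cov, status], axis=1)
    for c in cov.columns:
        for s in status.columns:
            x[f"{c}:{s}"] = cov[c] * status[s]
    return _fit(x, cohort["score"])
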