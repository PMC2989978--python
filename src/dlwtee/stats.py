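"""Group-comparison statistics for the smoking vs energy-expenditure analysis.

Implements the analysis battery applied to the cohort: per-group summaries,
two-sample t tests (from raw data or from published summary statistics),
Pearson correlations, per-sex multiple regression of TEE on smoking status,
fat-free mass, age and physical activity, and least-squares (covariate-
adjusted) means.  Sexes are analyzed separately throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import InvalidInputError

__all__ = [
    "GroupSummary",
    "TTestResult",
    "RegressionFit",
    "AdjustedMeans",
    "summarize",
    "pooled_t_from_summary",
    "welch_t_from_summary",
    "pooled_t",
    "pearson",
    "ols_fit",
    "ls_means",
    "run_analysis",
]

SMOKING_TERM = "current_smoker"


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise InvalidInputError("group summary requires n >= 1")
        if self.sd < 0:
            raise InvalidInputError("SD must be >= 0")


@dataclass(frozen=True)
class TTestResult:
    """Two-sample comparison, difference taken as group1 - group2."""

    diff: float
    se: float
    t: float
    df: float
    p: float
    ci_low: float
    ci_high: float
    variant: str  # "pooled" | "welch"


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of TEE on a smoking indicator plus continuous covariates."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    cov_params: pd.DataFrame
    resid_sd: float
    df_resid: float
    nobs: int
    terms: tuple[str, ...]
    covariate_means: pd.Series  # grand means over the fitted sample

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        tcrit = sps.t.ppf(1 - alpha / 2, self.df_resid)
        return pd.DataFrame(
            {"low": self.params - tcrit * self.bse,
             "high": self.params + tcrit * self.bse})


@dataclass(frozen=True)
class AdjustedMeans:
    """Model-predicted group means with covariates held at grand means."""

    means: Mapping[str, tuple[float, float]]  # label -> (mean, se)
    diff: float
    se_diff: float
    p: float


def summarize(values: Iterable[float], label: str = "") -> GroupSummary:
    """n, mean, sample SD (n-1 denominator) for one group."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise InvalidInputError(f"group '{label}' is empty")
    if arr.size == 1:
        raise InvalidInputError(f"group '{label}' has a single value; SD undefined")
    return GroupSummary(label=label, n=int(arr.size),
                        mean=float(arr.mean()), sd=float(arr.std(ddof=1)))


def _t_result(diff: float, se: float, df: float, alpha: float, variant: str) -> TTestResult:
    if se <= 0:
        if diff == 0:
            return TTestResult(diff, se, 0.0, df, 1.0, diff, diff, variant)
        raise InvalidInputError("zero standard error with nonzero difference")
    t = diff / se
    p = float(2.0 * sps.t.sf(abs(t), df))
    tcrit = float(sps.t.ppf(1 - alpha / 2, df))
    return TTestResult(diff, se, float(t), float(df), p,
                       diff - tcrit * se, diff + tcrit * se, variant)


def pooled_t_from_summary(g1: GroupSummary, g2: GroupSummary,
                          alpha: float = 0.05) -> TTestResult:
    """Pooled-variance two-sample t test and CI from summary statistics.

    sp^2 = ((n1-1)s1^2 + (n2-1)s2^2)/(n1+n2-2); df = n1+n2-2.  Identical to
    the raw-data pooled t when fed each group's n/mean/SD.
    """
    if g1.n < 2 or g2.n < 2:
        raise InvalidInputError("pooled t requires n >= 2 in each group")
    df = g1.n + g2.n - 2
    sp2 = ((g1.n - 1) * g1.sd**2 + (g2.n - 1) * g2.sd**2) / df
    se = math.sqrt(sp2 * (1.0 / g1.n + 1.0 / g2.n))
    return _t_result(g1.mean - g2.mean, se, df, alpha, "pooled")


def welch_t_from_summary(g1: GroupSummary, g2: GroupSummary,
                         alpha: float = 0.05) -> TTestResult:
    """Welch (unpooled) two-sample t with Welch-Satterthwaite df."""
    if g1.n < 2 or g2.n < 2:
        raise InvalidInputError("Welch t requires n >= 2 in each group")
    v1, v2 = g1.sd**2 / g1.n, g2.sd**2 / g2.n
    se2 = v1 + v2
    if se2 == 0:
        if g1.mean == g2.mean:
            return TTestResult(0.0, 0.0, 0.0, float(g1.n + g2.n - 2), 1.0,
                               0.0, 0.0, "welch")
        raise InvalidInputError("zero variance in both groups with nonzero difference")
    df = se2**2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    return _t_result(g1.mean - g2.mean, math.sqrt(se2), df, alpha, "welch")


def pooled_t(x1: Iterable[float], x2: Iterable[float],
             labels: tuple[str, str] = ("group1", "group2"),
             alpha: float = 0.05, variant: str = "pooled") -> TTestResult:
    """Two-sample t test on raw data (pooled by default, or Welch)."""
    g1 = summarize(x1, labels[0])
    g2 = summarize(x2, labels[1])
    fn = pooled_t_from_summary if variant == "pooled" else welch_t_from_summary
    return fn(g1, g2, alpha)


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation with a two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InvalidInputError("x and y must have equal length")
    if x.size < 3:
        raise InvalidInputError("correlation requires n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise InvalidInputError("correlation undefined for constant input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def _design(frame: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    X = pd.DataFrame(index=frame.index)
    X["const"] = 1.0
    X[SMOKING_TERM] = (frame["smoking_status"] == "current").astype(float)
    for c in covariates:
        X[c] = frame[c].astype(float)
    return X


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy()
    if np.linalg.matrix_rank(arr) == X.shape[1]:
        return
    # name the first column that is linearly dependent on its predecessors
    for j in range(1, X.shape[1]):
        if np.linalg.matrix_rank(arr[:, : j + 1]) <= np.linalg.matrix_rank(arr[:, :j]):
            raise InvalidInputError(f"design matrix rank deficient: term '{X.columns[j]}'")
    raise InvalidInputError("design matrix rank deficient")


def ols_fit(
    frame: pd.DataFrame,
    response: str = "tee_kcal_d",
    covariates: Sequence[str] = ("ffm_kg", "age_y", "pa_met_min_wk"),
) -> RegressionFit:
    """Per-sex multiple regression of TEE on smoking status and covariates.

    ``frame`` should already be restricted to one sex and to the analysis
    sample (never + current smokers).  The smoking term is an indicator for
    current smoking.
    """
    if response not in frame.columns:
        raise InvalidInputError(f"response column '{response}' missing")
    X = _design(frame, covariates)
    y = frame[response].astype(float)
    if len(frame) <= X.shape[1]:
        raise InvalidInputError("need more observations than terms")
    _check_rank(X)
    res = sm.OLS(y, X).fit()
    return RegressionFit(
        params=res.params, bse=res.bse, tvalues=res.tvalues, pvalues=res.pvalues,
        cov_params=res.cov_params(), resid_sd=float(np.sqrt(res.mse_resid)),
        df_resid=float(res.df_resid), nobs=int(res.nobs),
        terms=tuple(X.columns),
        covariate_means=X.drop(columns=["const", SMOKING_TERM]).mean(),
    )


def ls_means(fit: RegressionFit, alpha: float = 0.05) -> AdjustedMeans:
    """Least-squares means by smoking group at the covariate grand means.

    The group difference, its SE and p-value coincide with the smoking
    coefficient's test in the underlying regression.
    """
    if SMOKING_TERM not in fit.terms:
        raise InvalidInputError("fit has no smoking group term")
    means = {}
    for label, indicator in (("never", 0.0), ("current", 1.0)):
        x = pd.Series(0.0, index=list(fit.terms))
        x["const"] = 1.0
        x[SMOKING_TERM] = indicator
        for c in fit.covariate_means.index:
            x[c] = fit.covariate_means[c]
        mean = float(x @ fit.params)
        se = float(np.sqrt(x @ fit.cov_params @ x))
        means[label] = (mean, se)
    return AdjustedMeans(
        means=means,
        diff=float(fit.params[SMOKING_TERM]),
        se_diff=float(fit.bse[SMOKING_TERM]),
        p=float(fit.pvalues[SMOKING_TERM]),
    )


_CHARACTERISTICS = [
    ("age_y", "Age (y)"),
    ("height_cm", "Height (cm)"),
    ("weight_kg", "Weight (kg)"),
    ("bmi_kg_m2", "BMI (kg/m2)"),
    ("ffm_kg", "FFM (kg)"),
    ("pa_met_min_wk", "Physical activity (MET min/wk)"),
]


def run_analysis(
    cohort: pd.DataFrame,
    tee_col: str | None = None,
    variant: str = "pooled",
) -> dict[str, pd.DataFrame]:
    """Full per-sex analysis: characteristics, unadjusted TEE comparison,
    correlations, adjusted (LS) means under two covariate sets, and the
    multiple-regression coefficient table.

    Returns a dict of tidy DataFrames keyed ``characteristics``, ``tee``,
    ``correlations``, ``adjusted_means``, ``regression``.  If the physical-
    activity column is absent, the PA-adjusted rows are omitted.
    """
    if tee_col is None:
        tee_col = "tee_kcal_d" if "tee_kcal_d" in cohort.columns else "true_tee_kcal_d"
    has_pa = "pa_met_min_wk" in cohort.columns

    char_rows, tee_rows, corr_rows, adj_rows, reg_rows = [], [], [], [], []
    for sex in ("male", "female"):
        sub = cohort[cohort["sex"] == sex]
        if sub.empty:
            continue
        groups = {
            "current": sub[sub["smoking_status"] == "current"],
            "never": sub[sub["smoking_status"] == "never"],
        }
        # characteristics table
        for col, label in _CHARACTERISTICS:
            if col not in sub.columns:
                continue
            row = {"sex": sex, "variable": label}
            for gname, g in groups.items():
                s = summarize(g[col], gname)
                row[f"{gname}_n"] = s.n
                row[f"{gname}_mean"] = s.mean
                row[f"{gname}_sd"] = s.sd
            char_rows.append(row)
        # unadjusted TEE comparison (current - never)
        gs = {name: summarize(g[tee_col], name) for name, g in groups.items()}
        fn = pooled_t_from_summary if variant == "pooled" else welch_t_from_summary
        tt = fn(gs["current"], gs["never"])
        tee_rows.append({
            "sex": sex,
            "overall_mean": float(sub[tee_col].mean()),
            "overall_sd": float(sub[tee_col].std(ddof=1)),
            "never_mean": gs["never"].mean, "never_sd": gs["never"].sd,
            "current_mean": gs["current"].mean, "current_sd": gs["current"].sd,
            "diff": tt.diff, "se": tt.se, "p": tt.p,
            "ci_low": tt.ci_low, "ci_high": tt.ci_high,
        })
        # correlations of TEE with covariates
        corr_vars = [("ffm_kg", "FFM (kg)"), ("age_y", "Age (y)")]
        if has_pa:
            corr_vars.append(("pa_met_min_wk", "SR PA (MET min/wk)"))
        for col, label in corr_vars:
            r, p = pearson(sub[col], sub[tee_col])
            corr_rows.append({"sex": sex, "factor": label, "r": r, "p": p})
        # adjusted means under both covariate sets + regression table
        cov_sets = [("age, FFM", ("ffm_kg", "age_y"))]
        if has_pa:
            cov_sets.append(("age, FFM, PA", ("ffm_kg", "age_y", "pa_met_min_wk")))
        for set_label, covs in cov_sets:
            fit = ols_fit(sub, response=tee_col, covariates=covs)
            adj = ls_means(fit)
            adj_rows.append({
                "sex": sex, "adjusted_for": set_label,
                "never_mean": adj.means["never"][0], "never_se": adj.means["never"][1],
                "current_mean": adj.means["current"][0], "current_se": adj.means["current"][1],
                "diff": adj.diff, "se": adj.se_diff, "p": adj.p,
            })
        full_covs = cov_sets[-1][1]
        fit = ols_fit(sub, response=tee_col, covariates=full_covs)
        for term in fit.terms:
            if term == "const":
                continue
            reg_rows.append({
                "sex": sex, "term": term, "coef": float(fit.params[term]),
                "se": float(fit.bse[term]), "t": float(fit.tvalues[term]),
                "p": float(fit.pvalues[term]),
            })

    return {
        "characteristics": pd.DataFrame(char_rows),
        "tee": pd.DataFrame(tee_rows),
        "correlations": pd.DataFrame(corr_rows),
        "adjusted_means": pd.DataFrame(adj_rows),
        "regression": pd.DataFrame(reg_rows),
    }
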