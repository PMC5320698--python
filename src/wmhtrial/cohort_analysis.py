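"""The observational analysis stage on any cohort table.

Reproduces the reference study's analyses: completers-vs-dropouts group
comparisons (t tests for continuous variables, chi-square for categorical),
univariate and multivariable OLS of follow-up WMH volume on the ten
hypothesis-driven predictors, variance-inflation-factor collinearity checks,
and the proportional-odds model giving the odds ratio of a higher Fazekas
category per ml of WMH volume.  All model fits stand on statsmodels; missing
follow-up is excluded listwise (analyses run on completers only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .exceptions import DataError, DegenerateOutcomeError, SingularityError
from .synthetic_cohort import CohortTable

__all__ = [
    "DEFAULT_PREDICTORS",
    "LinearModelFit",
    "VIFReport",
    "OrdinalFit",
    "GroupComparison",
    "fit_progression_models",
    "compute_vif",
    "fit_volume_to_fazekas",
    "compare_dropout_groups",
]

#: The ten hypothesis-driven predictors of 1-year WMH volume, as cohort columns.
DEFAULT_PREDICTORS = [
    "wmh_baseline",
    "fazekas_baseline",
    "map",
    "pp",
    "hypertension",
    "age",
    "subtype",
    "smoker",
    "diabetes",
    "hyperlipidaemia",
]


def _as_frame(cohort: CohortTable | pd.DataFrame) -> pd.DataFrame:
    return cohort.data if isinstance(cohort, CohortTable) else cohort


@dataclass(frozen=True)
class LinearModelFit:
    """An OLS fit: per-predictor estimates with 95% CIs and p-values.

    ``table`` has one row per predictor with columns
    ``coef, ci_low, ci_high, p_value``.
    """

    table: pd.DataFrame
    r_squared: float
    resid_sd: float
    n_used: int
    outcome: str = "wmh_followup"

    def coef(self, predictor: str) -> float:
        return float(self.table.loc[predictor, "coef"])


@dataclass(frozen=True)
class VIFReport:
    """Per-predictor variance inflation factors, 1/(1 - R^2_j)."""

    vif: dict[str, float]

    def __getitem__(self, predictor: str) -> float:
        return self.vif[predictor]


@dataclass(frozen=True)
class OrdinalFit:
    """A proportional-odds fit of an ordinal score on a continuous predictor."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    log_or_se: float
    cutpoints: tuple[float, ...]
    n_used: int


@dataclass(frozen=True)
class GroupComparison:
    """A completers-minus-non-completers contrast for one baseline variable."""

    variable: str
    kind: str  # "continuous" | "binary" | "ordinal"
    difference: float | None  # means (continuous) or percentage points (binary)
    ci_low: float | None
    ci_high: float | None
    p_value: float
    test: str


def _complete_cases(df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    return df.dropna(subset=columns)


def _check_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # name the offending columns by locating ones whose removal restores rank
        bad = []
        for j, name in enumerate(X.columns):
            sub = np.delete(mat, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(name)
        raise SingularityError(f"design matrix is rank-deficient; collinear columns: {bad}")


def _ols_fit(df: pd.DataFrame, outcome: str, predictors: list[str]) -> LinearModelFit:
    y = df[outcome]
    X = sm.add_constant(df[predictors], has_constant="add")
    _check_rank(X)
    res = sm.OLS(y, X).fit()
    ci = res.conf_int(alpha=0.05)
    table = pd.DataFrame(
        {
            "coef": res.params,
            "ci_low": ci[0],
            "ci_high": ci[1],
            "p_value": res.pvalues,
        }
    ).loc[predictors]
    return LinearModelFit(
        table=table,
        r_squared=float(res.rsquared),
        resid_sd=float(np.sqrt(res.mse_resid)),
        n_used=int(res.nobs),
        outcome=outcome,
    )


def fit_progression_models(
    cohort: CohortTable | pd.DataFrame,
    predictors: list[str] | None = None,
    outcome: str = "wmh_followup",
) -> tuple[list[LinearModelFit], LinearModelFit]:
    """Univariate OLS fits (one per predictor) and the multivariable fit.

    Complete cases only; rows missing the outcome (dropouts) are excluded
    listwise, as in an observational analysis of completers.
    """
    predictors = list(DEFAULT_PREDICTORS if predictors is None else predictors)
    df = _complete_cases(_as_frame(cohort), [outcome] + predictors)
    if len(df) < len(predictors) + 2:
        raise DataError(
            f"need at least {len(predictors) + 2} complete cases, have {len(df)}"
        )
    univariate = [_ols_fit(df, outcome, [p]) for p in predictors]
    multivariable = _ols_fit(df, outcome, predictors)
    return univariate, multivariable


def compute_vif(
    cohort: CohortTable | pd.DataFrame, predictors: list[str] | None = None
) -> VIFReport:
    """Variance inflation factors, VIF_j = 1/(1 - R^2_j).

    ``R^2_j`` regresses predictor j on all the others (with intercept).  A
    perfectly collinear predictor yields an infinite VIF, reported as such
    with a warning.
    """
    predictors = list(DEFAULT_PREDICTORS if predictors is None else predictors)
    df = _complete_cases(_as_frame(cohort), predictors)
    out: dict[str, float] = {}
    for name in predictors:
        others = [p for p in predictors if p != name]
        X = sm.add_constant(df[others], has_constant="add")
        r2 = float(sm.OLS(df[name], X).fit().rsquared)
        if r2 >= 1.0 - 1e-12:
            warnings.warn(f"predictor {name!r} is perfectly collinear; VIF is infinite",
                          stacklevel=2)
            out[name] = float("inf")
        else:
            out[name] = 1.0 / (1.0 - r2)
    return VIFReport(out)


def fit_volume_to_fazekas(
    cohort: CohortTable | pd.DataFrame,
    volume_col: str = "wmh_baseline",
    score_col: str = "fazekas_baseline",
) -> OrdinalFit:
    """Proportional-odds model of the Fazekas score on WMH volume.

    Returns the odds ratio of being in a higher category per 1 ml of volume,
    with its Wald 95% CI and the fitted cutpoints.
    """
    df = _complete_cases(_as_frame(cohort), [volume_col, score_col])
    scores = df[score_col].astype(int)
    if scores.nunique() < 2:
        raise DegenerateOutcomeError(
            f"{score_col} has a single category; ordinal model is degenerate"
        )
    model = OrderedModel(
        pd.Categorical(scores, ordered=True), df[[volume_col]], distr="logit"
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(method="bfgs", disp=False, maxiter=500)
    beta = float(res.params.iloc[0])
    se = float(res.bse.iloc[0])
    cutpoints = tuple(float(c) for c in model.transform_threshold_params(res.params)[1:-1])
    return OrdinalFit(
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.959963984540054 * se)),
        ci_high=float(np.exp(beta + 1.959963984540054 * se)),
        log_or_se=se,
        cutpoints=cutpoints,
        n_used=len(df),
    )


_CONTINUOUS_VARS = ["wmh_baseline", "age", "map", "pp"]
_BINARY_VARS = ["hypertension", "subtype", "smoker", "diabetes", "hyperlipidaemia"]


def _welch_ci(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Difference in means (a - b) with Welch 95% CI."""
    diff = float(a.mean() - b.mean())
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    se = float(np.sqrt(va + vb))
    if se == 0:
        return diff, diff, diff
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    t = float(stats.t.ppf(0.975, df))
    return diff, diff - t * se, diff + t * se


def compare_dropout_groups(
    cohort: CohortTable | pd.DataFrame,
    *,
    equal_var: bool = False,
    continuity_correction: bool = False,
) -> list[GroupComparison]:
    """Baseline differences between completers and non-completers.

    Sign convention: completers minus non-completers (a positive number means
    patients with follow-up had the higher mean or larger proportion).
    Continuous variables use t tests (Welch by default), binary variables and
    the 7-category Fazekas distribution use chi-square tests.
    """
    df = _as_frame(cohort)
    comp = df[df["dropout"] == 0]
    drop = df[df["dropout"] == 1]
    if len(comp) == 0 or len(drop) == 0:
        raise DataError("both completer and non-completer groups must be non-empty")
    out: list[GroupComparison] = []
    for name in _CONTINUOUS_VARS:
        a = comp[name].to_numpy(dtype=float)
        b = drop[name].to_numpy(dtype=float)
        stat = stats.ttest_ind(a, b, equal_var=equal_var)
        diff, lo, hi = _welch_ci(a, b)
        out.append(
            GroupComparison(
                variable=name,
                kind="continuous",
                difference=diff,
                ci_low=lo,
                ci_high=hi,
                p_value=float(stat.pvalue),
                test="welch t" if not equal_var else "pooled t",
            )
        )
    for name in _BINARY_VARS:
        a = comp[name].to_numpy(dtype=int)
        b = drop[name].to_numpy(dtype=int)
        table = np.array(
            [[a.sum(), len(a) - a.sum()], [b.sum(), len(b) - b.sum()]], dtype=float
        )
        if np.any(table.sum(axis=0) == 0):
            p = 1.0
        else:
            p = float(
                stats.chi2_contingency(table, correction=continuity_correction)[1]
            )
        pa, pb = a.mean(), b.mean()
        se = float(np.sqrt(pa * (1 - pa) / len(a) + pb * (1 - pb) / len(b)))
        diff = float(pa - pb) * 100.0
        out.append(
            GroupComparison(
                variable=name,
                kind="binary",
                difference=diff,
                ci_low=diff - 196.0 * se,
                ci_high=diff + 196.0 * se,
                p_value=p,
                test="chi-square",
            )
        )
    # overall 7-category Fazekas comparison
    counts = pd.crosstab(df["dropout"], df["fazekas_baseline"].astype(int))
    counts = counts.loc[:, counts.sum(axis=0) > 0]
    if counts.shape[1] < 2:
        p = 1.0
    else:
        p = float(stats.chi2_contingency(counts.to_numpy(), correction=False)[1])
    out.append(
        GroupComparison(
            variable="fazekas_baseline",
            kind="ordinal",
            difference=None,
            ci_low=None,
            ci_high=None,
            p_value=p,
            test="chi-square (overall)",
        )
    )
    return out
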