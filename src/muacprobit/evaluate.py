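"""Performance metrics for the simulation study: bias, precision, coverage,
threshold classification, and the linear regression of bias on survey
characteristics.

All metric functions operate on slices of the result table produced by
:func:`muacprobit.simulate.run_study` (columns ``point``, ``ci_low``,
``ci_high``, ``true_prev``, ...).  Bias and precision are reported in
percentage points; coverage and classification probabilities as
proportions.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

__all__ = [
    "BiasResult",
    "ClassificationRow",
    "BiasRegressionTable",
    "bias",
    "precision",
    "coverage",
    "classify",
    "summarize",
    "gam_category",
    "mean_bias_table",
    "bias_regression",
]


def _valid(rows: pd.DataFrame) -> pd.DataFrame:
    if len(rows) == 0:
        raise ValueError("empty result slice")
    if "error_code" in rows.columns:
        rows = rows[(rows["error_code"] == "") | rows["error_code"].isna()]
    rows = rows.dropna(subset=["point"])
    if len(rows) == 0:
        raise ValueError("slice contains no successful estimates")
    return rows


class BiasResult(NamedTuple):
    """Mean and median of (estimate - truth), percentage points."""

    mean_pp: float
    median_pp: float


def bias(rows: pd.DataFrame) -> BiasResult:
    """Average (and median) difference between estimate and true prevalence."""
    rows = _valid(rows)
    diff = 100.0 * (rows["point"] - rows["true_prev"])
    return BiasResult(float(diff.mean()), float(diff.median()))


def precision(rows: pd.DataFrame) -> float:
    """Mean CI half-width |upper - lower| / 2, percentage points (smaller = better)."""
    rows = _valid(rows).dropna(subset=["ci_low", "ci_high"])
    if len(rows) == 0:
        raise ValueError("slice contains no confidence intervals")
    return float((100.0 * (rows["ci_high"] - rows["ci_low"]).abs() / 2.0).mean())


def coverage(rows: pd.DataFrame) -> float:
    """Proportion of CIs containing the true prevalence (closed interval)."""
    rows = _valid(rows)
    inside = (rows["ci_low"] <= rows["true_prev"]) & (rows["true_prev"] <= rows["ci_high"])
    return float(inside.mean())


@dataclasses.dataclass(frozen=True)
class ClassificationRow:
    """Threshold-classification performance at one (method, size, threshold).

    ``p_correct`` is the sensitivity reading: among surveys whose *true*
    prevalence is at or above the threshold, the share whose estimate is
    too.  Specificity (truth below, estimate below) and overall accuracy
    are carried alongside since the conditional/unconditional readings are
    both of interest.
    """

    threshold_pct: float
    p_correct: float | None
    specificity: float | None
    accuracy: float
    n_eligible: int

    def __post_init__(self):
        for v in (self.p_correct, self.specificity):
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError("classification probabilities must lie in [0,1]")


def classify(rows: pd.DataFrame, threshold_pct: float) -> ClassificationRow:
    """Probability of correctly classifying prevalence >= threshold."""
    rows = _valid(rows)
    thr = threshold_pct / 100.0
    truth_above = rows["true_prev"] >= thr
    est_above = rows["point"] >= thr
    n_eligible = int(truth_above.sum())
    p_correct = float(est_above[truth_above].mean()) if n_eligible else None
    n_below = int((~truth_above).sum())
    specificity = float((~est_above[~truth_above]).mean()) if n_below else None
    accuracy = float((truth_above == est_above).mean())
    return ClassificationRow(
        threshold_pct=threshold_pct,
        p_correct=p_correct,
        specificity=specificity,
        accuracy=accuracy,
        n_eligible=n_eligible,
    )


GAM_CATEGORY_LABELS = ("<5%", "5-9%", "10-14%", ">=15%")


def gam_category(true_gam) -> pd.Series | str:
    """Bin true GAM prevalence (proportion) into the standard four categories."""
    scalar = np.isscalar(true_gam)
    g = pd.Series(np.atleast_1d(np.asarray(true_gam, dtype=float)))
    out = pd.cut(
        g,
        bins=[-np.inf, 0.05, 0.10, 0.15, np.inf],
        labels=GAM_CATEGORY_LABELS,
        right=False,
    ).astype(str)
    return out.iloc[0] if scalar else out


def summarize(
    results: pd.DataFrame,
    group_keys: Sequence[str] = ("method", "cutoff_mm", "sample_size"),
    thresholds: Sequence[float] = (),
) -> pd.DataFrame:
    """Metrics grid: one row of bias/precision/coverage per group.

    ``group_keys`` may include ``gam_category`` or ``region`` for the
    stratified layouts.  Optional classification columns (``p_correct_T``)
    are added per threshold.  Groups left empty after dropping failed rows
    are omitted with a warning.
    """
    if len(results) == 0:
        raise ValueError("empty result table")
    df = results.copy()
    if "gam_category" in group_keys and "gam_category" not in df.columns:
        df["gam_category"] = gam_category(df["true_gam"]).to_numpy()
    for key in group_keys:
        if key not in df.columns:
            raise ValueError(f"unknown group key {key!r}")
    out_rows = []
    for keys, grp in df.groupby(list(group_keys), observed=True, sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        try:
            b = bias(grp)
            row = dict(zip(group_keys, keys))
            row.update(
                bias_pp=b.mean_pp,
                median_bias_pp=b.median_pp,
                precision_pp=precision(grp),
                coverage=coverage(grp),
                n_rows=int(len(_valid(grp))),
            )
        except ValueError:
            warnings.warn(f"group {keys!r} has no successful estimates; omitted")
            continue
        for t in thresholds:
            c = classify(grp, t)
            row[f"p_correct_{t:g}"] = c.p_correct
        out_rows.append(row)
    return pd.DataFrame(out_rows)


# ---------------------------------------------------------------------------
# bias regression

#: Predictors and their reference levels for the bias regression.
REFERENCE_LEVELS = {
    "region": "east_africa",
    "gam_category": "<5%",
    "livelihood": "agriculture",
    "residence": "rural",
    "sample_size": 25,
    "date_period": "before_2006",
    "design": "simple_random",
}


def mean_bias_table(results: pd.DataFrame, method: str, cutoff_mm: float = 125.0) -> pd.DataFrame:
    """Per-(population, sample size) mean bias for one method at one cutoff.

    This is the unit of analysis for :func:`bias_regression`: the finest
    granularity at which sample size is still a meaningful predictor.
    """
    df = _valid(results)
    df = df[(df["method"] == method) & (df["cutoff_mm"] == cutoff_mm)].copy()
    if len(df) == 0:
        raise ValueError(f"no rows for method {method!r} at cutoff {cutoff_mm}")
    df["bias_pp"] = 100.0 * (df["point"] - df["true_prev"])
    df["gam_category"] = gam_category(df["true_gam"]).to_numpy()
    keys = ["pop_id", "region", "gam_category", "livelihood", "residence",
            "date_period", "design", "sample_size"]
    out = df.groupby(keys, observed=True, as_index=False)["bias_pp"].mean()
    return out


@dataclasses.dataclass
class BiasRegressionTable:
    """OLS fit of mean bias on survey characteristics.

    ``table`` has one row per predictor level: coefficient, normal-theory
    95% CI, p-value; reference levels carry NaN coefficients and are
    flagged.
    """

    table: pd.DataFrame
    model_results: object  # statsmodels RegressionResults

    def coefficient(self, term: str) -> pd.Series:
        hit = self.table[self.table["term"] == term]
        if len(hit) != 1:
            raise KeyError(f"term {term!r} not found")
        return hit.iloc[0]

    def summary(self) -> str:
        return str(self.model_results.summary())


def bias_regression(
    mean_bias: pd.DataFrame,
    predictors: Sequence[str] = tuple(REFERENCE_LEVELS),
) -> BiasRegressionTable:
    """Ordinary least squares of mean bias (pp) on dummy-coded predictors.

    Categorical predictors use treatment coding at the field-standard
    reference levels (East Africa, GAM <5%, agriculture, rural, n=25,
    before 2006, simple random).  Raises on predictors with < 2 observed
    levels or a singular design matrix, naming the offender.
    """
    df = mean_bias.copy()
    terms = []
    for p in predictors:
        if p not in df.columns:
            raise ValueError(f"predictor {p!r} missing from table")
        levels = df[p].unique()
        if len(levels) < 2:
            raise ValueError(f"predictor {p!r} has a single level {levels[0]!r}")
        ref = REFERENCE_LEVELS.get(p)
        if ref is not None and ref in levels:
            terms.append(f"C({p}, Treatment({ref!r}))")
        else:
            terms.append(f"C({p})")
    if df["bias_pp"].isna().any():
        raise ValueError("mean bias table contains missing bias values")
    if len(df) <= len(predictors) + 1:
        raise ValueError("not enough rows to fit the regression")
    formula = "bias_pp ~ " + " + ".join(terms)
    fit = smf.ols(formula, data=df).fit()
    if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
        raise ValueError(
            "singular design matrix; collinear levels among " + ", ".join(predictors)
        )

    conf = fit.conf_int()
    rows = [{
        "predictor": "intercept", "term": "Intercept", "level": "",
        "coef": float(fit.params["Intercept"]),
        "ci_low": float(conf.loc["Intercept", 0]),
        "ci_high": float(conf.loc["Intercept", 1]),
        "p_value": float(fit.pvalues["Intercept"]),
        "is_reference": False,
    }]
    for p in predictors:
        ref = REFERENCE_LEVELS.get(p)
        for level in sorted(df[p].unique(), key=str):
            if level == ref:
                rows.append({
                    "predictor": p, "term": f"{p}[{level}]", "level": str(level),
                    "coef": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                    "p_value": np.nan, "is_reference": True,
                })
                continue
            name = _patsy_name(p, ref, level)
            if name not in fit.params.index:
                continue
            rows.append({
                "predictor": p, "term": f"{p}[{level}]", "level": str(level),
                "coef": float(fit.params[name]),
                "ci_low": float(conf.loc[name, 0]),
                "ci_high": float(conf.loc[name, 1]),
                "p_value": float(fit.pvalues[name]),
                "is_reference": False,
            })
    return BiasRegressionTable(table=pd.DataFrame(rows), model_results=fit)


def _patsy_name(predictor: str, ref, level) -> str:
    if ref is not None:
        return f"C({predictor}, Treatment({ref!r}))[T.{level}]"
    return f"C({predictor})[T.{level}]"
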