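"""Descriptives, correlations, group comparisons and the tertile GLM.

The headline analysis relates overall diet quality — the tertile category
of the total-diet HEI-2015 or NRF9.3 score — to intakes from each meal
type, using a general linear model adjusted for sex, age group, weight
status, dietary reporting status and survey year. Adjusted tertile means
are population-marginal: model predictions per tertile averaged over the
observed covariate distribution. The trend statistic refits the model
with the tertile as an ordinal 1/2/3 score and reports its slope p-value.

Group comparisons of scores follow the convention of descriptive diet-
quality tables: an independent t test for two-level groupings, one-way
ANOVA for three or more levels, with an all-pairs Bonferroni post hoc
(compact letter display) only when the overall ANOVA p is below 0.05.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

TERTILE_LABELS = ("T1", "T2", "T3")
DEFAULT_COVARIATES = ("sex", "age_band", "weight_status", "reporting_status",
                      "survey_year")


def age_band(age: int, edges: tuple[int, ...] = (40, 60)) -> str:
    """Age groups used as an adjustment factor (default <40, 40-59, >=60)."""
    if age < edges[0]:
        return f"<{edges[0]}"
    if age < edges[1]:
        return f"{edges[0]}-{edges[1] - 1}"
    return f">={edges[1]}"


# ---------------------------------------------------------------------------
# Tertiles
# ---------------------------------------------------------------------------

def assign_tertiles(scores: pd.Series) -> pd.DataFrame:
    """Split participants into score tertiles T1 < T2 < T3.

    Ranking uses average ranks for ties broken by stable input order, so
    the assignment is a deterministic, permutation-invariant function of
    the (id, score) pairs. Group sizes differ by at most one. Returns a
    frame indexed like *scores* with ``tertile`` plus the per-tertile
    median and range.
    """
    scores = scores.dropna()
    order = scores.rank(method="average").sort_values(kind="stable").index
    n = len(order)
    sizes = [n // 3 + (1 if i < n % 3 else 0) for i in range(3)]
    labels = np.repeat(list(TERTILE_LABELS), sizes)
    out = pd.DataFrame({"tertile": pd.Series(labels, index=order)})
    out["score"] = scores
    summary = (out.groupby("tertile")["score"]
               .agg(median="median", min="min", max="max"))
    return out.join(summary, on="tertile")


# ---------------------------------------------------------------------------
# Descriptives and correlations
# ---------------------------------------------------------------------------

def describe_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Mean, SD and quartiles of every score column.

    *scores* is a (participant x stratum)-indexed frame; the result has one
    row per (score column, stratum)."""
    rows = []
    for col in scores.columns:
        for stratum, sub in scores.groupby(level="stratum", observed=True):
            vals = sub[col].dropna()
            rows.append({
                "score": col, "stratum": stratum, "n": int(vals.size),
                "mean": vals.mean(), "sd": vals.std(ddof=1),
                "q25": vals.quantile(0.25), "median": vals.median(),
                "q75": vals.quantile(0.75),
            })
    return pd.DataFrame(rows).set_index(["score", "stratum"])


def correlate(score_wide: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations between strata (pairwise-complete).

    *score_wide* has one row per participant and one column per stratum.
    Zero-variance columns yield missing correlations (pandas semantics).
    """
    return score_wide.corr(method="pearson", min_periods=3)


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

def _compact_letters(levels, diff: dict[tuple, bool]) -> dict[str, str]:
    """Compact letter display: levels sharing a letter are not significantly
    different. Greedy insert-and-absorb over mean-ordered levels."""
    groups: list[set] = []
    for lv in levels:
        placed = False
        for g in groups:
            if all(not diff.get(tuple(sorted((lv, other))), False) for other in g):
                g.add(lv)
                placed = True
        if not placed:
            groups.append({lv})
    letters = {lv: "" for lv in levels}
    for letter, g in zip(string.ascii_lowercase, groups):
        for lv in g:
            letters[lv] += letter
    return letters


def compare_groups(values: pd.Series, grouping: pd.Series,
                   alpha: float = 0.05) -> dict:
    """Compare score means across the levels of one participant grouping.

    Two levels: independent t test. Three or more: one-way ANOVA; if the
    overall p is below *alpha*, all-pairs Bonferroni-corrected t tests
    produce post hoc letters. Levels with fewer than two observations are
    skipped with a warning.
    """
    df = pd.DataFrame({"value": values, "group": grouping}).dropna()
    counts = df.groupby("group", observed=True).size()
    small = counts[counts < 2]
    for level, cnt in small.items():
        logger.warning("group %r has n=%d < 2; skipped", level, cnt)
    levels = [lv for lv in counts.index if counts[lv] >= 2]
    samples = [df.loc[df["group"] == lv, "value"].to_numpy() for lv in levels]
    out = {
        "levels": levels,
        "n": {lv: int(counts[lv]) for lv in levels},
        "means": {lv: float(s.mean()) for lv, s in zip(levels, samples)},
        "sds": {lv: float(s.std(ddof=1)) for lv, s in zip(levels, samples)},
        "letters": None,
    }
    if len(levels) < 2:
        out.update(test=None, p_value=np.nan)
        return out
    if len(levels) == 2:
        t, p = stats.ttest_ind(*samples)
        out.update(test="t", statistic=float(t), p_value=float(p))
        return out
    f, p = stats.f_oneway(*samples)
    out.update(test="anova", statistic=float(f), p_value=float(p))
    if p < alpha:
        m = len(levels) * (len(levels) - 1) // 2
        diff = {}
        for i in range(len(levels)):
            for j in range(i + 1, len(levels)):
                _, pij = stats.ttest_ind(samples[i], samples[j])
                key = tuple(sorted((levels[i], levels[j])))
                diff[key] = min(pij * m, 1.0) < alpha
        out["letters"] = _compact_letters(levels, diff)
    return out


# ---------------------------------------------------------------------------
# Tertile general linear model
# ---------------------------------------------------------------------------

@dataclass
class AdjustedMeansResult:
    outcome: str
    adjusted_means: dict          # tertile label -> adjusted mean
    trend_slope: float
    trend_p: float
    covariates: tuple
    n: int
    dropped_levels: list = field(default_factory=list)


def _design(df: pd.DataFrame, factors) -> pd.DataFrame:
    """Treatment-coded design matrix with an intercept."""
    X = pd.DataFrame(index=df.index)
    X["const"] = 1.0
    for f in factors:
        dummies = pd.get_dummies(df[f].astype(str), prefix=f, drop_first=True,
                                 dtype=float)
        X = pd.concat([X, dummies], axis=1)
    return X


def tertile_glm(data: pd.DataFrame, outcome: str,
                tertile_col: str = "tertile",
                covariates: tuple = DEFAULT_COVARIATES) -> AdjustedMeansResult:
    """Linear model of *outcome* on the tertile category plus categorical
    covariates; see module docstring for the adjusted-means and trend
    conventions.

    Covariate levels with no observations are dropped automatically by the
    dummy coding (logged); a rank-deficient design falls back to the
    pseudoinverse solution.
    """
    df = data[[outcome, tertile_col, *covariates]].dropna().copy()
    dropped = []
    for f in covariates:
        seen = df[f].astype(str).unique()
        all_levels = data[f].dropna().astype(str).unique()
        for lv in set(all_levels) - set(seen):
            dropped.append(f"{f}={lv}")
            logger.warning("covariate level %s=%s unobserved; dropped", f, lv)

    X = _design(df, (tertile_col, *covariates))
    y = df[outcome].astype(float)
    model = sm.OLS(y, X).fit()

    # population-marginal adjusted means: predict each tertile for everyone
    tcols = [c for c in X.columns if c.startswith(f"{tertile_col}_")]
    adj = {}
    for label in TERTILE_LABELS:
        Xc = X.copy()
        for c in tcols:
            Xc[c] = 1.0 if c == f"{tertile_col}_{label}" else 0.0
        adj[label] = float(model.predict(Xc).mean())

    # ordinal trend: tertile as numeric 1/2/3
    Xt = _design(df, covariates)
    Xt.insert(1, "tertile_score",
              df[tertile_col].map({lb: i + 1 for i, lb in
                                   enumerate(TERTILE_LABELS)}).astype(float))
    trend = sm.OLS(y, Xt).fit()
    return AdjustedMeansResult(
        outcome=outcome, adjusted_means=adj,
        trend_slope=float(trend.params["tertile_score"]),
        trend_p=float(trend.pvalues["tertile_score"]),
        covariates=tuple(covariates), n=len(df), dropped_levels=dropped)


def tertile_table(data: pd.DataFrame, outcomes: list[str],
                  covariates: tuple = DEFAULT_COVARIATES) -> pd.DataFrame:
    """Run :func:`tertile_glm` for many outcomes; one row per outcome with
    T1/T2/T3 adjusted means and the trend p-value."""
    rows = []
    for outcome in outcomes:
        res = tertile_glm(data, outcome, covariates=covariates)
        rows.append({"outcome": outcome, **res.adjusted_means,
                     "trend_p": res.trend_p, "n": res.n})
    return pd.DataFrame(rows).set_index("outcome")
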