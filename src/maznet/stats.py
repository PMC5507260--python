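"""Nonparametric group comparisons of behavioral feature tables.

A thin layer over scipy's test routines mirroring the standard battery for
this kind of design: Kruskal-Wallis between groups per day (with pairwise
Mann-Whitney follow-ups), Friedman across days within a group (with pairwise
sign-test follow-ups), both under Ryan's step-down alpha adjustment, and
Pearson-R effect sizes binned as null / small / medium / large. Undefined
feature values (degenerate networks) are excluded pairwise and the exclusion
counts reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class ComparisonResult:
    """Outcome of one statistical comparison."""

    feature: str
    test: str
    statistic: float
    df: float | None
    p_value: float
    alpha: float
    significant: bool
    effect_size: float | None = None
    effect_class: str | None = None
    detail: dict = field(default_factory=dict)
    followups: list["ComparisonResult"] = field(default_factory=list)
    skipped: str | None = None


def effect_size_class(R: float) -> str:
    """Bin a Pearson-R effect size: null [0,0.1), small [0.1,0.3),
    medium [0.3,0.5), large [0.5,1]."""
    if not (0.0 <= R <= 1.0):
        raise ValueError("R must lie in [0, 1]")
    if R < 0.1:
        return "null"
    if R < 0.3:
        return "small"
    if R < 0.5:
        return "medium"
    return "large"


def ryan_adjusted_alpha(alpha: float, k_conditions: int, span_m: int) -> float:
    """Ryan's step-down adjusted significance level.

    For a pairwise comparison spanning ``span_m`` ordered conditions out of
    ``k_conditions`` total, the nominal level is alpha' = 2 alpha / (k (m-1));
    for the single comparison case (k = m = 2) this reduces to alpha itself.
    """
    if not (2 <= span_m <= k_conditions):
        raise ValueError("span_m must satisfy 2 <= span_m <= k_conditions")
    return 2.0 * alpha / (k_conditions * (span_m - 1))


def _mwu_effect_size(x: np.ndarray, y: np.ndarray, U: float) -> float:
    """Pearson R for a Mann-Whitney comparison via the normal approximation."""
    n1, n2 = len(x), len(y)
    mu = n1 * n2 / 2.0
    # tie-corrected variance
    all_v = np.concatenate([x, y])
    n = n1 + n2
    _, counts = np.unique(all_v, return_counts=True)
    tie = np.sum(counts**3 - counts)
    var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    if var <= 0:
        return 0.0
    z = (U - mu) / np.sqrt(var)
    return float(min(abs(z) / np.sqrt(n), 1.0))


def _sign_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Exact two-sided sign test on paired data; ties dropped.

    Returns (statistic = n_positive, p, n_informative).
    """
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0, 0
    n_pos = int(np.sum(d > 0))
    p = sps.binomtest(n_pos, n, 0.5).pvalue
    return float(n_pos), float(p), n


def between_group_per_day(
    table: pd.DataFrame,
    feature: str,
    group_key: str = "entry",
    day_col: str = "day",
    alpha: float = 0.05,
) -> list[ComparisonResult]:
    """Kruskal-Wallis per day between groups, with Mann-Whitney follow-ups.

    Expects one row per subject-day (daily-averaged features). NaN feature
    values are excluded pairwise with counts recorded. Follow-up pairwise
    Mann-Whitney tests run only when the omnibus test is significant, at the
    Ryan-adjusted level.
    """
    out: list[ComparisonResult] = []
    for day, sub in table.groupby(day_col, sort=True):
        groups, names = [], []
        n_excluded = 0
        for gname, g in sub.groupby(group_key, sort=True):
            v = g[feature].to_numpy(dtype=float)
            n_excluded += int(np.sum(~np.isfinite(v)))
            v = v[np.isfinite(v)]
            if len(v) >= 2:
                groups.append(v)
                names.append(gname)
        res = ComparisonResult(
            feature=feature, test="kruskal-wallis", statistic=np.nan, df=None,
            p_value=np.nan, alpha=alpha, significant=False,
            detail={"day": day, "n_excluded": n_excluded, "groups": names},
        )
        if len(groups) < 2:
            res.skipped = "fewer than 2 groups with >= 2 observations"
            out.append(res)
            continue
        if all(np.all(g == groups[0][0]) for g in groups):
            # identical constant groups: no evidence of difference
            res.statistic, res.p_value, res.df = 0.0, 1.0, float(len(groups) - 1)
        else:
            H, p = sps.kruskal(*groups)
            res.statistic, res.p_value, res.df = float(H), float(p), float(len(groups) - 1)
        res.significant = res.p_value < alpha
        if res.significant and len(groups) >= 2:
            k = len(groups)
            adj = ryan_adjusted_alpha(alpha, k, k) if k > 2 else alpha
            for (i, j) in combinations(range(k), 2):
                U, p = sps.mannwhitneyu(groups[i], groups[j], alternative="two-sided")
                R = _mwu_effect_size(groups[i], groups[j], float(U))
                out_p = ComparisonResult(
                    feature=feature, test="mann-whitney", statistic=float(U), df=None,
                    p_value=float(p), alpha=adj, significant=p < adj,
                    effect_size=R, effect_class=effect_size_class(R),
                    detail={"day": day, "pair": (names[i], names[j])},
                )
                res.followups.append(out_p)
        out.append(res)
    return out


def within_group_across_days(
    table: pd.DataFrame,
    feature: str,
    subject_key: str = "subject_id",
    day_col: str = "day",
    alpha: float = 0.05,
) -> ComparisonResult:
    """Friedman test of a feature across days, with sign-test follow-ups.

    Expects one row per subject-day. Subjects with a missing or undefined
    value on any day are dropped (complete-block requirement) and counted.
    Pairwise day comparisons use the exact sign test at Ryan-adjusted levels
    (span m = rank distance between the two days + 1).
    """
    wide = table.pivot_table(index=subject_key, columns=day_col, values=feature,
                             aggfunc="mean")
    n_before = len(wide)
    wide = wide.dropna()
    days = list(wide.columns)
    res = ComparisonResult(
        feature=feature, test="friedman", statistic=np.nan, df=None,
        p_value=np.nan, alpha=alpha, significant=False,
        detail={"n_subjects": len(wide), "n_dropped": n_before - len(wide),
                "days": days},
    )
    if len(days) < 2:
        res.skipped = "fewer than 2 days"
        return res
    if len(wide) < 3:
        res.skipped = "fewer than 3 complete subjects"
        return res
    cols = [wide[d].to_numpy(dtype=float) for d in days]
    if all(np.array_equal(cols[0], c) for c in cols[1:]):
        res.statistic, res.p_value = 0.0, 1.0
    else:
        stat, p = sps.friedmanchisquare(*cols)
        res.statistic, res.p_value = float(stat), float(p)
    res.df = float(len(days) - 1)
    res.significant = res.p_value < alpha
    if res.significant:
        k = len(days)
        # order days by mean rank for the step-down span
        mean_rank = wide.rank(axis=1).mean(axis=0)
        order = {d: r for r, d in enumerate(mean_rank.sort_values().index)}
        for (i, j) in combinations(range(k), 2):
            di, dj = days[i], days[j]
            span = abs(order[di] - order[dj]) + 1
            adj = ryan_adjusted_alpha(alpha, k, max(span, 2))
            stat, p, n_inf = _sign_test(wide[di].to_numpy(), wide[dj].to_numpy())
            R = _sign_effect_size(stat, n_inf)
            res.followups.append(ComparisonResult(
                feature=feature, test="sign", statistic=stat, df=None,
                p_value=p, alpha=adj, significant=p < adj,
                effect_size=R, effect_class=effect_size_class(R) if R is not None else None,
                detail={"pair": (di, dj), "n_informative": n_inf},
            ))
    return res


def _sign_effect_size(n_pos: float, n: int) -> float | None:
    if n == 0:
        return None
    z = (2 * n_pos - n) / np.sqrt(n)
    return float(min(abs(z) / np.sqrt(n), 1.0))


def results_table(results) -> pd.DataFrame:
    """Flatten ComparisonResults (and their follow-ups) into a DataFrame."""
    rows = []
    def _add(r: ComparisonResult, parent: str | None = None):
        rows.append({
            "feature": r.feature, "test": r.test, "statistic": r.statistic,
            "df": r.df, "p_value": r.p_value, "alpha": r.alpha,
            "significant": r.significant, "effect_size": r.effect_size,
            "effect_class": r.effect_class, "skipped": r.skipped,
            "parent": parent, **{f"detail_{k}": str(v) for k, v in r.detail.items()},
        })
        for f in r.followups:
            _add(f, parent=r.test)
    if isinstance(results, ComparisonResult):
        results = [results]
    for r in results:
        _add(r)
    return pd.DataFrame(rows)
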