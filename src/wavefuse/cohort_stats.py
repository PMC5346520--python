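"""Group-comparison statistics for cohort description tables.

One-way ANOVA (computable either from raw per-group vectors or directly
from printed n/mean/SD summaries — the two paths agree exactly when the
raw data realize the summaries), Pearson chi-square on category counts
(no continuity correction), and pairwise post hoc tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "anova_oneway",
    "anova_from_summaries",
    "chi_square",
    "posthoc_pairwise",
    "realize_summary",
    "table_one",
]


@dataclass(frozen=True)
class GroupSummary:
    """Printed descriptive statistics for one group on one variable."""

    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("group n must be >= 2")
        if self.sd <= 0:
            raise ValueError("sd must be positive")


def anova_from_summaries(summaries: Sequence[GroupSummary]) -> dict:
    """One-way ANOVA from per-group n/mean/SD.

    Between-group sum of squares from the group means about the grand
    mean; within-group sum of squares from the (n-1)-weighted variances.
    Identical to the raw-data F whenever the raw data exactly realize the
    summaries (SDs taken with ddof=1).
    """
    if len(summaries) < 2:
        raise ValueError("need at least 2 groups")
    ns = np.array([s.n for s in summaries], dtype=float)
    means = np.array([s.mean for s in summaries])
    sds = np.array([s.sd for s in summaries])
    N = ns.sum()
    k = len(ns)
    grand = float((ns * means).sum() / N)
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(((ns - 1) * sds**2).sum())
    df_between = k - 1
    df_within = int(N - k)
    F = (ss_between / df_between) / (ss_within / df_within)
    return {
        "F": F,
        "df_between": df_between,
        "df_within": df_within,
        "p": float(stats.f.sf(F, df_between, df_within)),
    }


def anova_oneway(groups) -> dict:
    """One-way ANOVA from raw vectors or from printed summaries.

    ``groups`` is either a sequence of 1D arrays (raw path) or a sequence
    of :class:`GroupSummary` (summary path).
    """
    groups = list(groups)
    if groups and isinstance(groups[0], GroupSummary):
        return anova_from_summaries(groups)
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("every group needs n >= 2")
    summaries = [
        GroupSummary(n=len(a), mean=float(a.mean()), sd=float(a.std(ddof=1)))
        for a in arrays
    ]
    return anova_from_summaries(summaries)


def chi_square(table) -> dict:
    """Pearson chi-square on a groups x categories count table.

    No Yates continuity correction; df = (rows-1)(cols-1).
    """
    table = np.asarray(table, dtype=float)
    if table.sum() <= 0:
        raise ValueError("count table must have a positive grand total")
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise ValueError("zero marginal row or column")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return {"chi2": float(chi2), "df": int(df), "p": float(p)}


def posthoc_pairwise(
    groups: Mapping[str, Sequence[float]], method: str = "tukey"
) -> pd.DataFrame:
    """Pairwise post hoc comparisons following a one-way ANOVA.

    ``method="tukey"`` (default) uses Tukey's HSD on the pooled variance;
    ``method="games-howell"`` drops the equal-variance assumption (Welch
    degrees of freedom with a studentized-range reference).
    """
    names = list(groups)
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    rows = []
    if method == "tukey":
        res = stats.tukey_hsd(*[arrays[k] for k in names])
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                rows.append({
                    "group_a": names[i],
                    "group_b": names[j],
                    "mean_diff": float(arrays[names[i]].mean() - arrays[names[j]].mean()),
                    "p": float(res.pvalue[i, j]),
                })
    elif method == "games-howell":
        k = len(names)
        for i in range(k):
            for j in range(i + 1, k):
                a, b = arrays[names[i]], arrays[names[j]]
                na, nb = len(a), len(b)
                va, vb = a.var(ddof=1), b.var(ddof=1)
                se2 = va / na + vb / nb
                t = (a.mean() - b.mean()) / np.sqrt(se2)
                df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
                p = float(stats.studentized_range.sf(np.abs(t) * np.sqrt(2), k, df))
                rows.append({
                    "group_a": names[i],
                    "group_b": names[j],
                    "mean_diff": float(a.mean() - b.mean()),
                    "p": p,
                })
    else:
        raise ValueError(f"unknown method {method!r}")
    return pd.DataFrame(rows)


def realize_summary(n: int, mean: float, sd: float) -> np.ndarray:
    """A deterministic raw vector whose sample mean/SD (ddof=1) are exact.

    Useful for checking that the summary and raw ANOVA paths agree, and for
    constructing post hoc inputs from printed descriptives.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    base = np.linspace(-1.0, 1.0, n)
    base = (base - base.mean()) / base.std(ddof=1)
    return mean + sd * base


def table_one(subjects, cortisol_features=None) -> pd.DataFrame:
    """Descriptive group-comparison table from subject records.

    Chi-square rows for the categorical demographics, ANOVA rows for age,
    the four questionnaire scales and (when provided) the cortisol release
    feature.  Missing categorical entries (None) are excluded per-variable.
    """
    groups = ("HC", "GAD", "MD")
    by_group = {g: [s for s in subjects if s.group == g] for g in groups}
    rows = []

    def cat_row(label, attr, positive):
        counts = []
        for g in groups:
            vals = [getattr(s, attr) for s in by_group[g] if getattr(s, attr) is not None]
            counts.append([sum(v == positive for v in vals),
                           sum(v != positive for v in vals)])
        res = chi_square(counts)
        rows.append({
            "variable": label,
            "HC": counts[0][0], "GAD": counts[1][0], "MD": counts[2][0],
            "statistic": res["chi2"], "df": res["df"], "p": res["p"],
            "test": "chi2",
        })

    def num_row(label, values_by_group):
        res = anova_oneway([values_by_group[g] for g in groups])
        means = {g: float(np.mean(values_by_group[g])) for g in groups}
        rows.append({
            "variable": label,
            "HC": means["HC"], "GAD": means["GAD"], "MD": means["MD"],
            "statistic": res["F"], "df": res["df_between"], "p": res["p"],
            "test": "anova",
        })

    cat_row("female_sex", "sex", "female")
    cat_row("right_handed", "handedness", "right")
    cat_row("secondary_school", "education", "secondary")
    cat_row("nonsmoker", "smoker", "no")
    num_row("age", {g: [s.age for s in by_group[g]] for g in groups})
    for scale in ("pswq", "bdi", "ius12", "stait"):
        num_row(scale, {g: [getattr(s, scale) for s in by_group[g]] for g in groups})
    if cortisol_features is not None:
        auc = {f.subject_id: f.log_auc for f in cortisol_features}
        vals = {
            g: [auc[s.subject_id] for s in by_group[g] if s.subject_id in auc]
            for g in groups
        }
        num_row("log_auc", vals)
    return pd.DataFrame(rows)
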