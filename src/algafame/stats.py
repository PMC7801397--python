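"""Treatment-vs-control significance testing and report assembly.

One-way ANOVA plus pairwise post-hoc comparison between culture treatments,
with both Tukey's HSD (studentized-range) and Fisher's LSD (pooled-t,
uncorrected) available — reports always label which method produced them.
Fisher's LSD is the less conservative test for k > 2 groups; for exactly
two groups both reduce to the pooled two-sample comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _scistats

__all__ = [
    "anova_oneway",
    "PairwiseDecision",
    "posthoc_pairwise",
    "ComparisonResult",
    "compare_treatments",
    "build_report",
    "render_report_text",
]

POSTHOC_METHODS = ("tukey_hsd", "fisher_lsd")


def _check_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    if len(groups) < 2:
        raise ValueError(f"need at least 2 groups, got {len(groups)}")
    arrays = []
    for i, g in enumerate(groups):
        arr = np.asarray(g, dtype=float)
        if arr.size < 2:
            raise ValueError(f"group {i} has fewer than 2 values ({arr.size})")
        arrays.append(arr)
    if all(np.ptp(a) == 0 for a in arrays):
        raise ValueError("zero within-group variance in every group; F undefined")
    return arrays


def anova_oneway(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p-value."""
    arrays = _check_groups(groups)
    res = _scistats.f_oneway(*arrays)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class PairwiseDecision:
    group_i: int
    group_j: int
    mean_diff: float  # mean_i - mean_j
    p_value: float
    significant: bool


def _pooled_within(arrays: list[np.ndarray]) -> tuple[float, int]:
    n_total = sum(a.size for a in arrays)
    k = len(arrays)
    ssw = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays)
    df = n_total - k
    return ssw / df, df


def posthoc_pairwise(
    groups: Sequence[Sequence[float]],
    method: str = "fisher_lsd",
    alpha: float = 0.05,
) -> list[PairwiseDecision]:
    """All pairwise group comparisons by Tukey's HSD or Fisher's LSD.

    Tukey uses the studentized-range distribution (scipy's implementation);
    Fisher's LSD is the pooled-variance t test on each pair with the ANOVA
    within-group mean square and N - k degrees of freedom, uncorrected.
    """
    if method not in POSTHOC_METHODS:
        raise ValueError(f"unknown post-hoc method {method!r}; choose from {POSTHOC_METHODS}")
    arrays = _check_groups(groups)
    k = len(arrays)
    decisions: list[PairwiseDecision] = []
    if method == "tukey_hsd":
        res = _scistats.tukey_hsd(*arrays)
        for i in range(k):
            for j in range(i + 1, k):
                p = float(res.pvalue[i, j])
                decisions.append(
                    PairwiseDecision(
                        i, j, float(arrays[i].mean() - arrays[j].mean()), p, p < alpha
                    )
                )
        return decisions
    msw, df = _pooled_within(arrays)
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(arrays[i].mean() - arrays[j].mean())
            se = math.sqrt(msw * (1.0 / arrays[i].size + 1.0 / arrays[j].size))
            if se == 0.0:
                p = 1.0 if diff == 0 else 0.0
            else:
                t = diff / se
                p = 2.0 * float(_scistats.t.sf(abs(t), df))
            decisions.append(PairwiseDecision(i, j, diff, p, p < alpha))
    return decisions


@dataclass
class ComparisonResult:
    """One metric-by-day treatment comparison (ANOVA + post-hoc)."""

    metric: str
    day: int
    f_statistic: float
    p_value: float
    posthoc: list[PairwiseDecision] = field(default_factory=list)
    method: str = "fisher_lsd"
    groups: tuple[str, ...] = ()


def compare_treatments(
    metrics: pd.DataFrame,
    method: str = "fisher_lsd",
    alpha: float = 0.05,
) -> list[ComparisonResult]:
    """NS-vs-NR (or any set of treatments) comparison within each day.

    ``metrics`` is tidy with columns treatment, day, replicate, metric,
    value. Days where any treatment group is degenerate are skipped.
    """
    results = []
    for (metric, day), sub in metrics.groupby(["metric", "day"], sort=True):
        treatments = sorted(sub["treatment"].unique())
        groups = [
            sub.loc[sub["treatment"] == t, "value"].to_numpy() for t in treatments
        ]
        try:
            f, p = anova_oneway(groups)
            decisions = posthoc_pairwise(groups, method=method, alpha=alpha)
        except ValueError:
            continue
        results.append(
            ComparisonResult(
                metric=str(metric),
                day=int(day),
                f_statistic=f,
                p_value=p,
                posthoc=decisions,
                method=method,
                groups=tuple(treatments),
            )
        )
    return results


def _stars_for(comparison: ComparisonResult) -> dict[str, bool]:
    """Which treatment gets the star: the larger mean of a significant pair."""
    stars: dict[str, bool] = {t: False for t in comparison.groups}
    for dec in comparison.posthoc:
        if dec.significant:
            winner = (
                comparison.groups[dec.group_i]
                if dec.mean_diff > 0
                else comparison.groups[dec.group_j]
            )
            stars[winner] = True
    return stars


def build_report(
    metrics: pd.DataFrame,
    comparisons: Iterable[ComparisonResult] = (),
    ndigits: int = 1,
) -> dict[str, pd.DataFrame]:
    """Wide mean +/- SD tables per metric with significance stars.

    Returns one DataFrame per metric (rows: day; columns: treatments) whose
    cells are fixed-precision "mean ± sd" strings, starred on the larger
    mean of a significant pair. Comparisons referring to (metric, day) keys
    absent from ``metrics`` are an error listing the orphans.
    """
    required = {"treatment", "day", "replicate", "metric", "value"}
    missing = required - set(metrics.columns)
    if missing:
        raise ValueError(f"metrics frame missing columns: {sorted(missing)}")
    available = set(zip(metrics["metric"], metrics["day"]))
    comparisons = list(comparisons)
    orphans = [
        (c.metric, c.day) for c in comparisons if (c.metric, c.day) not in available
    ]
    if orphans:
        raise ValueError(f"comparisons without matching metric rows: {orphans}")
    by_key = {(c.metric, c.day): c for c in comparisons}

    tables: dict[str, pd.DataFrame] = {}
    for metric, sub in metrics.groupby("metric", sort=True):
        days = sorted(sub["day"].unique())
        treatments = sorted(sub["treatment"].unique())
        table = pd.DataFrame(index=days, columns=treatments, dtype=object)
        table.index.name = "day"
        for day in days:
            comp = by_key.get((metric, day))
            stars = _stars_for(comp) if comp is not None else {}
            for trt in treatments:
                vals = sub.loc[
                    (sub["day"] == day) & (sub["treatment"] == trt), "value"
                ].to_numpy(dtype=float)
                if vals.size == 0:
                    table.at[day, trt] = ""
                    continue
                mean = vals.mean()
                sd = vals.std(ddof=1) if vals.size > 1 else 0.0
                star = "*" if stars.get(trt, False) else ""
                table.at[day, trt] = f"{mean:.{ndigits}f} ± {sd:.{ndigits}f}{star}"
        tables[str(metric)] = table
    return tables


def render_report_text(tables: Mapping[str, pd.DataFrame]) -> str:
    """Human-readable rendering of the report tables."""
    blocks = []
    for metric in sorted(tables):
        blocks.append(f"== {metric} ==")
        blocks.append(tables[metric].to_string())
        blocks.append("")
    return "\n".join(blocks)
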