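"""Cross-cohort validation of subtype survival by normalized medians.

Subtypes that are statistically indistinguishable in a cohort can be
merged; each cohort's subtype medians are then normalized to a baseline
median and compared across cohorts by ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .survival import cox_ph, km_median


@dataclass
class MergeRecord:
    group_a: str
    group_b: str
    p_value: float
    merged: bool
    merged_label: str | None


@dataclass
class NormalizedOS:
    """Per-subtype raw and baseline-normalized median OS."""

    medians: dict[str, float]  # raw median months per subtype
    normalized: dict[str, float]  # ratio to baseline median
    baseline_groups: list[str]
    baseline_median: float


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r: float
    n: int
    labels: list[str] = field(default_factory=list)


def merge_indistinguishable(
    data: pd.DataFrame,
    candidate_pair: tuple[str, str],
    alpha: float = 0.05,
    group_col: str = "subtype",
    duration_col: str = "os_months",
    event_col: str = "event",
    ties: str = "efron",
) -> tuple[pd.DataFrame, MergeRecord]:
    """Merge a pair of groups when their pairwise Cox p exceeds alpha.

    Returns the (possibly relabeled) data and the test record.  With
    alpha = 0 no merge ever fires.
    """
    ga, gb = candidate_pair
    df = data.dropna(subset=[duration_col, event_col]).copy()
    if alpha <= 0:  # alpha = 0 disables merging entirely
        for g in (ga, gb):
            if (df[group_col] == g).sum() == 0:
                raise ValueError(f"candidate group {g!r} is empty")
        return df, MergeRecord(ga, gb, float("nan"), False, None)
    for g in (ga, gb):
        if (df[group_col] == g).sum() == 0:
            raise ValueError(f"candidate group {g!r} is empty")
    sub = df[df[group_col].isin([ga, gb])].copy()
    sub["_ind"] = (sub[group_col] == gb).astype(float)
    res = cox_ph(sub, duration_col, event_col, ["_ind"], ties=ties)
    p = float(res.p[0])
    if p > alpha:
        merged_label = f"{ga}/{gb}"
        df.loc[df[group_col].isin([ga, gb]), group_col] = merged_label
        return df, MergeRecord(ga, gb, p, True, merged_label)
    return df, MergeRecord(ga, gb, p, False, None)


def normalize_os(
    data: pd.DataFrame,
    baseline_groups: list[str],
    group_col: str = "subtype",
    duration_col: str = "os_months",
    event_col: str = "event",
) -> NormalizedOS:
    """Normalize each group's KM median to the pooled-baseline KM median.

    The baseline median is computed on the pooled records of the baseline
    groups (not the mean of their medians), so the baseline set's own
    normalized value is exactly 1 when it is a single group.
    """
    df = data.dropna(subset=[duration_col, event_col])
    groups = sorted(df[group_col].unique())
    medians: dict[str, float] = {}
    for g in groups:
        sub = df[df[group_col] == g]
        m = km_median(sub[duration_col].to_numpy(), sub[event_col].to_numpy())
        if not np.isfinite(m):
            raise ValueError(f"median OS undefined for group {g!r}")
        medians[g] = m
    missing = [g for g in baseline_groups if g not in groups]
    if missing:
        raise ValueError(f"baseline group(s) not present: {missing}")
    pooled = df[df[group_col].isin(baseline_groups)]
    base = km_median(pooled[duration_col].to_numpy(), pooled[event_col].to_numpy())
    if not np.isfinite(base) or base <= 0:
        raise ValueError("baseline median undefined or non-positive")
    normalized = {g: m / base for g, m in medians.items()}
    return NormalizedOS(medians, normalized, list(baseline_groups), base)


def cross_cohort_regression(
    norm_a: NormalizedOS, norm_b: NormalizedOS, through_origin: bool = False
) -> RegressionResult:
    """OLS of cohort-b normalized medians on cohort-a's over shared labels."""
    labels = sorted(set(norm_a.normalized) & set(norm_b.normalized))
    if len(labels) < 2:
        raise ValueError(f"need ≥2 shared subtype labels; got {labels}")
    xs = np.array([norm_a.normalized[g] for g in labels])
    ys = np.array([norm_b.normalized[g] for g in labels])
    r = float(stats.pearsonr(xs, ys).statistic) if np.ptp(xs) > 0 and np.ptp(ys) > 0 else 1.0
    if through_origin:
        slope = float(np.sum(xs * ys) / np.sum(xs * xs))
        intercept = 0.0
    else:
        slope, intercept = np.polyfit(xs, ys, 1)
    return RegressionResult(float(slope), float(intercept), r, len(labels), labels)


def validate_cohorts(
    cohort_a: pd.DataFrame,
    cohort_b: pd.DataFrame,
    baseline_groups: list[str],
    merge_candidate: tuple[str, str] | None = ("W1", "W2"),
    alpha: float = 0.05,
    group_col: str = "subtype",
    through_origin: bool = False,
) -> dict:
    """Full validation flow: optional merge in each cohort, normalization,
    and the cross-cohort regression.

    When the merge fires the merged label replaces its members in the
    baseline set of that cohort.
    """
    records = {}
    norms = {}
    for name, cohort in (("a", cohort_a), ("b", cohort_b)):
        df = cohort
        baseline = list(baseline_groups)
        if merge_candidate is not None:
            df, rec = merge_indistinguishable(df, merge_candidate, alpha, group_col=group_col)
            records[name] = rec
            if rec.merged:
                members = {rec.group_a, rec.group_b}
                if members & set(baseline):
                    baseline = [g for g in baseline if g not in members] + [rec.merged_label]
        norms[name] = normalize_os(df, baseline, group_col=group_col)
    regression = cross_cohort_regression(norms["a"], norms["b"], through_origin=through_origin)
    return {
        "merge_records": records,
        "normalized_a": norms["a"],
        "normalized_b": norms["b"],
        "regression": regression,
    }
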