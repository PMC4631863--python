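"""Group summaries, one-way ANOVA and Fisher LSD post-hoc comparisons.

Sums of squares are computed from first principles; only the F and t
distribution tails come from scipy (regularized incomplete beta under the
hood). Classical usage gates the LSD table on a significant omnibus F —
:func:`lsd_posthoc` exposes that as ``gate_on_omnibus`` and the CLI applies
it; the ungated decisions are exactly unadjusted pooled-variance t-tests
using MS_error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from collections.abc import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GroupData",
    "GroupSummary",
    "PairwiseComparison",
    "AnovaResult",
    "group_summary",
    "one_way_anova",
    "lsd_posthoc",
]


@dataclass(frozen=True)
class GroupData:
    group_label: str
    values: tuple[float, ...]
    timepoint: str | None = None

    def __init__(self, group_label: str, values: Iterable[float], timepoint: str | None = None):
        if not group_label:
            raise ValueError("group_label must be non-empty")
        vals = tuple(float(v) for v in values)
        if any(not math.isfinite(v) for v in vals):
            raise ValueError(f"group {group_label!r} contains non-finite values")
        object.__setattr__(self, "group_label", group_label)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "timepoint", timepoint)

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class GroupSummary:
    group_label: str
    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class PairwiseComparison:
    pair: tuple[str, str]
    mean_difference: float
    lsd_threshold: float
    significant: bool


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    ms_error: float
    group_labels: tuple[str, ...]
    group_means: tuple[float, ...]
    group_ns: tuple[int, ...]
    degenerate: bool = False
    pairwise: tuple[PairwiseComparison, ...] = ()


def group_summary(group: GroupData) -> GroupSummary:
    """Mean, sample SD (n−1 denominator; 0 for n=1) and n of one group."""
    if group.n < 1:
        raise ValueError(f"group {group.group_label!r} is empty")
    values = np.asarray(group.values)
    sd = float(values.std(ddof=1)) if group.n > 1 else 0.0
    return GroupSummary(group_label=group.group_label,
                        mean=float(values.mean()), sd=sd, n=group.n)


def one_way_anova(groups: Sequence[GroupData]) -> AnovaResult:
    """Standard one-way fixed-effects ANOVA.

    F = MS_between / MS_within; the p-value is the upper tail of
    F(df_between, df_within). All groups constant and identical is reported
    as F = 0, p = 1 with ``degenerate`` set rather than as 0/0.
    """
    groups = list(groups)
    if len(groups) < 2:
        raise ValueError("one_way_anova requires at least 2 groups")
    for g in groups:
        if g.n < 2:
            raise ValueError(f"group {g.group_label!r} has n={g.n}; need n >= 2")
    labels = tuple(g.group_label for g in groups)
    if len(set(labels)) != len(labels):
        raise ValueError("group labels must be unique")

    arrays = [np.asarray(g.values) for g in groups]
    ns = np.array([a.size for a in arrays])
    means = np.array([a.mean() for a in arrays])
    grand = float(np.concatenate(arrays).mean())
    n_total = int(ns.sum())
    k = len(groups)

    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(np.sum((a - m) ** 2) for a, m in zip(arrays, means)))
    df_between, df_within = k - 1, n_total - k
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within

    degenerate = False
    if ms_within == 0.0:
        if ss_between == 0.0:
            f, p, degenerate = 0.0, 1.0, True
        else:
            f, p, degenerate = math.inf, 0.0, True
    else:
        f = ms_between / ms_within
        p = float(stats.f.sf(f, df_between, df_within))

    return AnovaResult(
        f_statistic=f,
        df_between=df_between,
        df_within=df_within,
        p_value=p,
        ms_error=ms_within,
        group_labels=labels,
        group_means=tuple(float(m) for m in means),
        group_ns=tuple(int(n) for n in ns),
        degenerate=degenerate,
    )


def lsd_posthoc(
    anova: AnovaResult,
    groups: Sequence[GroupData],
    alpha: float = 0.01,
    gate_on_omnibus: bool = False,
) -> tuple[PairwiseComparison, ...]:
    """Fisher least-significant-difference comparisons for every group pair.

    LSD(i,j) = t_{1−α/2, df_within} · √(MS_error · (1/n_i + 1/n_j));
    a pair is significant iff |mean_i − mean_j| > LSD. With
    ``gate_on_omnibus`` all pairs are declared non-significant when the
    omnibus p exceeds ``alpha`` (the textbook protected-LSD procedure).
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha!r}")
    labels = tuple(g.group_label for g in groups)
    if labels != anova.group_labels:
        raise ValueError("groups do not match the ANOVA result (labels/order differ)")
    if anova.ms_error == 0.0:
        raise ValueError("LSD undefined with zero within-group variance")
    omnibus_ok = anova.p_value <= alpha
    t_crit = float(stats.t.ppf(1.0 - alpha / 2.0, anova.df_within))
    out = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            diff = anova.group_means[i] - anova.group_means[j]
            lsd = t_crit * math.sqrt(
                anova.ms_error * (1.0 / anova.group_ns[i] + 1.0 / anova.group_ns[j])
            )
            significant = abs(diff) > lsd
            if gate_on_omnibus and not omnibus_ok:
                significant = False
            out.append(PairwiseComparison(
                pair=(labels[i], labels[j]),
                mean_difference=diff,
                lsd_threshold=lsd,
                significant=significant,
            ))
    return tuple(out)
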