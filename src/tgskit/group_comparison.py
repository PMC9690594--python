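"""Group-level inference: t-tests, one-way ANOVA with a linear-trend contrast,
TGS-performance regression, and genotype-group performance contrasts."""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import EmptyGroupError
from .genotype_data import Cohort, Locus
from .tgs import ScoreTable, tgs_cohort


@dataclass(frozen=True)
class GroupComparison:
    """A statistical comparison between ordered groups.

    ``statistic_name`` is one of ``t``, ``F``, ``trend-t`` or ``slope-t``;
    ``effect`` carries the statistic-specific effect summary (mean
    difference, contrast estimate, or regression slope/R^2).
    """

    groups: tuple[str, ...]
    ns: tuple[int, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]
    statistic_name: str
    statistic: float
    df: float | tuple[float, float]
    p: float
    effect: Mapping[str, float]
    note: str = ""

    def summary(self) -> str:
        parts = [
            f"{g}: {m:.2f} +/- {s:.2f} (n={n})"
            for g, n, m, s in zip(self.groups, self.ns, self.means, self.sds)
        ]
        return (
            f"{self.statistic_name} = {self.statistic:.3f}, df = {self.df}, "
            f"p = {self.p:.3f} | " + "; ".join(parts)
        )


def _describe(values: Sequence[float]) -> tuple[int, float, float]:
    arr = np.asarray(values, dtype=float)
    return arr.size, float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0


def two_group_t(
    values_a: Sequence[float],
    values_b: Sequence[float],
    labels: tuple[str, str] = ("a", "b"),
    equal_var: bool = True,
) -> GroupComparison:
    """Two-sided unpaired t-test (pooled-variance by default, Welch optional)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise EmptyGroupError("each group needs at least two observations")
    na, ma, sa = _describe(a)
    nb, mb, sb = _describe(b)
    if sa == 0.0 and sb == 0.0:
        # zero variance everywhere: identical means are uninformative, not infinite
        if ma == mb:
            return GroupComparison(
                labels, (na, nb), (ma, mb), (sa, sb), "t", 0.0, na + nb - 2, 1.0,
                {"mean_difference": 0.0}, note="degenerate: zero variance, equal means",
            )
        return GroupComparison(
            labels, (na, nb), (ma, mb), (sa, sb), "t", math.inf, na + nb - 2, 0.0,
            {"mean_difference": ma - mb}, note="degenerate: zero variance, unequal means",
        )
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    if equal_var:
        df: float = na + nb - 2
    else:
        va, vb = sa**2 / na, sb**2 / nb
        df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
    return GroupComparison(
        labels, (na, nb), (ma, mb), (sa, sb), "t", float(t), df, float(p),
        {"mean_difference": ma - mb},
    )


def anova(values_by_group: Mapping[str, Sequence[float]]) -> GroupComparison:
    """One-way ANOVA omnibus F-test over two or more groups."""
    groups = tuple(values_by_group)
    if len(groups) < 2:
        raise EmptyGroupError("ANOVA needs at least two groups")
    arrays = [np.asarray(values_by_group[g], dtype=float) for g in groups]
    if any(arr.size < 2 for arr in arrays):
        raise EmptyGroupError("every group needs at least two observations")
    stats_ = [_describe(arr) for arr in arrays]
    k = len(arrays)
    n_total = sum(s[0] for s in stats_)
    note = ""
    if all(s[2] == 0.0 for s in stats_):
        # no within-group variance: equal means are uninformative, not 0/0
        means = {s[1] for s in stats_}
        f, p = (0.0, 1.0) if len(means) == 1 else (math.inf, 0.0)
        note = "degenerate: zero within-group variance"
    else:
        f, p = stats.f_oneway(*arrays)
    return GroupComparison(
        groups,
        tuple(s[0] for s in stats_),
        tuple(s[1] for s in stats_),
        tuple(s[2] for s in stats_),
        "F", float(f), (k - 1, n_total - k), float(p),
        {"grand_mean": float(np.concatenate(arrays).mean())},
        note=note,
    )


def linear_trend(values_by_group: Mapping[str, Sequence[float]]) -> GroupComparison:
    """Linear-trend contrast across ordered groups.

    Uses equally spaced, centered contrast coefficients on the group means
    (for three groups: -1, 0, +1) with the pooled within-group mean square
    as the error term; t is referred to a Student distribution on N - k df.
    Group order in the mapping defines the trend direction.
    """
    groups = tuple(values_by_group)
    arrays = [np.asarray(values_by_group[g], dtype=float) for g in groups]
    k = len(arrays)
    if k < 2:
        raise EmptyGroupError("a trend needs at least two ordered groups")
    if any(arr.size < 2 for arr in arrays):
        raise EmptyGroupError("every group needs at least two observations")
    coefs = np.arange(k, dtype=float) - (k - 1) / 2.0
    ns = np.array([arr.size for arr in arrays])
    means = np.array([arr.mean() for arr in arrays])
    sds = np.array([arr.std(ddof=1) for arr in arrays])
    n_total = int(ns.sum())
    mse = float(((ns - 1) * sds**2).sum() / (n_total - k))
    estimate = float(coefs @ means)
    if mse == 0.0:
        t = 0.0 if estimate == 0.0 else math.copysign(math.inf, estimate)
        p = 1.0 if estimate == 0.0 else 0.0
        note = "degenerate: zero within-group variance"
    else:
        se = math.sqrt(mse * float((coefs**2 / ns).sum()))
        t = estimate / se
        p = float(2 * stats.t.sf(abs(t), n_total - k))
        note = ""
    return GroupComparison(
        groups, tuple(int(n) for n in ns), tuple(map(float, means)),
        tuple(map(float, sds)), "trend-t", float(t), n_total - k, p,
        {"contrast_estimate": estimate}, note=note,
    )


def anova_with_trend(
    values_by_group: Mapping[str, Sequence[float]],
) -> tuple[GroupComparison, GroupComparison]:
    """Omnibus one-way ANOVA plus the linear-trend contrast, as a pair."""
    return anova(values_by_group), linear_trend(values_by_group)


def regress_performance_on_tgs(
    cohort: Cohort, score_table: ScoreTable, groups: Sequence[str] | None = None
) -> GroupComparison:
    """Ordinary least squares of performance (Wilks points) on individual TGS.

    Individuals lacking a performance value or any model genotype are
    excluded.  Reports slope, intercept, R^2 and the two-sided slope test.
    """
    sub = cohort if groups is None else cohort.subset(groups)
    scores, _ = tgs_cohort(score_table, sub)
    wilks = pd.Series(np.asarray(sub.data["wilks"], dtype=float), index=sub.data["id"])
    wilks = wilks.reindex(scores.index)
    keep = wilks.notna()
    x = scores[keep].to_numpy()
    y = wilks[keep].to_numpy()
    if x.size < 3:
        raise EmptyGroupError("regression needs at least three complete records")
    if np.ptp(x) == 0.0:
        raise EmptyGroupError("TGS has zero variance; slope is undefined")
    fit = stats.linregress(x, y)
    if fit.stderr == 0.0:  # perfect fit: slope test degenerates
        slope_t = math.copysign(math.inf, fit.slope) if fit.slope else 0.0
    else:
        slope_t = float(fit.slope / fit.stderr)
    return GroupComparison(
        ("cohort",), (x.size,), (float(y.mean()),), (float(y.std(ddof=1)),),
        "slope-t", slope_t, x.size - 2, float(fit.pvalue),
        {
            "slope": float(fit.slope),
            "intercept": float(fit.intercept),
            "r_squared": float(fit.rvalue**2),
        },
    )


def genotype_performance_compare(
    cohort: Cohort,
    locus: Locus,
    grouping: str,
    groups: Sequence[str] | None = None,
    equal_var: bool = True,
) -> GroupComparison:
    """Compare performance between genotype-defined groups at one locus.

    ``grouping`` is ``dominant``/``recessive`` (two collapsed categories,
    following the locus's published orientation) or ``genotypic`` (all
    three).  Two categories are compared by unpaired t-test, three by
    one-way ANOVA; per-category mean +/- sd of Wilks points is reported.
    """
    sub = cohort if groups is None else cohort.subset(groups)
    frame = sub.data[[locus.rs_id, "wilks"]].dropna()
    hi, het, lo = locus.genotype_labels
    if grouping == "genotypic":
        split = [(hi,), (het,), (lo,)]
    elif grouping in ("dominant", "recessive"):
        singleton = locus.dominant_singleton
        if grouping == "recessive":
            singleton = "lo" if singleton == "hi" else "hi"
        split = [(hi,), (het, lo)] if singleton == "hi" else [(hi, het), (lo,)]
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    values_by_group = {}
    for labels in split:
        name = "+".join(labels)
        values = frame.loc[frame[locus.rs_id].isin(labels), "wilks"].to_numpy(dtype=float)
        if values.size < 2:
            raise EmptyGroupError(
                f"{locus.rs_id} {grouping}: category {name} has n={values.size} < 2"
            )
        values_by_group[name] = values
    if len(values_by_group) == 2:
        (la, va), (lb, vb) = values_by_group.items()
        return two_group_t(va, vb, labels=(la, lb), equal_var=equal_var)
    return anova(values_by_group)
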