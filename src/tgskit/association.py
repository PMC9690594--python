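"""Hardy-Weinberg testing and case-control association under collapsed genetic models.

A biallelic locus with genotype counts ``(n_hi, n_het, n_lo)`` can be
compared between cases and controls in four ways:

* ``dominant`` - 2x2, one homozygote against the other two genotypes (the
  homozygote that stands alone is locus-specific, see
  :attr:`~tgskit.genotype_data.Locus.dominant_singleton`);
* ``recessive`` - 2x2, the complementary split;
* ``allele`` - 2x2 on allele counts, ``(2*n_hi + n_het, n_het + 2*n_lo)``;
* ``genotypic`` - 2x3 on the raw three-genotype split.

All tests are plain Pearson chi-square without continuity correction, which
is the convention the reference results were produced under; Fisher's exact
test is available as an option for 2x2 tables.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._errors import DegenerateTableError
from .genotype_data import CountTable, GenotypeCounts, Locus

MODELS = ("dominant", "recessive", "allele", "genotypic")
#: The models used in the published case-control screen.
SCREEN_MODELS = ("dominant", "recessive", "allele")

ALPHA = 0.05


def collapse_counts(counts: GenotypeCounts, model: str) -> tuple[int, ...]:
    """Collapse three genotype counts into the category vector of a genetic model."""
    a, b, c = counts.as_tuple()
    if model == "genotypic":
        return (a, b, c)
    if model == "allele":
        return (2 * a + b, b + 2 * c)
    singleton = counts.locus.dominant_singleton
    if model == "recessive":
        singleton = "lo" if singleton == "hi" else "hi"
    elif model != "dominant":
        raise ValueError(f"unknown genetic model {model!r}")
    return (a, b + c) if singleton == "hi" else (a + b, c)


def model_label(locus: Locus, model: str) -> str:
    """Human-readable category split, e.g. ``DD/ID+II`` or ``D/I``."""
    hi, het, lo = locus.genotype_labels
    if model == "genotypic":
        return f"{hi}/{het}/{lo}"
    if model == "allele":
        return f"{locus.allele_hi}/{locus.allele_lo}"
    singleton = locus.dominant_singleton
    if model == "recessive":
        singleton = "lo" if singleton == "hi" else "hi"
    if singleton == "hi":
        return f"{hi}/{het}+{lo}"
    return f"{hi}+{het}/{lo}"


@dataclass(frozen=True)
class Chi2Result:
    chi2: float
    df: int
    p: float


def chi_square_2xk(case: Sequence[int], control: Sequence[int]) -> Chi2Result:
    """Pearson chi-square comparing two category vectors (no continuity correction).

    Columns with a zero margin make the statistic undefined and raise
    :class:`DegenerateTableError` rather than being dropped silently.
    """
    table = np.asarray([case, control], dtype=float)
    if table.min() < 0:
        raise ValueError("negative cell counts")
    if table.shape[0] != 2 or table.shape[1] < 2:
        raise ValueError("expected a 2xk table with k >= 2")
    if (table.sum(axis=1) == 0).any():
        raise DegenerateTableError("a row of the table is all zero")
    if (table.sum(axis=0) == 0).any():
        raise DegenerateTableError("a category has zero total count across groups")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return Chi2Result(float(chi2), int(df), float(p))


def fisher_exact_2x2(case: Sequence[int], control: Sequence[int]) -> Chi2Result:
    """Fisher's exact test as an optional alternative for 2x2 tables (df reported as 1)."""
    table = np.asarray([case, control])
    if table.shape != (2, 2):
        raise ValueError("Fisher's exact test requires a 2x2 table")
    _, p = stats.fisher_exact(table)
    return Chi2Result(float("nan"), 1, float(p))


@dataclass(frozen=True)
class OddsRatioResult:
    value: float
    ci95: tuple[float, float]
    corrected: bool  # Haldane-Anscombe 0.5 added to every cell because of a zero


def odds_ratio(table: Sequence[Sequence[float]]) -> OddsRatioResult:
    """Odds ratio ad/bc with Wald 95% CI on the log scale.

    A zero cell triggers the Haldane-Anscombe correction (0.5 added to all
    four cells) and sets the ``corrected`` flag.
    """
    (a, b), (c, d) = table
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    value = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(value) - 1.96 * se)
    hi = math.exp(math.log(value) + 1.96 * se)
    return OddsRatioResult(value, (lo, hi), corrected)


@dataclass(frozen=True)
class HweResult:
    locus: Locus
    group: str
    chi2: float
    p: float
    in_hwe: bool
    monomorphic: bool = False


def hwe_test(counts: GenotypeCounts, alpha: float = ALPHA) -> HweResult:
    """Chi-square goodness-of-fit test against Hardy-Weinberg proportions.

    Expected counts are ``n*(p^2, 2pq, q^2)`` with the allele frequency
    estimated from the observed counts; df = 1 for a biallelic locus.  A
    monomorphic sample is in equilibrium by construction and is flagged.
    """
    n = counts.total
    if n == 0:
        raise ValueError("empty counts")
    p = counts.allele_frequency_hi()
    if p in (0.0, 1.0):
        return HweResult(counts.locus, counts.group, 0.0, 1.0, True, monomorphic=True)
    expected = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2])
    observed = np.array(counts.as_tuple(), dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    pval = float(stats.chi2.sf(chi2, df=1))
    return HweResult(counts.locus, counts.group, chi2, pval, pval >= alpha)


def hwe_screen(tables: Mapping[str, CountTable], alpha: float = ALPHA) -> list[HweResult]:
    """HWE test for every locus of every table, in table/panel order."""
    return [
        hwe_test(table[rs_id], alpha=alpha)
        for table in tables.values()
        for rs_id in table.loci
    ]


def bonferroni(p_values: Sequence[float], m: int | None = None) -> list[float]:
    """Bonferroni adjustment ``min(1, p*m)``; ``m`` defaults to the number of tests."""
    p_values = list(p_values)
    if m is None:
        m = len(p_values)
    if m <= 0:
        raise ValueError("number of tests m must be positive")
    if m < len(p_values):
        raise ValueError("m must be at least the number of p-values")
    for p in p_values:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p} outside [0, 1]")
    return [min(1.0, p * m) for p in p_values]


@dataclass(frozen=True)
class AssociationResult:
    """One locus x model x case-group comparison against the control group."""

    locus: Locus
    case_group: str
    model: str
    table: tuple[tuple[int, ...], tuple[int, ...]]
    chi2: float
    df: int
    p: float
    odds_ratio: float | None = None
    or_ci95: tuple[float, float] | None = None
    or_corrected: bool = False

    @property
    def label(self) -> str:
        return model_label(self.locus, self.model)

    def significant(self, alpha: float = ALPHA) -> bool:
        return self.p < alpha


def associate(
    case: GenotypeCounts,
    control: GenotypeCounts,
    model: str,
    method: str = "pearson",
) -> AssociationResult:
    case_vec = collapse_counts(case, model)
    ctrl_vec = collapse_counts(control, model)
    if method == "pearson":
        res = chi_square_2xk(case_vec, ctrl_vec)
    elif method == "fisher":
        res = fisher_exact_2x2(case_vec, ctrl_vec)
    else:
        raise ValueError(f"unknown method {method!r}")
    orr = or_ci = None
    corrected = False
    if len(case_vec) == 2:
        est = odds_ratio((case_vec, ctrl_vec))
        orr, or_ci, corrected = est.value, est.ci95, est.corrected
    return AssociationResult(
        case.locus, case.group, model, (tuple(case_vec), tuple(ctrl_vec)),
        res.chi2, res.df, res.p, orr, or_ci, corrected,
    )


def run_case_control_screen(
    case_tables: Mapping[str, CountTable],
    control_table: CountTable,
    models: Sequence[str] = SCREEN_MODELS,
    method: str = "pearson",
) -> list[AssociationResult]:
    """Full association grid: every case group x locus x genetic model vs controls."""
    results = []
    for table in case_tables.values():
        for rs_id in control_table.loci:
            for model in models:
                results.append(associate(table[rs_id], control_table[rs_id], model, method))
    return results


def screen_frame(results: Sequence[AssociationResult]) -> "object":
    """Tabulate association results as a pandas DataFrame (full precision)."""
    import pandas as pd

    rows = []
    for r in results:
        rows.append(
            {
                "gene": r.locus.gene,
                "rs_id": r.locus.rs_id,
                "case_group": r.case_group,
                "model": r.model,
                "split": r.label,
                "case_counts": "/".join(map(str, r.table[0])),
                "control_counts": "/".join(map(str, r.table[1])),
                "chi2": r.chi2,
                "df": r.df,
                "p": r.p,
                "odds_ratio": r.odds_ratio,
                "or_ci_low": r.or_ci95[0] if r.or_ci95 else None,
                "or_ci_high": r.or_ci95[1] if r.or_ci95 else None,
                "or_zero_cell_corrected": r.or_corrected,
            }
        )
    return pd.DataFrame(rows)
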