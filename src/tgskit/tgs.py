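"""Total genotype scores (TGS): score tables, the 0-100 score, and exact distributions.

A score table assigns each locus's genotypes the integer scores {0, 1, 2}:
2 for the "optimal" homozygote, 1 for the heterozygote, 0 for the other
homozygote.  For ``L`` loci the total genotype score of an individual is

    TGS = 100 / (2 L) * sum of per-locus scores,

so it always lies in [0, 100].  Two packaged models cover the weightlifter
study: the 12-locus literature-based power model (PWM) and the 6-locus
weightlifting-related model (WRM) derived from the study's own case-control
screen.  :func:`build_wrm` re-derives such a data-driven model from any
screen output.
"""

from __future__ import annotations

import json
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import (
    EmptyModelError,
    MissingGenotypeError,
    PanelMismatchError,
    UnresolvedDirectionError,
)
from .association import ALPHA, AssociationResult, chi_square_2xk
from .genotype_data import Cohort, CountTable, Locus


@dataclass(frozen=True)
class ScoreTable:
    """A named genotype->score map over a set of loci, with 0-100 scaling."""

    model_name: str
    entries: Mapping[str, Mapping[str, int]]  # rs_id -> {genotype label -> 0|1|2}

    def __post_init__(self) -> None:
        for rs_id, scores in self.entries.items():
            if sorted(scores.values()) != [0, 1, 2]:
                raise ValueError(
                    f"{self.model_name}/{rs_id}: genotype scores must be exactly {{0,1,2}}"
                )

    @property
    def loci(self) -> tuple[str, ...]:
        return tuple(self.entries)

    @property
    def n_loci(self) -> int:
        return len(self.entries)

    @property
    def scale(self) -> float:
        """Points per unit of raw score sum: 100 / (2 L)."""
        return 100.0 / (2 * self.n_loci)

    def score(self, rs_id: str, genotype: str) -> int:
        try:
            return self.entries[rs_id][genotype]
        except KeyError:
            if rs_id not in self.entries:
                raise PanelMismatchError(f"{self.model_name} has no locus {rs_id}") from None
            raise MissingGenotypeError(
                f"{self.model_name}/{rs_id}: unknown genotype {genotype!r}"
            ) from None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "model_name": self.model_name,
            "scale_denominator": 2 * self.n_loci,
            "entries": [
                {"rs_id": rs, "scores": dict(scores)} for rs, scores in self.entries.items()
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ScoreTable":
        payload = json.loads(Path(path).read_text())
        entries = {e["rs_id"]: e["scores"] for e in payload["entries"]}
        return cls(payload["model_name"], entries)


def load_score_tables() -> tuple[ScoreTable, ScoreTable]:
    """The packaged (PWM, WRM) score tables of the weightlifter study."""
    raw = json.loads(resources.files("tgskit.data").joinpath("score_tables.json").read_text())
    return (
        ScoreTable(raw["PWM"]["model_name"], raw["PWM"]["entries"]),
        ScoreTable(raw["WRM"]["model_name"], raw["WRM"]["entries"]),
    )


def tgs_individual(table: ScoreTable, genotypes: Mapping[str, str | None]) -> float:
    """TGS of one individual; every locus of the table must be genotyped."""
    total = 0
    for rs_id in table.loci:
        genotype = genotypes.get(rs_id)
        if genotype is None or (isinstance(genotype, float) and pd.isna(genotype)):
            raise MissingGenotypeError(f"missing genotype at {rs_id}")
        total += table.score(rs_id, genotype)
    return table.scale * total


def tgs_cohort(table: ScoreTable, cohort: Cohort) -> tuple[pd.Series, int]:
    """Per-individual TGS for a cohort.

    Individuals missing any table locus are excluded (no proration); the
    second return value is the number excluded.
    """
    missing_cols = [rs for rs in table.loci if rs not in cohort.data.columns]
    if missing_cols:
        raise PanelMismatchError(f"cohort lacks loci {missing_cols}")
    sub = cohort.data[list(table.loci)]
    complete = sub.notna().all(axis=1)
    scores = pd.Series(0, index=cohort.data.index, dtype=float)
    for rs_id in table.loci:
        scores += sub[rs_id].map(lambda g, rs=rs_id: np.nan if g is None else table.score(rs, g))
    result = (table.scale * scores)[complete]
    result.index = cohort.data.loc[complete, "id"]
    return result, int((~complete).sum())


@dataclass(frozen=True)
class TgsSummary:
    """Group-level TGS summary; ``sd``/``pmf`` only where derivable."""

    model_name: str
    group: str
    n: int
    mean: float
    sd: float | None = None
    score_sums: np.ndarray | None = field(default=None, compare=False)
    pmf: np.ndarray | None = field(default=None, compare=False)
    scale: float | None = None


def _locus_probs_and_scores(
    table: ScoreTable, counts: CountTable, rs_id: str
) -> tuple[np.ndarray, np.ndarray]:
    gc = counts[rs_id]
    probs = np.array(gc.genotype_probabilities())
    scores = np.array([table.score(rs_id, lbl) for lbl in gc.locus.genotype_labels])
    return probs, scores


def tgs_mean_from_counts(table: ScoreTable, counts: CountTable) -> TgsSummary:
    """Group mean TGS from marginal genotype counts, by linearity of expectation.

    The mean needs no individual-level data: it is the scale times the sum
    over loci of the count-weighted mean genotype score.  The standard
    deviation is *not* derivable from marginals (it depends on between-locus
    covariance) and is left undefined.
    """
    mean_sum = 0.0
    for rs_id in table.loci:
        probs, scores = _locus_probs_and_scores(table, counts, rs_id)
        mean_sum += float(probs @ scores)
    n = max(counts[rs].total for rs in table.loci)
    return TgsSummary(table.model_name, counts.group, n, table.scale * mean_sum,
                      scale=table.scale)


def tgs_distribution(table: ScoreTable, counts: CountTable) -> TgsSummary:
    """Exact TGS distribution under between-locus independence.

    Convolves the per-locus score distributions (each supported on {0,1,2}
    with probabilities taken from the marginal genotype frequencies) into
    the probability mass function of the integer score sum, 0 .. 2L.
    Within-group genotype independence across loci is an assumption, not a
    property of the marginal counts; see the methods note.
    """
    pmf = np.ones(1)
    for rs_id in table.loci:
        probs, scores = _locus_probs_and_scores(table, counts, rs_id)
        locus_pmf = np.zeros(3)
        for s, p in zip(scores, probs):
            locus_pmf[s] += p
        pmf = np.convolve(pmf, locus_pmf)
    sums = np.arange(pmf.size)
    mean = table.scale * float(sums @ pmf)
    var = (table.scale**2) * float((sums**2) @ pmf - (sums @ pmf) ** 2)
    n = max(counts[rs].total for rs in table.loci)
    return TgsSummary(
        table.model_name, counts.group, n, mean, sd=float(np.sqrt(var)),
        score_sums=sums, pmf=pmf, scale=table.scale,
    )


def proportion_at_least(summary: TgsSummary, threshold: float = 50.0) -> float:
    """P(TGS >= threshold) from an exact distribution summary."""
    if not 0.0 <= threshold <= 100.0:
        raise ValueError("threshold must lie in [0, 100]")
    if summary.pmf is None or summary.scale is None:
        raise ValueError("summary carries no distribution; use tgs_distribution")
    points = summary.scale * summary.score_sums
    return float(summary.pmf[points >= threshold - 1e-9].sum())


def empirical_proportion_at_least(values: Sequence[float], threshold: float = 50.0) -> float:
    """Fraction of individual TGS values at or above the threshold."""
    if not 0.0 <= threshold <= 100.0:
        raise ValueError("threshold must lie in [0, 100]")
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no TGS values")
    return float((values >= threshold - 1e-9).mean())


def compare_threshold_proportions(
    values_a: Sequence[float], values_b: Sequence[float], threshold: float = 50.0
) -> tuple[float, float, float]:
    """Compare two groups' >= threshold fractions with a 2x2 chi-square.

    Returns (fraction_a, fraction_b, p).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    ka, kb = int((a >= threshold - 1e-9).sum()), int((b >= threshold - 1e-9).sum())
    res = chi_square_2xk((ka, a.size - ka), (kb, b.size - kb))
    return float(ka / a.size), float(kb / b.size), res.p


# ---------------------------------------------------------------------------
# Data-driven model construction


@dataclass(frozen=True)
class WrmSelection:
    """Audit record for one locus admitted to a data-driven score model."""

    locus: Locus
    triggering: tuple[AssociationResult, ...]  # all significant results for the locus
    trigger_group: str                         # case group defining the direction
    optimal_allele: str
    case_freq: float
    control_freq: float


def build_wrm(
    screen_results: Sequence[AssociationResult],
    case_tables: Mapping[str, CountTable],
    control_table: CountTable,
    alpha: float = ALPHA,
    model_name: str = "WRM",
    trigger_priority: Sequence[str] | None = None,
) -> tuple[ScoreTable, list[WrmSelection]]:
    """Derive a weightlifting-related score model from a case-control screen.

    A locus enters the model when any screened genetic model reaches
    ``p < alpha`` in any case group.  The score direction is set by allele
    enrichment in the *trigger group* (the first group in
    ``trigger_priority`` with a significant result; by default the case
    tables' own order, i.e. the broadest group first): the allele with
    higher frequency in the trigger group than in controls defines the
    score-2 "optimal" homozygote, the heterozygote always scores 1.

    Returns the score table plus per-locus audit records.  Raises
    :class:`EmptyModelError` if nothing is selected and
    :class:`UnresolvedDirectionError` on an exact allele-frequency tie.
    """
    if trigger_priority is None:
        trigger_priority = tuple(case_tables)
    by_locus: dict[str, list[AssociationResult]] = {}
    for res in screen_results:
        if res.significant(alpha):
            by_locus.setdefault(res.locus.rs_id, []).append(res)

    entries: dict[str, dict[str, int]] = {}
    audit: list[WrmSelection] = []
    for rs_id in control_table.loci:  # preserve panel order
        hits = by_locus.get(rs_id)
        if not hits:
            continue
        locus = control_table[rs_id].locus
        groups_hit = {r.case_group for r in hits}
        trigger_group = next((g for g in trigger_priority if g in groups_hit), None)
        if trigger_group is None:
            raise ValueError(f"{rs_id}: significant groups {groups_hit} not in priority list")
        case_freq = case_tables[trigger_group][rs_id].allele_frequency_hi()
        control_freq = control_table[rs_id].allele_frequency_hi()
        if case_freq == control_freq:
            raise UnresolvedDirectionError(
                f"{rs_id}: hi-allele frequency ties between {trigger_group} and controls"
            )
        optimal_hi = case_freq > control_freq
        hi, het, lo = locus.genotype_labels
        entries[rs_id] = {hi: 2 if optimal_hi else 0, het: 1, lo: 0 if optimal_hi else 2}
        audit.append(
            WrmSelection(
                locus, tuple(hits), trigger_group,
                locus.allele_hi if optimal_hi else locus.allele_lo,
                case_freq, control_freq,
            )
        )
    if not entries:
        raise EmptyModelError(f"no locus reached p < {alpha} in any case group")
    return ScoreTable(model_name, entries), audit


def tgs_summaries(
    table: ScoreTable, count_tables: Mapping[str, CountTable], exact: bool = True
) -> dict[str, TgsSummary]:
    """Group TGS summaries for several count tables at once."""
    fn = tgs_distribution if exact else tgs_mean_from_counts
    return {name: fn(table, ct) for name, ct in count_tables.items()}
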