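"""Domain types and I/O for biallelic genotype data.

The package works with two representations:

* marginal genotype *counts* per locus and group (:class:`GenotypeCounts`,
  :class:`CountTable`), the form in which published case-control tables
  report data; and
* *individual-level* genotype matrices (:class:`Cohort`), one row per person,
  one column per locus, with an optional performance phenotype (Wilks points).

Twelve autosomal strength/power candidate polymorphisms form the default
study panel (:data:`STUDY_PANEL`).  Each :class:`Locus` owns its canonical
genotype spellings plus a synonym map, so that dialects such as ACTN3
``RR/RX/XX`` (protein-level R577X) versus ``CC/CT/TT`` (nucleotide-level),
or opposite-strand reports of IGF2 rs680, all resolve to one spelling.
"""

from __future__ import annotations

import io
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import NamedTuple

import pandas as pd

from ._errors import (
    GenotypeLabelError,
    InconsistentTablesError,
    UnknownGroupError,
    UnknownLocusError,
)

#: Sentinel used in TSV output for a missing genotype; empty cells also read as missing.
MISSING = ""

_MISSING_TOKENS = {"", ".", "NA", "N/A", "-", "NAN", "NONE"}


@dataclass(frozen=True)
class Locus:
    """One biallelic SNP and its three genotype categories.

    ``allele_hi`` is the allele whose homozygote is listed first in the
    source count table; counts and collapse orientations are stored in that
    order (hi-homozygote, heterozygote, lo-homozygote).

    ``dominant_singleton`` records which homozygote stands alone in this
    locus's published *dominant* collapse (``"hi"`` or ``"lo"``); the
    recessive collapse isolates the other homozygote.  The published
    orientation is not uniform across loci, so it is locus-level data, not
    a convention.
    """

    gene: str
    rs_id: str
    allele_hi: str
    allele_lo: str
    het_label: str
    allele_synonyms: Mapping[str, str] = field(default_factory=dict)
    dominant_singleton: str = "hi"

    def __post_init__(self) -> None:
        if self.allele_hi == self.allele_lo:
            raise ValueError(f"{self.rs_id}: alleles must differ")
        if self.dominant_singleton not in ("hi", "lo"):
            raise ValueError(f"{self.rs_id}: dominant_singleton must be 'hi' or 'lo'")
        if set(self.het_label) != {self.allele_hi, self.allele_lo}:
            raise ValueError(f"{self.rs_id}: het label {self.het_label!r} does not use both alleles")

    @property
    def hom_hi_label(self) -> str:
        return self.allele_hi * 2

    @property
    def hom_lo_label(self) -> str:
        return self.allele_lo * 2

    @property
    def genotype_labels(self) -> tuple[str, str, str]:
        """Canonical labels ordered (hi-homozygote, heterozygote, lo-homozygote)."""
        return (self.hom_hi_label, self.het_label, self.hom_lo_label)

    def canonicalize(self, raw: str | None) -> str | None:
        """Resolve a raw genotype spelling to the canonical label.

        Case-insensitive and allele-order-insensitive (``GA`` == ``AG``);
        empty cells and common NA tokens map to ``None``.  Idempotent on
        canonical labels.  Raises :class:`GenotypeLabelError` otherwise.
        """
        if raw is None or (isinstance(raw, float) and pd.isna(raw)):
            return None
        label = str(raw).strip().upper()
        if label in _MISSING_TOKENS:
            return None
        if len(label) != 2:
            raise GenotypeLabelError(f"{self.rs_id}: malformed genotype label {raw!r}")
        alleles = []
        for ch in label:
            ch = self.allele_synonyms.get(ch, ch)
            if ch not in (self.allele_hi, self.allele_lo):
                raise GenotypeLabelError(
                    f"{self.rs_id}: allele {ch!r} in label {raw!r} is neither "
                    f"{self.allele_hi!r} nor {self.allele_lo!r}"
                )
            alleles.append(ch)
        n_hi = alleles.count(self.allele_hi)
        return self.genotype_labels[2 - n_hi]


def _panel(*loci: Locus) -> dict[str, Locus]:
    return {locus.rs_id: locus for locus in loci}


#: The twelve-locus study panel.  Genotype spellings and the per-locus
#: dominant/recessive orientation follow the published count table; ACTN3 and
#: CKM isolate the lo-homozygote in their dominant collapse, all other loci
#: the hi-homozygote.  ACE I/D is carried by rs4341 (perfect LD proxy); IGF2
#: rs680 is stored on the C/T strand with G/A accepted as the opposite strand.
STUDY_PANEL: dict[str, Locus] = _panel(
    Locus("ACE", "rs4341", "D", "I", "ID"),
    Locus("ACTN3", "rs1815739", "C", "T", "CT",
          allele_synonyms={"R": "C", "X": "T"}, dominant_singleton="lo"),
    Locus("ALDH2", "rs671", "G", "A", "GA"),
    Locus("CHRNB3", "rs4950", "A", "G", "GA"),
    Locus("CKM", "rs8111989", "A", "G", "GA", dominant_singleton="lo"),
    Locus("CNTFR", "rs41274853", "C", "T", "CT"),
    Locus("FTO", "rs9939609", "T", "A", "TA"),
    Locus("GALNTL6", "rs558129", "C", "T", "CT"),
    Locus("IGF2", "rs680", "C", "T", "CT", allele_synonyms={"G": "C", "A": "T"}),
    Locus("MCT1", "rs1049434", "A", "T", "TA"),
    Locus("PPARGC1A", "rs8192678", "A", "G", "GA"),
    Locus("TRHR", "rs7832552", "T", "C", "CT"),
)


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts for one locus in one group, in (hi, het, lo) order."""

    locus: Locus
    group: str
    n_hi: int
    n_het: int
    n_lo: int

    def __post_init__(self) -> None:
        for value in (self.n_hi, self.n_het, self.n_lo):
            if int(value) != value or value < 0:
                raise ValueError(f"{self.locus.rs_id}/{self.group}: counts must be non-negative integers")

    @property
    def total(self) -> int:
        return self.n_hi + self.n_het + self.n_lo

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.n_hi, self.n_het, self.n_lo)

    def allele_frequency_hi(self) -> float:
        """Sample frequency of the hi allele."""
        if self.total == 0:
            raise ValueError(f"{self.locus.rs_id}/{self.group}: empty counts")
        return (2 * self.n_hi + self.n_het) / (2 * self.total)

    def genotype_probabilities(self) -> tuple[float, float, float]:
        n = self.total
        if n == 0:
            raise ValueError(f"{self.locus.rs_id}/{self.group}: empty counts")
        return (self.n_hi / n, self.n_het / n, self.n_lo / n)


@dataclass(frozen=True)
class CountTable:
    """Per-locus genotype counts for one group.

    Published tables are *uniform*: every locus's counts sum to the group
    sample size.  Tables tallied from cohorts with missing genotypes may be
    ragged; pass ``allow_ragged=True`` for those.
    """

    group: str
    counts: Mapping[str, GenotypeCounts]
    allow_ragged: bool = False

    def __post_init__(self) -> None:
        totals = {gc.locus.rs_id: gc.total for gc in self.counts.values()}
        if not self.allow_ragged and len(set(totals.values())) > 1:
            raise InconsistentTablesError(
                f"{self.group}: loci disagree on sample size: {totals}"
            )

    @property
    def n_total(self) -> int:
        totals = {gc.total for gc in self.counts.values()}
        if len(totals) > 1:
            raise InconsistentTablesError(
                f"{self.group}: ragged table has no single sample size"
            )
        return totals.pop()

    @property
    def loci(self) -> tuple[str, ...]:
        return tuple(self.counts)

    def __getitem__(self, rs_id: str) -> GenotypeCounts:
        try:
            return self.counts[rs_id]
        except KeyError:
            raise UnknownLocusError(rs_id) from None

    def subtract(self, other: "CountTable", group: str) -> "CountTable":
        """Cell-wise subtraction, e.g. all weightlifters minus international."""
        if set(self.counts) != set(other.counts):
            raise InconsistentTablesError(
                f"{self.group} and {other.group} cover different loci"
            )
        new = {}
        for rs_id, gc in self.counts.items():
            oc = other.counts[rs_id]
            diff = tuple(a - b for a, b in zip(gc.as_tuple(), oc.as_tuple()))
            if min(diff) < 0:
                raise InconsistentTablesError(
                    f"{rs_id}: subtracting {other.group} from {self.group} "
                    f"gives negative counts {diff}"
                )
            new[rs_id] = GenotypeCounts(gc.locus, group, *diff)
        return CountTable(group, new)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gc in self.counts.values():
            for label, count in zip(gc.locus.genotype_labels, gc.as_tuple()):
                rows.append((self.group, gc.locus.gene, gc.locus.rs_id, label, count))
        return pd.DataFrame(rows, columns=["group", "gene", "rs_id", "genotype", "count"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


class FixtureTables(NamedTuple):
    controls: CountTable
    all_weightlifters: CountTable
    international: CountTable


def count_table_from_frame(
    frame: pd.DataFrame, group: str, panel: Mapping[str, Locus] = STUDY_PANEL
) -> CountTable:
    """Build a CountTable from a long-format frame (group, rs_id, genotype, count)."""
    sub = frame[frame["group"] == group]
    if sub.empty:
        raise UnknownGroupError(group)
    counts: dict[str, GenotypeCounts] = {}
    for rs_id in panel:
        locus = panel[rs_id]
        rows = sub[sub["rs_id"] == rs_id]
        if rows.empty:
            raise UnknownLocusError(f"{group}: no counts for {rs_id}")
        by_label = {locus.canonicalize(g): int(c) for g, c in zip(rows["genotype"], rows["count"])}
        counts[rs_id] = GenotypeCounts(
            locus, group, *(by_label.get(lbl, 0) for lbl in locus.genotype_labels)
        )
    return CountTable(group, counts)


def read_count_table(path: str | Path, group: str, panel: Mapping[str, Locus] = STUDY_PANEL) -> CountTable:
    return count_table_from_frame(pd.read_csv(path, sep="\t"), group, panel)


def load_fixture_table2() -> FixtureTables:
    """Load the packaged per-group genotype counts of the weightlifter study.

    Returns tables for the controls (n=416), all weightlifters (n=192) and
    the international-level subset (n=67), covering the twelve-locus panel.
    """
    with resources.files("tgskit.data").joinpath("table2_counts.tsv").open("r") as fh:
        frame = pd.read_csv(fh, sep="\t")
    return FixtureTables(
        controls=count_table_from_frame(frame, "controls"),
        all_weightlifters=count_table_from_frame(frame, "all_weightlifters"),
        international=count_table_from_frame(frame, "international"),
    )


def derive_national(all_weightlifters: CountTable, international: CountTable) -> CountTable:
    """National-level counts as all weightlifters minus the international subset."""
    return all_weightlifters.subtract(international, "national")


# ---------------------------------------------------------------------------
# Individual-level cohorts


@dataclass
class Cohort:
    """Individual-level genotype records with optional performance phenotype.

    ``data`` has columns ``id``, ``group``, ``wilks`` and one column per
    panel rs id holding canonical genotype labels (``None``/NaN = missing).
    """

    data: pd.DataFrame
    panel: Mapping[str, Locus] = field(default_factory=lambda: dict(STUDY_PANEL))

    def __post_init__(self) -> None:
        for col in ("id", "group"):
            if col not in self.data.columns:
                raise ValueError(f"cohort frame lacks required column {col!r}")
        if "wilks" not in self.data.columns:
            self.data = self.data.assign(wilks=float("nan"))

    @property
    def groups(self) -> tuple[str, ...]:
        seen: list[str] = []
        for g in self.data["group"]:
            if g not in seen:
                seen.append(g)
        return tuple(seen)

    @property
    def loci(self) -> tuple[str, ...]:
        return tuple(rs for rs in self.panel if rs in self.data.columns)

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, groups: str | Iterable[str]) -> "Cohort":
        if isinstance(groups, str):
            groups = [groups]
        groups = list(groups)
        unknown = set(groups) - set(self.data["group"])
        if unknown:
            raise UnknownGroupError(sorted(unknown)[0])
        return Cohort(self.data[self.data["group"].isin(groups)].reset_index(drop=True), self.panel)


def read_cohort(
    path: str | Path | io.TextIOBase, panel: Mapping[str, Locus] = STUDY_PANEL
) -> Cohort:
    """Read a tab-separated genotype matrix and canonicalize all labels.

    Expected header: ``id``, optional ``group`` and ``wilks``, then one
    column per locus named by rs id.  Unknown rs columns, unresolvable
    genotype labels (reported with row and column), and non-numeric
    performance values raise errors.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "id" not in frame.columns:
        raise ValueError("genotype matrix lacks an 'id' column")
    meta = {"id", "group", "wilks"}
    rs_cols = [c for c in frame.columns if c not in meta]
    for col in rs_cols:
        if col not in panel:
            raise UnknownLocusError(col)

    problems: list[str] = []
    out = pd.DataFrame({"id": frame["id"]})
    out["group"] = frame["group"] if "group" in frame.columns else "cohort"
    if "wilks" in frame.columns:
        wilks = []
        for i, raw in enumerate(frame["wilks"]):
            raw = raw.strip()
            if raw in _MISSING_TOKENS:
                wilks.append(float("nan"))
                continue
            try:
                value = float(raw)
            except ValueError:
                problems.append(f"row {i + 2}, column 'wilks': non-numeric value {raw!r}")
                continue
            if value < 0:
                problems.append(f"row {i + 2}, column 'wilks': negative value {raw!r}")
                continue
            wilks.append(value)
        if not problems:
            out["wilks"] = wilks
    else:
        out["wilks"] = float("nan")

    for col in rs_cols:
        locus = panel[col]
        canon = []
        for i, raw in enumerate(frame[col]):
            try:
                canon.append(locus.canonicalize(raw))
            except GenotypeLabelError as exc:
                problems.append(f"row {i + 2}, column {col!r}: {exc}")
                canon.append(None)
        out[col] = canon
    if problems:
        raise GenotypeLabelError("unreadable cells:\n  " + "\n  ".join(problems))
    return Cohort(out, dict(panel))


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write the cohort back to the TSV dialect accepted by :func:`read_cohort`."""
    frame = cohort.data.copy()
    for rs in cohort.loci:
        frame[rs] = frame[rs].map(lambda g: MISSING if g is None or pd.isna(g) else g)
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def counts_from_cohort(cohort: Cohort, group: str, locus: Locus) -> GenotypeCounts:
    """Tally one locus within one group; missing genotypes are excluded."""
    if group not in set(cohort.data["group"]):
        raise UnknownGroupError(group)
    column = cohort.data.loc[cohort.data["group"] == group, locus.rs_id]
    tally = column.value_counts()
    return GenotypeCounts(
        locus, group, *(int(tally.get(lbl, 0)) for lbl in locus.genotype_labels)
    )


def count_table_from_cohort(
    cohort: Cohort, group: str, panel: Mapping[str, Locus] | None = None
) -> CountTable:
    panel = panel or {rs: cohort.panel[rs] for rs in cohort.loci}
    return CountTable(
        group,
        {rs: counts_from_cohort(cohort, group, panel[rs]) for rs in panel},
        allow_ragged=True,
    )
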