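"""Exception hierarchy shared across the package."""


class TgskitError(Exception):
    """Base class for all package-specific errors."""


class GenotypeLabelError(TgskitError, ValueError):
    """A genotype label could not be resolved to one of the locus's three categories."""


class UnknownLocusError(TgskitError, KeyError):
    """An rs identifier is not part of the active locus panel."""


class UnknownGroupError(TgskitError, KeyError):
    """A group label is not present in the cohort or table collection."""


class InconsistentTablesError(TgskitError, ValueError):
    """Two count tables cannot be combined (mismatched loci or negative differences)."""


class DegenerateTableError(TgskitError, ValueError):
    """A contingency table has a zero margin and the chi-square test is undefined."""


class EmptyModelError(TgskitError, ValueError):
    """A data-driven score model selected no loci."""


class UnresolvedDirectionError(TgskitError, ValueError):
    """Allele frequencies tie between cases and controls; the score direction is undefined."""


class PanelMismatchError(TgskitError, ValueError):
    """A score table refers to loci that are absent from the cohort or count table."""


class MissingGenotypeError(TgskitError, ValueError):
    """An individual-level score was requested for a record with missing genotypes."""


class EmptyGroupError(TgskitError, ValueError):
    """A genotype-defined comparison group has too few observations."""
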