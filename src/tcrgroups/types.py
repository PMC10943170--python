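"""Core domain types shared across the pipeline.

The pipeline operates on clonotype observations (one CDR3beta amino-acid
sequence seen in one sample), per-patient HLA/metadata profiles, tetramer
reference entries, and the specificity groups built from the clonotypes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

#: the 20 canonical amino acids; CDR3beta sequences must be drawn from this set
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_CDR3_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]+$")


class FormatError(ValueError):
    """Raised when an input file does not match the expected dialect."""


class ValidationError(ValueError):
    """Raised when parsed data violates a documented invariant."""


class Tissue(str, Enum):
    """Origin of a sample: tumor tissue or normal tissue adjacent to tumor."""

    TUMOR = "TUMOR"
    NAT = "NAT"


def is_valid_cdr3(seq: str, min_length: int = 6) -> bool:
    """True if ``seq`` is over the 20-letter alphabet and long enough to
    retain a non-empty interior after flank trimming."""
    return len(seq) >= min_length and bool(_CDR3_RE.match(seq))


@dataclass(frozen=True)
class ClonotypeRecord:
    """One CDR3beta clonotype observation in one sample."""

    sample_id: str
    patient_id: str
    tissue: Tissue
    cdr3b_aa: str
    v_gene: str
    j_gene: str
    count: int = 1
    productive: bool = True

    def __post_init__(self) -> None:
        if not self.sample_id or not self.patient_id:
            raise ValidationError("sample_id and patient_id must be non-empty")
        if self.count < 0:
            raise ValidationError(f"negative count for {self.cdr3b_aa!r}")


@dataclass
class PatientProfile:
    """Per-patient HLA genotype and categorical metadata.

    HLA alleles are normalized to two-field resolution (``locus*group``,
    e.g. ``B*44``); ``mutations`` holds gene symbols with MUT status.
    """

    patient_id: str
    hla_alleles: frozenset[str] = frozenset()
    subtype: Optional[str] = None
    mutations: frozenset[str] = frozenset()
    cancer_type: Optional[str] = None


_ALLELE_RE = re.compile(r"^(?:HLA-)?([A-Z][A-Z0-9]*)\*(\d+)")


def normalize_allele(allele: str) -> str:
    """Reduce an HLA allele string to two-field resolution, ``locus*group``.

    ``"HLA-A*02:01"`` → ``"A*02"``; ``"DRB1*13"`` → ``"DRB1*13"``.
    """
    m = _ALLELE_RE.match(allele.strip())
    if not m:
        raise ValidationError(f"unparseable HLA allele: {allele!r}")
    return f"{m.group(1)}*{m.group(2)}"


@dataclass(frozen=True)
class TetramerRecord:
    """A CDR3beta → (epitope, antigen source, MHC) reference entry."""

    cdr3b_aa: str
    epitope: str
    antigen_source: str
    mhc_allele: str

    def __post_init__(self) -> None:
        if not self.cdr3b_aa or not self.mhc_allele:
            raise ValidationError("tetramer record needs cdr3b_aa and mhc_allele")


@dataclass
class GroupScores:
    """The four score families of a specificity group.

    simpson_v / simpson_len are Simpson concentration indices (sum p_i^2)
    over member V genes / CDR3 lengths; the p-values are permutation tails
    against random same-size selections from the whole dataset; p_expansion
    compares the summed member clone counts against random clonotype draws;
    hla_enrichments lists (allele, n_carrier_patients, one-sided Fisher p).
    """

    simpson_v: Optional[float] = None
    p_vbias: Optional[float] = None
    simpson_len: Optional[float] = None
    p_lenbias: Optional[float] = None
    p_expansion: Optional[float] = None
    hla_enrichments: list[tuple[str, int, float]] = field(default_factory=list)


@dataclass
class SpecificityGroup:
    """A convergence group of CDR3beta sequences presumed to share
    peptide-MHC specificity, grouped by a local motif or global homology."""

    group_id: str
    method: str  # "LOCAL" | "GLOBAL"
    pattern: str  # display form, e.g. "local GQG" or "global SPTG%YNE"
    members: list[ClonotypeRecord] = field(default_factory=list)
    scores: Optional[GroupScores] = None

    @property
    def cdr3_set(self) -> frozenset[str]:
        return frozenset(m.cdr3b_aa for m in self.members)

    @property
    def patient_set(self) -> frozenset[str]:
        return frozenset(m.patient_id for m in self.members)

    @property
    def distinct_cdr3_count(self) -> int:
        return len(self.cdr3_set)

    @property
    def distinct_patient_count(self) -> int:
        return len(self.patient_set)

    @property
    def tumor_only(self) -> bool:
        """True when every member record comes from a tumor sample."""
        return bool(self.members) and all(m.tissue == Tissue.TUMOR for m in self.members)
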