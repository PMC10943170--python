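"""Convergence grouping of CDR3beta sequences.

Two routes mirror the paratope-hotspot grouping idea: LOCAL groups collect
sequences whose CDR3 *interior* shares a short k-mer that is enriched in
the sample relative to a reference repertoire (one-sided binomial tail);
GLOBAL groups collect identical-length sequences that differ at exactly
one interior position (single-substitution homology, displayed with a
``%`` wildcard).

The interior is the CDR3 with membrane-proximal flanks trimmed (default
4 N-terminal / 1 C-terminal residues): flank residues contact MHC rather
than peptide, so convergence evidence is restricted to the loop apex.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from scipy.stats import binom

from .types import ClonotypeRecord, SpecificityGroup

log = logging.getLogger(__name__)

#: flank trimming convention: residues dropped before interior comparisons
DEFAULT_TRIM_N = 4
DEFAULT_TRIM_C = 1

#: local-motif defaults (k-mer sizes, occurrence / fold / p stringency)
DEFAULT_KS = (3, 4)
DEFAULT_MIN_OCCURRENCE = 3
DEFAULT_MIN_FOLD = 10.0
DEFAULT_MAX_P = 1e-3


def interior(seq: str, trim_n: int = DEFAULT_TRIM_N, trim_c: int = DEFAULT_TRIM_C) -> str:
    """Interior of a CDR3 after trimming the MHC-proximal flanks."""
    return seq[trim_n : len(seq) - trim_c]


def _kmers_of(s: str, k: int) -> set[str]:
    return {s[i : i + k] for i in range(len(s) - k + 1)}


@dataclass
class ReferenceRepertoire:
    """A background repertoire indexed by interior k-mer presence.

    ``kmer_counts[k][kmer]`` is the number of reference interiors that
    contain ``kmer`` at least once; ``n_interiors`` the number of indexed
    sequences. Rates are therefore per-interior presence probabilities.
    """

    sequences: list[str]
    ks: tuple[int, ...]
    trim_n: int
    trim_c: int
    kmer_counts: dict[int, Counter] = field(default_factory=dict)

    @property
    def n_interiors(self) -> int:
        return len(self.sequences)

    def rate(self, kmer: str) -> float:
        """Per-interior presence rate, floored at 1/(n+1) for unseen k-mers."""
        count = self.kmer_counts.get(len(kmer), Counter())[kmer]
        if count == 0:
            log.debug("k-mer %s absent from reference; rate floored", kmer)
            return 1.0 / (self.n_interiors + 1)
        return count / self.n_interiors


def build_reference(
    sequences: Iterable[str],
    ks: tuple[int, ...] = (2, 3, 4),
    trim_n: int = DEFAULT_TRIM_N,
    trim_c: int = DEFAULT_TRIM_C,
) -> ReferenceRepertoire:
    """Index a reference repertoire for motif enrichment.

    Counts are presence counts: each interior contributes at most one to a
    k-mer's count. Raises on empty input; warns below 100 sequences.
    """
    seqs = list(sequences)
    if not seqs:
        raise ValueError("reference repertoire must be non-empty")
    if len(seqs) < 100:
        log.warning("reference repertoire has only %d sequences", len(seqs))
    counts: dict[int, Counter] = {k: Counter() for k in ks}
    for seq in seqs:
        core = interior(seq, trim_n, trim_c)
        for k in ks:
            counts[k].update(_kmers_of(core, k))
    return ReferenceRepertoire(
        sequences=seqs, ks=tuple(ks), trim_n=trim_n, trim_c=trim_c, kmer_counts=counts
    )


@dataclass(frozen=True)
class Motif:
    """A sample-enriched interior k-mer."""

    kmer: str
    sample_count: int
    sample_freq: float
    ref_freq: float
    fold: float
    p_enrich: float


def find_local_motifs(
    sample: Sequence[str],
    ref: ReferenceRepertoire,
    min_fold: float = DEFAULT_MIN_FOLD,
    max_p: float = DEFAULT_MAX_P,
    min_occurrence: int = DEFAULT_MIN_OCCURRENCE,
    ks: tuple[int, ...] = DEFAULT_KS,
) -> list[Motif]:
    """Find interior k-mers enriched in the sample versus the reference.

    ``sample`` is the list of (typically distinct) CDR3 sequences under
    study. For each candidate k-mer seen in >= ``min_occurrence`` sample
    interiors, the enrichment p-value is the one-sided binomial tail
    P(X >= x) with X ~ Binomial(n_sample_interiors, ref_rate). Motifs must
    also reach ``min_fold`` on the frequency ratio.
    """
    interiors = [interior(s, ref.trim_n, ref.trim_c) for s in sample]
    n = len(interiors)
    sample_counts: dict[int, Counter] = {k: Counter() for k in ks}
    for core in interiors:
        for k in ks:
            sample_counts[k].update(_kmers_of(core, k))

    motifs: list[Motif] = []
    for k in ks:
        for kmer, x in sample_counts[k].items():
            if x < min_occurrence:
                continue
            ref_rate = ref.rate(kmer)
            sample_freq = x / n
            fold = sample_freq / ref_rate
            if fold < min_fold:
                continue
            p = float(binom.sf(x - 1, n, ref_rate))
            if p > max_p:
                continue
            motifs.append(
                Motif(
                    kmer=kmer,
                    sample_count=x,
                    sample_freq=sample_freq,
                    ref_freq=ref_rate,
                    fold=fold,
                    p_enrich=p,
                )
            )
    motifs.sort(key=lambda m: (m.p_enrich, m.kmer))
    return motifs


@dataclass(frozen=True)
class GlobalCluster:
    """Identical-length sequences differing at one interior position."""

    masked: str  # full sequence with '%' at the variable position
    position: int  # index of the wildcard in the full sequence
    sequences: frozenset[str]

    @property
    def pattern(self) -> str:
        return self.masked

    def matches(self, seq: str) -> bool:
        if len(seq) != len(self.masked):
            return False
        return all(a == b or a == "%" for a, b in zip(self.masked, seq))


def find_global_clusters(
    sequences: Iterable[str],
    trim_n: int = DEFAULT_TRIM_N,
    trim_c: int = DEFAULT_TRIM_C,
) -> list[GlobalCluster]:
    """Cluster sequences by single-substitution homology.

    Each cluster holds >= 2 distinct, identical-length sequences whose
    pairwise differences are confined to one shared interior position (the
    wildcard). Sequences differing in the trimmed flanks never cluster.
    """
    unique = sorted(set(sequences))
    buckets: dict[tuple[int, str], set[str]] = defaultdict(set)
    for seq in unique:
        for pos in range(trim_n, len(seq) - trim_c):
            masked = seq[:pos] + "%" + seq[pos + 1 :]
            buckets[(pos, masked)].add(seq)
    clusters = []
    for (pos, masked), seqs in buckets.items():
        if len(seqs) >= 2:
            clusters.append(
                GlobalCluster(masked=masked, position=pos, sequences=frozenset(seqs))
            )
    clusters.sort(key=lambda c: (c.masked, c.position))
    return clusters


def assemble_groups(
    local_motifs: Sequence[Motif],
    global_clusters: Sequence[GlobalCluster],
    records: Sequence[ClonotypeRecord],
    trim_n: int = DEFAULT_TRIM_N,
    trim_c: int = DEFAULT_TRIM_C,
) -> list[SpecificityGroup]:
    """Materialize specificity groups from motifs/clusters over the records.

    A group's members are *all* records whose CDR3 satisfies the pattern
    (LOCAL: interior contains the k-mer; GLOBAL: exact match with the
    wildcard free). Groups with identical member CDR3 sets are
    deduplicated (first kept, LOCAL before GLOBAL); group ids are assigned
    deterministically in pattern order.
    """
    groups: list[SpecificityGroup] = []
    seen_member_sets: set[frozenset[str]] = set()

    candidates: list[tuple[str, str, list[ClonotypeRecord]]] = []
    for motif in sorted(local_motifs, key=lambda m: m.kmer):
        members = [
            r for r in records if motif.kmer in interior(r.cdr3b_aa, trim_n, trim_c)
        ]
        candidates.append(("LOCAL", f"local {motif.kmer}", members))
    for cluster in sorted(global_clusters, key=lambda c: (c.masked, c.position)):
        members = [r for r in records if r.cdr3b_aa in cluster.sequences]
        pattern = interior(cluster.masked, trim_n, trim_c)
        candidates.append(("GLOBAL", f"global {pattern}", members))

    idx = 0
    for method, pattern, members in candidates:
        if not members:
            continue
        member_set = frozenset(m.cdr3b_aa for m in members)
        if member_set in seen_member_sets:
            continue
        seen_member_sets.add(member_set)
        # stable member order regardless of input record order
        members = sorted(
            members, key=lambda r: (r.cdr3b_aa, r.sample_id, r.v_gene, r.j_gene, r.count)
        )
        idx += 1
        groups.append(
            SpecificityGroup(
                group_id=f"C{idx}", method=method, pattern=pattern, members=members
            )
        )
    return groups
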