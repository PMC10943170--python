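"""Tetramer annotation, the shared-CDR3 group network, and consistency stats.

A group is annotated when any member CDR3beta exactly matches a tetramer
reference entry; the matched epitope(s) propagate to the whole group.
Groups form an undirected network with an edge whenever two groups share
at least one identical CDR3beta sequence. Two consistency statistics
validate the annotations: the fraction of annotated, non-isolated groups
with a same-tetramer direct neighbor, and the per-HLA-supertype
concordance between a group's tetramer restriction and its own
significant HLA enrichments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

from .types import SpecificityGroup, TetramerRecord, normalize_allele

log = logging.getLogger(__name__)


@dataclass
class GroupAnnotation:
    group_id: str
    matched_cdr3s: list[str] = field(default_factory=list)
    epitopes: set[tuple[str, str, str]] = field(default_factory=set)
    # each epitope tuple is (epitope, antigen_source, mhc_allele)

    @property
    def annotated(self) -> bool:
        return bool(self.matched_cdr3s)

    @property
    def sources(self) -> set[str]:
        return {src for _, src, _ in self.epitopes}


def annotate_groups(
    groups: Sequence[SpecificityGroup],
    tetramer_db: Sequence[TetramerRecord],
) -> list[GroupAnnotation]:
    """Annotate each group by exact CDR3beta match into the tetramer db.

    Matching uses CDR3 identity only; the record's MHC allele rides along
    as an attribute. All matching entries are retained (no arbitration).
    Idempotent, and monotone in the database.
    """
    if not tetramer_db:
        log.warning("empty tetramer database: no group can be annotated")
    by_cdr3: dict[str, list[TetramerRecord]] = {}
    for rec in tetramer_db:
        by_cdr3.setdefault(rec.cdr3b_aa, []).append(rec)

    annotations = []
    for g in groups:
        ann = GroupAnnotation(group_id=g.group_id)
        for cdr3 in sorted(g.cdr3_set):
            for rec in by_cdr3.get(cdr3, ()):
                if cdr3 not in ann.matched_cdr3s:
                    ann.matched_cdr3s.append(cdr3)
                ann.epitopes.add((rec.epitope, rec.antigen_source, rec.mhc_allele))
        annotations.append(ann)
    return annotations


def tabulate_antigen_sources(
    annotations: Sequence[GroupAnnotation],
    ti_group_ids: set[str],
) -> pd.DataFrame:
    """Per antigen source: group counts/proportions, split TI vs T-N-common.

    Proportions are over all groups in the split (annotated or not), so
    the two columns are comparable fractions of each compartment.
    """
    n_ti = sum(1 for a in annotations if a.group_id in ti_group_ids)
    n_common = len(annotations) - n_ti
    sources = sorted({s for a in annotations for s in a.sources})
    rows = []
    for src in sources:
        ti = sum(1 for a in annotations if a.group_id in ti_group_ids and src in a.sources)
        common = sum(
            1 for a in annotations if a.group_id not in ti_group_ids and src in a.sources
        )
        rows.append(
            {
                "antigen_source": src,
                "n_ti_groups": ti,
                "prop_ti": ti / n_ti if n_ti else 0.0,
                "n_common_groups": common,
                "prop_common": common / n_common if n_common else 0.0,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["antigen_source", "n_ti_groups", "prop_ti", "n_common_groups", "prop_common"],
    )


def build_group_network(groups: Sequence[SpecificityGroup]) -> nx.Graph:
    """Undirected graph over groups; edge iff member CDR3 sets intersect.

    No self-loops; nodes carry pattern/method attributes.
    """
    graph = nx.Graph()
    for g in groups:
        graph.add_node(g.group_id, pattern=g.pattern, method=g.method)
    # index CDR3 -> groups to avoid the quadratic scan on large inputs
    by_cdr3: dict[str, list[str]] = {}
    for g in groups:
        for cdr3 in g.cdr3_set:
            by_cdr3.setdefault(cdr3, []).append(g.group_id)
    for ids in by_cdr3.values():
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                if a != b:
                    graph.add_edge(a, b)
    return graph


@dataclass(frozen=True)
class ConsistencyReport:
    n_consistent: int
    n_eligible: int
    n_annotated: int
    percent: Optional[float]  # None when no group is eligible


def tetramer_consistency(
    network: nx.Graph,
    annotations: Sequence[GroupAnnotation],
) -> ConsistencyReport:
    """Fraction of annotated, non-isolated groups with a same-tetramer neighbor.

    Eligible: annotated groups with at least one network edge. Consistent:
    eligible groups with a direct neighbor sharing an identical tetramer
    entry (epitope, antigen source, MHC). Percent is rounded to one
    decimal; None (not-applicable) when nothing is eligible.
    """
    by_id = {a.group_id: a for a in annotations}
    missing = [n for n in network.nodes if n not in by_id]
    if missing:
        raise ValueError(f"annotations missing for network nodes {missing[:3]}")
    eligible = [
        a for a in annotations
        if a.annotated and a.group_id in network and network.degree(a.group_id) > 0
    ]
    n_consistent = 0
    for a in eligible:
        for nb in network.neighbors(a.group_id):
            if by_id[nb].epitopes & a.epitopes:
                n_consistent += 1
                break
    n_eligible = len(eligible)
    percent = round(100.0 * n_consistent / n_eligible, 1) if n_eligible else None
    return ConsistencyReport(
        n_consistent=n_consistent,
        n_eligible=n_eligible,
        n_annotated=sum(1 for a in annotations if a.annotated),
        percent=percent,
    )


def supertype_of(allele: str, supertype_map: Mapping[str, str] = None) -> str:
    """Supertype of an allele: the mapped value of its two-field prefix,
    defaulting to the prefix itself (e.g. any A*02:xx → "A*02")."""
    prefix = normalize_allele(allele)
    if supertype_map and prefix in supertype_map:
        return supertype_map[prefix]
    return prefix


def hla_supertype_consistency(
    groups: Sequence[SpecificityGroup],
    annotations: Sequence[GroupAnnotation],
    supertype_map: Mapping[str, str] = None,
    supertypes: Sequence[str] = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-supertype concordance between tetramer restriction and HLA enrichment.

    For each supertype S: among groups annotated with a tetramer of S, the
    percentage whose own significant HLA enrichments (p < ``alpha``)
    include an allele of S. The ``other`` columns give the same percentage
    among groups annotated only with tetramers of other supertypes — the
    comparison row of the validation.
    """
    by_id = {g.group_id: g for g in groups}
    ann_supertypes: dict[str, set[str]] = {}
    for a in annotations:
        sts = {supertype_of(mhc, supertype_map) for _, _, mhc in a.epitopes}
        if sts:
            ann_supertypes[a.group_id] = sts

    def enriched_supertypes(group_id: str) -> set[str]:
        g = by_id.get(group_id)
        if g is None or g.scores is None:
            return set()
        return {
            supertype_of(allele, supertype_map)
            for allele, _n, p in g.scores.hla_enrichments
            if p < alpha
        }

    if supertypes is None:
        supertypes = sorted({s for sts in ann_supertypes.values() for s in sts})

    rows = []
    for st in supertypes:
        in_st = [gid for gid, sts in ann_supertypes.items() if st in sts]
        other = [gid for gid, sts in ann_supertypes.items() if st not in sts]
        n_conc = sum(1 for gid in in_st if st in enriched_supertypes(gid))
        n_other_conc = sum(1 for gid in other if st in enriched_supertypes(gid))
        rows.append(
            {
                "supertype": st,
                "n_annotated": len(in_st),
                "n_concordant": n_conc,
                "percent": round(100.0 * n_conc / len(in_st), 1) if in_st else None,
                "n_other": len(other),
                "n_other_concordant": n_other_conc,
                "percent_other": round(100.0 * n_other_conc / len(other), 1) if other else None,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "supertype", "n_annotated", "n_concordant", "percent",
            "n_other", "n_other_concordant", "percent_other",
        ],
    )
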