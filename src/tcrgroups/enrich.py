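"""Categorical metadata enrichment for tumor-infiltrating groups.

Each (group, attribute) pair with at least two group carriers is tested
with the one-sided hypergeometric upper tail P(X >= k) against the chosen
patient universe; Benjamini–Hochberg adjustment runs across all tests of
the same attribute kind. The default universe is the union of patients in
the tested groups (the tumor-infiltrating patient set), configurable to
the whole cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .types import PatientProfile, SpecificityGroup

log = logging.getLogger(__name__)

KINDS = ("SUBTYPE", "MUTATION")


@dataclass(frozen=True)
class EnrichmentResult:
    group_id: str
    kind: str
    value: str
    k: int  # group patients carrying the attribute
    n: int  # group patients in the universe
    K: int  # universe patients carrying the attribute
    N: int  # universe size
    p_hyper: float
    p_adj: float


def _attribute_values(profile: PatientProfile, kind: str) -> frozenset[str]:
    if kind == "SUBTYPE":
        return frozenset([profile.subtype]) if profile.subtype else frozenset()
    if kind == "MUTATION":
        return profile.mutations
    raise ValueError(f"unknown attribute kind {kind!r}")


def enrich_categorical(
    groups: Sequence[SpecificityGroup],
    profiles: Mapping[str, PatientProfile],
    kind: str,
    universe: Optional[Iterable[str]] = None,
    min_carriers: int = 2,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of one attribute kind across groups.

    ``universe`` defaults to the union of the groups' patients; pass an
    explicit patient list (e.g. the whole cohort) to widen it. Attributes
    absent from the universe are skipped with a note. ``alpha`` is only
    used downstream (significance = p_adj < alpha); all tests are returned.
    """
    if universe is None:
        universe_set = set().union(*(set(g.patient_set) for g in groups)) if groups else set()
    else:
        universe_set = set(universe)
    universe_set &= set(profiles)
    N = len(universe_set)
    if N == 0 or not any(_attribute_values(profiles[p], kind) for p in universe_set):
        log.warning("no %s data in the enrichment universe", kind)
        return []

    carriers_by_value: dict[str, set[str]] = {}
    for p in universe_set:
        for value in _attribute_values(profiles[p], kind):
            carriers_by_value.setdefault(value, set()).add(p)

    tests: list[tuple[str, str, int, int, int, float]] = []
    for g in groups:
        group_patients = set(g.patient_set) & universe_set
        n = len(group_patients)
        if n == 0:
            continue
        counts: dict[str, int] = {}
        for p in group_patients:
            for value in _attribute_values(profiles[p], kind):
                counts[value] = counts.get(value, 0) + 1
        for value, k in counts.items():
            if k < min_carriers:
                continue
            if value not in carriers_by_value:
                log.warning("attribute %s=%s absent from universe; skipped", kind, value)
                continue
            K = len(carriers_by_value[value])
            p_hyper = float(hypergeom.sf(k - 1, N, K, n))
            tests.append((g.group_id, value, k, n, K, p_hyper))

    if not tests:
        return []
    _, p_adj, _, _ = multipletests([t[5] for t in tests], method="fdr_bh")
    results = [
        EnrichmentResult(
            group_id=gid, kind=kind, value=value, k=k, n=n, K=K, N=N,
            p_hyper=p_hyper, p_adj=float(adj),
        )
        for (gid, value, k, n, K, p_hyper), adj in zip(tests, p_adj)
    ]
    results.sort(key=lambda r: (r.p_adj, r.p_hyper, r.group_id, r.value))
    return results


def summarize_enrichment_matrix(
    results: Sequence[EnrichmentResult],
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, list[str]]:
    """Group × attribute matrix of significant results (cells hold k).

    Returns the matrix and the list of groups significant for both a
    subtype and a mutation.
    """
    significant = [r for r in results if r.p_adj < alpha]
    if not significant:
        return pd.DataFrame(), []
    df = pd.DataFrame(
        [(r.group_id, f"{r.kind}:{r.value}", r.k) for r in significant],
        columns=["group_id", "attribute", "k"],
    )
    matrix = df.pivot_table(index="group_id", columns="attribute", values="k", aggfunc="max")
    kinds_by_group: dict[str, set[str]] = {}
    for r in significant:
        kinds_by_group.setdefault(r.group_id, set()).add(r.kind)
    dual = sorted(g for g, kinds in kinds_by_group.items() if {"SUBTYPE", "MUTATION"} <= kinds)
    return matrix, dual
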