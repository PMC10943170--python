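"""Group statistics: V-gene / CDR3-length bias, clonal expansion, HLA use.

The bias scores are Simpson concentration indices (sum p_i^2) over the
group members' V genes or CDR3 lengths; their p-values ask how often a
uniform random selection of the same number of records from the whole
dataset concentrates at least as strongly. Clonal expansion compares the
group's summed clone counts against random same-size clonotype draws.
All permutation p-values use the add-one estimator
p = (1 + #{perm >= observed}) / (n_perm + 1), so p is never zero and lies
in [1/(n_perm+1), 1]; a fixed seed reproduces them bit-exactly.

HLA enrichment is a one-sided Fisher exact test per allele carried by at
least two distinct member patients, on the 2x2 table
(carrier / non-carrier) x (in-group patients / all other patients).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import fisher_exact

from .types import ClonotypeRecord, GroupScores, PatientProfile, SpecificityGroup

log = logging.getLogger(__name__)

DEFAULT_N_PERM = 1000

#: cap on elements per vectorized permutation chunk (memory guard)
_CHUNK_BUDGET = 20_000_000


def simpson(values: Sequence) -> float:
    """Simpson concentration index sum p_i^2 of a categorical sample."""
    arr = np.asarray(values)
    if arr.size == 0:
        raise ValueError("simpson undefined on empty sample")
    _, counts = np.unique(arr, return_counts=True)
    p = counts / counts.sum()
    return float(np.sum(p * p))


def _perm_index_draws(n: int, m: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """(n_perm, m) indices, each row a uniform draw without replacement."""
    out = np.empty((n_perm, m), dtype=np.intp)
    rows_per_chunk = max(1, _CHUNK_BUDGET // max(n, 1))
    start = 0
    while start < n_perm:
        stop = min(start + rows_per_chunk, n_perm)
        keys = rng.random((stop - start, n))
        out[start:stop] = np.argpartition(keys, m - 1, axis=1)[:, :m]
        start = stop
    return out


def _perm_simpson_pvalue(
    member_codes: np.ndarray,
    pool_codes: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    m = member_codes.size
    _, counts = np.unique(member_codes, return_counts=True)
    observed = float(np.sum((counts / m) ** 2))

    idx = _perm_index_draws(pool_codes.size, m, n_perm, rng)
    draws = pool_codes[idx]
    n_ge = 0
    rows_per_chunk = max(1, _CHUNK_BUDGET // (m * m))
    for start in range(0, n_perm, rows_per_chunk):
        chunk = draws[start : start + rows_per_chunk]
        # sum over g of n_g^2 equals the number of equal ordered pairs
        eq = chunk[:, :, None] == chunk[:, None, :]
        stat = eq.sum(axis=(1, 2)) / (m * m)
        n_ge += int(np.sum(stat >= observed - 1e-12))
    p = (1 + n_ge) / (n_perm + 1)
    return observed, p


def score_vgene_bias(
    group: SpecificityGroup,
    all_records: Sequence[ClonotypeRecord],
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> tuple[float, float]:
    """Simpson index over member V genes and its permutation p-value."""
    if len(group.members) < 2:
        raise ValueError(f"group {group.group_id}: V-bias undefined below 2 members")
    rng = np.random.default_rng(seed)
    pool = [r.v_gene for r in all_records]
    codes = {v: i for i, v in enumerate(sorted(set(pool)))}
    member_codes = np.array([codes[m.v_gene] for m in group.members])
    pool_codes = np.array([codes[v] for v in pool])
    return _perm_simpson_pvalue(member_codes, pool_codes, n_perm, rng)


def score_length_bias(
    group: SpecificityGroup,
    all_records: Sequence[ClonotypeRecord],
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> tuple[float, float]:
    """Simpson index over member CDR3 lengths and its permutation p-value."""
    if len(group.members) < 2:
        raise ValueError(f"group {group.group_id}: length bias undefined below 2 members")
    rng = np.random.default_rng(seed)
    member_codes = np.array([len(m.cdr3b_aa) for m in group.members])
    pool_codes = np.array([len(r.cdr3b_aa) for r in all_records])
    return _perm_simpson_pvalue(member_codes, pool_codes, n_perm, rng)


def score_expansion(
    group: SpecificityGroup,
    all_records: Sequence[ClonotypeRecord],
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> float:
    """Clonal-expansion p-value for a group.

    Observed statistic: total clone count over member records. Null: the
    summed count of a uniform draw (without replacement) of the same
    number of clonotype records from the whole dataset.
    """
    rng = np.random.default_rng(seed)
    counts = np.array([r.count for r in all_records], dtype=np.int64)
    observed = sum(m.count for m in group.members)
    if observed == 0:
        log.warning("group %s: all member counts zero; p_expansion = 1", group.group_id)
        return 1.0
    m = len(group.members)
    idx = _perm_index_draws(counts.size, m, n_perm, rng)
    sums = counts[idx].sum(axis=1)
    p = (1 + int(np.sum(sums >= observed))) / (n_perm + 1)
    return p


def score_hla_enrichment(
    group: SpecificityGroup,
    profiles: Mapping[str, PatientProfile],
) -> list[tuple[str, int, float]]:
    """One-sided Fisher enrichment per allele with >= 2 member carriers.

    Returns (allele, n member carrier patients, p) sorted by p. Member
    patients missing from ``profiles`` are dropped with a warning; an
    empty HLA table yields an empty list.
    """
    group_patients = sorted(group.patient_set)
    missing = [p for p in group_patients if p not in profiles]
    if missing:
        log.warning(
            "group %s: %d member patient(s) lack HLA profiles", group.group_id, len(missing)
        )
    group_patients = [p for p in group_patients if p in profiles]
    other_patients = [p for p in profiles if p not in set(group_patients)]
    if not profiles or not group_patients:
        return []

    allele_carriers: dict[str, int] = {}
    for p in group_patients:
        for allele in profiles[p].hla_alleles:
            allele_carriers[allele] = allele_carriers.get(allele, 0) + 1

    results = []
    n_in = len(group_patients)
    n_out = len(other_patients)
    for allele, a in allele_carriers.items():
        if a < 2:
            continue
        c = sum(1 for p in other_patients if allele in profiles[p].hla_alleles)
        table = [[a, n_in - a], [c, n_out - c]]
        _, p = fisher_exact(table, alternative="greater")
        results.append((allele, a, float(p)))
    results.sort(key=lambda t: (t[2], t[0]))
    return results


def score_groups(
    groups: Sequence[SpecificityGroup],
    all_records: Sequence[ClonotypeRecord],
    profiles: Mapping[str, PatientProfile] = None,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> list[SpecificityGroup]:
    """Fill every group's GroupScores in place (and return the list).

    Per-group seeds are spawned deterministically from ``seed`` so results
    do not depend on how many groups precede a given group.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(groups))
    for group, child in zip(groups, children):
        s0, s1, s2 = child.generate_state(3).tolist()
        simpson_v, p_v = score_vgene_bias(group, all_records, n_perm, s0)
        simpson_len, p_len = score_length_bias(group, all_records, n_perm, s1)
        p_exp = score_expansion(group, all_records, n_perm, s2)
        hla = score_hla_enrichment(group, profiles) if profiles else []
        group.scores = GroupScores(
            simpson_v=simpson_v,
            p_vbias=p_v,
            simpson_len=simpson_len,
            p_lenbias=p_len,
            p_expansion=p_exp,
            hla_enrichments=hla,
        )
    return list(groups)
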