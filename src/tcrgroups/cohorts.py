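"""Patient cohort stratification and repertoire diversity.

Patients are stratified by whether they carry at least one TCR in a
clonal-expanded (CE) group or a tumor-infiltrating (TI) group. TI groups
are a subset of CE groups, so carrying a TI TCR implies carrying a CE TCR
(a progressive relationship), and the five cohort views reduce to a
three-way partition TI / CE_nonTI / nonCE plus the complements nonTI and
nonCE.

Per-sample diversity is the Gini–Simpson index 1 - sum p_i^2 over
clonotype count frequencies, with clonotype identity
(cdr3b_aa, v_gene, j_gene).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import kruskal, mannwhitneyu

from .types import ClonotypeRecord, SpecificityGroup, ValidationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CohortAssignment:
    patient_id: str
    is_TI: bool
    is_CE: bool

    def __post_init__(self) -> None:
        if self.is_TI and not self.is_CE:
            raise ValidationError(
                f"patient {self.patient_id}: TI without CE violates the progressive relationship"
            )

    @property
    def label(self) -> str:
        if self.is_TI:
            return "TI"
        if self.is_CE:
            return "CE_nonTI"
        return "nonCE"


GroupsOrPatients = Iterable[Union[SpecificityGroup, frozenset, set]]


def _patient_union(groups: GroupsOrPatients) -> frozenset[str]:
    out: set[str] = set()
    for g in groups:
        out |= set(g.patient_set if isinstance(g, SpecificityGroup) else g)
    return frozenset(out)


def stratify_patients(
    all_patients: Iterable[str],
    ti_groups: GroupsOrPatients,
    ce_groups: GroupsOrPatients,
) -> list[CohortAssignment]:
    """Assign every patient a cohort from TI / CE group membership.

    ``ti_groups`` and ``ce_groups`` may be SpecificityGroups or plain
    patient-id sets. TI patients must be covered by the CE patient union
    (TI groups derive from CE groups) and by ``all_patients``.
    """
    patients = list(dict.fromkeys(all_patients))
    ti_patients = _patient_union(ti_groups)
    ce_patients = _patient_union(ce_groups)
    if not ti_patients <= ce_patients:
        raise ValidationError(
            "tumor-infiltrating patients are not a subset of clonal-expanded patients"
        )
    unknown = ce_patients - set(patients)
    if unknown:
        raise ValidationError(
            f"{len(unknown)} group patient(s) absent from the patient list, e.g. {sorted(unknown)[:3]}"
        )
    return [
        CohortAssignment(patient_id=p, is_TI=p in ti_patients, is_CE=p in ce_patients)
        for p in patients
    ]


def cohort_counts(assignments: Sequence[CohortAssignment]) -> dict[str, int]:
    """Counts of the five cohort views plus the total."""
    n_ti = sum(a.is_TI for a in assignments)
    n_ce = sum(a.is_CE for a in assignments)
    n = len(assignments)
    return {
        "n_total": n,
        "n_TI": n_ti,
        "n_nonTI": n - n_ti,
        "n_CE": n_ce,
        "n_nonCE": n - n_ce,
        "n_CE_nonTI": n_ce - n_ti,
    }


def gini_simpson(counts: Sequence[int]) -> float:
    """Gini–Simpson diversity 1 - sum (c_i / sum c)^2.

    0 for a monoclonal sample, approaching 1 - 1/n for n even clones.
    """
    arr = np.asarray(counts, dtype=float)
    if arr.size == 0 or np.any(arr < 0):
        raise ValueError("counts must be non-negative and non-empty")
    total = arr.sum()
    if total == 0:
        raise ValueError("gini_simpson undefined when all counts are zero")
    p = arr / total
    return float(1.0 - np.sum(p * p))


def diversity_by_sample(records: Sequence[ClonotypeRecord]) -> pd.DataFrame:
    """Per-sample Gini–Simpson diversity over clonotype count frequencies.

    Clonotype identity is (cdr3b_aa, v_gene, j_gene); counts of identical
    clonotypes within a sample are pooled before computing the index.
    """
    df = pd.DataFrame(
        [(r.sample_id, r.cdr3b_aa, r.v_gene, r.j_gene, r.count) for r in records],
        columns=["sample_id", "cdr3b_aa", "v_gene", "j_gene", "count"],
    )
    pooled = (
        df.groupby(["sample_id", "cdr3b_aa", "v_gene", "j_gene"], sort=True)["count"]
        .sum()
        .reset_index()
    )
    rows = []
    for sample_id, sub in pooled.groupby("sample_id", sort=True):
        counts = sub["count"].to_numpy()
        rows.append(
            {
                "sample_id": sample_id,
                "gini_simpson": gini_simpson(counts),
                "n_clonotypes": len(counts),
                "total_count": int(counts.sum()),
            }
        )
    return pd.DataFrame(rows, columns=["sample_id", "gini_simpson", "n_clonotypes", "total_count"])


def significance_stars(p: float) -> str:
    """Star convention: ns > 0.05 >= * > 0.01 >= ** > 0.001 >= *** > 1e-4 >= ****."""
    if p <= 1e-4:
        return "****"
    if p <= 1e-3:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def compare_strata(values_by_stratum: Mapping[str, Sequence[float]]) -> dict:
    """Kruskal–Wallis across strata plus pairwise two-sided rank-sum tests.

    Strata with fewer than 2 observations are skipped with a note. The
    exact rank-sum distribution is used where scipy can (no ties, small n).
    """
    usable = {k: np.asarray(v, dtype=float) for k, v in values_by_stratum.items() if len(v) >= 2}
    skipped = [k for k in values_by_stratum if k not in usable]
    report: dict = {"skipped": skipped, "pairwise": []}
    names = sorted(usable)
    if len(usable) >= 2 and any(
        not np.array_equal(usable[names[0]], usable[k]) for k in names[1:]
    ):
        stat, p = kruskal(*[usable[k] for k in names])
        report["kruskal"] = {"strata": names, "statistic": float(stat), "p": float(p)}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if np.array_equal(usable[a], usable[b]):
                stat, p = float("nan"), 1.0
            else:
                stat, p = mannwhitneyu(usable[a], usable[b], alternative="two-sided")
                stat, p = float(stat), float(p)
            report["pairwise"].append(
                {"a": a, "b": b, "statistic": stat, "p": p, "stars": significance_stars(p)}
            )
    return report


def compare_cohort_diversity(
    diversity: pd.DataFrame,
    assignments: Sequence[CohortAssignment],
    sample_to_patient: Mapping[str, str],
    grouping: str = "label",
) -> dict:
    """Compare per-sample diversity across patient cohorts.

    ``grouping``: "label" for the TI / CE_nonTI / nonCE partition,
    "TI" for TI vs nonTI, "CE" for CE vs nonCE.
    """
    by_patient = {a.patient_id: a for a in assignments}
    strata: dict[str, list[float]] = {}
    for row in diversity.itertuples():
        patient = sample_to_patient.get(row.sample_id)
        if patient is None or patient not in by_patient:
            continue
        a = by_patient[patient]
        if grouping == "label":
            key = a.label
        elif grouping == "TI":
            key = "TI" if a.is_TI else "nonTI"
        elif grouping == "CE":
            key = "CE" if a.is_CE else "nonCE"
        else:
            raise ValueError(f"unknown grouping {grouping!r}")
        strata.setdefault(key, []).append(row.gini_simpson)
    return compare_strata(strata)
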