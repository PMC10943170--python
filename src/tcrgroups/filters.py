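"""The group filtering cascade.

high-confidence (>=3 distinct CDR3s, >=3 distinct patients, significant
V-gene bias) → clonal-expanded (expansion score < 0.05) →
tumor-infiltrating (every member record from a tumor sample). Both
p-value thresholds are strict: a group sitting exactly at 0.05 is
dropped. Each filter only removes groups, so the three stages nest.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .types import SpecificityGroup, Tissue


@dataclass(frozen=True)
class FilterThresholds:
    min_distinct_cdr3: int = 3
    min_distinct_patients: int = 3
    max_p_vbias: float = 0.05
    max_p_expansion: float = 0.05

    def __post_init__(self) -> None:
        if self.min_distinct_cdr3 <= 0 or self.min_distinct_patients <= 0:
            raise ValueError("member/patient minima must be positive")
        if not (0 < self.max_p_vbias < 1) or not (0 < self.max_p_expansion < 1):
            raise ValueError("p-value thresholds must lie in (0, 1)")


def _require_scores(group: SpecificityGroup, fields: tuple[str, ...]) -> None:
    if group.scores is None or any(getattr(group.scores, f) is None for f in fields):
        raise ValueError(f"group {group.group_id} has not been scored")


def filter_high_confidence(
    groups: Sequence[SpecificityGroup],
    thresholds: FilterThresholds = FilterThresholds(),
) -> list[SpecificityGroup]:
    """Keep groups with enough distinct CDR3s/patients and V-bias p < threshold."""
    out = []
    for g in groups:
        _require_scores(g, ("p_vbias",))
        if (
            g.distinct_cdr3_count >= thresholds.min_distinct_cdr3
            and g.distinct_patient_count >= thresholds.min_distinct_patients
            and g.scores.p_vbias < thresholds.max_p_vbias
        ):
            out.append(g)
    return out


def filter_clonal_expanded(
    groups: Sequence[SpecificityGroup],
    thresholds: FilterThresholds = FilterThresholds(),
) -> list[SpecificityGroup]:
    """Keep groups with expansion score strictly below the threshold."""
    out = []
    for g in groups:
        _require_scores(g, ("p_expansion",))
        if g.scores.p_expansion < thresholds.max_p_expansion:
            out.append(g)
    return out


def filter_tumor_infiltrating(groups: Sequence[SpecificityGroup]) -> list[SpecificityGroup]:
    """Keep groups whose member records all come from tumor samples."""
    return [g for g in groups if g.members and all(m.tissue == Tissue.TUMOR for m in g.members)]


def summarize_pipeline(stages: dict[str, Sequence[SpecificityGroup]]) -> pd.DataFrame:
    """Stage-count report: groups, distinct CDR3s and distinct patients.

    ``stages`` maps stage name → group list, in pipeline order (insertion
    order is preserved in the output).
    """
    rows = []
    for name, groups in stages.items():
        cdr3s = set().union(*(g.cdr3_set for g in groups)) if groups else set()
        patients = set().union(*(g.patient_set for g in groups)) if groups else set()
        rows.append(
            {
                "stage": name,
                "n_groups": len(groups),
                "n_distinct_cdr3": len(cdr3s),
                "n_distinct_patients": len(patients),
            }
        )
    return pd.DataFrame(rows, columns=["stage", "n_groups", "n_distinct_cdr3", "n_distinct_patients"])
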