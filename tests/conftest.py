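from __future__ import annotations

import pytest

from tcrgroups.types import ClonotypeRecord, Tissue


@pytest.fixture
def rec():
    """Factory for clonotype records with sensible defaults."""

    def make(
        cdr3: str,
        v: str = "TRBV5-1",
        j: str = "TRBJ2-7",
        sample: str = "S1",
        patient: str = "P1",
        tissue: Tissue = Tissue.TUMOR,
        count: int = 1,
        productive: bool = True,
    ) -> ClonotypeRecord:
        return ClonotypeRecord(
            sample_id=sample,
            patient_id=patient,
            tissue=tissue,
            cdr3b_aa=cdr3,
            v_gene=v,
            j_gene=j,
            count=count,
            productive=productive,
        )

    return make
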