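"""Synthetic multi-patient repertoires with known ground truth.

The generator emulates the statistical structure the analysis assumes:
per-sample background clonotypes with a CASS...F junction scaffold and
random interiors, planted convergence groups that implant a shared
interior motif (and a shared V gene) into members spread over several
patients, tumor-restricted or tumor/NAT-shared placement, clonal
expansion via a count multiplier, and optional HLA restriction that
confines members to carrier patients. Every planted fact is recorded in
a truth ledger so recovery can be checked end to end.

All randomness flows from integer-seeded numpy generators; the same
config and seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import AA_ALPHABET, ClonotypeRecord, PatientProfile, TetramerRecord, Tissue
from . import io as rio

_AA = list(AA_ALPHABET)

DEFAULT_V_GENES = [
    "TRBV5-1", "TRBV7-9", "TRBV28", "TRBV10-2", "TRBV10-3", "TRBV7-8",
    "TRBV6-1", "TRBV19", "TRBV20-1", "TRBV27", "TRBV9", "TRBV2",
    "TRBV4-1", "TRBV12-3", "TRBV18",
]
DEFAULT_J_GENES = ["TRBJ2-7", "TRBJ2-1", "TRBJ1-4", "TRBJ1-1", "TRBJ2-3", "TRBJ1-2"]
CANCER_TYPES = ["ESCA", "STAD", "PAAD", "LIHC", "COAD", "READ"]

DEFAULT_HLA_POOL: dict[str, list[tuple[str, float]]] = {
    "A": [("A*02", 0.30), ("A*11", 0.15), ("A*24", 0.15), ("A*01", 0.10), ("A*03", 0.10)],
    "B": [("B*44", 0.15), ("B*35", 0.15), ("B*07", 0.15), ("B*08", 0.10), ("B*51", 0.10)],
    "C": [("C*07", 0.30), ("C*04", 0.20), ("C*06", 0.10)],
    "DQA1": [("DQA1*03", 0.25), ("DQA1*01", 0.30), ("DQA1*05", 0.20)],
    "DQB1": [("DQB1*03", 0.30), ("DQB1*06", 0.25), ("DQB1*02", 0.20)],
    "DRB1": [("DRB1*13", 0.15), ("DRB1*07", 0.20), ("DRB1*15", 0.20), ("DRB1*04", 0.15)],
}

DEFAULT_SUBTYPES = [("CIN", 0.25), ("GS", 0.20), ("MSI", 0.20), ("EBV+", 0.15)]
DEFAULT_MUTATIONS = [("TP53", 0.40), ("TTN", 0.35), ("MUC16", 0.30), ("KRAS", 0.25), ("CSMD3", 0.20)]

ANTIGEN_SOURCES = ["EBV", "CMV", "influenza", "SARS-CoV-2", "homo"]


@dataclass
class PlantedGroupSpec:
    """One planted convergence group: what is implanted and where."""

    name: str
    motif: Optional[str] = None  # 4-mer; drawn at random when None
    n_members: int = 6
    n_patients: int = 4
    tissue: str = "TUMOR_ONLY"  # or "SHARED"
    expansion: float = 10.0  # count multiplier for member clonotypes
    hla_allele: Optional[str] = None  # members confined to carriers when set


def default_planted() -> list[PlantedGroupSpec]:
    """The study conditions: expanded tumor-restricted groups (one
    HLA-restricted), an expanded shared group, and two unexpanded
    controls for the expansion-score null."""
    return [
        PlantedGroupSpec(name="G1", tissue="TUMOR_ONLY", expansion=10.0),
        PlantedGroupSpec(name="G2", tissue="TUMOR_ONLY", expansion=10.0, hla_allele="A*11"),
        PlantedGroupSpec(name="G3", tissue="SHARED", expansion=10.0),
        PlantedGroupSpec(name="G4", tissue="TUMOR_ONLY", expansion=1.0),
        PlantedGroupSpec(name="G5", tissue="SHARED", expansion=1.0),
    ]


@dataclass
class SimConfig:
    """Cohort-generation parameters (defaults define the study conditions)."""

    n_patients: int = 20
    nat_fraction: float = 0.25  # fraction of patients with an additional NAT sample
    background_mean: float = 30.0  # Poisson mean clonotypes per sample
    planted: list[PlantedGroupSpec] = field(default_factory=default_planted)
    hla_pool: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_HLA_POOL.items()})
    subtypes: list = field(default_factory=lambda: list(DEFAULT_SUBTYPES))
    mutations: list = field(default_factory=lambda: list(DEFAULT_MUTATIONS))
    reference_size: int = 2000
    min_len: int = 11
    max_len: int = 17
    v_genes: list = field(default_factory=lambda: list(DEFAULT_V_GENES))
    j_genes: list = field(default_factory=lambda: list(DEFAULT_J_GENES))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0 or self.background_mean <= 0 or self.reference_size <= 0:
            raise ValueError("counts must be positive")
        for locus, pool in self.hla_pool.items():
            if sum(f for _, f in pool) > 1 + 1e-9:
                raise ValueError(f"HLA frequencies for locus {locus} sum above 1")


def _random_cdr3(rng: np.random.Generator, min_len: int, max_len: int) -> str:
    length = int(rng.integers(min_len, max_len + 1))
    core = "".join(rng.choice(_AA, size=length - 5))
    return "CASS" + core + "F"


def _cdr3_with_motif(rng: np.random.Generator, motif: str) -> str:
    # interior spans positions 4 .. L-2; length chosen so the motif fits
    length = int(rng.integers(max(12, len(motif) + 7), 17))
    core_len = length - 5
    offset = int(rng.integers(0, core_len - len(motif) + 1))
    core = "".join(rng.choice(_AA, size=core_len))
    core = core[:offset] + motif + core[offset + len(motif) :]
    return "CASS" + core + "F"


def generate_cohort(
    config: SimConfig,
) -> tuple[list[ClonotypeRecord], dict[str, PatientProfile], dict]:
    """Generate (records, profiles, truth ledger) for one synthetic cohort."""
    rng = np.random.default_rng(config.seed)
    patients = [f"P{i:03d}" for i in range(1, config.n_patients + 1)]
    n_nat = max(1, round(config.nat_fraction * config.n_patients))
    nat_patients = list(rng.choice(patients, size=n_nat, replace=False))

    samples: dict[str, tuple[str, Tissue]] = {}
    for p in patients:
        samples[f"{p}_T"] = (p, Tissue.TUMOR)
    for p in nat_patients:
        samples[f"{p}_N"] = (p, Tissue.NAT)

    # HLA: one categorical draw per locus; remainder of the frequency mass
    # means no call at that locus
    hla: dict[str, set[str]] = {p: set() for p in patients}
    for locus, pool in sorted(config.hla_pool.items()):
        alleles = [a for a, _ in pool] + [""]
        freqs = [f for _, f in pool]
        probs = freqs + [max(0.0, 1.0 - sum(freqs))]
        draws = rng.choice(alleles, size=len(patients), p=np.array(probs) / sum(probs))
        for p, a in zip(patients, draws):
            if a:
                hla[p].add(str(a))

    subtype_names = [s for s, _ in config.subtypes] + [""]
    subtype_probs = [f for _, f in config.subtypes]
    subtype_probs = subtype_probs + [max(0.0, 1.0 - sum(subtype_probs))]
    subtype_draws = rng.choice(
        subtype_names, size=len(patients), p=np.array(subtype_probs) / sum(subtype_probs)
    )
    subtypes = {p: (str(s) or None) for p, s in zip(patients, subtype_draws)}
    mutations: dict[str, set[str]] = {p: set() for p in patients}
    for gene, prev in config.mutations:
        hits = rng.random(len(patients)) < prev
        for p, h in zip(patients, hits):
            if h:
                mutations[p].add(gene)
    cancer = {p: CANCER_TYPES[i % len(CANCER_TYPES)] for i, p in enumerate(patients)}

    records: list[ClonotypeRecord] = []
    for sample_id in sorted(samples):
        patient, tissue = samples[sample_id]
        n_bg = max(1, int(rng.poisson(config.background_mean)))
        for _ in range(n_bg):
            records.append(
                ClonotypeRecord(
                    sample_id=sample_id,
                    patient_id=patient,
                    tissue=tissue,
                    cdr3b_aa=_random_cdr3(rng, config.min_len, config.max_len),
                    v_gene=str(rng.choice(config.v_genes)),
                    j_gene=str(rng.choice(config.j_genes)),
                    count=int(rng.geometric(0.6)),
                )
            )

    truth_groups = []
    used_motifs: set[str] = set()
    for spec in config.planted:
        motif = spec.motif
        while motif is None or motif in used_motifs:
            motif = "".join(rng.choice(_AA, size=4))
        used_motifs.add(motif)

        if spec.hla_allele is not None:
            carrier_pool = patients
            group_patients = list(rng.choice(carrier_pool, size=spec.n_patients, replace=False))
            for p in group_patients:
                hla[p].add(spec.hla_allele)  # force carrier status; recorded in truth
        elif spec.tissue == "SHARED":
            if spec.n_patients > len(patients):
                raise ValueError(f"group {spec.name} demands more patients than exist")
            # guarantee at least one chosen patient has a NAT sample
            first = rng.choice(nat_patients)
            rest = [p for p in patients if p != first]
            group_patients = [str(first)] + list(
                rng.choice(rest, size=spec.n_patients - 1, replace=False)
            )
        else:
            group_patients = list(rng.choice(patients, size=spec.n_patients, replace=False))
        if spec.n_patients > len(patients):
            raise ValueError(f"group {spec.name} demands more patients than exist")

        v_gene = str(rng.choice(config.v_genes))
        member_seqs: list[str] = []
        member_rows = []
        for i in range(spec.n_members):
            patient = str(group_patients[i % len(group_patients)])
            if spec.tissue == "SHARED" and i == 0:
                sample_id, tissue = f"{patient}_N", Tissue.NAT
            else:
                sample_id, tissue = f"{patient}_T", Tissue.TUMOR
            seq = _cdr3_with_motif(rng, motif)
            while seq in member_seqs:
                seq = _cdr3_with_motif(rng, motif)
            member_seqs.append(seq)
            count = max(1, int(round(int(rng.geometric(0.6)) * spec.expansion)))
            rec = ClonotypeRecord(
                sample_id=sample_id,
                patient_id=patient,
                tissue=tissue,
                cdr3b_aa=seq,
                v_gene=v_gene,
                j_gene=str(rng.choice(config.j_genes)),
                count=count,
            )
            records.append(rec)
            member_rows.append(rec)
        truth_groups.append(
            {
                "name": spec.name,
                "motif": motif,
                "v_gene": v_gene,
                "members": member_seqs,
                "patients": sorted(set(r.patient_id for r in member_rows)),
                "tissue": spec.tissue,
                "expansion": spec.expansion,
                "hla_allele": spec.hla_allele,
            }
        )

    profiles = {
        p: PatientProfile(
            patient_id=p,
            hla_alleles=frozenset(hla[p]),
            subtype=subtypes[p],
            mutations=frozenset(mutations[p]),
            cancer_type=cancer[p],
        )
        for p in patients
    }
    truth = {
        "seed": config.seed,
        "patients": patients,
        "nat_patients": sorted(nat_patients),
        "groups": truth_groups,
    }
    return records, profiles, truth


def generate_reference(config: SimConfig, size: Optional[int] = None) -> list[str]:
    """Background CDR3 sequences without planted motifs (reference repertoire).

    Uses a stream independent of the cohort's so reference and cohort can
    be generated in either order.
    """
    rng = np.random.default_rng([config.seed, 1])
    n = size if size is not None else config.reference_size
    return [_random_cdr3(rng, config.min_len, config.max_len) for _ in range(n)]


def generate_tetramer_db(
    config: SimConfig,
    truth: dict,
    groups_to_cover: Optional[Sequence[str]] = None,
    n_decoys: int = 20,
) -> list[TetramerRecord]:
    """Tetramer entries covering planted-group member CDR3s, plus decoys.

    Antigen sources cycle through the standard panel; the MHC allele is
    the group's restricting allele when planted, otherwise a class-I draw.
    Decoys are random CDR3s guaranteed to match no planted member.
    """
    rng = np.random.default_rng([config.seed, 2])
    class_i = [a for locus in ("A", "B") for a, _ in config.hla_pool.get(locus, [])]
    planted_members = {s for g in truth["groups"] for s in g["members"]}
    entries: list[TetramerRecord] = []
    for i, g in enumerate(truth["groups"]):
        if groups_to_cover is not None and g["name"] not in groups_to_cover:
            continue
        source = ANTIGEN_SOURCES[i % len(ANTIGEN_SOURCES)]
        mhc = g["hla_allele"] or str(rng.choice(class_i))
        cdr3 = g["members"][int(rng.integers(0, len(g["members"])))]
        epitope = "".join(rng.choice(_AA, size=9))
        entries.append(
            TetramerRecord(cdr3b_aa=cdr3, epitope=epitope, antigen_source=source, mhc_allele=mhc)
        )
    for _ in range(n_decoys):
        seq = _random_cdr3(rng, config.min_len, config.max_len)
        while seq in planted_members:
            seq = _random_cdr3(rng, config.min_len, config.max_len)
        entries.append(
            TetramerRecord(
                cdr3b_aa=seq,
                epitope="".join(rng.choice(_AA, size=9)),
                antigen_source=str(rng.choice(ANTIGEN_SOURCES)),
                mhc_allele=str(rng.choice(class_i)),
            )
        )
    return entries


def write_cohort(
    outdir: Path,
    config: SimConfig,
    records: Sequence[ClonotypeRecord],
    profiles: dict[str, PatientProfile],
    truth: dict,
    reference: Sequence[str],
    tetramers: Sequence[TetramerRecord],
) -> None:
    """Write a generated cohort in the TSV dialects the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rio.write_clonotypes(list(records), outdir / "clonotypes.tsv")

    sample_rows = sorted({(r.sample_id, r.patient_id, r.tissue.value) for r in records})
    pd.DataFrame(
        [
            (s, p, t, profiles[p].cancer_type or "")
            for s, p, t in sample_rows
        ],
        columns=["sample_id", "patient_id", "tissue", "cancer_type"],
    ).to_csv(outdir / "sample_meta.tsv", sep="\t", index=False)

    hla_rows = []
    for p in sorted(profiles):
        for allele in sorted(profiles[p].hla_alleles):
            locus = allele.split("*")[0]
            hla_rows.append((p, locus, allele, "pass"))
    pd.DataFrame(hla_rows, columns=["patient_id", "locus", "allele", "qual"]).to_csv(
        outdir / "hla.tsv", sep="\t", index=False
    )

    meta_rows = []
    for p in sorted(profiles):
        if profiles[p].subtype:
            meta_rows.append((p, "SUBTYPE", profiles[p].subtype))
        for gene in sorted(profiles[p].mutations):
            meta_rows.append((p, "MUTATION", gene))
    pd.DataFrame(meta_rows, columns=["patient_id", "kind", "value"]).to_csv(
        outdir / "metadata.tsv", sep="\t", index=False
    )

    pd.DataFrame(
        [(t.cdr3b_aa, t.epitope, t.antigen_source, t.mhc_allele) for t in tetramers],
        columns=["cdr3", "antigen.epitope", "antigen.species", "mhc.a"],
    ).to_csv(outdir / "tetramer.tsv", sep="\t", index=False)

    (outdir / "reference.txt").write_text("\n".join(reference) + "\n")
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    (outdir / "sim_config.json").write_text(
        json.dumps(asdict(config), indent=2, sort_keys=True, default=str) + "\n"
    )
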