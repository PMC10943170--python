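"""Readers and writers for the standard TSV dialects the pipeline consumes.

Supported inputs: AIRR Rearrangement TSV, TRUST4 ``report`` TSV, a
sample-metadata TSV (sample_id, patient_id, tissue, cancer_type), an HLA
call TSV (patient_id, locus, allele, qual), a patient-metadata TSV
(patient_id, kind, value) and a tetramer reference TSV in VDJdb-export
layout (cdr3, antigen.epitope, antigen.species, mhc.a).

All readers return plain domain objects; the canonical clonotype TSV
written by :func:`write_clonotypes` round-trips exactly through
:func:`read_clonotypes`.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd

from .types import (
    ClonotypeRecord,
    FormatError,
    PatientProfile,
    TetramerRecord,
    Tissue,
    ValidationError,
    is_valid_cdr3,
    normalize_allele,
)

log = logging.getLogger(__name__)

PathLike = Union[str, Path]

#: canonical clonotype table columns (stable external layout)
CLONOTYPE_COLUMNS = [
    "sample_id",
    "patient_id",
    "tissue",
    "cdr3b_aa",
    "v_gene",
    "j_gene",
    "count",
    "productive",
]

_QUAL_RANK = {"pass": 0, "ambiguous": 1, "low coverage": 2, "low_coverage": 2}


def read_sample_meta(path: PathLike) -> pd.DataFrame:
    """Read the sample-metadata TSV mapping samples to patients and tissues."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "patient_id", "tissue"):
        if col not in df.columns:
            raise FormatError(f"sample metadata is missing column {col!r}")
    return df


def _meta_lookup(sample_meta: Union[pd.DataFrame, Mapping[str, tuple]]) -> dict:
    if isinstance(sample_meta, pd.DataFrame):
        return {
            row.sample_id: (row.patient_id, Tissue(row.tissue))
            for row in sample_meta.itertuples()
        }
    return {k: (v[0], Tissue(v[1])) for k, v in sample_meta.items()}


def read_airr(path: PathLike, sample_meta: Union[pd.DataFrame, Mapping]) -> list[ClonotypeRecord]:
    """Read an AIRR Rearrangement TSV into clonotype records.

    Requires ``junction_aa``, ``v_call`` and ``j_call``; the sample is taken
    from a ``sample_id`` (or ``repertoire_id``) column and joined against
    ``sample_meta`` for patient and tissue. Rows with an empty junction are
    skipped and counted.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("junction_aa", "v_call", "j_call"):
        if col not in df.columns:
            raise FormatError(f"AIRR file {path} is missing mandatory column {col!r}")
    sample_col = "sample_id" if "sample_id" in df.columns else "repertoire_id"
    if sample_col not in df.columns:
        raise FormatError(f"AIRR file {path} has no sample_id/repertoire_id column")
    lookup = _meta_lookup(sample_meta)

    records: list[ClonotypeRecord] = []
    n_skipped = 0
    for row in df.itertuples():
        junction = getattr(row, "junction_aa")
        if not isinstance(junction, str) or not junction:
            n_skipped += 1
            continue
        sample = getattr(row, sample_col)
        if sample not in lookup:
            raise ValidationError(f"sample {sample!r} absent from sample metadata")
        patient, tissue = lookup[sample]
        count = getattr(row, "duplicate_count", None)
        count = int(count) if isinstance(count, str) and count.isdigit() else 1
        productive = str(getattr(row, "productive", "T")).upper() in ("T", "TRUE", "1")
        records.append(
            ClonotypeRecord(
                sample_id=sample,
                patient_id=patient,
                tissue=tissue,
                cdr3b_aa=junction,
                v_gene=getattr(row, "v_call"),
                j_gene=getattr(row, "j_call"),
                count=count,
                productive=productive,
            )
        )
    if n_skipped:
        log.warning("read_airr: skipped %d rows without junction_aa", n_skipped)
    return records


def read_trust4_report(
    path: PathLike,
    sample_id: str,
    sample_meta: Union[pd.DataFrame, Mapping],
) -> list[ClonotypeRecord]:
    """Read a TRUST4 per-sample ``report`` TSV, keeping TRB chains only.

    A row is TRB when its V (or, lacking a V call, its J) gene begins with
    TRBV/TRBJ. ``out_of_frame`` CDR3s and sequences with non-alphabet
    characters are kept but flagged nonproductive.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.lstrip("#") for c in df.columns]
    required = {"count", "CDR3aa", "V", "J"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path} does not look like a TRUST4 report (missing {sorted(required - set(df.columns))})"
        )
    lookup = _meta_lookup(sample_meta)
    if sample_id not in lookup:
        raise ValidationError(f"sample {sample_id!r} absent from sample metadata")
    patient, tissue = lookup[sample_id]

    records: list[ClonotypeRecord] = []
    for row in df.itertuples():
        v = row.V if isinstance(row.V, str) else ""
        j = row.J if isinstance(row.J, str) else ""
        if v.startswith("TRBV") or (v in ("", "*", ".") and j.startswith("TRBJ")):
            cdr3 = row.CDR3aa if isinstance(row.CDR3aa, str) else ""
            productive = is_valid_cdr3(cdr3, min_length=1) and cdr3 != "out_of_frame"
            records.append(
                ClonotypeRecord(
                    sample_id=sample_id,
                    patient_id=patient,
                    tissue=tissue,
                    cdr3b_aa=cdr3,
                    v_gene=v,
                    j_gene=j,
                    count=int(float(row.count)),
                    productive=productive,
                )
            )
    return records


def filter_productive(
    records: Iterable[ClonotypeRecord], min_length: int = 6
) -> list[ClonotypeRecord]:
    """Keep productive records with an alphabet-valid CDR3 of ``min_length``+.

    Idempotent and order-preserving. The minimum length guarantees a
    non-empty interior after flank trimming.
    """
    return [
        r
        for r in records
        if r.productive and is_valid_cdr3(r.cdr3b_aa, min_length=min_length)
    ]


def read_hla(path: PathLike) -> dict[str, frozenset[str]]:
    """Read HLA calls, resolving per-(patient, locus) conflicts by quality.

    Quality ranks ``pass > ambiguous > low coverage``; ties are broken by
    first occurrence (logged). Alleles are normalized to two-field
    resolution. Returns patient_id → frozenset of alleles.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("patient_id", "locus", "allele", "qual"):
        if col not in df.columns:
            raise FormatError(f"HLA table is missing column {col!r}")
    bad = set(df["qual"]) - set(_QUAL_RANK)
    if bad:
        raise ValidationError(f"unknown qual token(s): {sorted(bad)}")

    best: dict[tuple[str, str], tuple[int, str]] = {}
    for row in df.itertuples():
        key = (row.patient_id, row.locus)
        rank = _QUAL_RANK[row.qual]
        allele = normalize_allele(row.allele)
        if key not in best:
            best[key] = (rank, allele)
        elif rank < best[key][0]:
            best[key] = (rank, allele)
        elif rank == best[key][0] and allele != best[key][1]:
            log.warning(
                "read_hla: conflicting %s calls for patient %s locus %s; keeping first (%s)",
                row.qual, key[0], key[1], best[key][1],
            )
    out: dict[str, set[str]] = {}
    for (patient, _locus), (_rank, allele) in best.items():
        out.setdefault(patient, set()).add(allele)
    return {p: frozenset(a) for p, a in out.items()}


def read_patient_metadata(path: PathLike) -> tuple[dict[str, str], dict[str, frozenset[str]]]:
    """Read the categorical metadata TSV (patient_id, kind, value).

    ``kind`` is SUBTYPE or MUTATION; at most one subtype per patient
    (violation → error). Returns (subtype map, mutation-set map).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("patient_id", "kind", "value"):
        if col not in df.columns:
            raise FormatError(f"patient metadata is missing column {col!r}")
    subtypes: dict[str, str] = {}
    mutations: dict[str, set[str]] = {}
    for row in df.itertuples():
        if row.kind == "SUBTYPE":
            if row.patient_id in subtypes and subtypes[row.patient_id] != row.value:
                raise ValidationError(f"patient {row.patient_id} has two subtypes")
            subtypes[row.patient_id] = row.value
        elif row.kind == "MUTATION":
            mutations.setdefault(row.patient_id, set()).add(row.value)
        else:
            raise ValidationError(f"unknown metadata kind {row.kind!r}")
    return subtypes, {p: frozenset(m) for p, m in mutations.items()}


def build_profiles(
    patient_ids: Iterable[str],
    hla: Mapping[str, frozenset[str]] = None,
    subtypes: Mapping[str, str] = None,
    mutations: Mapping[str, frozenset[str]] = None,
    cancer_types: Mapping[str, str] = None,
) -> dict[str, PatientProfile]:
    """Assemble PatientProfiles from the individually read tables."""
    hla = hla or {}
    subtypes = subtypes or {}
    mutations = mutations or {}
    cancer_types = cancer_types or {}
    return {
        p: PatientProfile(
            patient_id=p,
            hla_alleles=hla.get(p, frozenset()),
            subtype=subtypes.get(p),
            mutations=mutations.get(p, frozenset()),
            cancer_type=cancer_types.get(p),
        )
        for p in patient_ids
    }


def read_tetramer_db(path: PathLike) -> list[TetramerRecord]:
    """Read a tetramer reference TSV in VDJdb-export layout."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("cdr3", "antigen.epitope", "antigen.species", "mhc.a"):
        if col not in df.columns:
            raise FormatError(f"tetramer table is missing column {col!r}")
    return [
        TetramerRecord(
            cdr3b_aa=row[0], epitope=row[1], antigen_source=row[2], mhc_allele=row[3]
        )
        for row in df[["cdr3", "antigen.epitope", "antigen.species", "mhc.a"]].itertuples(
            index=False
        )
    ]


GROUP_TABLE_COLUMNS = [
    "group_id", "method", "pattern", "cdr3b", "v", "j", "sample", "patient", "tissue", "count",
]


def write_group_table(groups: Sequence, path: PathLike) -> None:
    """Write groups as the stable one-row-per-member TSV layout."""
    rows = []
    for g in groups:
        for m in g.members:
            rows.append(
                (g.group_id, g.method, g.pattern, m.cdr3b_aa, m.v_gene, m.j_gene,
                 m.sample_id, m.patient_id, m.tissue.value, m.count)
            )
    pd.DataFrame(rows, columns=GROUP_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_group_table(path: PathLike) -> list:
    """Read a group-table TSV back into SpecificityGroups (unscored)."""
    from .types import SpecificityGroup

    df = pd.read_csv(path, sep="\t", dtype={c: str for c in GROUP_TABLE_COLUMNS[:-1]})
    missing = set(GROUP_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"group table is missing columns {sorted(missing)}")
    groups: dict[str, SpecificityGroup] = {}
    for row in df.itertuples():
        g = groups.get(row.group_id)
        if g is None:
            g = groups[row.group_id] = SpecificityGroup(
                group_id=row.group_id, method=row.method, pattern=row.pattern
            )
        g.members.append(
            ClonotypeRecord(
                sample_id=row.sample,
                patient_id=row.patient,
                tissue=Tissue(row.tissue),
                cdr3b_aa=row.cdr3b,
                v_gene=row.v,
                j_gene=row.j,
                count=int(row.count),
            )
        )
    return list(groups.values())


def write_group_scores(groups: Sequence, scores_path: PathLike, hla_path: PathLike = None) -> None:
    """Write the group-score TSV (and optionally the HLA-enrichment TSV)."""
    rows = []
    hla_rows = []
    for g in groups:
        s = g.scores
        if s is None:
            raise ValueError(f"group {g.group_id} has no scores to write")
        rows.append(
            (g.group_id, s.simpson_v, s.p_vbias, s.simpson_len, s.p_lenbias, s.p_expansion)
        )
        for allele, n_carriers, p in s.hla_enrichments:
            hla_rows.append((g.group_id, allele, n_carriers, p))
    pd.DataFrame(
        rows,
        columns=["group_id", "simpson_v", "p_vbias", "simpson_len", "p_lenbias", "p_expansion"],
    ).to_csv(scores_path, sep="\t", index=False)
    if hla_path is not None:
        pd.DataFrame(hla_rows, columns=["group_id", "allele", "n_carriers", "p_hla"]).to_csv(
            hla_path, sep="\t", index=False
        )


def attach_scores(groups: Sequence, scores_path: PathLike, hla_path: PathLike = None) -> None:
    """Attach scores from the score TSVs to groups in place."""
    from .types import GroupScores

    df = pd.read_csv(scores_path, sep="\t")
    by_id = {row.group_id: row for row in df.itertuples()}
    hla_by_id: dict[str, list[tuple[str, int, float]]] = {}
    if hla_path is not None and Path(hla_path).exists():
        hdf = pd.read_csv(hla_path, sep="\t")
        for row in hdf.itertuples():
            hla_by_id.setdefault(row.group_id, []).append(
                (row.allele, int(row.n_carriers), float(row.p_hla))
            )
    for g in groups:
        row = by_id.get(g.group_id)
        if row is None:
            continue
        g.scores = GroupScores(
            simpson_v=float(row.simpson_v),
            p_vbias=float(row.p_vbias),
            simpson_len=float(row.simpson_len),
            p_lenbias=float(row.p_lenbias),
            p_expansion=float(row.p_expansion),
            hla_enrichments=hla_by_id.get(g.group_id, []),
        )


def write_clonotypes(records: Sequence[ClonotypeRecord], path: PathLike) -> None:
    """Write records to the canonical clonotype TSV (round-trip stable)."""
    df = pd.DataFrame(
        [
            (
                r.sample_id,
                r.patient_id,
                r.tissue.value,
                r.cdr3b_aa,
                r.v_gene,
                r.j_gene,
                r.count,
                r.productive,
            )
            for r in records
        ],
        columns=CLONOTYPE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_clonotypes(path: PathLike) -> list[ClonotypeRecord]:
    """Read the canonical clonotype TSV written by :func:`write_clonotypes`."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={c: str for c in CLONOTYPE_COLUMNS[:-2]},
    )
    missing = set(CLONOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"clonotype table is missing columns {sorted(missing)}")
    return [
        ClonotypeRecord(
            sample_id=row.sample_id,
            patient_id=row.patient_id,
            tissue=Tissue(row.tissue),
            cdr3b_aa=row.cdr3b_aa,
            v_gene=row.v_gene,
            j_gene=row.j_gene,
            count=int(row.count),
            productive=bool(row.productive),
        )
        for row in df.itertuples()
    ]
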