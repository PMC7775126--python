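"""Cohort table IO and mutation-load accounting.

Readers and writers for the tab-delimited cohort tables (MAF-like somatic
mutation table, clinical table, expression matrix), the controlled
variant-classification vocabulary, and per-sample mutation-load summaries.

Coordinates are 1-based inclusive throughout (MAF convention), in readers
and writers alike.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VARIANT_CLASSIFICATIONS",
    "NON_NEUTRAL_CLASSES",
    "MutationRecord",
    "ClinicalRecord",
    "LoadSummary",
    "read_mutations",
    "write_mutations",
    "read_clinical",
    "write_clinical",
    "read_expression",
    "write_expression",
    "is_non_neutral",
    "load_summary",
]

#: Controlled vocabulary of variant classifications (MAF dialect).
VARIANT_CLASSIFICATIONS = frozenset(
    {
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Splice_Site",
        "Silent",
        "Intron",
        "3'UTR",
        "5'UTR",
        "5'Flank",
        "IGR",
        "RNA",
        "Translation_Start_Site",
        "De_novo_Start",
    }
)

#: The eight classes counted as non-neutral (coding, protein-changing) in
#: load summaries and recurrence discovery.
NON_NEUTRAL_CLASSES = frozenset(
    {
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Splice_Site",
    }
)

VARIANT_TYPES = frozenset({"SNP", "INS", "DEL"})

_BASES = frozenset("ACGT")

#: Fallback classification used in lenient mode for unknown labels.
LENIENT_FALLBACK = "RNA"

MUTATION_COLUMNS = [
    "sample_id",
    "gene",
    "chrom",
    "pos",
    "ref",
    "alt",
    "variant_type",
    "variant_classification",
    "protein_change",
    "context3",
]


@dataclass(frozen=True)
class MutationRecord:
    """One somatic SNV or small indel call.

    ``pos`` is 1-based; for indels ``ref`` or ``alt`` may be ``-``.
    ``context3`` is the trinucleotide reference context centred on ``pos``
    (SNVs only), as written by the annotation step; it is consumed, never
    computed from a reference genome.
    """

    sample_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_type: str
    variant_classification: str
    protein_change: str | None = None
    context3: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.variant_type not in VARIANT_TYPES:
            raise ValueError(f"unknown variant_type: {self.variant_type!r}")
        if self.variant_classification not in VARIANT_CLASSIFICATIONS:
            raise ValueError(
                f"unknown variant_classification: {self.variant_classification!r}"
            )
        if self.variant_type == "SNP":
            if len(self.ref) != 1 or len(self.alt) != 1:
                raise ValueError("SNP must have single-base ref and alt")
            if self.ref == self.alt:
                raise ValueError("SNP ref equals alt")
            if self.ref not in _BASES or self.alt not in _BASES:
                raise ValueError(f"non-ACGT SNP alleles: {self.ref}>{self.alt}")


@dataclass(frozen=True)
class ClinicalRecord:
    """Per-patient clinical annotation."""

    sample_id: str
    localization: str  # tarsal | bulbar
    origin: str | None = None  # PAM/C-MIN | nevus | de novo
    lymph_invasion: bool | None = None
    thickness_mm: float | None = None
    pigmentation: int | None = None
    recurrence: bool | None = None
    metastasis: bool | None = None
    death: bool | None = None

    def __post_init__(self) -> None:
        if self.localization not in ("tarsal", "bulbar"):
            raise ValueError(f"unknown localization: {self.localization!r}")
        if self.pigmentation is not None and self.pigmentation not in (0, 1, 2, 3):
            raise ValueError(f"pigmentation must be 0-3, got {self.pigmentation}")
        if self.thickness_mm is not None and self.thickness_mm <= 0:
            raise ValueError("thickness_mm must be positive")


@dataclass
class LoadSummary:
    """Per-sample and cohort mutation-load statistics.

    ``per_sample`` has one row per sample with columns ``n_snv``,
    ``n_indel``, ``n_non_neutral``; ``cohort`` holds mean/median/min/max
    for each of the three counts.
    """

    per_sample: pd.DataFrame
    cohort: pd.DataFrame

    def __post_init__(self) -> None:
        bad = self.per_sample.query("n_non_neutral > n_snv + n_indel")
        if len(bad):
            raise ValueError("n_non_neutral exceeds total count for some samples")


# ---------------------------------------------------------------------------
# readers / writers


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")


def read_mutations(path, lenient: bool = False) -> list[MutationRecord]:
    """Read a MAF-like tab-delimited mutation table.

    Rows with classifications outside the controlled vocabulary are rejected
    with their row number, unless ``lenient`` is set, in which case they are
    mapped to ``RNA`` (a neutral class) and kept.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(
        df,
        ["sample_id", "gene", "chrom", "pos", "ref", "alt", "variant_type",
         "variant_classification"],
        path,
    )
    records: list[MutationRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        vc = row.variant_classification
        if vc not in VARIANT_CLASSIFICATIONS:
            if lenient:
                vc = LENIENT_FALLBACK
            else:
                raise ValueError(
                    f"{path}: row {i}: unknown variant_classification {row.variant_classification!r}"
                )
        try:
            pos = int(row.pos)
        except ValueError as e:
            raise ValueError(f"{path}: row {i}: malformed position {row.pos!r}") from e
        try:
            rec = MutationRecord(
                sample_id=row.sample_id,
                gene=row.gene,
                chrom=row.chrom,
                pos=pos,
                ref=row.ref,
                alt=row.alt,
                variant_type=row.variant_type,
                variant_classification=vc,
                protein_change=getattr(row, "protein_change", "") or None,
                context3=getattr(row, "context3", "") or None,
            )
        except ValueError as e:
            raise ValueError(f"{path}: row {i}: {e}") from e
        records.append(rec)
    return records


def write_mutations(records: Iterable[MutationRecord], path) -> None:
    """Write records as a MAF-like TSV (1-based inclusive positions)."""
    rows = [
        {
            "sample_id": r.sample_id,
            "gene": r.gene,
            "chrom": r.chrom,
            "pos": r.pos,
            "ref": r.ref,
            "alt": r.alt,
            "variant_type": r.variant_type,
            "variant_classification": r.variant_classification,
            "protein_change": r.protein_change or "",
            "context3": r.context3 or "",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=MUTATION_COLUMNS).to_csv(path, sep="\t", index=False)


_BOOL_MAP = {"True": True, "False": False, "1": True, "0": False, "": None}


def read_clinical(path) -> list[ClinicalRecord]:
    """Read the per-patient clinical TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ["sample_id", "localization"], path)
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        def _bool(name):
            v = getattr(row, name, "")
            if v not in _BOOL_MAP:
                raise ValueError(f"{path}: row {i}: bad boolean {name}={v!r}")
            return _BOOL_MAP[v]

        out.append(
            ClinicalRecord(
                sample_id=row.sample_id,
                localization=row.localization,
                origin=getattr(row, "origin", "") or None,
                lymph_invasion=_bool("lymph_invasion"),
                thickness_mm=float(row.thickness_mm) if getattr(row, "thickness_mm", "") else None,
                pigmentation=int(row.pigmentation) if getattr(row, "pigmentation", "") else None,
                recurrence=_bool("recurrence"),
                metastasis=_bool("metastasis"),
                death=_bool("death"),
            )
        )
    return out


def write_clinical(records: Iterable[ClinicalRecord], path) -> None:
    def _s(v):
        return "" if v is None else v

    rows = [
        {
            "sample_id": r.sample_id,
            "localization": r.localization,
            "origin": _s(r.origin),
            "lymph_invasion": _s(r.lymph_invasion),
            "thickness_mm": _s(r.thickness_mm),
            "pigmentation": _s(r.pigmentation),
            "recurrence": _s(r.recurrence),
            "metastasis": _s(r.metastasis),
            "death": _s(r.death),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_expression(path) -> pd.DataFrame:
    """Read a gene x sample expression TSV (first column = gene symbol)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicated sample ids in header")
    if (df.values < 0).any():
        raise ValueError(f"{path}: negative expression values")
    return df


def write_expression(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# load accounting


def is_non_neutral(record: MutationRecord) -> bool:
    """True iff the record's classification is one of the eight coding,
    protein-changing classes (frameshift, in-frame indel, missense,
    nonsense, nonstop, splice site)."""
    return record.variant_classification in NON_NEUTRAL_CLASSES


def load_summary(
    records: Iterable[MutationRecord], samples: Sequence[str] | None = None
) -> LoadSummary:
    """Per-sample SNV/indel/non-neutral counts with cohort statistics.

    If ``samples`` is given, every listed sample appears in the output (zero
    counts if it has no records) and an unknown sample id in ``records`` is
    an error; otherwise the sample set is taken from the records themselves.
    """
    records = list(records)
    if samples is not None:
        samples = list(samples)
        known = set(samples)
        for r in records:
            if r.sample_id not in known:
                raise ValueError(f"record with unknown sample id {r.sample_id!r}")
    else:
        seen = []
        for r in records:
            if r.sample_id not in seen:
                seen.append(r.sample_id)
        samples = seen

    counts = pd.DataFrame(
        0, index=pd.Index(samples, name="sample_id"),
        columns=["n_snv", "n_indel", "n_non_neutral"], dtype=int,
    )
    for r in records:
        if r.variant_type == "SNP":
            counts.at[r.sample_id, "n_snv"] += 1
        else:
            counts.at[r.sample_id, "n_indel"] += 1
        if is_non_neutral(r):
            counts.at[r.sample_id, "n_non_neutral"] += 1

    if len(counts):
        cohort = pd.DataFrame(
            {
                "mean": counts.mean(),
                "median": counts.median(),
                "min": counts.min().astype(float),
                "max": counts.max().astype(float),
            }
        )
    else:
        cohort = pd.DataFrame(
            np.nan, index=counts.columns, columns=["mean", "median", "min", "max"]
        )
    return LoadSummary(per_sample=counts, cohort=cohort)
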