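"""Four-class genomic classification and recurrence-based candidate discovery.

Samples are assigned to the BRAF / RAS / NF1 / triple wild-type scheme used
for cutaneous melanoma: a BRAF hotspot missense outranks a RAS hotspot,
which outranks an inactivating NF1 variant; a sample with none of the three
is triple wild-type. The precedence order is configurable. Candidate
discovery reports protein changes (or genes) carrying non-synonymous
mutations in at least ``min_carriers`` distinct samples; known drivers and
blacklisted genes are flagged, never silently dropped.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .io import MutationRecord, is_non_neutral
from .stats import TestResult, chi_squared

__all__ = [
    "DriverCatalog",
    "GenomicClass",
    "CLASS_LABELS",
    "assign_class",
    "classify_cohort",
    "recurrent_candidates",
    "class_distribution_test",
]

CLASS_LABELS = ("BRAF", "RAS", "NF1", "TripleWT")

_P_CHANGE = re.compile(r"^p\.[A-Za-z*]+\d+")
_CODON = re.compile(r"^p\.[A-Za-z*]{1,3}(\d+)")


@dataclass
class DriverCatalog:
    """Driver events defining the four genomic classes."""

    braf_hotspots: frozenset[str] = frozenset({"p.V600E", "p.G466E"})
    ras_genes: frozenset[str] = frozenset({"NRAS", "HRAS", "KRAS"})
    ras_hotspot_codons: frozenset[int] = frozenset({12, 13, 61})
    nf1_gene: str = "NF1"
    nf1_lof_classes: frozenset[str] = frozenset(
        {
            "Nonsense_Mutation",
            "Frame_Shift_Del",
            "Frame_Shift_Ins",
            "Splice_Site",
            "Nonstop_Mutation",
        }
    )
    precedence: tuple[str, ...] = ("BRAF", "RAS", "NF1")

    def __post_init__(self) -> None:
        for hs in self.braf_hotspots:
            if not _P_CHANGE.match(hs):
                raise ValueError(f"malformed protein change {hs!r}")
        if not self.ras_genes or not self.nf1_gene:
            raise ValueError("gene symbols must be non-empty")
        if sorted(self.precedence) != sorted(("BRAF", "RAS", "NF1")):
            raise ValueError("precedence must order BRAF, RAS, NF1")

    # -- per-record predicates ------------------------------------------
    def is_braf_hotspot(self, r: MutationRecord) -> bool:
        return (
            r.gene == "BRAF"
            and r.variant_classification == "Missense_Mutation"
            and (r.protein_change or "") in self.braf_hotspots
        )

    def is_ras_hotspot(self, r: MutationRecord) -> bool:
        if r.gene not in self.ras_genes or not r.protein_change:
            return False
        m = _CODON.match(r.protein_change)
        return bool(m) and int(m.group(1)) in self.ras_hotspot_codons

    def is_nf1_lof(self, r: MutationRecord) -> bool:
        return r.gene == self.nf1_gene and r.variant_classification in self.nf1_lof_classes

    def evidence(self, label: str, records: Iterable[MutationRecord]):
        pred = {
            "BRAF": self.is_braf_hotspot,
            "RAS": self.is_ras_hotspot,
            "NF1": self.is_nf1_lof,
        }[label]
        return [r for r in records if pred(r)]


@dataclass
class GenomicClass:
    """Class assignment for one sample, with the qualifying records."""

    sample_id: str
    class_label: str
    evidence: list[MutationRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class {self.class_label!r}")
        if self.class_label == "TripleWT" and self.evidence:
            raise ValueError("TripleWT must have empty evidence")
        if self.class_label != "TripleWT" and not self.evidence:
            raise ValueError(f"{self.class_label} assignment requires evidence")


def assign_class(
    sample_id: str,
    records: Iterable[MutationRecord],
    catalog: DriverCatalog | None = None,
) -> GenomicClass:
    """Assign one sample's class by driver precedence (BRAF > RAS > NF1 by
    default); triple wild-type if no catalog event is present."""
    catalog = catalog or DriverCatalog()
    records = [r for r in records if r.sample_id == sample_id]
    for label in catalog.precedence:
        ev = catalog.evidence(label, records)
        if ev:
            return GenomicClass(sample_id=sample_id, class_label=label, evidence=ev)
    return GenomicClass(sample_id=sample_id, class_label="TripleWT")


def classify_cohort(
    records: Iterable[MutationRecord],
    samples: Sequence[str],
    catalog: DriverCatalog | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Classify every sample; returns the per-sample table and the counts
    4-vector over (BRAF, RAS, NF1, TripleWT)."""
    catalog = catalog or DriverCatalog()
    records = list(records)
    known = set(samples)
    for r in records:
        if r.sample_id not in known:
            raise ValueError(f"record with unknown sample id {r.sample_id!r}")
    by_sample: dict[str, list[MutationRecord]] = defaultdict(list)
    for r in records:
        by_sample[r.sample_id].append(r)
    rows = []
    for s in samples:
        gc = assign_class(s, by_sample.get(s, []), catalog)
        rows.append(
            {
                "sample_id": s,
                "class_label": gc.class_label,
                "evidence": ";".join(
                    f"{e.gene}:{e.protein_change or e.variant_classification}"
                    for e in gc.evidence
                ),
            }
        )
    table = pd.DataFrame(rows, columns=["sample_id", "class_label", "evidence"])
    counts = pd.Series(
        [int((table["class_label"] == c).sum()) for c in CLASS_LABELS],
        index=list(CLASS_LABELS),
    )
    return table, counts


def recurrent_candidates(
    records: Iterable[MutationRecord],
    min_carriers: int = 3,
    blacklist: Sequence[str] = (),
    catalog: DriverCatalog | None = None,
    level: str = "variant",
) -> pd.DataFrame:
    """Non-synonymous events shared by at least ``min_carriers`` samples.

    ``level="variant"`` (default) keys on the identical variant (gene plus
    protein change, or the genomic change when no protein annotation
    exists) — both hits this procedure was built to find are identical
    shared variants;
    ``level="gene"`` keys on the gene symbol alone. Per-sample duplicates
    are collapsed before counting. Entries in ``blacklist`` or matching the
    driver catalog are flagged in the output, not removed.
    """
    if min_carriers < 2:
        raise ValueError("min_carriers must be >= 2")
    if level not in ("variant", "gene"):
        raise ValueError(f"unknown level {level!r}")
    catalog = catalog or DriverCatalog()
    blacklist = set(blacklist)

    carriers: dict[tuple, set[str]] = defaultdict(set)
    for r in records:
        if not is_non_neutral(r):
            continue
        if level == "gene":
            key = (r.gene,)
        else:
            # identical-variant identity: protein change when annotated,
            # otherwise the genomic change itself
            ident = r.protein_change or f"{r.chrom}:{r.pos}:{r.ref}>{r.alt}"
            key = (r.gene, ident)
        carriers[key].add(r.sample_id)

    rows = []
    for key, samps in carriers.items():
        if len(samps) < min_carriers:
            continue
        gene = key[0]
        pchange = key[1] if level == "variant" else ""
        known_driver = gene == "BRAF" or gene == catalog.nf1_gene or gene in catalog.ras_genes
        rows.append(
            {
                "gene": gene,
                "protein_change": pchange,
                "n_carriers": len(samps),
                "samples": ",".join(sorted(samps)),
                "flag": (
                    "blacklist" if gene in blacklist
                    else "known_driver" if known_driver
                    else ""
                ),
            }
        )
    out = pd.DataFrame(
        rows, columns=["gene", "protein_change", "n_carriers", "samples", "flag"]
    )
    return out.sort_values(
        ["n_carriers", "gene", "protein_change"], ascending=[False, True, True]
    ).reset_index(drop=True)


def class_distribution_test(counts_a, counts_b) -> TestResult:
    """Pearson chi-squared comparison of two cohorts' class-count 4-vectors
    (2x4 table, df = 3, no continuity correction)."""
    table = [list(counts_a), list(counts_b)]
    if len(table[0]) != len(table[1]):
        raise ValueError("count vectors must have equal length")
    return chi_squared(table)
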