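"""Ten-pathway alteration scoring.

Combines per-sample SNV/indel impact with cohort-level CNV–expression
concordance into a pathway x sample alteration matrix. A pathway is altered
by SNV in a sample when any member gene carries a protein-impacting variant
there; it is altered by CNV when any member gene with a cohort-level
concordance direction carries a matching non-neutral copy-number call in
that sample. SNV and CNV evidence are reported as separate columns — the
two lines of evidence are never merged into one flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .io import MutationRecord

__all__ = [
    "PATHWAY_NAMES",
    "SNV_IMPACT_CLASSES",
    "PathwayDefinition",
    "snv_impact",
    "pathway_matrix",
    "pathway_frequencies",
]

PATHWAY_NAMES = (
    "cell cycle",
    "p53",
    "Hippo",
    "Myc",
    "Nrf2",
    "PI3K/Akt",
    "RTK-RAS",
    "TGFbeta",
    "Notch",
    "Wnt",
)

#: Protein-impacting classes for pathway scoring: missense / nonsense /
#: nonstop / splice site / frameshift ins or del / start-codon impact /
#: de novo start. Differs from the load-summary non-neutral set: in-frame
#: indels are excluded, start-site classes included.
SNV_IMPACT_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Splice_Site",
        "Frame_Shift_Ins",
        "Frame_Shift_Del",
        "Translation_Start_Site",
        "De_novo_Start",
    }
)


@dataclass(frozen=True)
class PathwayDefinition:
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"pathway {self.name!r} has an empty gene set")


def snv_impact(record: MutationRecord) -> bool:
    """True iff the variant class is protein-impacting for pathway scoring."""
    return record.variant_classification in SNV_IMPACT_CLASSES


def pathway_matrix(
    pathways: Sequence[PathwayDefinition],
    mutations: Iterable[MutationRecord],
    samples: Sequence[str],
    gene_calls: pd.DataFrame | None = None,
    concordance_calls: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Pathway x sample alteration flags.

    Returns a long-format table with one row per (pathway, sample) and
    boolean columns ``altered_by_snv`` and ``altered_by_cnv``. CNV evidence
    needs both the gene-level call table and the cohort concordance table;
    when either is missing all CNV flags are False.
    """
    names = [p.name for p in pathways]
    if len(set(names)) != len(names):
        raise ValueError("duplicate pathway names")
    mutations = list(mutations)

    impacted: dict[str, set[str]] = {s: set() for s in samples}
    for r in mutations:
        if r.sample_id in impacted and snv_impact(r):
            impacted[r.sample_id].add(r.gene)

    # cohort-level concordant direction per gene
    directions: dict[str, str] = {}
    if concordance_calls is not None and len(concordance_calls):
        for row in concordance_calls.itertuples(index=False):
            if row.direction in ("deleted", "amplified"):
                directions[row.gene] = row.direction

    seen_genes = {r.gene for r in mutations}
    if gene_calls is not None:
        seen_genes |= set(gene_calls.index)

    rows = []
    for p in pathways:
        missing = p.genes - seen_genes
        if missing == p.genes:
            warnings.warn(
                f"no gene of pathway {p.name!r} appears in any input; "
                "treated as unaltered",
                stacklevel=2,
            )
        for s in samples:
            by_snv = any(g in impacted[s] for g in p.genes)
            by_cnv = False
            if gene_calls is not None and s in gene_calls.columns:
                for g in p.genes:
                    d = directions.get(g)
                    if d is None or g not in gene_calls.index:
                        continue
                    level = int(gene_calls.at[g, s])
                    if d == "deleted" and level < 0:
                        by_cnv = True
                        break
                    if d == "amplified" and level > 0:
                        by_cnv = True
                        break
            rows.append(
                {
                    "pathway": p.name,
                    "sample_id": s,
                    "altered_by_snv": by_snv,
                    "altered_by_cnv": by_cnv,
                }
            )
    return pd.DataFrame(rows)


def pathway_frequencies(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-pathway alteration frequencies (row means of the flags)."""
    return (
        matrix.groupby("pathway", sort=False)[["altered_by_snv", "altered_by_cnv"]]
        .mean()
        .rename(columns={"altered_by_snv": "freq_snv", "altered_by_cnv": "freq_cnv"})
    )
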