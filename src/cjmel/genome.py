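"""Miniature genome model, gene/arm maps and bundled gene sets.

The simulator works on a 1000x scaled-down genome: 24 pseudo-chromosomes
with the GRCh37 chromosome proportions (total ~3.1 Mb instead of ~3.1 Gb),
so segment arithmetic behaves like the real genome at a fraction of the
cost. Coordinates are 1-based inclusive. A deterministic gene map places
the driver, pathway, program and filler genes along the pseudo-chromosomes;
the arm map splits each chromosome 40/60 into p and q.

Pathway and transcriptomic-program memberships ship as editable GMT files
under ``cjmel/data`` — small curated stand-in sets, data not code.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd

from .expression import read_gmt
from .pathways import PATHWAY_NAMES, PathwayDefinition

__all__ = [
    "MINI_SCALE",
    "GRCH37_CHROM_LENGTHS",
    "mini_chrom_lengths",
    "mini_genome_length",
    "default_gene_map",
    "default_arm_map",
    "default_pathways",
    "default_programs",
]

MINI_SCALE = 1000

#: GRCh37 primary-assembly chromosome lengths (bp).
GRCH37_CHROM_LENGTHS = {
    "chr1": 249_250_621, "chr2": 243_199_373, "chr3": 198_022_430,
    "chr4": 191_154_276, "chr5": 180_915_260, "chr6": 171_115_067,
    "chr7": 159_138_663, "chr8": 146_364_022, "chr9": 141_213_431,
    "chr10": 135_534_747, "chr11": 135_006_516, "chr12": 133_851_895,
    "chr13": 115_169_878, "chr14": 107_349_540, "chr15": 102_531_392,
    "chr16": 90_354_753, "chr17": 81_195_210, "chr18": 78_077_248,
    "chr19": 59_128_983, "chr20": 63_025_520, "chr21": 48_129_895,
    "chr22": 51_304_566, "chrX": 155_270_560, "chrY": 59_373_566,
}


def mini_chrom_lengths(scale: int = MINI_SCALE) -> dict[str, int]:
    return {c: length // scale for c, length in GRCH37_CHROM_LENGTHS.items()}


def mini_genome_length(scale: int = MINI_SCALE) -> int:
    return sum(mini_chrom_lengths(scale).values())


def _data_path(name: str):
    return resources.files("cjmel.data").joinpath(name)


@lru_cache(maxsize=1)
def default_pathways() -> tuple[PathwayDefinition, ...]:
    """The ten canonical signaling pathways with bundled gene sets."""
    sets = read_gmt(_data_path("pathways.gmt"))
    missing = set(PATHWAY_NAMES) - set(sets)
    if missing:
        raise ValueError(f"bundled pathway file missing sets: {sorted(missing)}")
    return tuple(
        PathwayDefinition(name=n, genes=frozenset(sets[n])) for n in PATHWAY_NAMES
    )


@lru_cache(maxsize=1)
def default_programs() -> dict[str, list[str]]:
    """Bundled immune / keratin / cell-cycle program gene sets."""
    return read_gmt(_data_path("programs.gmt"))


def _named_genes() -> list[str]:
    ordered: list[str] = []
    seen = set()
    for g in ("BRAF", "NRAS", "HRAS", "KRAS", "NF1", "ACSS3", "USH2A"):
        ordered.append(g)
        seen.add(g)
    for p in default_pathways():
        for g in sorted(p.genes):
            if g not in seen:
                ordered.append(g)
                seen.add(g)
    for genes in default_programs().values():
        for g in genes:
            if g not in seen:
                ordered.append(g)
                seen.add(g)
    return ordered


@lru_cache(maxsize=1)
def default_gene_map() -> pd.DataFrame:
    """Deterministic gene map on the miniature genome.

    Columns gene/chrom/start/end (1-based inclusive). Driver, pathway and
    program genes come first, followed by numbered filler genes, laid out
    round-robin across the 22 autosomes with fixed spacing.
    """
    genes = _named_genes() + [f"GENE{i:03d}" for i in range(1, 101)]
    lengths = mini_chrom_lengths()
    autosomes = [f"chr{i}" for i in range(1, 23)]
    rows = []
    offsets = dict.fromkeys(autosomes, 1000)
    width, spacing = 60, 2500
    for i, gene in enumerate(genes):
        chrom = autosomes[i % len(autosomes)]
        start = offsets[chrom]
        end = start + width - 1
        if end > lengths[chrom]:
            raise RuntimeError(f"gene map overflows {chrom}")
        rows.append({"gene": gene, "chrom": chrom, "start": start, "end": end})
        offsets[chrom] = start + spacing
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])


@lru_cache(maxsize=1)
def default_arm_map() -> pd.DataFrame:
    """p/q arm intervals for the miniature genome (p = first 40%)."""
    rows = []
    for chrom, length in mini_chrom_lengths().items():
        split = max(1, int(length * 0.4))
        name = chrom.removeprefix("chr")
        rows.append({"arm": f"{name}p", "chrom": chrom, "start": 1, "end": split})
        rows.append({"arm": f"{name}q", "chrom": chrom, "start": split + 1, "end": length})
    return pd.DataFrame(rows, columns=["arm", "chrom", "start", "end"])
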