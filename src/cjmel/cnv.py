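"""Copy-number profile analysis.

Purity-corrected log2 copy-ratio segments are thresholded into integer
levels (−2 deep deletion … +2 amplification), summarized as genome fraction
altered, lifted to per-gene calls (largest-overlap rule) and aggregated
into per-arm alteration frequencies. Default level cutoffs translate the
verbal call definitions (homozygous loss, heterozygous loss, 1.5–2×
increase, >2× increase) into log2-ratio space; all four are configurable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CnvSegment",
    "GeneCnvCall",
    "LevelThresholds",
    "GRCH37_GENOME_LENGTH",
    "call_level",
    "genome_fraction_altered",
    "gene_calls",
    "arm_frequency",
    "read_segments",
    "write_segments",
]

#: GRCh37 total assembly length in bp (overridable everywhere it is used).
GRCH37_GENOME_LENGTH = 3_095_677_412


@dataclass(frozen=True)
class CnvSegment:
    """One purity-corrected copy-ratio segment (1-based inclusive)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    log2_ratio: float
    purity: float | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start > end: {self.start} > {self.end}")
        if not math.isfinite(self.log2_ratio):
            raise ValueError("non-finite log2 ratio")
        if self.purity is not None and not (0 < self.purity <= 1):
            raise ValueError(f"purity out of (0, 1]: {self.purity}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GeneCnvCall:
    """Thresholded integer copy-number level for one gene in one sample."""

    sample_id: str
    gene: str
    level: int

    def __post_init__(self) -> None:
        if self.level not in (-2, -1, 0, 1, 2):
            raise ValueError(f"level must be in -2..2, got {self.level}")


@dataclass(frozen=True)
class LevelThresholds:
    """log2-ratio cutoffs for the five integer levels.

    Defaults: deep deletion below log2(0.25), shallow deletion below
    log2(0.75), gain from log2(1.5) to log2(2), amplification above
    log2(2); neutral otherwise.
    """

    deep_below: float = math.log2(0.25)
    shallow_below: float = math.log2(0.75)
    gain_at_least: float = math.log2(1.5)
    amp_above: float = math.log2(2.0)

    def __post_init__(self) -> None:
        if not (self.deep_below < self.shallow_below <= self.gain_at_least <= self.amp_above):
            raise ValueError("thresholds must be ordered deep < shallow <= gain <= amp")


def call_level(log2_ratio: float, thresholds: LevelThresholds | None = None) -> int:
    """Threshold one log2 copy ratio into an integer level in −2..+2."""
    t = thresholds or LevelThresholds()
    if not math.isfinite(log2_ratio):
        raise ValueError("non-finite log2 ratio")
    if log2_ratio < t.deep_below:
        return -2
    if log2_ratio < t.shallow_below:
        return -1
    if log2_ratio > t.amp_above:
        return 2
    if log2_ratio >= t.gain_at_least:
        return 1
    return 0


def _merged_nonneutral_length(
    segments: Iterable[CnvSegment], thresholds: LevelThresholds | None
) -> int:
    """Union length of non-neutral segments, per chromosome."""
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for s in segments:
        lv = call_level(s.log2_ratio, thresholds)
        if lv == 0:
            continue
        by_chrom.setdefault(s.chrom, []).append((s.start, s.end, lv))
    total = 0
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        cur_start, cur_end, cur_sign = None, None, 0
        for start, end, lv in ivs:
            if cur_start is not None and start <= cur_end + 1:
                if np.sign(lv) != cur_sign:
                    warnings.warn(
                        f"overlapping segments with conflicting sign on {chrom}; "
                        "merged by union",
                        stacklevel=3,
                    )
                cur_end = max(cur_end, end)
            else:
                if cur_start is not None:
                    total += cur_end - cur_start + 1
                cur_start, cur_end, cur_sign = start, end, int(np.sign(lv))
        if cur_start is not None:
            total += cur_end - cur_start + 1
    return total


def genome_fraction_altered(
    segments: Iterable[CnvSegment],
    genome_length: int = GRCH37_GENOME_LENGTH,
    thresholds: LevelThresholds | None = None,
    merge: bool = True,
) -> float:
    """Fraction of the genome covered by non-neutral copy-number events.

    Overlapping events are merged by union by default (``merge=False`` sums
    raw event lengths instead).
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    segments = list(segments)
    if merge:
        altered = _merged_nonneutral_length(segments, thresholds)
    else:
        altered = sum(
            s.length for s in segments if call_level(s.log2_ratio, thresholds) != 0
        )
    return min(1.0, altered / genome_length)


def cohort_fraction_altered(
    segments: Iterable[CnvSegment],
    samples: Sequence[str],
    genome_length: int = GRCH37_GENOME_LENGTH,
    thresholds: LevelThresholds | None = None,
) -> pd.Series:
    """Genome fraction altered per sample (zero for samples w/o segments)."""
    by_sample: dict[str, list[CnvSegment]] = {s: [] for s in samples}
    for seg in segments:
        if seg.sample_id not in by_sample:
            raise ValueError(f"segment with unknown sample id {seg.sample_id!r}")
        by_sample[seg.sample_id].append(seg)
    return pd.Series(
        {
            s: genome_fraction_altered(segs, genome_length, thresholds)
            for s, segs in by_sample.items()
        },
        name="fraction_altered",
    ).reindex(list(samples))


def gene_calls(
    segments: Iterable[CnvSegment],
    gene_map: pd.DataFrame,
    thresholds: LevelThresholds | None = None,
) -> pd.DataFrame:
    """Per-gene thresholded levels (gene x sample table of −2..+2).

    ``gene_map`` needs columns gene/chrom/start/end (1-based inclusive).
    Each gene takes the level of the overlapping segment with the largest
    overlap; genes with no overlapping segment are neutral. A segment on a
    chromosome absent from the gene map is allowed; a gene on a chromosome
    with no segments is neutral.
    """
    for col in ("gene", "chrom", "start", "end"):
        if col not in gene_map.columns:
            raise ValueError(f"gene_map missing column {col!r}")
    segs = list(segments)
    samples = sorted({s.sample_id for s in segs})
    by_key: dict[tuple[str, str], list[CnvSegment]] = {}
    for s in segs:
        by_key.setdefault((s.sample_id, s.chrom), []).append(s)

    out = pd.DataFrame(
        0, index=pd.Index(gene_map["gene"], name="gene"), columns=samples, dtype=int
    )
    for row in gene_map.itertuples(index=False):
        for sample in samples:
            best_olap, best_level = 0, 0
            for seg in by_key.get((sample, row.chrom), ()):
                olap = min(seg.end, row.end) - max(seg.start, row.start) + 1
                if olap > best_olap:
                    best_olap = olap
                    best_level = call_level(seg.log2_ratio, thresholds)
            if best_olap > 0:
                # the largest-overlap segment decides, even if neutral
                out.at[row.gene, sample] = best_level
    return out


def arm_frequency(
    segments: Iterable[CnvSegment],
    arm_map: pd.DataFrame,
    samples: Sequence[str],
    min_arm_fraction: float = 0.5,
    thresholds: LevelThresholds | None = None,
) -> pd.DataFrame:
    """Per-arm counts of amplified / deleted samples.

    A sample counts as arm-altered in one direction when at least
    ``min_arm_fraction`` of the arm length is covered by non-neutral
    segments of that direction. ``arm_map`` needs columns
    arm/chrom/start/end.
    """
    for col in ("arm", "chrom", "start", "end"):
        if col not in arm_map.columns:
            raise ValueError(f"arm_map missing column {col!r}")
    segs = list(segments)
    rows = []
    for arm in arm_map.itertuples(index=False):
        arm_len = arm.end - arm.start + 1
        n_amp = n_del = 0
        for sample in samples:
            cov = {1: 0, -1: 0}
            for seg in segs:
                if seg.sample_id != sample or seg.chrom != arm.chrom:
                    continue
                lv = call_level(seg.log2_ratio, thresholds)
                if lv == 0:
                    continue
                olap = min(seg.end, arm.end) - max(seg.start, arm.start) + 1
                if olap > 0:
                    cov[int(np.sign(lv))] += olap
            if cov[1] / arm_len >= min_arm_fraction:
                n_amp += 1
            if cov[-1] / arm_len >= min_arm_fraction:
                n_del += 1
        rows.append({"arm": arm.arm, "n_amplified": n_amp, "n_deleted": n_del})
    return pd.DataFrame(rows).set_index("arm")


# ---------------------------------------------------------------------------
# SEG-like IO

SEG_COLUMNS = ["sample_id", "chrom", "start", "end", "log2_ratio", "purity"]


def read_segments(path) -> list[CnvSegment]:
    """Read a SEG-like TSV (1-based inclusive coordinates)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False)
    for col in SEG_COLUMNS[:5]:
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        purity = getattr(row, "purity", "")
        out.append(
            CnvSegment(
                sample_id=str(row.sample_id),
                chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
                log2_ratio=float(row.log2_ratio),
                purity=float(purity) if purity not in ("", None) else None,
            )
        )
    return out


def write_segments(segments: Iterable[CnvSegment], path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "chrom": s.chrom,
            "start": s.start,
            "end": s.end,
            "log2_ratio": s.log2_ratio,
            "purity": "" if s.purity is None else s.purity,
        }
        for s in segments
    ]
    pd.DataFrame(rows, columns=SEG_COLUMNS).to_csv(path, sep="\t", index=False)
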