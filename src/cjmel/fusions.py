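"""Gene-fusion candidate filtering and summary.

Annotated fusion candidates pass a four-rule cascade, applied in order with
first-fire attribution:

1. either partner is an uncharacterized, immunoglobulin or mitochondrial
   gene;
2. both partners are the same gene, or an annotated paralog pair;
3. the fusion is present in normal-sample databases;
4. the fusion was called only by STAR-Fusion with FFPM < ``ffpm_min`` (a
   candidate also seen by EricScript survives regardless of FFPM).

Fusion identity is the ordered 5'→3' gene pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

__all__ = ["FusionCandidate", "filter_fusions", "fusion_summary",
           "read_fusions", "write_fusions"]

CALLERS = frozenset({"star_fusion", "ericscript"})

DEFAULT_FFPM_MIN = 0.1


@dataclass(frozen=True)
class FusionCandidate:
    """One annotated fusion candidate (flags are inputs, from upstream
    annotation; the package never queries external databases)."""

    sample_id: str
    gene5: str
    gene3: str
    ffpm: float
    callers: frozenset[str]
    is_uncharacterized: bool = False
    is_immunoglobulin: bool = False
    is_mitochondrial: bool = False
    is_paralog_pair: bool = False
    in_normal_db: bool = False
    is_known_cancer_gene5: bool = False
    is_known_cancer_gene3: bool = False

    def __post_init__(self) -> None:
        if self.ffpm < 0:
            raise ValueError("FFPM must be non-negative")
        if not self.callers or not self.callers <= CALLERS:
            raise ValueError(f"callers must be a non-empty subset of {sorted(CALLERS)}")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene5, self.gene3)


@dataclass
class FilterResult:
    retained: list[FusionCandidate]
    rejected: list[tuple[FusionCandidate, int]] = field(default_factory=list)

    def rejection_log(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"sample_id": c.sample_id, "gene5": c.gene5, "gene3": c.gene3,
                 "rule": rule}
                for c, rule in self.rejected
            ],
            columns=["sample_id", "gene5", "gene3", "rule"],
        )


def _first_failing_rule(c: FusionCandidate, ffpm_min: float) -> int | None:
    if c.is_uncharacterized or c.is_immunoglobulin or c.is_mitochondrial:
        return 1
    if c.gene5 == c.gene3 or c.is_paralog_pair:
        return 2
    if c.in_normal_db:
        return 3
    if c.callers == {"star_fusion"} and c.ffpm < ffpm_min:
        return 4
    return None


def filter_fusions(
    candidates: Iterable[FusionCandidate], ffpm_min: float = DEFAULT_FFPM_MIN
) -> FilterResult:
    """Apply the four-rule cascade; each rejection cites the first rule
    that fired. retained + rejected partition the input."""
    retained, rejected = [], []
    for c in candidates:
        rule = _first_failing_rule(c, ffpm_min)
        if rule is None:
            retained.append(c)
        else:
            rejected.append((c, rule))
    return FilterResult(retained=retained, rejected=rejected)


def fusion_summary(retained: Iterable[FusionCandidate]) -> pd.DataFrame:
    """Unique (ordered 5'→3') fusion pairs with distinct-sample counts,
    recurrence flag (≥2 samples) and cancer-gene involvement."""
    by_pair: dict[tuple[str, str], dict] = {}
    for c in retained:
        entry = by_pair.setdefault(
            c.pair,
            {"gene5": c.gene5, "gene3": c.gene3, "samples": set(),
             "involves_cancer_gene": False},
        )
        entry["samples"].add(c.sample_id)
        if c.is_known_cancer_gene5 or c.is_known_cancer_gene3:
            entry["involves_cancer_gene"] = True
    rows = [
        {
            "gene5": e["gene5"],
            "gene3": e["gene3"],
            "n_samples": len(e["samples"]),
            "samples": ",".join(sorted(e["samples"])),
            "recurrent": len(e["samples"]) >= 2,
            "involves_cancer_gene": e["involves_cancer_gene"],
        }
        for e in by_pair.values()
    ]
    out = pd.DataFrame(
        rows,
        columns=["gene5", "gene3", "n_samples", "samples", "recurrent",
                 "involves_cancer_gene"],
    )
    return out.sort_values(
        ["n_samples", "gene5", "gene3"], ascending=[False, True, True]
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# STAR-Fusion-style TSV IO

FUSION_COLUMNS = [
    "sample_id", "gene5", "gene3", "ffpm", "callers",
    "is_uncharacterized", "is_immunoglobulin", "is_mitochondrial",
    "is_paralog_pair", "in_normal_db",
    "is_known_cancer_gene5", "is_known_cancer_gene3",
]

_FLAGS = FUSION_COLUMNS[5:]


def read_fusions(path) -> list[FusionCandidate]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    for col in FUSION_COLUMNS[:5]:
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    out = []
    for row in df.itertuples(index=False):
        kwargs = {f: str(getattr(row, f, "False")) in ("True", "1") for f in _FLAGS}
        out.append(
            FusionCandidate(
                sample_id=str(row.sample_id),
                gene5=str(row.gene5),
                gene3=str(row.gene3),
                ffpm=float(row.ffpm),
                callers=frozenset(str(row.callers).split(",")),
                **kwargs,
            )
        )
    return out


def write_fusions(candidates: Iterable[FusionCandidate], path) -> None:
    rows = []
    for c in candidates:
        row = {
            "sample_id": c.sample_id,
            "gene5": c.gene5,
            "gene3": c.gene3,
            "ffpm": c.ffpm,
            "callers": ",".join(sorted(c.callers)),
        }
        row.update({f: getattr(c, f) for f in _FLAGS})
        rows.append(row)
    pd.DataFrame(rows, columns=FUSION_COLUMNS).to_csv(path, sep="\t", index=False)
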