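"""CNV–expression dosage concordance and transcriptomic program scores.

A gene is concordantly *deleted* when samples carrying a shallow/deep
deletion express it significantly lower than the remaining samples, and
concordantly *amplified* when gain/amplification carriers express it
significantly higher (Welch t-test by default, alpha 0.05, both groups at
least ``min_group`` samples, shift required in the defining direction).

Program scores standardize the mean log10 expression of a gene set across
samples (gene-set Z-score); each sample's transcriptomic subtype is the
arg-max program among immune, keratin and cell-cycle sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import t_test

__all__ = [
    "ConcordanceCall",
    "concordance",
    "concordance_table",
    "program_zscores",
    "log_transform",
    "read_gmt",
    "write_gmt",
]

PROGRAMS = ("immune", "keratin", "cell_cycle")


def log_transform(expression: pd.DataFrame) -> pd.DataFrame:
    """log10(x + 1) transform of a non-negative expression matrix."""
    if (expression.values < 0).any():
        raise ValueError("negative expression values")
    return np.log10(expression + 1.0)


@dataclass
class ConcordanceCall:
    """Cohort-level dosage-concordance verdict for one gene."""

    gene: str
    direction: str  # deleted | amplified | none
    p_value: float
    n_carriers: int
    n_rest: int

    def __post_init__(self) -> None:
        if self.direction not in ("deleted", "amplified", "none"):
            raise ValueError(f"unknown direction {self.direction!r}")


def _directional_test(expr_row, levels, carrier_levels, flavor, min_group, sign):
    carriers = [s for s in expr_row.index if levels.get(s, 0) in carrier_levels]
    rest = [s for s in expr_row.index if levels.get(s, 0) not in carrier_levels]
    if len(carriers) < min_group or len(rest) < min_group:
        return None, len(carriers), len(rest)
    x = expr_row[carriers].values
    y = expr_row[rest].values
    if np.allclose(x.var(), 0) and np.allclose(y.var(), 0):
        return None, len(carriers), len(rest)
    res = t_test(x, y, flavor=flavor)
    shift = x.mean() - y.mean()
    if np.sign(shift) != sign:
        return None, len(carriers), len(rest)
    return res, len(carriers), len(rest)


def concordance(
    gene: str,
    gene_calls: pd.DataFrame,
    log_expression: pd.DataFrame,
    alpha: float = 0.05,
    min_group: int = 2,
    flavor: str = "welch",
) -> ConcordanceCall:
    """Test one gene for CNV–expression dosage concordance.

    ``gene_calls`` is the gene x sample integer-level table; expression must
    already be log-transformed. The deletion test compares level −1/−2
    carriers against the rest, the amplification test level +1/+2 carriers;
    at most one direction is reported (the smaller p), and a call requires
    p < alpha, a shift in the defining direction and both groups of size at
    least ``min_group``.
    """
    if gene not in log_expression.index:
        raise KeyError(f"gene {gene!r} absent from expression matrix")
    if gene not in gene_calls.index:
        raise KeyError(f"gene {gene!r} absent from gene-call table")
    expr_row = log_expression.loc[gene]
    levels = gene_calls.loc[gene].to_dict()

    del_res, n_del, n_rest_d = _directional_test(
        expr_row, levels, {-1, -2}, flavor, min_group, sign=-1
    )
    amp_res, n_amp, n_rest_a = _directional_test(
        expr_row, levels, {1, 2}, flavor, min_group, sign=+1
    )
    candidates = []
    if del_res is not None and del_res.p_value < alpha:
        candidates.append(("deleted", del_res.p_value, n_del, n_rest_d))
    if amp_res is not None and amp_res.p_value < alpha:
        candidates.append(("amplified", amp_res.p_value, n_amp, n_rest_a))
    if not candidates:
        return ConcordanceCall(gene, "none", 1.0, 0, 0)
    direction, p, n_c, n_r = min(candidates, key=lambda c: c[1])
    return ConcordanceCall(gene, direction, p, n_c, n_r)


def concordance_table(
    gene_calls: pd.DataFrame,
    log_expression: pd.DataFrame,
    alpha: float = 0.05,
    min_group: int = 2,
    flavor: str = "welch",
) -> pd.DataFrame:
    """Concordance calls for every gene present in both tables."""
    genes = [g for g in gene_calls.index if g in log_expression.index]
    rows = [
        vars(concordance(g, gene_calls, log_expression, alpha, min_group, flavor))
        for g in genes
    ]
    return pd.DataFrame(
        rows, columns=["gene", "direction", "p_value", "n_carriers", "n_rest"]
    )


def program_zscores(
    expression: pd.DataFrame,
    program_gene_sets: dict[str, list[str]],
    already_log: bool = False,
) -> pd.DataFrame:
    """Gene-set Z-scores per sample and arg-max subtype assignment.

    Per program: score(sample) = mean log10 expression over the measured
    set genes, standardized to mean 0 / sd 1 across samples. Returns a
    samples x (programs + assigned_subtype) table.
    """
    if expression.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    logx = expression if already_log else log_transform(expression)
    scores = {}
    for program, genes in program_gene_sets.items():
        measured = [g for g in genes if g in logx.index]
        if not measured:
            raise ValueError(f"no measured genes for program {program!r}")
        raw = logx.loc[measured].mean(axis=0)
        sd = raw.std(ddof=0)
        if sd == 0:
            raise ValueError(
                f"program {program!r} score is constant across samples; "
                "Z-score undefined"
            )
        scores[program] = (raw - raw.mean()) / sd
    out = pd.DataFrame(scores)
    out.index.name = "sample_id"
    out["assigned_subtype"] = out.idxmax(axis=1)
    return out


# ---------------------------------------------------------------------------
# GMT gene-set files


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets from a GMT file (name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "cjmel") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")
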