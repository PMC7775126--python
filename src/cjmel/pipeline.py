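"""End-to-end cohort analysis: load -> spectrum -> signatures -> classes ->
CNV -> dosage concordance -> pathways -> fusions -> cohort statistics.

``run_all`` consumes the five cohort tables plus optional catalog/maps and
writes one TSV per stage and a JSON manifest recording package version,
thresholds and per-stage row counts; every output is deterministic given
the inputs and configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import cnv as cnvmod
from .catalogs import default_catalog
from .classify import DriverCatalog, classify_cohort, recurrent_candidates
from .expression import concordance_table, log_transform, program_zscores, read_gmt
from .fusions import filter_fusions, fusion_summary, read_fusions, write_fusions
from .genome import default_arm_map, default_gene_map, default_pathways, default_programs
from .io import is_non_neutral, load_summary, read_clinical, read_expression, read_mutations
from .pathways import PathwayDefinition, pathway_frequencies, pathway_matrix
from .spectrum import (
    collapse_substitution,
    context_matrix,
    fit_cohort_exposures,
    read_catalog,
    spectrum,
)
from .stats import fisher_one_sided, t_test

log = logging.getLogger("cjmel")

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Paths and thresholds for one full analysis run."""

    mutations: Path
    clinical: Path
    outdir: Path
    cnv: Path | None = None
    expression: Path | None = None
    fusions: Path | None = None
    catalog: Path | None = None  # COSMIC-v2-layout TSV; bundled synthetic if None
    gene_map: Path | None = None
    arm_map: Path | None = None
    pathway_gmt: Path | None = None
    program_gmt: Path | None = None
    alpha: float = 0.05
    min_group: int = 2
    min_carriers: int = 3
    ffpm_min: float = 0.1
    genome_length: int | None = None  # None: infer (mini genome for bundled maps)
    blacklist: tuple[str, ...] = ()
    reference_class_counts: tuple[int, ...] | None = None  # comparison cohort
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.ffpm_min < 0:
            raise ValueError("ffpm_min must be >= 0")
        if self.min_carriers < 2:
            raise ValueError("min_carriers must be >= 2")


def _stage(name, n_in, n_out):
    log.info("stage=%s rows_in=%s rows_out=%s", name, n_in, n_out)


def run_all(config: RunConfig) -> dict:
    """Run every analysis stage; returns {stage: output path or table}."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "cjmel",
        "version": __version__,
        "thresholds": {
            "alpha": config.alpha, "min_group": config.min_group,
            "min_carriers": config.min_carriers, "ffpm_min": config.ffpm_min,
        },
        "stages": {},
    }
    results: dict = {}

    def _emit(name: str, df: pd.DataFrame, index=False):
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=index)
        manifest["stages"][name] = {"rows": int(len(df))}
        results[name] = path
        return path

    try:
        clinical = read_clinical(config.clinical)
        samples = [c.sample_id for c in clinical]
        records = read_mutations(config.mutations)
        _stage("read", len(records), len(samples))

        # mutation load
        loads = load_summary(records, samples)
        _emit("loads", loads.per_sample.reset_index())
        _emit("load_cohort", loads.cohort.reset_index(names="count"))

        # spectra and exposures
        by_sample = {s: [r for r in records if r.sample_id == s] for s in samples}
        spec_rows = {s: spectrum(by_sample[s]).proportions for s in samples}
        spectra = pd.DataFrame(spec_rows).T
        spectra.index.name = "sample_id"
        _emit("spectrum", spectra, index=True)

        catalog = read_catalog(config.catalog) if config.catalog else default_catalog()
        contexts = context_matrix(records, samples)
        exposures = fit_cohort_exposures(contexts, catalog)
        _emit("exposures", exposures, index=True)

        # genomic classification + recurrence
        driver_catalog = DriverCatalog()
        class_table, class_counts = classify_cohort(records, samples, driver_catalog)
        _emit("classes", class_table)
        candidates = recurrent_candidates(
            records, min_carriers=config.min_carriers,
            blacklist=config.blacklist, catalog=driver_catalog,
        )
        _emit("recurrent_candidates", candidates)

        # CNV
        gene_levels = None
        fractions = None
        if config.cnv is not None:
            segments = cnvmod.read_segments(config.cnv)
            gene_map = (pd.read_csv(config.gene_map, sep="\t")
                        if config.gene_map else default_gene_map())
            arm_map = (pd.read_csv(config.arm_map, sep="\t")
                       if config.arm_map else default_arm_map())
            genome_length = config.genome_length
            if genome_length is None:
                from .genome import mini_genome_length
                genome_length = (mini_genome_length() if config.gene_map is None
                                 else cnvmod.GRCH37_GENOME_LENGTH)
            fractions = cnvmod.cohort_fraction_altered(
                segments, samples, genome_length
            )
            _emit("cnv_fraction", fractions.rename_axis("sample_id").reset_index())
            gene_levels = cnvmod.gene_calls(segments, gene_map)
            _emit("gene_cnv", gene_levels, index=True)
            arms = cnvmod.arm_frequency(segments, arm_map, samples)
            _emit("arm_frequency", arms.reset_index())

        # expression integration
        concordance = None
        if config.expression is not None:
            expr = read_expression(config.expression)
            logx = log_transform(expr)
            programs = (read_gmt(config.program_gmt) if config.program_gmt
                        else default_programs())
            zscores = program_zscores(expr, programs)
            _emit("program_scores", zscores, index=True)
            if gene_levels is not None:
                concordance = concordance_table(
                    gene_levels, logx, alpha=config.alpha,
                    min_group=config.min_group,
                )
                _emit("concordance", concordance)

        # pathways
        if config.pathway_gmt:
            sets = read_gmt(config.pathway_gmt)
            pathways = tuple(PathwayDefinition(n, frozenset(g))
                             for n, g in sets.items())
        else:
            pathways = default_pathways()
        matrix = pathway_matrix(pathways, records, samples, gene_levels, concordance)
        _emit("pathway_matrix", matrix)
        _emit("pathway_frequencies", pathway_frequencies(matrix).reset_index())

        # fusions
        if config.fusions is not None:
            cands = read_fusions(config.fusions)
            fres = filter_fusions(cands, ffpm_min=config.ffpm_min)
            write_fusions(fres.retained, out / "fusions_retained.tsv")
            results["fusions_retained"] = out / "fusions_retained.tsv"
            manifest["stages"]["fusions_retained"] = {"rows": len(fres.retained)}
            _emit("fusions_rejected", fres.rejection_log())
            _emit("fusion_summary", fusion_summary(fres.retained))

        # cohort statistics
        stats_rows = _cohort_statistics(
            clinical, records, samples, loads, class_table, class_counts,
            fractions, config.reference_class_counts,
        )
        _emit("statistics", pd.DataFrame(stats_rows))
    except Exception as e:
        raise RuntimeError(f"pipeline failed: {e}") from e

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    results["manifest"] = manifest_path
    return results


def _cohort_statistics(clinical, records, samples, loads, class_table,
                       class_counts, fractions, reference_class_counts):
    """The group comparisons reported for a cohort, as tidy rows."""
    rows = []
    per = loads.per_sample
    cls = class_table.set_index("sample_id")["class_label"]
    loc = {c.sample_id: c.localization for c in clinical}
    lymph = {c.sample_id: c.lymph_invasion for c in clinical}

    def add(name, res):
        rows.append({
            "comparison": name, "statistic": res.statistic, "p_value": res.p_value,
            "method": res.method,
            "group_means": ";".join(f"{m:.6g}" for m in res.group_means)
            if res.group_means else "",
        })

    # tarsal vs bulbar non-neutral load
    tarsal = [per.at[s, "n_non_neutral"] for s in samples if loc[s] == "tarsal"]
    bulbar = [per.at[s, "n_non_neutral"] for s in samples if loc[s] == "bulbar"]
    if len(tarsal) >= 2 and len(bulbar) >= 2:
        add("load_tarsal_vs_bulbar", t_test(tarsal, bulbar))

    # triple-WT vs rest: non-neutral load and C>T count
    wt = [s for s in samples if cls[s] == "TripleWT"]
    rest = [s for s in samples if cls[s] != "TripleWT"]
    if len(wt) >= 2 and len(rest) >= 2:
        add("load_triplewt_vs_rest",
            t_test([per.at[s, "n_non_neutral"] for s in wt],
                   [per.at[s, "n_non_neutral"] for s in rest]))
        ct = {s: 0 for s in samples}
        for r in records:
            if r.variant_type == "SNP":
                c, _ = collapse_substitution(r.ref, r.alt)
                if c == "C>T":
                    ct[r.sample_id] += 1
        add("ct_count_triplewt_vs_rest",
            t_test([ct[s] for s in wt], [ct[s] for s in rest]))

    # lymph invasion vs mutational load
    present = [per.at[s, "n_non_neutral"] for s in samples if lymph[s] is True]
    absent = [per.at[s, "n_non_neutral"] for s in samples if lymph[s] is False]
    if len(present) >= 2 and len(absent) >= 2:
        add("load_lymph_present_vs_absent", t_test(present, absent))

    # NF1 class vs rest: lymph-node invasion (one-sided Fisher)
    nf1 = [s for s in samples if cls[s] == "NF1"]
    other = [s for s in samples if cls[s] != "NF1"]
    tab = [[sum(1 for s in nf1 if lymph[s] is True),
            sum(1 for s in nf1 if lymph[s] is False)],
           [sum(1 for s in other if lymph[s] is True),
            sum(1 for s in other if lymph[s] is False)]]
    if all(sum(r) for r in tab) and sum(c[0] for c in tab) > 0:
        add("lymph_nf1_vs_rest", fisher_one_sided(tab, alternative="less"))

    # BRAF class vs rest genome fraction altered
    if fractions is not None:
        braf = [fractions[s] for s in samples if cls[s] == "BRAF"]
        nonbraf = [fractions[s] for s in samples if cls[s] != "BRAF"]
        if len(braf) >= 2 and len(nonbraf) >= 2:
            add("cnv_fraction_braf_vs_rest", t_test(braf, nonbraf))

    # class distribution vs a reference cohort
    if reference_class_counts is not None:
        from .classify import class_distribution_test
        add("class_distribution_vs_reference",
            class_distribution_test(list(class_counts), list(reference_class_counts)))
    return rows
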