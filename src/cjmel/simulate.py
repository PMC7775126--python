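"""Synthetic-cohort generator with known ground truth.

Generates complete cohorts — clinical, somatic mutation, copy-number,
expression and fusion tables — whose statistical structure emulates a
small conjunctival-melanoma cohort: per-sample mutation loads drawn from
localization-dependent log-normals, 96-context counts drawn from
signature-mixture multinomials (UV-dominated profile for sun-exposed
bulbar tumors, mixed profile for tarsal ones), one class-defining driver
planted per sample according to the BRAF/RAS/NF1/triple-WT composition,
copy-number segments reaching a class-dependent genome fraction altered,
expression with gene-dosage effects and three transcriptomic program
offsets, and fusion candidates exercising every filter rule.

Every planted event is recorded in a truth table so downstream stages can
be tested end to end without external data. All draws are deterministic
given the config seed; each table uses its own sub-stream so adding a
feature to one table does not perturb the others.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cnv as cnvmod
from .catalogs import default_catalog
from .classify import CLASS_LABELS
from .genome import (
    default_gene_map,
    default_programs,
    mini_chrom_lengths,
    mini_genome_length,
)
from .io import (
    ClinicalRecord,
    MutationRecord,
    write_clinical,
    write_expression,
    write_mutations,
)
from .fusions import FusionCandidate, write_fusions
from .spectrum import CONTEXTS_96, _COMPLEMENT, _revcomp

__all__ = ["CohortConfig", "SyntheticCohort", "generate_cohort", "truth_report"]

_AA = "ARNDCQEGHILKMFPSTWYV"

# neutral SNV classes and their relative frequencies
_NEUTRAL_SNV_CLASSES = ("Silent", "Intron", "3'UTR", "5'UTR", "5'Flank", "IGR", "RNA")
_NEUTRAL_SNV_PROBS = (0.18, 0.38, 0.09, 0.05, 0.05, 0.21, 0.04)
# coding non-neutral SNV classes
_CODING_SNV_CLASSES = ("Missense_Mutation", "Nonsense_Mutation", "Splice_Site",
                       "Nonstop_Mutation")
_CODING_SNV_PROBS = (0.88, 0.065, 0.045, 0.01)
# indel classes (first four are non-neutral)
_INDEL_CLASSES = ("Frame_Shift_Del", "Frame_Shift_Ins", "In_Frame_Del",
                  "In_Frame_Ins", "Intron")
_INDEL_PROBS = (0.55, 0.20, 0.08, 0.07, 0.10)


def _quota_allocate(probs: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder integer allocation of n items to categories."""
    keys = list(probs)
    raw = np.array([probs[k] for k in keys], dtype=float) * n
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    for i in range(rem):
        base[order[i]] += 1
    return dict(zip(keys, base.tolist()))


@dataclass
class CohortConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults reproduce the 14-patient study composition: 4 tarsal tumors
    (one of which carries the UV-type molecular profile of a bulbar tumor),
    class mix BRAF 4 / RAS 3 / NF1 5 / triple-WT 2, per-profile mean
    non-neutral loads 195 (tarsal) / 742 (bulbar), mean indel count 87,
    genome fraction altered 0.18 (BRAF class) / 0.37 (others), a recurrent
    ACSS3 p.P532S missense in 3 carriers and a 3-carrier artifact gene.
    """

    n_patients: int = 14
    seed: int = 0
    localization_mix: float = 4 / 14  # fraction tarsal
    tarsal_bulbar_like: int = 1  # tarsal samples with the UV (bulbar) profile
    class_probs: dict[str, float] = field(
        default_factory=lambda: {"BRAF": 4 / 14, "RAS": 3 / 14,
                                 "NF1": 5 / 14, "TripleWT": 2 / 14}
    )
    # mean NON-NEUTRAL (coding) load per molecular profile
    nonneutral_means: dict[str, float] = field(
        default_factory=lambda: {"tarsal": 195.0, "bulbar": 742.0}
    )
    load_sigma: float = 0.45  # log-normal sigma of per-sample loads
    class_load_scale: dict[str, float] = field(
        default_factory=lambda: {"TripleWT": 0.35}
    )
    snv_nonneutral_fraction: float = 0.34  # coding fraction of all SNVs
    indel_mean: float = 87.0
    indel_sigma: float = 0.28
    exposure_templates: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "tarsal": {"Signature_1": 0.20, "Signature_7": 0.35, "Signature_30": 0.45},
            "bulbar": {"Signature_1": 0.15, "Signature_7": 0.80, "Signature_30": 0.05},
        }
    )
    exposure_alpha: float = 60.0  # Dirichlet concentration of per-sample jitter
    cnv_fraction_means: dict[str, float] = field(
        default_factory=lambda: {"BRAF": 0.18, "RAS": 0.37, "NF1": 0.37,
                                 "TripleWT": 0.37}
    )
    cnv_fraction_sd: float = 0.09
    dosage_effect: float = 0.35  # log10 expression shift per copy level
    dosage_genes: dict[str, str] = field(
        default_factory=lambda: {
            "PTEN": "deleted", "CDKN2A": "deleted", "TP53": "deleted",
            "SMAD4": "deleted", "MYC": "amplified", "EGFR": "amplified",
            "YAP1": "amplified", "CTNNB1": "amplified",
        }
    )
    program_mix: dict[str, float] = field(
        default_factory=lambda: {"immune": 5 / 11, "keratin": 3 / 11,
                                 "cell_cycle": 3 / 11}
    )
    program_offset: float = 0.6  # log10 offset on program genes
    expression_noise_sd: float = 0.15
    recurrent_variant_spec: tuple[str, str, int] = ("ACSS3", "p.P532S", 3)
    artifact_gene_spec: tuple[str, str, int] = ("USH2A", "p.T2205M", 3)
    extra_nf1_carriers: int = 2  # secondary NF1 LoF in RAS-class samples

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if abs(sum(self.class_probs.values()) - 1.0) > 1e-9:
            raise ValueError("class_probs must sum to 1")
        if set(self.class_probs) != set(CLASS_LABELS):
            raise ValueError(f"class_probs must cover {CLASS_LABELS}")
        if not (0.0 <= self.localization_mix <= 1.0):
            raise ValueError("localization_mix must be in [0, 1]")
        for name, m in {**self.nonneutral_means,
                        "indel": self.indel_mean}.items():
            if m <= 0:
                raise ValueError(f"mean for {name!r} must be > 0")
        for spec in (self.recurrent_variant_spec, self.artifact_gene_spec):
            if spec[2] > self.n_patients:
                raise ValueError(
                    f"carrier count {spec[2]} for {spec[0]} exceeds cohort size "
                    f"{self.n_patients}"
                )
        for loc, t in self.exposure_templates.items():
            if abs(sum(t.values()) - 1.0) > 1e-9:
                raise ValueError(f"exposure template {loc!r} must sum to 1")


@dataclass
class SyntheticCohort:
    """One generated cohort plus its ground-truth record."""

    samples: list[str]
    clinical: list[ClinicalRecord]
    mutations: list[MutationRecord]
    cnv: list  # list[CnvSegment]
    expression: pd.DataFrame
    fusions: list[FusionCandidate]
    truth: dict

    def write(self, outdir) -> dict[str, Path]:
        """Write all tables (TSV) and the truth record (JSON) to outdir."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "clinical": outdir / "clinical.tsv",
            "mutations": outdir / "mutations.tsv",
            "cnv": outdir / "cnv_segments.tsv",
            "expression": outdir / "expression.tsv",
            "fusions": outdir / "fusions.tsv",
            "truth": outdir / "truth.json",
        }
        write_clinical(self.clinical, paths["clinical"])
        write_mutations(self.mutations, paths["mutations"])
        cnvmod.write_segments(self.cnv, paths["cnv"])
        write_expression(self.expression, paths["expression"])
        write_fusions(self.fusions, paths["fusions"])
        paths["truth"].write_text(json.dumps(self.truth, indent=1, sort_keys=True))
        return paths


def _rng(config: CohortConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _lognormal(rng, mean: float, sigma: float) -> float:
    return float(rng.lognormal(math.log(mean) - sigma**2 / 2, sigma))


def _random_protein_change(rng) -> str:
    a, b = rng.choice(list(_AA), size=2)
    return f"p.{a}{int(rng.integers(30, 1500))}{b}"


def _context_record(rng, sample, gene, chrom, pos, cls, tri, classification,
                    protein_change=None):
    """Build one SNV record from a pyrimidine-strand context, randomly
    presenting it on either strand."""
    ref, alt = cls[0], cls[2]
    ctx = tri
    if rng.random() < 0.5:
        ref, alt, ctx = _COMPLEMENT[ref], _COMPLEMENT[alt], _revcomp(ctx)
    return MutationRecord(
        sample_id=sample, gene=gene, chrom=chrom, pos=pos, ref=ref, alt=alt,
        variant_type="SNP", variant_classification=classification,
        protein_change=protein_change, context3=ctx,
    )


def generate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Generate one synthetic cohort. Deterministic given ``config.seed``."""
    config = config or CohortConfig()
    n = config.n_patients
    samples = [f"CM{i:02d}" for i in range(1, n + 1)]
    catalog = default_catalog()
    gene_map = default_gene_map()
    chrom_lengths = mini_chrom_lengths()
    genome_len = mini_genome_length()
    gene_rows = {r.gene: r for r in gene_map.itertuples(index=False)}
    filler_genes = [g for g in gene_map["gene"] if g.startswith("GENE")]

    truth: dict = {"planted": [], "per_sample": {}}

    # ---- composition: localization, molecular profile, class, subtype ----
    rng_comp = _rng(config, 1)
    n_tarsal = int(round(config.localization_mix * n))
    loc = ["tarsal"] * n_tarsal + ["bulbar"] * (n - n_tarsal)
    rng_comp.shuffle(loc)
    localization = dict(zip(samples, loc))
    # molecular profile: some tarsal tumors carry the UV/bulbar profile
    tarsal_ids = [s for s in samples if localization[s] == "tarsal"]
    n_flip = min(config.tarsal_bulbar_like, len(tarsal_ids))
    flipped = set(rng_comp.choice(tarsal_ids, size=n_flip, replace=False)) if n_flip else set()
    profile = {
        s: ("bulbar" if (localization[s] == "bulbar" or s in flipped) else "tarsal")
        for s in samples
    }

    class_counts = _quota_allocate(config.class_probs, n)
    class_list = [c for c in CLASS_LABELS for _ in range(class_counts[c])]
    rng_comp.shuffle(class_list)
    truth_class = dict(zip(samples, class_list))

    subtype_counts = _quota_allocate(config.program_mix, n)
    subtype_list = [p for p in subtype_counts for _ in range(subtype_counts[p])]
    rng_comp.shuffle(subtype_list)
    subtype = dict(zip(samples, subtype_list))

    # ---- clinical table ----
    rng_clin = _rng(config, 2)
    clinical = []
    for s in samples:
        origin = rng_clin.choice(["PAM/C-MIN", "nevus", "de novo"],
                                 p=[9 / 14, 1 / 14, 4 / 14])
        clinical.append(
            ClinicalRecord(
                sample_id=s,
                localization=localization[s],
                origin=str(origin),
                lymph_invasion=bool(rng_clin.random() < 0.21),
                thickness_mm=float(np.round(_lognormal(rng_clin, 3.0, 0.5), 2)),
                pigmentation=int(rng_clin.integers(0, 4)),
                recurrence=bool(rng_clin.random() < 9 / 14),
                metastasis=bool(rng_clin.random() < 3 / 14),
                death=bool(rng_clin.random() < 2 / 14),
            )
        )

    # ---- mutation table ----
    rng_mut = _rng(config, 3)
    sig_names = catalog.names
    A = catalog.profiles.values  # 96 x K
    mutations: list[MutationRecord] = []
    exposures_truth = {}
    for s in samples:
        prof = profile[s]
        template = np.array(
            [config.exposure_templates[prof].get(k, 0.0) for k in sig_names]
        )
        w = rng_mut.dirichlet(np.maximum(template, 1e-9) * config.exposure_alpha)
        exposures_truth[s] = dict(zip(sig_names, np.round(w, 4).tolist()))

        scale = config.class_load_scale.get(truth_class[s], 1.0)
        nn_target = _lognormal(
            rng_mut, config.nonneutral_means[prof] * scale, config.load_sigma
        )
        n_indel = max(1, round(_lognormal(rng_mut, config.indel_mean,
                                          config.indel_sigma)))
        indel_classes = rng_mut.choice(_INDEL_CLASSES, size=n_indel, p=_INDEL_PROBS)
        nn_indel = int(sum(c != "Intron" for c in indel_classes))
        nn_snv = max(10, round(nn_target) - nn_indel)
        n_snv = max(nn_snv, round(nn_snv / config.snv_nonneutral_fraction))

        # contexts: multinomial from the sample's mixed signature profile
        p96 = A @ w
        p96 = p96 / p96.sum()
        ctx_counts = rng_mut.multinomial(n_snv, p96)
        coding_flags = np.zeros(n_snv, dtype=bool)
        coding_flags[rng_mut.choice(n_snv, size=nn_snv, replace=False)] = True
        i_flat = 0
        for ci, count in enumerate(ctx_counts):
            cls, tri = CONTEXTS_96[ci]
            for _ in range(count):
                if coding_flags[i_flat]:
                    classification = str(rng_mut.choice(_CODING_SNV_CLASSES,
                                                        p=_CODING_SNV_PROBS))
                    gene = str(rng_mut.choice(filler_genes))
                    row = gene_rows[gene]
                    chrom = row.chrom
                    pos = int(rng_mut.integers(row.start, row.end + 1))
                    if classification == "Splice_Site":
                        # annotator-style splice notation keeps variant
                        # identity in protein space
                        pchange = f"p.X{int(rng_mut.integers(30, 1500))}_splice"
                    else:
                        pchange = _random_protein_change(rng_mut)
                else:
                    classification = str(rng_mut.choice(_NEUTRAL_SNV_CLASSES,
                                                        p=_NEUTRAL_SNV_PROBS))
                    chrom = str(rng_mut.choice(list(chrom_lengths)))
                    pos = int(rng_mut.integers(1, chrom_lengths[chrom] + 1))
                    gene = "Unknown"
                    pchange = None
                mutations.append(
                    _context_record(rng_mut, s, gene, chrom, pos, cls, tri,
                                    classification, pchange)
                )
                i_flat += 1

        # indel records
        for c in indel_classes:
            gene = str(rng_mut.choice(filler_genes))
            row = gene_rows[gene]
            pos = int(rng_mut.integers(row.start, row.end + 1))
            is_del = "Del" in c or c == "Intron"
            if c == "Intron":
                pchange = None
            else:
                aa = str(rng_mut.choice(list(_AA)))
                num = int(rng_mut.integers(30, 1500))
                suffix = "fs" if c.startswith("Frame_Shift") else (
                    "del" if is_del else "ins")
                pchange = f"p.{aa}{num}{suffix}"
            mutations.append(
                MutationRecord(
                    sample_id=s, gene=gene, chrom=row.chrom, pos=pos,
                    ref="ACT" if is_del else "-",
                    alt="-" if is_del else "ACT",
                    variant_type="DEL" if is_del else "INS",
                    variant_classification=str(c),
                    protein_change=pchange, context3=None,
                )
            )

    # ---- planted drivers ----
    rng_plant = _rng(config, 4)

    def plant(sample, gene, classification, pchange, kind, cls="C>T", tri="CCA"):
        row = gene_rows[gene]
        pos = int(rng_plant.integers(row.start, row.end + 1))
        if classification == "Missense_Mutation" or classification == "Nonsense_Mutation":
            rec = _context_record(rng_plant, sample, gene, row.chrom, pos,
                                  cls, tri, classification, pchange)
        else:  # LoF indel
            rec = MutationRecord(
                sample_id=sample, gene=gene, chrom=row.chrom, pos=pos,
                ref="AC", alt="-", variant_type="DEL",
                variant_classification=classification, protein_change=pchange,
            )
        mutations.append(rec)
        truth["planted"].append(
            {"sample_id": sample, "gene": gene, "protein_change": pchange or "",
             "classification": classification, "kind": kind}
        )

    braf_samples = [s for s in samples if truth_class[s] == "BRAF"]
    for i, s in enumerate(braf_samples):
        # three of four carriers share the canonical V600E; one gets G466E
        pchange = "p.G466E" if (len(braf_samples) >= 4 and i == len(braf_samples) - 1) \
            else "p.V600E"
        plant(s, "BRAF", "Missense_Mutation", pchange, "class_driver")
    ras_hotspots = [("HRAS", "p.Q61R"), ("HRAS", "p.G13D"), ("NRAS", "p.Q61L")]
    ras_samples = [s for s in samples if truth_class[s] == "RAS"]
    for i, s in enumerate(ras_samples):
        gene, pchange = ras_hotspots[i % len(ras_hotspots)]
        plant(s, gene, "Missense_Mutation", pchange, "class_driver")
    # LoF positions scatter across NF1, as real truncating variants do
    for s in (s for s in samples if truth_class[s] == "NF1"):
        plant(s, "NF1", "Nonsense_Mutation",
              f"p.R{int(rng_plant.integers(100, 2700))}*", "class_driver",
              tri="TCG")
    for s in ras_samples[: config.extra_nf1_carriers]:
        plant(s, "NF1", "Frame_Shift_Del",
              f"p.L{int(rng_plant.integers(100, 2700))}fs", "secondary_nf1")
    for s in (s for s in samples if truth_class[s] == "TripleWT"):
        # a non-hotspot RTK-RAS missense keeps the sample triple wild-type
        plant(s, "EGFR", "Missense_Mutation", "p.A289V", "rtk_ras_nonclassifying")

    rec_gene, rec_change, rec_n = config.recurrent_variant_spec
    for s in samples[:rec_n]:
        plant(s, rec_gene, "Missense_Mutation", rec_change, "recurrent_candidate",
              tri="CCT")
    art_gene, art_change, art_n = config.artifact_gene_spec
    for s in samples[len(samples) - art_n:]:
        plant(s, art_gene, "Missense_Mutation", art_change, "artifact", tri="ACA")

    # ---- CNV segments ----
    rng_cnv = _rng(config, 5)
    segments: list[cnvmod.CnvSegment] = []
    dosage_carriers: dict[str, list[str]] = {}
    occupied: dict[str, dict[str, list[tuple[int, int]]]] = {s: {} for s in samples}

    def _place(sample, chrom, start, end, log2):
        segments.append(
            cnvmod.CnvSegment(str(sample), chrom, start, end, round(float(log2), 6))
        )
        occupied[sample].setdefault(chrom, []).append((start, end))

    for gene, direction in config.dosage_genes.items():
        row = gene_rows[gene]
        n_carr = max(2, n // 2)
        carriers = sorted(str(s) for s in rng_cnv.choice(samples, size=n_carr,
                                                         replace=False))
        dosage_carriers[gene] = carriers
        for s in carriers:
            pad = int(rng_cnv.integers(200, 800))
            start = max(1, row.start - pad)
            end = min(chrom_lengths[row.chrom], row.end + pad)
            if direction == "deleted":
                log2 = float(rng_cnv.uniform(-1.2, -0.55))
                if rng_cnv.random() < 0.2:
                    log2 = float(rng_cnv.uniform(-3.0, -2.1))
            else:
                log2 = float(rng_cnv.uniform(0.62, 0.95))
                if rng_cnv.random() < 0.2:
                    log2 = float(rng_cnv.uniform(1.05, 1.7))
            _place(s, row.chrom, start, end, log2)

    chroms = list(chrom_lengths)
    chrom_w = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    chrom_w /= chrom_w.sum()
    fraction_truth = {}
    for s in samples:
        target = float(np.clip(
            rng_cnv.normal(config.cnv_fraction_means[truth_class[s]],
                           config.cnv_fraction_sd),
            0.05, 0.75,
        ))
        fraction_truth[s] = target
        altered = sum(e - b + 1 for ivs in occupied[s].values() for b, e in ivs)
        tries = 0
        while altered < target * genome_len and tries < 400:
            tries += 1
            chrom = str(rng_cnv.choice(chroms, p=chrom_w))
            length = int(min(
                chrom_lengths[chrom],
                max(2000, _lognormal(rng_cnv, 0.025 * genome_len, 0.8)),
            ))
            remaining = int(target * genome_len - altered)
            length = max(2000, min(length, remaining))  # hit the target, not past it
            if length > chrom_lengths[chrom]:
                continue
            start = int(rng_cnv.integers(1, chrom_lengths[chrom] - length + 2))
            end = start + length - 1
            if any(start <= e and end >= b for b, e in occupied[s].get(chrom, [])):
                continue
            if rng_cnv.random() < 0.5:
                log2 = float(rng_cnv.uniform(-1.2, -0.5))
            else:
                log2 = float(rng_cnv.uniform(0.62, 1.4))
            _place(s, chrom, start, end, log2)
            altered += length

    # ---- expression matrix ----
    rng_expr = _rng(config, 6)
    programs = default_programs()
    gene_levels = cnvmod.gene_calls(segments, gene_map)
    genes = list(gene_map["gene"])
    baseline = pd.Series(rng_expr.normal(2.0, 0.4, size=len(genes)), index=genes)
    logx = pd.DataFrame(
        rng_expr.normal(0.0, config.expression_noise_sd, size=(len(genes), n)),
        index=genes, columns=samples,
    ).add(baseline, axis=0)
    for gene in config.dosage_genes:
        if gene in gene_levels.index:
            logx.loc[gene] += config.dosage_effect * gene_levels.loc[gene].reindex(
                samples).fillna(0).values
    for prog, prog_genes in programs.items():
        members = [g for g in prog_genes if g in logx.index]
        carriers = [s for s in samples if subtype[s] == prog]
        if members and carriers:
            logx.loc[members, carriers] += config.program_offset
    expression = (10.0 ** logx.clip(lower=0.0)).round(3)
    expression.index.name = "gene"

    # ---- fusion candidates ----
    fusions, fusion_truth = _make_fusions(samples, _rng(config, 7))

    truth["per_sample"] = {
        s: {
            "class": truth_class[s],
            "localization": localization[s],
            "profile": profile[s],
            "subtype": subtype[s],
            "exposures": exposures_truth[s],
            "cnv_fraction_target": round(fraction_truth[s], 4),
        }
        for s in samples
    }
    truth["dosage_genes"] = {
        g: {"direction": d, "carriers": dosage_carriers[g]}
        for g, d in config.dosage_genes.items()
    }
    truth["fusions"] = fusion_truth
    truth["genome_length"] = genome_len

    return SyntheticCohort(
        samples=samples, clinical=clinical, mutations=mutations, cnv=segments,
        expression=expression, fusions=fusions, truth=truth,
    )


def _make_fusions(samples, rng):
    """Fusion candidates: retained pairs (three recurrent in 2 samples,
    several involving known cancer genes) plus one decoy per filter rule."""
    n = len(samples)

    def ffpm():
        return round(_lognormal(rng, 0.6, 0.5), 3)

    both = frozenset({"star_fusion", "ericscript"})
    star = frozenset({"star_fusion"})
    out, truth = [], []

    def add(sample, g5, g3, *, ffpm_v=None, callers=both, expected_rule=None, **kw):
        c = FusionCandidate(
            sample_id=sample, gene5=g5, gene3=g3,
            ffpm=ffpm() if ffpm_v is None else ffpm_v, callers=callers, **kw,
        )
        out.append(c)
        truth.append({"sample_id": sample, "gene5": g5, "gene3": g3,
                      "expected_rule": expected_rule})

    recurrent = [("RP11-206L10.9", "PSPH"), ("STEAP1", "RAPGEF5"),
                 ("ACTG2", "ACTG1")]
    for i, (g5, g3) in enumerate(recurrent):
        for j in range(2):
            add(samples[(2 * i + j) % n], g5, g3)
    singles = [
        ("PMEL", "SQSTM1", True), ("PPTC7", "HVCN1", True),
        ("PMEL", "GENE009", False), ("PMEL", "GENE010", False),
        ("PMEL", "GENE011", False), ("NTRK1", "TPM3", True),
        ("GENE012", "GENE013", False), ("GENE014", "GENE015", False),
    ]
    for i, (g5, g3, cancer) in enumerate(singles):
        add(samples[i % n], g5, g3,
            is_known_cancer_gene5=cancer, is_known_cancer_gene3=cancer)
    # low-FFPM candidate rescued by the second caller
    add(samples[0], "GENE007", "GENE008", ffpm_v=0.05, callers=both)

    # decoys, one per rule
    add(samples[0], "AC012345.1", "GENE003", is_uncharacterized=True,
        expected_rule=1)
    add(samples[1 % n], "IGHV3-23", "MYC", is_immunoglobulin=True,
        expected_rule=1)
    add(samples[2 % n], "MT-CO1", "GENE004", is_mitochondrial=True,
        expected_rule=1)
    add(samples[3 % n], "KRT5", "KRT5", expected_rule=2)
    add(samples[4 % n], "KRT5", "KRT6A", is_paralog_pair=True, expected_rule=2)
    add(samples[5 % n], "TTTY15", "USP9Y", in_normal_db=True, expected_rule=3)
    add(samples[6 % n], "GENE005", "GENE006", ffpm_v=0.05, callers=star,
        expected_rule=4)
    return out, truth


def truth_report(cohort: SyntheticCohort) -> pd.DataFrame:
    """One row per planted mutation event (locus, sample, type)."""
    rows = []
    by_key = {}
    for r in cohort.mutations:
        by_key.setdefault((r.sample_id, r.gene, r.protein_change or ""), r)
    for ev in cohort.truth["planted"]:
        rec = by_key.get((ev["sample_id"], ev["gene"], ev["protein_change"]))
        rows.append(
            {
                **ev,
                "chrom": rec.chrom if rec else "",
                "pos": rec.pos if rec else -1,
            }
        )
    return pd.DataFrame(
        rows, columns=["sample_id", "gene", "protein_change", "classification",
                       "kind", "chrom", "pos"]
    )
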