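# Methods

`cjmel` re-implements the downstream somatic-landscape analysis used for
small conjunctival-melanoma (CJM) cohorts: mutation-load accounting,
mutational spectra and signature refitting, the four-class genomic
classification adopted from cutaneous melanoma, copy-number profiling,
CNV–expression integration, ten-pathway alteration scoring, fusion
filtering and the cohort statistics. It consumes annotated tables
(MAF-like mutations, SEG-like copy-ratio segments, expression matrices,
annotated fusion candidates) and never performs alignment, variant
calling, segmentation or annotation itself.

## Mutation load

Per-sample counts split into SNVs, indels and the *non-neutral* subset:
the eight MAF classes Frame_Shift_Del/Ins, In_Frame_Del/Ins,
Missense_Mutation, Nonsense_Mutation, Nonstop_Mutation and Splice_Site.
The same predicate backs load summaries, group comparisons and recurrence
discovery; "non-neutral", "non-synonymous" and "exonic somatic changes"
are treated as synonyms for this one definition. Samples with zero
variants enter cohort statistics only when an explicit sample list is
supplied, which prevents silent dropouts. Coordinates are 1-based
inclusive everywhere.

## Spectra and signatures

Substitutions are collapsed onto the pyrimidine strand (six classes;
purine-reference changes are reverse-complemented together with their
trinucleotide context), giving the standard 96 context types in
class-major order. Contexts are taken from the mutation table's context
column — there is no reference-genome fetch — so records lacking context
contribute to six-class spectra but not to 96-context fits.

Exposures are refit by non-negative least squares on the normalized
96-vector against a column-stochastic catalog, then renormalized to sum
to one; the cosine similarity between observed and reconstructed vectors
is always reported. NNLS refitting was chosen because the task is
attribution against a fixed catalog, not de-novo extraction; exposures
are invariant to rescaling the input counts. Cohort PCA runs on the
six-class proportion vectors by default (96-class optional), centered,
full SVD.

The bundled 96×3 catalog is **synthetic**: three deterministic profiles
with the qualitative structure of a CpG-deamination clock process, a UV
dipyrimidine C>T process, and a broad C>T/T>C process. Peaks of the three
columns are kept on disjoint context subsets so the columns are mutually
identifiable under multinomial noise — with them, planted 0.7/0.3
mixtures at 2,000 draws are recovered within ±0.05. Real-cohort analyses
should substitute a published catalog file (COSMIC-v2 text layout is
read tolerantly of row/column order).

## Genomic classification

Per sample, precedence BRAF hotspot missense (default {p.V600E, p.G466E})
> RAS hotspot (NRAS/HRAS/KRAS, codons 12/13/61) > NF1 inactivating
(nonsense, frameshift, splice, nonstop) > triple wild-type. The tie-break
order follows the TCGA cutaneous-melanoma scheme and is configurable;
mutual exclusivity is not assumed, it is imposed by the precedence.

Recurrence discovery reports events shared by ≥3 distinct samples,
keyed by identical variant (protein change when annotated, otherwise the
genomic change) by default because the motivating hits are identical
shared variants; a gene-level mode is provided. Known drivers and
blacklisted genes (e.g. suspected sequencing artifacts) are flagged in
the output rather than removed, keeping the audit trail intact.

## Copy number

Purity-corrected log2 ratios are thresholded at log2(0.25), log2(0.75),
log2(1.5) and log2(2.0) into levels −2…+2. These cutoffs translate the
verbal call definitions (homozygous loss, heterozygous loss, 1.5–2×
increase, >2× increase); all four are configuration keys since exact
caller boundaries are tool-specific. Genome fraction altered merges
non-neutral segments by union (a raw-length mode is exposed) and divides
by the total genome length (GRCh37 default 3,095,677,412 bp,
overridable). Gene levels follow the largest-overlap rule — the segment
covering most of the gene decides, even when neutral; genes with no
overlapping segment are neutral. A sample counts as arm-altered when
≥50% of the arm is covered in one direction (threshold configurable).

## Expression integration

Expression is log10(x+1)-transformed. Dosage concordance per gene: Welch
t-test (pooled-variance optional) of carriers of level −1/−2 (deletion
test) or +1/+2 (amplification test) against the rest; a call needs
p < 0.05, a mean shift in the defining direction, and both groups ≥2
samples; when both directions pass, the smaller p wins. The direction
requirement and the minimum group size are this package's guards for
degenerate one-sample groups.

Transcriptomic programs (immune / keratin / cell-cycle) are scored as
gene-set Z-scores: per-sample mean log expression over the set,
standardized across samples; the subtype is the arg-max program. This
replaces SOM-portrait clustering with the quantity the subtype display
actually shows; the bundled gene sets are small curated stand-ins
(editable GMT files), not any study's exact sets, so subtype structure is
reproduced qualitatively only.

## Pathways

Ten canonical signaling pathways (cell cycle, p53, Hippo, Myc, Nrf2,
PI3K/Akt, RTK-RAS, TGFβ, Notch, Wnt) with editable GMT membership. A
pathway is altered-by-SNV in a sample when any member gene carries a
protein-impacting variant there — missense, nonsense, nonstop, splice,
frameshift, start-site or de-novo-start; note this list deliberately
differs from the load predicate (in-frame indels out, start classes in).
Altered-by-CNV requires both a cohort-level concordant gene and that
sample carrying a call in the matching direction. SNV and CNV evidence
stay separate columns; no merged flag is emitted because any merge rule
would be arbitrary.

## Fusion filtering

Four rules in fixed order with first-fire attribution: (1)
uncharacterized / immunoglobulin / mitochondrial partner, (2) same gene
or paralog pair, (3) present in normal-sample databases, (4) called only
by STAR-Fusion with FFPM < 0.1 (a second caller rescues the candidate).
Annotation flags are inputs; the package queries no external databases.
Fusion identity is the ordered 5'→3' pair. Filtering is idempotent and
retained + rejected partition the input; both unique-pair and
pair×sample counts are derivable from the summary since "unique events"
is ambiguous between the two.

## Statistics

Welch's t (default; pooled optional, since "t-test" alone underdetermines
the flavor), one-sided Fisher exact (exact hypergeometric tail), Pearson
chi-squared without continuity correction. No multiple-testing correction
anywhere, matching the analysis style this package reproduces; a warning
is emitted when more than 20 tests run in one report.

One printed result is knowingly irreproducible as printed: the NF1-class
lymph-invasion table described as 0:6 vs 3:4 yields a one-sided p of
210/1716 ≈ 0.122; the reported 0.049 corresponds to 0:6 vs 4:3
(84/1716). The package flags the discrepancy rather than silently
correcting either orientation; the 0.049-reproducing orientation is used
where that result is recomputed.

## Synthetic cohorts

The generator emulates a 14-patient CJM cohort with known ground truth.
Study-condition defaults: 4/14 tarsal tumors, one of which carries the
UV (bulbar) molecular profile, mirroring the discordant tarsal case such
cohorts contain; class composition BRAF 4 / RAS 3 / NF1 5 / triple-WT 2
via largest-remainder quota allocation (stratified composition — at
n = 14 the composition is exact rather than multinomially noisy); two
extra NF1 inactivating variants in RAS-class samples so NF1 is mutated
in 7/14 while staying exclusive with BRAF.

Loads: per-profile mean non-neutral counts 195 (tarsal) / 742 (bulbar),
log-normal with σ = 0.45, triple-WT samples scaled by 0.35 (they carry
the lowest loads); 0.34 of SNVs are coding non-neutral; indel counts
log-normal with mean 87. These four numbers are calibration choices
fixed so that the default cohort's summary statistics (median
non-neutral ≈ 518, mean SNVs ≈ 1,447, triple-WT mean ≈ 223) match the
study conditions; per-sample variance is not reported anywhere, so σ is
a design choice bracketing the published range.

Contexts are multinomial draws from the sample's Dirichlet-jittered
(α = 60) signature mixture — bulbar template 0.80 UV / 0.15 clock / 0.05
broad, tarsal 0.35 / 0.20 / 0.45 — presented on random strands so the
collapse step is exercised. CNV segments are placed without overlap on a
miniature genome (24 pseudo-chromosomes, GRCh37 proportions scaled
1000×) until a class-dependent target fraction is reached (BRAF 0.18,
others 0.37, sd 0.09), the last segment trimmed to the target; dosage
genes get dedicated segments in about half the samples. Expression is
log-normal baseline + 0.35 log10 per copy level on dosage genes + 0.6
log10 program offset; subtype quotas ≈ 5:3:3 immune/keratin/cell-cycle.
Fusion tables mix retained candidates (three pairs recurrent in two
samples, several involving known cancer genes) with one decoy per filter
rule.

What the generator does *not* emulate: positional clustering and
mutational hotspots beyond the planted drivers, subclonal structure,
APOBEC-style processes, arm-level CNV correlation structure, realistic
gene lengths (the 1000× compression shrinks coordinate space, which is
why background variants carry annotator-style protein identities), or
missing RNA for a subset of patients. Passing tests therefore demonstrate
correctness of the analysis logic under the stated statistical
conditions, not performance on real sequencing artifacts.

## Problem sizes and numerics

Cohort-statistic checks average six to ten 14-sample cohorts, the scale
the method targets. NNLS uses scipy's active-set solver; exposures below
machine precision are exactly zero by construction. Z-scores use
population (ddof = 0) standardization. Ties in largest-overlap gene
calls resolve to the first segment encountered in input order; quota
allocation breaks remainder ties in class order. Degenerate inputs
(all-zero context vectors, constant expression, zero-margin tables,
single-carrier groups) raise explicit errors or guarded "none" calls
rather than propagating NaN.

## Known limitations

- Exposure values for real cohorts depend on the catalog supplied;
  bundled-catalog results are structural, not biological.
- The pathway and program gene sets are deliberately small; frequencies
  computed from them are not comparable to publications using the full
  curated sets.
- `arm_frequency` uses a coverage-fraction rule, not a segmentation-aware
  caller; GISTIC-style significance (q-values) is out of scope.
- The miniature genome is for simulation only; real SEG inputs should be
  analysed with the true genome length and a real gene map.
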