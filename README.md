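# cjmel

Somatic-landscape analysis for conjunctival melanoma (CJM) cohorts — and
for any small tumor cohort with MAF-like mutation tables, purity-corrected
copy-ratio segments, an expression matrix and annotated fusion candidates.

CJM is a rare, UV-associated cancer of the eye surface. Cohorts are
necessarily small (about a dozen tumor/normal pairs), so the analysis that
matters is careful downstream accounting rather than large-scale driver
discovery: how heavy is the mutation load, which mutational processes
(signatures) explain the 96-context substitution pattern, which of the
four cutaneous-melanoma genomic classes (*BRAF*, *RAS*, *NF1*, triple
wild-type) each tumor falls into, how much of the genome is altered by
copy number, which copy-number changes are dosage-concordant with
expression, which of the ten canonical signaling pathways are hit, and
which gene fusions survive a conservative filtering cascade. `cjmel`
implements each of those stages as a tested library with a thin CLI, plus
a synthetic-cohort simulator with known ground truth so the whole stack is
verifiable without access to patient data.

## Core quantities

- **Non-neutral load** — count of variants in the eight protein-changing
  MAF classes (frameshift and in-frame indels, missense, nonsense,
  nonstop, splice site).
- **Signature exposures** — non-negative weights *w* minimizing
  ‖C·w − m‖₂ with w ≥ 0, where *m* is the sample's normalized 96-context
  vector and *C* a column-stochastic signature catalog (NNLS refitting);
  reported with the cosine similarity of the reconstruction.
- **Genomic class** — precedence BRAF hotspot > RAS hotspot (codons
  12/13/61) > NF1 inactivating > triple wild-type.
- **Genome fraction altered** — union length of non-neutral copy-number
  segments divided by genome length; gene levels −2…+2 by thresholding
  log2 ratios at log2(0.25), log2(0.75), log2(1.5), log2(2).
- **Dosage concordance** — Welch t-test of carriers vs rest on log10
  expression, with a direction requirement (deleted ⇒ lower, amplified ⇒
  higher), α = 0.05 and both groups ≥ 2.
- **Pathway alteration matrix** — per pathway × sample, separate SNV and
  concordant-CNV evidence flags.
- **Fusion filter** — four rules in order: bad partner classes, same
  gene/paralogs, normal-database hits, single-caller support with
  FFPM < 0.1.

See `docs/methods.md` for the full model description, parameter defaults
and limitations.

## Worked example

Simulate a 14-patient cohort at the default study conditions and classify
it:

```sh
cjmel simulate --n 14 --seed 7 --outdir demo/sim
cjmel classify --mutations demo/sim/mutations.tsv --clinical demo/sim/clinical.tsv
```

```
sample_id   class_label  evidence
CM01        NF1          NF1:p.R618*
...
CM06        BRAF         BRAF:p.V600E
CM13        BRAF         BRAF:p.G466E
CM14        RAS          NRAS:p.Q61L
# counts    BRAF=4  RAS=3  NF1=5  TripleWT=2
```

Four samples carry BRAF hotspot missense changes, three carry RAS hotspot
mutations, five have inactivating NF1 variants and two are triple
wild-type — the composition the simulator plants, recovered exactly from
the mutation table alone.

Signature refitting against the bundled (synthetic) three-column catalog:

```sh
cjmel signatures --mutations demo/sim/mutations.tsv --clinical demo/sim/clinical.tsv
```

```
sample_id  Signature_1  Signature_7  Signature_30  cosine
CM01       0.000        0.954        0.046         0.992
CM02       0.059        0.918        0.023         0.997
CM03       0.000        0.697        0.303         0.834
...
```

Bulbar (UV-exposed) tumors are dominated by the UV-type column; the
tarsal low-load samples show a mixed profile with a lower reconstruction
cosine, as expected from their smaller mutation counts.

Recurrence discovery with an artifact blacklist:

```sh
cjmel recurrence --mutations demo/sim/mutations.tsv --blacklist USH2A
```

```
gene    protein_change  n_carriers  samples             flag
ACSS3   p.P532S         3           CM01,CM02,CM03
BRAF    p.V600E         3           CM06,CM08,CM10      known_driver
USH2A   p.T2205M        3           CM12,CM13,CM14      blacklist
```

Three identical variants shared by three samples each: the known driver
is flagged as such, the blacklisted artifact gene is flagged rather than
silently dropped, and the remaining hit (`ACSS3 p.P532S`) is the novel
candidate the procedure exists to surface.

`cjmel run-all` executes every stage (loads, spectra, exposures, classes,
recurrence, CNV fractions, gene-level calls, arm frequencies, program
Z-scores, concordance, pathway matrix, fusion filtering, cohort
statistics) into one output directory with a JSON manifest; re-running it
on the same inputs is byte-identical.

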