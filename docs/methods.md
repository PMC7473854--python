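# Methods

## The mosaic knockout model

An F0 embryo injected with Cas9 ribonucleoprotein at an early cleavage
stage is modeled as `n_cells` independent cells, each carrying two
alleles. Every allele is edited independently with probability `e` (the
guide's per-allele on-target efficiency) and, once edited, carries a
frameshifting repair product with probability `f` (the guide's frameshift
frequency, i.e. the frameshift mass of its mutant outcome spectrum).
Cells then fall into four classes:

| class | probability |
|---|---|
| biallelic frameshift (full knockout) | (e·f)² |
| biallelic edited, ≥1 in-frame allele | e² − (e·f)² |
| monoallelic edited | 2·e·(1−e) |
| unedited | (1−e)² |

Assumptions worth making explicit:

- **Efficiency is per allele**, with alleles independent. The alternative
  (per-cell efficiency with both alleles cut together) is not
  distinguishable from the printed worked values at `e = 1`, where both
  reduce to `f²`; per-allele independence is the modeling choice here and
  is what `biallelic_frameshift_prob(e, f) = (e·f)²` encodes.
- **Cells are independent** — no lineage or clonal structure. Real
  embryos inherit repair outcomes clonally from the blastomere in which
  each cut occurred; modeling that correlation is a non-goal. The model
  describes expected cell-class *fractions*, not their spatial
  arrangement.
- The "biallelic edited with in-frame" class includes any biallelic
  edited cell that is not biallelic-frameshift, i.e. frameshift/in-frame
  heterozygous cells count here, since one in-frame allele suffices to
  retain potentially functional protein.
- An in-frame edit is assumed to preserve function. This is conservative
  for knockout calling: in-frame indels in critical residues may still be
  deleterious.

The **KO-score** is `f²` (reported 0–100): the predicted fraction of
biallelic-frameshift cells among all cells at full efficiency, and the
quantity maximized when ranking guides per gene.

`simulate_mosaic` draws allele states per cell with a seeded
`numpy.random.Generator`; when a full outcome distribution is supplied
instead of scalar `f`, each edited allele samples a concrete outcome and
the frameshift flag follows from the outcome's net length change
(mod 3 ≠ 0).

### Prior pushforward

`transform_prior` maps a discrete prior over `f` (the spectrum of
frameshift frequencies over candidate target sites) through
`f ↦ (e·f)²`. Two modes:

- **infinite-cells** (`n_cells=None`): the direct pushforward of the
  prior atoms — the distribution of the *expected* knockout-cell
  fraction.
- **finite-cells**: the mixture over the prior of
  `Binomial(n_cells, (e·f)²) / n_cells`, i.e. the realized fraction in an
  embryo of `n_cells` cells. The default of 100 cells mirrors a
  schematic 100-cell mosaic.

`tail_probability` integrates mass at or **above** the threshold
(inclusive boundary — a point mass exactly at the threshold counts).
Uniform priors are discretized at bin midpoints; with 10⁴ atoms the
pushforward tail at 0.8 matches the closed form `1 − √0.8` to better
than 10⁻³.

## Outcome spectra and comparison rules

`EditingOutcome` represents one repair product. Coordinates: the cut
site sits between protospacer positions 17 and 18 (3 bp 5′ of the NGG
PAM); deletion starts are 0-based offsets relative to the cut. A
deletion flanked by microhomology has several equivalent alignments; all
shift-equivalent representations of the same edited sequence collapse to
one left-aligned genotype key, and the microhomology length μ is defined
as (number of equivalent representations − 1). This makes keys from
different predictors and aligners comparable.

Observed sequencing tables are prepared for comparison in two steps:

1. **`normalize_observed`** removes wild-type reads and insertions longer
   than 1 bp (classes outside what outcome predictors model) and
   renormalizes the residual mutant frequencies to 1.
2. **`curate_to_reference_classes`** restricts both sides to the
   predictor's 99%-cumulative class universe: scanning +1-insertion mass
   plus deletions by increasing length, the smallest deletion length L\*
   at which cumulative probability first exceeds 0.99 fixes the cutoff;
   only +1 insertions and deletions ≤ L\* are retained, renormalized.
   This prevents rare large deletions from dominating Pearson
   correlations. The +1-only insertion rule is applied to both sides.

Frequency tolerances: ingested third-party tables may be off 100% by
rounding; totals off by more than 0.1 percentage points are renormalized
with a logged warning, and `cumulative_frameshift` requires its input to
sum to 1 within 10⁻⁶. All internal normalizations conserve unit mass to
10⁻⁹.

## Concordance harness

Per guide, predicted and observed curated spectra are matched over the
union of genotype keys (zero-filled, key-sorted, hence order-invariant)
and compared by Pearson correlation with two-sided p-values from the
t-transform; no multiple-testing correction is applied (raw correlation
p-values are the convention for this design). Pooled concordance
concatenates all guides' matched class-frequency pairs into a single
correlation, weighting classes rather than guides. Frameshift
concordance correlates per-guide cumulative frameshift frequencies and
requires ≥ 3 guides.

A guide is **underpowered** when fewer than 3 matched classes survive
curation or its observed table derives from fewer than `min_reads`
(default 500) reads; such guides get no r, are excluded from the
mean ± SD summary, and are counted explicitly. Residual analyses report
predicted − observed per class (+1 insertion, or per deletion length)
with mean, SD and SEM = SD/√n over guides.

`ice_average` combines Sanger-trace-deconvolution tables from replicate
embryos: it refuses fewer than 3 embryos, averages per-class frequencies
arithmetically (absent classes contribute 0), keeps only 1-bp insertions
and deletions ≤ 20 bp, and renormalizes.

## Predictors

**Activity.** The on-target activity model is a linear regression over
position-specific mono- and di-nucleotide indicators in a 35-nt window
(6 nt upstream of the protospacer + 20-nt protospacer + 3-nt PAM + 6 nt
downstream), the architecture used by in-vivo activity models trained on
T7-transcribed guides. Coefficients are supplied as CSV
(`feature,position,weight` plus an `Intercept` row); the published
coefficient tables are external supplementary material, so tests use
synthetic coefficient tables generated at test time. The linear
predictor maps to the 0–100 reporting scale by fixed affine constants
(`score = clip(offset + scale·lp, 0, 100)`, defaults offset 0 /
scale 100) — never data-driven min/max, for reproducibility.

**Outcome spectra.** The predictor contract is: 80-nt context (40 nt
each side of the cut) in, normalized mutant `OutcomeDistribution` out.
The built-in `predict_outcomes_mh` is a transparent microhomology
heuristic, *not* a re-implementation of any trained neural network: it
enumerates every unique deletion product spanning the cut up to 30 bp,
weights each by `exp(−0.25·L) · (1+μ)²`, and adds four 1-bp insertion
channels in which the base duplicating the nucleotide 5′ of the cut gets
weight 0.25 versus 0.01 for the others (the templated-insertion bias of
staggered Cas9 cuts). Defaults were chosen once to be qualitatively
realistic — deletions dominate, mass decays with deletion length,
microhomology-mediated products are enriched, +1 insertions carry a
minority share. Exports from trained predictors are ingested via
`load_predictions` with explicit dialects (never sniffed).

**MMEJ fraction.** The fraction of mutant mass in deletions with
μ ≥ `mu_min`. The literature does not fix the microhomology length that
qualifies a deletion as MMEJ-repaired; the default is μ ≥ 2 nt, exposed
as a parameter.

## Guide design

`scan_targets` enumerates all 20-nt + NGG sites on both strands of each
CDS record, keeping only sites whose full 80-nt context fits inside the
record, in deterministic (cut position, strand) order; records with
ambiguity codes are skipped with a log entry. T7 compatibility is
interpreted as the canonical GG protospacer start, with GA acceptance as
an option. Coordinates are CDS-relative, 0-based, half-open; minus-
strand guides report the cut on the forward coordinate. Scanning is a
generator, so genome-scale runs are O(1) in memory over gene count.
Entire CDS entries are scanned (no restriction to a window around exon
starts).

Per gene, exactly one highest- and one lowest-KO-score guide is flagged;
ties break by higher activity score, then 5′-most cut position, making
flags permutation-stable. A single-guide gene carries both flags. The
quadrant report uses strict thresholds (ko > 75, activity > 50,
MMEJ > 0.90 by default) on highest-in-class guides.

## Synthetic data

The generators emulate the study design the harness targets: a panel of
28 guides over 21 genes, amplicon tables of 10⁵ reads at per-allele
efficiency 0.7, triplicate-embryo Sanger-style summaries, random CDS of
mean length 1.5 kb at GC 0.45. Ground truth distributions are built by
the microhomology heuristic from each guide's context, so they carry
realistic class structure, and their true frameshift/MMEJ values are
recorded in metadata for recovery tests.

- `gen_amplicon_table`: one multinomial draw over {WT: 1−e} ∪
  {e·truth}; frequencies are integer-count ratios.
- `gen_prediction_table`: multiplicative log-normal distortion (log-SD =
  the single `distortion` knob) then renormalization; distortion 0 is an
  exact copy.
- `gen_ice_tables`: each embryo's table is built from a *small number of
  discrete repair events* (2 × `cells_per_embryo` alleles), not
  read-level noise, so few-cell embryos show the high between-embryo
  variance that underpowers spectra measured early in development;
  deletions > 20 bp are dropped to match trace-deconvolution ingestion,
  and an embryo with zero edited alleles yields no table.

What the generators do **not** emulate: sequencing error, PCR bias,
alignment artifacts, clonal lineage structure, or the cell-type-specific
biology that real trained predictors capture. Passing recovery tests
therefore demonstrates the harness and models are self-consistent and
unbiased under the stated sampling assumptions — not that any particular
external predictor is accurate on real embryos.

## Pigment quantification

Images are pre-cropped single-eye 8-bit grayscale rasters (conversion
from RGB uses the standard Rec. 601 luminance weights 0.299/0.587/0.114,
opt-in). The pigment mask counts pixels with intensity in [1, 30], both
bounds inclusive (dark pixels; 0 excluded as background). The phenotype
score is `(max_ref − masked_pixels) / max_ref` against the most
pigmented reference eye of the batch, clipped at 0 with a warning if a
count exceeds the reference; `max_ref` is always explicit, never
auto-detected, so scores are comparable across runs.

## Problem sizes and numerical choices

Monte-Carlo checks use 10⁵ cells (binomial SE ≈ 0.0015 at p = 0.64,
asserted within 3 SE); prior pushforwards use 10⁴ atoms; oracle
equivalence tests use 1,000 random activity pairs, 200 random scan
sequences, and 100 random curation references; panel recovery uses 28
guides at 10⁵ reads. These sizes make every statistical check decisively
powered while keeping the full suite fast.

## Known limitations

- The built-in outcome heuristic is a stand-in: use trained predictor
  exports for real design decisions.
- No off-target assessment; pair the design output with an external
  off-target screen.
- The mosaic model ignores clonal structure and assumes binary
  functional/non-functional alleles.
- Observed tables are ingested pre-summarized; no read alignment or
  variant calling from FASTQ.
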