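# mosaicko

Guide-RNA prioritization and mosaic F0 knockout modeling for CRISPR/Cas9
experiments in early vertebrate embryos (*Xenopus*, zebrafish, and similar
injection-based systems).

## The problem

CRISPR/Cas9 injected into a one- to few-cell embryo produces a **mosaic**
F0 animal: each cell repairs its double-strand breaks independently, so
cells carry different mixtures of deletions, insertions, and unedited
alleles. Even with efficient cutting, a phenotype can be masked by cells
that retain an **in-frame** allele producing functional protein. Because
repair outcomes are dictated by local sequence context, they are
predictable — and that predictability can be exploited at design time to
pick guides whose editing spectra are enriched for frameshifts.

With per-allele editing probability *e* and per-edited-allele frameshift
probability *f* (alleles and cells independent), the probability that a
single cell is a complete protein knockout (biallelic frameshift) is

    P(KO cell) = (e · f)²

At full efficiency this is *f*² — the **KO-score** (reported 0–100). The
relation is quadratic, so a guide with *f* = 0.80 still leaves 36% of
cells with at least one potentially functional allele, and the penalty
grows quickly as *f* or *e* drop.

`mosaicko` provides:

- **`outcome_core`** — editing-outcome spectra (deletions / insertions /
  wild type) with the standard comparison rules: wild-type and >1-bp
  insertion filtering of observed tables, 99%-cumulative curation to a
  predictor's class universe, frameshift frequency, KO-score.
- **`predictors`** — position-specific k-mer activity regression (0–100
  scoring from a coefficient CSV), a pluggable outcome-predictor contract
  with a built-in microhomology heuristic, MMEJ-fraction computation, and
  readers for external predictor exports.
- **`mosaic_model`** — analytic and Monte-Carlo mosaic-embryo models, and
  the pushforward of a frameshift-frequency prior into the distribution
  of knockout-cell fractions (with tail probabilities).
- **`concordance`** — per-guide, pooled, and cumulative-frameshift
  Pearson correlations between predicted and observed spectra, residual
  analyses, underpowered-guide flagging, and averaging of replicate
  Sanger-deconvolution tables.
- **`guide_design`** — CDS scanning for SpCas9 sites (T7-compatible GG
  starts), per-guide scoring, highest/lowest-in-class flags per gene, and
  threshold quadrant reports.
- **`synthetic_data`** — seeded generators for every input format with
  known ground truth, for parameter-recovery testing.
- **`pigment_quant`** — masked-pixel eye-pigmentation scoring used as a
  knockout phenotype readout.

## Worked example

```python
from mosaicko import (
    predict_outcomes_mh, cumulative_frameshift, mmej_fraction,
    ko_score_percent, expected_mosaic, FrameshiftPrior,
    transform_prior, tail_probability,
)

# 80-nt context around a cut site (40 nt each side)
ctx = "GATTACAGGCTTAACGTGCA" * 4
dist = predict_outcomes_mh(ctx, guide_id="demo")

f = cumulative_frameshift(dist)
print(f"frameshift = {f:.3f}")                  # frameshift = 0.722
print(f"mmej       = {mmej_fraction(dist):.3f}")  # mmej       = 0.210
print(f"ko_score   = {ko_score_percent(f):.1f}")  # ko_score   = 52.1

# a perfect-efficiency guide with an 80% frameshift spectrum:
m = expected_mosaic(e=1.0, f=0.8)
print(m.fractions["biallelic_frameshift"])      # 0.64

# chance a randomly designed guide (uniform frameshift prior) yields
# >= 80% knockout cells at full efficiency:
prior = FrameshiftPrior.uniform(10_000)
tail = tail_probability(transform_prior(prior, 1.0, n_cells=None), 0.8)
print(f"{tail:.4f}")                            # 0.1056  (= 1 - sqrt(0.8))
```

`predict_outcomes_mh` is a documented heuristic stand-in (exponential
deletion-length decay × microhomology bonus + 1-bp insertion channels);
exports from trained outcome predictors drop in through
`load_predictions` without code changes.

A command-line interface mirrors the three workflows:

```sh
mosaicko design genes.fasta --coeffs crisprscan_coeffs.csv --out guides.csv
mosaicko evaluate --pred predicted.csv --obs observed.csv --out report.csv
mosaicko simulate -e 1.0 -f 0.8 --prior uniform --threshold 0.8 --out sim.json
mosaicko synth --seed 2 --outdir panel/
mosaicko pigment eye*.png --max-ref 79408 --out pigment.csv
```

## Documentation

See `docs/methods.md` for the model assumptions, parameter defaults,
numerical conventions, and known limitations.
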