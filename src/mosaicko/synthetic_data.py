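"""Synthetic inputs with controlled ground truth.

Every file format and table the pipeline consumes can be generated here
with a known underlying truth, enabling parameter-recovery tests end to
end: random coding sequences (FASTA), per-guide ground-truth outcome
distributions, deep-sequencing amplicon indel tables (multinomial read
sampling at a given editing efficiency), distorted mock prediction
tables, and few-embryo Sanger-deconvolution-style summaries whose
between-embryo variance comes from a small number of discrete repair
events — the mechanism that underpowers spectra measured in embryos with
few cells at the time of editing.

All generators are seeded and bit-reproducible; seeds and parameters are
recorded in each output's metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .outcome_core import (
    EditingOutcome,
    OutcomeDistribution,
    OutcomeKind,
    cumulative_frameshift,
)
from .predictors import MHPredictorParams, mmej_fraction, predict_outcomes_mh

__all__ = [
    "SynthConfig",
    "gen_cds",
    "write_fasta",
    "gen_guide_panel",
    "gen_truth",
    "gen_amplicon_table",
    "gen_prediction_table",
    "gen_ice_tables",
]

BASES = np.array(list("ACGT"))


@dataclass
class SynthConfig:
    """Study-scale defaults for a synthetic guide panel.

    Defaults mirror a typical amplicon-sequencing panel in injected
    embryos: a panel of 28 guides over 21 genes, deep amplicon coverage,
    per-allele editing efficiencies in the range observed in practice,
    and triplicate embryos for Sanger-style summaries.
    """

    rng_seed: int = 0
    n_genes: int = 21
    n_guides: int = 28
    gene_length_mean: int = 1500
    gene_length_sd: int = 400
    gene_length_min: int = 300
    gc_content: float = 0.45
    efficiency: float = 0.7
    n_reads: int = 100_000
    distortion: float = 0.0
    n_embryos: int = 3
    cells_per_embryo: int = 16
    truth_params: MHPredictorParams = field(default_factory=MHPredictorParams)

    def __post_init__(self) -> None:
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")
        if not 0 <= self.efficiency <= 1:
            raise ValueError("efficiency must be in [0, 1]")
        if self.distortion < 0:
            raise ValueError("distortion must be >= 0")


def gen_cds(config: SynthConfig) -> list[tuple[str, str]]:
    """Random coding-like sequences as (gene_id, sequence) pairs.

    Lengths are normal around ``gene_length_mean`` (clipped below at
    ``gene_length_min``); base composition is i.i.d. with the requested GC
    content.  Deterministic per seed.
    """
    rng = np.random.default_rng(config.rng_seed)
    gc = config.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    records = []
    for i in range(config.n_genes):
        length = int(
            max(
                config.gene_length_min,
                rng.normal(config.gene_length_mean, config.gene_length_sd),
            )
        )
        seq = "".join(rng.choice(BASES, size=length, p=probs))
        records.append((f"gene{i:04d}", seq))
    return records


def write_fasta(records: list[tuple[str, str]], path) -> None:
    """Write (id, sequence) pairs as FASTA, 70 columns."""
    with open(path, "w") as fh:
        for gene_id, seq in records:
            fh.write(f">{gene_id}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def gen_truth(
    context80: str, config: SynthConfig | None = None, guide_id: str = "truth"
) -> OutcomeDistribution:
    """Ground-truth mutant outcome distribution for one cut site.

    Built from the sequence context by the microhomology heuristic (so +1
    insertions, microhomology and non-microhomology deletions all appear
    with realistic structure); the distribution's frameshift frequency and
    MMEJ fraction are recorded in metadata as the recoverable ground truth.
    """
    config = config or SynthConfig()
    dist = predict_outcomes_mh(context80, config.truth_params, guide_id=guide_id)
    dist = replace(dist, source="predicted", method="synthetic-truth")
    dist.metadata["true_frameshift"] = cumulative_frameshift(dist)
    dist.metadata["true_mmej"] = mmej_fraction(dist)
    return dist


def gen_amplicon_table(
    truth: OutcomeDistribution, e: float, n_reads: int, seed: int
) -> OutcomeDistribution:
    """Simulated deep-sequencing indel table, wild-type reads included.

    Reads are a single multinomial draw: wild type with probability
    ``1 - e``, mutant mass ``e`` split according to ``truth``.  Frequencies
    are counts / n_reads; efficiency, seed and read depth are recorded in
    metadata.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if not 0 <= e <= 1:
        raise ValueError("efficiency must be in [0, 1]")
    rng = np.random.default_rng(seed)
    truth = truth.normalized()
    outcomes = [o for o, _ in truth.entries]
    probs = np.array([f for _, f in truth.entries])
    full_probs = np.concatenate([[1 - e], e * probs])
    counts = rng.multinomial(n_reads, full_probs)
    entries: list[tuple[EditingOutcome, float]] = []
    if counts[0] > 0:
        entries.append((EditingOutcome(OutcomeKind.WILDTYPE), counts[0] / n_reads))
    for o, c in zip(outcomes, counts[1:]):
        if c > 0:
            entries.append((o, c / n_reads))
    return OutcomeDistribution(
        guide_id=truth.guide_id,
        source="observed",
        method="synthetic-amplicon",
        entries=entries,
        metadata={"efficiency": e, "n_reads": n_reads, "seed": seed},
    )


def gen_prediction_table(
    truth: OutcomeDistribution, distortion: float, seed: int
) -> OutcomeDistribution:
    """Mock predictor export: truth distorted by multiplicative noise.

    Each frequency is multiplied by an i.i.d. log-normal factor with
    log-SD ``distortion`` and the table renormalized — the simplex stays
    valid and ``distortion=0`` returns an exact copy.  This is the single
    knob that degrades prediction-observation concordance in simulation
    studies.
    """
    if distortion < 0:
        raise ValueError("distortion must be >= 0")
    truth = truth.normalized()
    entries = truth.entries
    if distortion > 0:
        rng = np.random.default_rng(seed)
        factors = rng.lognormal(mean=0.0, sigma=distortion, size=len(entries))
        entries = [(o, f * w) for (o, f), w in zip(entries, factors)]
    dist = OutcomeDistribution(
        guide_id=truth.guide_id,
        source="predicted",
        method="synthetic-prediction",
        entries=list(entries),
        metadata={"distortion": distortion, "seed": seed},
    )
    return dist.normalized()


def gen_ice_tables(
    truth: OutcomeDistribution,
    e: float,
    n_embryos: int,
    cells_per_embryo: int,
    seed: int,
) -> list[OutcomeDistribution]:
    """Per-embryo Sanger-deconvolution-style mutant outcome tables.

    Each embryo contributes ``2 * cells_per_embryo`` alleles, each edited
    with probability ``e``; edited alleles draw a discrete repair outcome
    from ``truth``.  The embryo's table is the empirical mutant-outcome
    frequency over those few discrete repair events, with deletions longer
    than 20 bp dropped (and the table renormalized) to match
    trace-deconvolution ingestion.  Few cells per embryo therefore give
    noisy, high-variance tables — the small-mosaic underpowering regime.
    Embryos with no mutant allele yield no table (they carry no editable
    signal).
    """
    if n_embryos < 1 or cells_per_embryo < 1:
        raise ValueError("n_embryos and cells_per_embryo must be >= 1")
    if not 0 <= e <= 1:
        raise ValueError("efficiency must be in [0, 1]")
    rng = np.random.default_rng(seed)
    truth = truth.normalized()
    outcomes = [o for o, _ in truth.entries]
    probs = np.array([f for _, f in truth.entries])
    tables: list[OutcomeDistribution] = []
    for embryo in range(n_embryos):
        n_alleles = 2 * cells_per_embryo
        edited = rng.random(n_alleles) < e
        n_mut = int(edited.sum())
        if n_mut == 0:
            continue
        draws = rng.choice(len(outcomes), size=n_mut, p=probs)
        counts: dict[int, int] = {}
        for d in draws:
            counts[d] = counts.get(d, 0) + 1
        entries = [
            (outcomes[i], c / n_mut)
            for i, c in sorted(counts.items())
            if not (
                outcomes[i].kind is OutcomeKind.DELETION and outcomes[i].length > 20
            )
        ]
        if not entries:
            continue
        dist = OutcomeDistribution(
            guide_id=truth.guide_id,
            source="observed",
            method="synthetic-ice",
            entries=entries,
            metadata={
                "efficiency": e,
                "cells_per_embryo": cells_per_embryo,
                "embryo": embryo,
                "seed": seed,
            },
        )
        tables.append(dist.normalized())
    return tables


def gen_guide_panel(config: SynthConfig) -> list[tuple[str, str]]:
    """Draw (guide_id, context80) pairs from synthetic coding sequences.

    Genes are generated with :func:`gen_cds`; cut sites are placed
    uniformly at random (with full 40-nt flanks), cycling through genes so
    the panel covers roughly ``n_guides / n_genes`` guides per gene as in
    a multi-guide-per-gene panel.
    """
    rng = np.random.default_rng(config.rng_seed + 1)
    records = gen_cds(config)
    panel = []
    for k in range(config.n_guides):
        gene_id, seq = records[k % len(records)]
        cut = int(rng.integers(40, len(seq) - 40 + 1))
        panel.append((f"{gene_id}:g{k}", seq[cut - 40 : cut + 40]))
    return panel
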