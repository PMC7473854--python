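"""Genome-wide guide scanning, scoring and per-gene classification.

Scans coding sequences for SpCas9 target sites (20-nt protospacer + NGG
PAM, both strands), extracts the sequence-context windows each scorer
needs, and computes per guide: an on-target activity score, the predicted
frameshift frequency, the microhomology-repair (MMEJ) fraction, and the
knockout score (square of the frameshift frequency, 0-100 scale).  Per
gene, the guides with the maximal and minimal KO-score are flagged
highest- and lowest-in-class; a quadrant report then counts how many genes
own a highest-in-class guide clearing joint KO-score / activity
thresholds.

Coordinates are CDS-relative, 0-based and half-open.  The cut site lies
between protospacer positions 17 and 18 (3 bp 5' of the PAM); minus-strand
guides report the cut on the forward CDS coordinate.  Scanning streams
record by record so memory stays flat in gene count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Iterator

from Bio.Seq import Seq

from .outcome_core import OutcomeDistribution, cumulative_frameshift, ko_score_percent
from .predictors import (
    ActivityModel,
    PredictorContext,
    activity_score,
    mmej_fraction,
)

__all__ = [
    "GuideTarget",
    "GuideScores",
    "ScoredGuide",
    "scan_targets",
    "score_guide",
    "classify_per_gene",
    "quadrant_report",
]

logger = logging.getLogger(__name__)

PROTOSPACER_LEN = 20
#: cut offset from protospacer start: between positions 17 and 18
CUT_OFFSET = 17
UPSTREAM_CONTEXT = 40  # context80 half-width around the cut
_MIN_FLANK = 40  # bases required on each side of the cut for full contexts


@dataclass(frozen=True)
class GuideTarget:
    """One protospacer+PAM hit with its extracted context windows."""

    gene_id: str
    protospacer: str
    pam: str
    strand: str  # "+" or "-"
    cut_pos: int  # forward CDS coordinate, 0-based, between nucleotides
    contexts: PredictorContext

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if len(self.protospacer) != PROTOSPACER_LEN:
            raise ValueError("protospacer must be 20 nt")
        if len(self.pam) != 3 or self.pam[1:] != "GG":
            raise ValueError(f"PAM {self.pam!r} does not match NGG")

    @property
    def guide_id(self) -> str:
        return f"{self.gene_id}:{self.cut_pos}:{self.strand}"


@dataclass
class GuideScores:
    """All per-guide predictions on their reporting scales."""

    activity: float  # 0-100
    frameshift_freq: float  # 0-1
    mmej: float  # 0-1
    ko_score: float  # 0-100
    highest_in_class: bool = False
    lowest_in_class: bool = False

    def __post_init__(self) -> None:
        # the square relation must hold between the 0-1 and 0-100 scales
        if abs(self.ko_score - 100.0 * self.frameshift_freq**2) > 1e-6:
            raise ValueError("ko_score inconsistent with frameshift_freq**2")


@dataclass
class ScoredGuide:
    target: GuideTarget
    scores: GuideScores
    outcome_distribution: OutcomeDistribution | None = None


def _contexts_at(seq: str, cut: int, strand: str) -> PredictorContext | None:
    """Extract guide-strand context windows around a forward cut coordinate."""
    if cut < _MIN_FLANK or cut + _MIN_FLANK > len(seq):
        return None
    window80 = seq[cut - 40 : cut + 40]
    if strand == "-":
        window80 = str(Seq(window80).reverse_complement())
    context65 = window80[10:75]
    context35 = window80[40 - CUT_OFFSET - 6 : 40 - CUT_OFFSET - 6 + 35]
    return PredictorContext(window80, context65, context35)


def scan_targets(
    gene_sequences: Iterable[tuple[str, str]],
    t7_filter: bool = True,
    t7_allow_ga: bool = False,
) -> Iterator[GuideTarget]:
    """Enumerate SpCas9 targets with full context windows, both strands.

    ``gene_sequences`` yields ``(gene_id, sequence)`` pairs (SeqRecords
    work too).  Sites whose 80-nt context would extend past the record are
    skipped, as are records containing non-ACGT symbols (with a log entry).
    With ``t7_filter`` only protospacers starting GG (optionally GA) are
    kept — the canonical requirement for efficient T7 in-vitro
    transcription.  Output order is deterministic: by cut position, then
    strand (+ before -).
    """

    def _passes_t7(protospacer: str) -> bool:
        head = protospacer[:2]
        return head == "GG" or (t7_allow_ga and head == "GA")

    for record in gene_sequences:
        if hasattr(record, "seq"):  # Bio.SeqRecord
            gene_id, seq = record.id, str(record.seq)
        else:
            gene_id, seq = record
        seq = seq.upper()
        if any(b not in "ACGT" for b in seq):
            logger.warning("record %s contains non-ACGT symbols; skipped", gene_id)
            continue
        if len(seq) < 2 * _MIN_FLANK:
            logger.info("record %s shorter than minimal context; skipped", gene_id)
            continue
        hits = []
        # + strand: protospacer [i, i+20), PAM [i+20, i+23) = NGG, cut at i+17
        for i in range(0, len(seq) - PROTOSPACER_LEN - 3 + 1):
            if seq[i + 21 : i + 23] == "GG":
                hits.append((i + CUT_OFFSET, "+", seq[i : i + 20], seq[i + 20 : i + 23]))
        # - strand: forward CCN at [j, j+3), protospacer revcomp of [j+3, j+23),
        # cut between forward positions j+5 and j+6
        for j in range(0, len(seq) - 23 + 1):
            if seq[j : j + 2] == "CC":
                proto = str(Seq(seq[j + 3 : j + 23]).reverse_complement())
                pam = str(Seq(seq[j : j + 3]).reverse_complement())
                hits.append((j + 6, "-", proto, pam))
        hits.sort(key=lambda h: (h[0], h[1]))
        for cut, strand, proto, pam in hits:
            if t7_filter and not _passes_t7(proto):
                continue
            contexts = _contexts_at(seq, cut, strand)
            if contexts is None:
                continue
            yield GuideTarget(
                gene_id=gene_id,
                protospacer=proto,
                pam=pam,
                strand=strand,
                cut_pos=cut,
                contexts=contexts,
            )


def score_guide(
    target: GuideTarget,
    activity_model: ActivityModel,
    outcome_predictor: Callable[[str], OutcomeDistribution],
    mmej_mu_min: int = 2,
    keep_distribution: bool = False,
) -> ScoredGuide:
    """Score one target: activity, frameshift frequency, MMEJ, KO-score.

    ``outcome_predictor`` maps an 80-nt context to a mutant
    :class:`OutcomeDistribution` (the built-in heuristic or a loader of
    external predictions).  Predictor failures propagate with the guide
    identity attached.
    """
    act = activity_score(target.contexts.context35, activity_model)
    try:
        dist = outcome_predictor(target.contexts.context80)
        fs = cumulative_frameshift(dist)
        mmej = mmej_fraction(dist, mu_min=mmej_mu_min, context=target.contexts.context80)
    except Exception as exc:
        raise RuntimeError(f"outcome prediction failed for guide {target.guide_id}") from exc
    scores = GuideScores(
        activity=act,
        frameshift_freq=fs,
        mmej=mmej,
        ko_score=ko_score_percent(fs),
    )
    return ScoredGuide(target, scores, dist if keep_distribution else None)


def classify_per_gene(guides: list[ScoredGuide]) -> dict[str, dict]:
    """Flag the highest- and lowest-KO-score guide of every gene (in place).

    Ties break by higher activity score, then by 5'-most cut position, so
    flags are stable under input permutation.  A single-guide gene carries
    both flags.  Returns a per-gene summary mapping.
    """
    if not guides:
        raise ValueError("no guides to classify")
    by_gene: dict[str, list[ScoredGuide]] = {}
    for g in guides:
        by_gene.setdefault(g.target.gene_id, []).append(g)
    summary: dict[str, dict] = {}
    for gene_id, group in by_gene.items():
        def _rank(g: ScoredGuide):
            return (g.scores.ko_score, g.scores.activity, -g.target.cut_pos)

        best = max(group, key=_rank)
        worst = min(group, key=_rank)
        for g in group:
            g.scores.highest_in_class = g is best
            g.scores.lowest_in_class = g is worst
        summary[gene_id] = {
            "n_guides": len(group),
            "highest_in_class": best.target.guide_id,
            "highest_ko_score": best.scores.ko_score,
            "highest_activity": best.scores.activity,
            "highest_mmej": best.scores.mmej,
            "lowest_in_class": worst.target.guide_id,
            "lowest_ko_score": worst.scores.ko_score,
        }
    return summary


def quadrant_report(
    guides: list[ScoredGuide],
    ko_threshold: float = 75.0,
    activity_threshold: float = 50.0,
    mmej_threshold: float = 0.90,
) -> dict:
    """Threshold summary over a classified guide table.

    Reports (with exact counts) the fraction of genes whose
    highest-in-class guide clears both the KO-score and activity
    thresholds (the designable-gene quadrant), and the fraction of
    highest-in-class guides whose predicted MMEJ repair exceeds
    ``mmej_threshold``; invariant to row order.
    """
    if not 0 <= ko_threshold <= 100 or not 0 <= activity_threshold <= 100:
        raise ValueError("ko/activity thresholds must be in [0, 100]")
    if not 0 <= mmej_threshold <= 1:
        raise ValueError("mmej threshold must be in [0, 1]")
    hic = [g for g in guides if g.scores.highest_in_class]
    if not hic:
        raise ValueError("no highest-in-class flags set; run classify_per_gene first")
    n_genes = len({g.target.gene_id for g in hic})
    n_pass = sum(
        1
        for g in hic
        if g.scores.ko_score > ko_threshold and g.scores.activity > activity_threshold
    )
    n_mmej = sum(1 for g in hic if g.scores.mmej > mmej_threshold)
    return {
        "n_genes": n_genes,
        "n_guides": len(guides),
        "ko_threshold": ko_threshold,
        "activity_threshold": activity_threshold,
        "mmej_threshold": mmej_threshold,
        "genes_with_designable_guide": n_pass,
        "fraction_genes_designable": n_pass / n_genes,
        "highest_in_class_high_mmej": n_mmej,
        "fraction_highest_high_mmej": n_mmej / len(hic),
    }
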