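"""Prediction-versus-observation concordance for editing-outcome spectra.

Given predicted outcome distributions and experimentally observed indel
tables for a panel of guides, this harness reproduces the standard
evaluation battery: per-guide Pearson correlation over matched outcome
classes, a pooled correlation over all guides' class frequencies
concatenated, a correlation of per-guide cumulative frameshift
frequencies, and residual (predicted - observed) analyses per outcome
class.  Observed tables are first passed through the wild-type /
long-insertion filter and both sides are curated to the predictor's
99%-cumulative class universe, so rare large deletions do not dominate
the correlations.

Guides whose matched class count falls below 3, or whose observed table
was built from fewer reads than ``min_reads``, are flagged *underpowered*:
no r is reported for them and they are excluded from the mean +/- SD
summary (the count of such guides is surfaced).  Sanger-deconvolution
summaries from replicate embryos are combined by :func:`ice_average`
before entering the harness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .outcome_core import (
    OutcomeDistribution,
    OutcomeKind,
    cumulative_frameshift,
    curate_to_reference_classes,
    match_outcomes,
    normalize_observed,
)

__all__ = [
    "GuideConcordance",
    "ConcordanceResult",
    "prepare_pair",
    "guide_concordance",
    "pooled_concordance",
    "frameshift_concordance",
    "residual_analysis",
    "ice_average",
    "evaluate_panel",
]


@dataclass
class GuideConcordance:
    guide_id: str
    r: float | None
    p: float | None
    n_classes: int
    underpowered: bool = False


@dataclass
class ConcordanceResult:
    """Full evaluation of a guide panel against one predictor."""

    per_guide: list[GuideConcordance]
    pooled_r: float
    pooled_p: float
    frameshift_r: float | None
    frameshift_p: float | None
    mean_r: float
    sd_r: float
    n_underpowered: int
    residual_plus1: pd.DataFrame
    residual_deletions: pd.DataFrame

    def per_guide_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "guide_id": g.guide_id,
                    "r": g.r,
                    "p": g.p,
                    "n_classes": g.n_classes,
                    "underpowered": g.underpowered,
                }
                for g in self.per_guide
            ]
        )


def prepare_pair(
    pred: OutcomeDistribution, obs_raw: OutcomeDistribution
) -> tuple[OutcomeDistribution, OutcomeDistribution]:
    """Filter and curate one (predicted, observed) pair for comparison.

    The observed table loses wild-type reads and >1-bp insertions and is
    renormalized; both sides are then restricted to the predicted
    distribution's 99%-cumulative classes (+1 insertions, deletions up to
    L*) and renormalized.
    """
    obs = normalize_observed(obs_raw)
    pred_c = curate_to_reference_classes(pred, pred)
    obs_c = curate_to_reference_classes(obs, pred)
    return pred_c, obs_c


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def guide_concordance(
    pred: OutcomeDistribution,
    obs: OutcomeDistribution,
    min_reads: int | None = 500,
) -> GuideConcordance:
    """Pearson correlation over one guide's matched, zero-filled class vectors.

    Inputs must already be curated (see :func:`prepare_pair`).  Fewer than
    3 matched classes, or an observed table derived from fewer than
    ``min_reads`` reads (when the read count is recorded), flags the guide
    underpowered with no r reported.
    """
    keys, pvec, ovec = match_outcomes(pred, obs)
    n_reads = obs.metadata.get("n_reads")
    underpowered = len(keys) < 3 or (
        min_reads is not None and n_reads is not None and n_reads < min_reads
    )
    if underpowered:
        return GuideConcordance(pred.guide_id, None, None, len(keys), True)
    r, p = _pearson(pvec, ovec)
    return GuideConcordance(pred.guide_id, r, p, len(keys), False)


def pooled_concordance(
    pairs: list[tuple[OutcomeDistribution, OutcomeDistribution]],
) -> tuple[float, float]:
    """Single Pearson correlation over all guides' class frequencies at once.

    Matched zero-filled vectors are concatenated across guides; this
    weights every outcome class equally rather than every guide.
    """
    if not pairs:
        raise ValueError("pooled concordance requires at least one pair")
    xs, ys = [], []
    for pred, obs in pairs:
        _, pvec, ovec = match_outcomes(pred, obs)
        xs.append(pvec)
        ys.append(ovec)
    return _pearson(np.concatenate(xs), np.concatenate(ys))


def frameshift_concordance(
    pairs: list[tuple[OutcomeDistribution, OutcomeDistribution]],
) -> tuple[float, float]:
    """Pearson correlation of per-guide cumulative frameshift frequencies."""
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 guides for a frameshift correlation, got {len(pairs)}")
    x = np.array([cumulative_frameshift(p) for p, _ in pairs])
    y = np.array([cumulative_frameshift(o) for _, o in pairs])
    return _pearson(x, y)


def residual_analysis(
    pairs: list[tuple[OutcomeDistribution, OutcomeDistribution]],
    class_selector: str = "plus1",
) -> pd.DataFrame:
    """Per-class residuals (predicted - observed) across the guide panel.

    ``class_selector="plus1"`` reports the +1-insertion class (summed over
    inserted bases) — the class HEK293T-trained predictors systematically
    inflate relative to embryo observations.  ``"deletion_length"`` reports
    one row per deletion length.  Each row carries the residual mean, SD,
    and SEM = SD / sqrt(n) over guides.
    """
    if class_selector not in ("plus1", "deletion_length"):
        raise ValueError(f"unknown class selector {class_selector!r}")

    def class_freqs(dist: OutcomeDistribution) -> dict:
        out: dict = {}
        for o, f in dist.entries:
            if class_selector == "plus1":
                if o.kind is OutcomeKind.INSERTION and o.length == 1:
                    out["+1"] = out.get("+1", 0.0) + f
            else:
                if o.kind is OutcomeKind.DELETION:
                    out[o.length] = out.get(o.length, 0.0) + f
        return out

    residuals: dict = {}
    for pred, obs in pairs:
        pf, of = class_freqs(pred), class_freqs(obs)
        for cls in set(pf) | set(of):
            residuals.setdefault(cls, []).append(pf.get(cls, 0.0) - of.get(cls, 0.0))
    if not residuals:
        raise ValueError(f"selector {class_selector!r} matched no class in any guide")
    rows = []
    for cls in sorted(residuals, key=str):
        vals = np.array(residuals[cls])
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        rows.append(
            {
                "outcome_class": cls,
                "n_guides": len(vals),
                "mean_residual": float(vals.mean()),
                "sd": sd,
                "sem": sd / np.sqrt(len(vals)) if len(vals) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def ice_average(
    embryo_tables: list[OutcomeDistribution], min_embryos: int = 3
) -> OutcomeDistribution:
    """Average Sanger-deconvolution indel tables over replicate embryos.

    Requires at least ``min_embryos`` tables for the same guide; per-class
    frequencies are arithmetically averaged (absent classes count as 0),
    restricted to 1-bp insertions and deletions of at most 20 bp, and
    renormalized.
    """
    if not embryo_tables:
        raise ValueError("no embryo tables supplied")
    guide_ids = {t.guide_id for t in embryo_tables}
    if len(guide_ids) != 1:
        raise ValueError(f"embryo tables mix guides: {sorted(guide_ids)}")
    gid = embryo_tables[0].guide_id
    if len(embryo_tables) < min_embryos:
        raise ValueError(
            f"guide {gid!r}: {len(embryo_tables)} embryo tables, need >= {min_embryos}"
        )
    n = len(embryo_tables)
    acc: dict[str, list] = {}
    for table in embryo_tables:
        for o, f in table.entries:
            if o.genotype_key in acc:
                acc[o.genotype_key][1] += f
            else:
                acc[o.genotype_key] = [o, f]
    kept = []
    for o, total in acc.values():
        if o.kind is OutcomeKind.INSERTION and o.length == 1:
            kept.append((o, total / n))
        elif o.kind is OutcomeKind.DELETION and o.length <= 20:
            kept.append((o, total / n))
    if not kept:
        raise ValueError(f"guide {gid!r}: no classes survive the ICE ingestion filter")
    out = OutcomeDistribution(
        guide_id=gid,
        source="observed",
        method="ice-average",
        entries=kept,
        metadata={"n_embryos": n},
    )
    return out.normalized()


def evaluate_panel(
    pred_by_guide: dict[str, OutcomeDistribution],
    obs_by_guide: dict[str, OutcomeDistribution],
    min_reads: int | None = 500,
) -> ConcordanceResult:
    """Run the full harness over a panel of guides.

    Guide ids must match between sides; mismatches are reported explicitly.
    The mean +/- SD of per-guide r covers non-underpowered guides only.
    """
    missing = sorted(set(pred_by_guide) ^ set(obs_by_guide))
    if missing:
        raise ValueError(f"guide ids present on one side only: {missing}")
    per_guide: list[GuideConcordance] = []
    pairs = []
    for gid in sorted(pred_by_guide):
        pred_c, obs_c = prepare_pair(pred_by_guide[gid], obs_by_guide[gid])
        pairs.append((pred_c, obs_c))
        per_guide.append(guide_concordance(pred_c, obs_c, min_reads=min_reads))
    pooled_r, pooled_p = pooled_concordance(pairs)
    if len(pairs) >= 3:
        fs_r, fs_p = frameshift_concordance(pairs)
    else:
        fs_r = fs_p = None
    rs = np.array([g.r for g in per_guide if not g.underpowered], dtype=float)
    return ConcordanceResult(
        per_guide=per_guide,
        pooled_r=pooled_r,
        pooled_p=pooled_p,
        frameshift_r=fs_r,
        frameshift_p=fs_p,
        mean_r=float(rs.mean()) if rs.size else np.nan,
        sd_r=float(rs.std(ddof=1)) if rs.size > 1 else 0.0,
        n_underpowered=sum(g.underpowered for g in per_guide),
        residual_plus1=residual_analysis(pairs, "plus1"),
        residual_deletions=residual_analysis(pairs, "deletion_length"),
    )
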