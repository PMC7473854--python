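"""On-target activity scoring and editing-outcome prediction.

Two independent predictions are made per guide:

* **Activity** — how efficiently the guide cuts in vivo, scored by a
  position-specific mono-/di-nucleotide linear regression over a 35-nt
  window (6 nt upstream of the protospacer, the 20-nt protospacer, the
  3-nt PAM and 6 nt downstream), in the style of in-vivo activity models
  trained on T7-transcribed guides.  Coefficients are loaded from CSV;
  the linear predictor is affinely rescaled to 0-100.

* **Repair outcome spectrum** — which deletions/insertions the cell's
  end-joining machinery will produce, predicted from the 80-nt sequence
  context centred on the cut.  The module defines the predictor contract
  (context in, :class:`~mosaicko.outcome_core.OutcomeDistribution` out) and
  ships a built-in microhomology heuristic honouring it, so externally
  computed tables (e.g. neural-network exports) drop in without code
  changes via :func:`load_predictions`.

The built-in heuristic is a documented stand-in, not a re-implementation of
any trained model: candidate deletions spanning the cut are weighted by an
exponential length penalty times a microhomology bonus, and a 1-bp
insertion channel favours duplication of the base 5' of the cut.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .outcome_core import (
    EditingOutcome,
    OutcomeDistribution,
    OutcomeKind,
)

__all__ = [
    "ActivityModel",
    "PredictorContext",
    "MHPredictorParams",
    "activity_score",
    "predict_outcomes_mh",
    "mmej_fraction",
    "deletion_microhomology",
    "load_predictions",
]

logger = logging.getLogger(__name__)

ACTIVITY_WINDOW = 35
#: cut position inside the 35-nt window: 6 upstream + protospacer pos 17
CUT_IN_WINDOW35 = 23

_VALID_SEQ = re.compile(r"^[ACGT]+$")


def _check_seq(seq: str, length: int, name: str) -> str:
    seq = seq.upper()
    if len(seq) != length:
        raise ValueError(f"{name} must be {length} nt, got {len(seq)}")
    if not _VALID_SEQ.match(seq):
        raise ValueError(f"{name} contains non-ACGT characters")
    return seq


@dataclass(frozen=True)
class PredictorContext:
    """The three sequence windows extracted around one cut site.

    ``context80``: 40 nt upstream + 40 nt downstream of the cleavage site
    (outcome prediction input).  ``context65``: 30 upstream + 35 downstream
    (alternative predictor input).  ``context35``: the activity-scoring
    window.  All are guide-strand sequences, uppercase ACGT.
    """

    context80: str
    context65: str
    context35: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "context80", _check_seq(self.context80, 80, "context80"))
        object.__setattr__(self, "context65", _check_seq(self.context65, 65, "context65"))
        object.__setattr__(
            self, "context35", _check_seq(self.context35, ACTIVITY_WINDOW, "context35")
        )
        # the same cleavage junction must appear at position 40 of context80
        # and position 30 of context65
        if self.context80[10:70] != self.context65[:60]:
            raise ValueError("context80 and context65 disagree around the cut site")


@dataclass
class ActivityModel:
    """Position-specific k-mer regression for on-target activity.

    ``weights`` maps ``(position, kmer)`` — 0-based position in the 35-nt
    window, k in {1, 2} — to a regression coefficient.  The linear
    predictor ``intercept + sum(matching weights)`` is mapped to the
    reporting scale by ``score = clip(offset + scale * lp, 0, 100)``; the
    affine constants are fixed model parameters, never fit to data at
    scoring time.
    """

    weights: dict[tuple[int, str], float]
    intercept: float = 0.0
    scale: float = 100.0
    offset: float = 0.0

    def __post_init__(self) -> None:
        for (pos, kmer), _ in self.weights.items():
            k = len(kmer)
            if k not in (1, 2) or not _VALID_SEQ.match(kmer):
                raise ValueError(f"unparseable feature k-mer {kmer!r}")
            if not 0 <= pos <= ACTIVITY_WINDOW - k:
                raise ValueError(
                    f"feature ({pos}, {kmer!r}) outside the {ACTIVITY_WINDOW}-nt window"
                )

    @classmethod
    def from_csv(cls, path: str | Path, scale: float = 100.0, offset: float = 0.0) -> "ActivityModel":
        """Load coefficients from CSV with columns feature, position, weight.

        The intercept row has feature ``Intercept`` and an empty position.
        """
        df = pd.read_csv(path, keep_default_na=False)
        required = {"feature", "position", "weight"}
        if not required.issubset(df.columns):
            raise ValueError(f"coefficient table needs columns {sorted(required)}")
        weights: dict[tuple[int, str], float] = {}
        intercept = 0.0
        for row in df.itertuples(index=False):
            feat = str(row.feature).strip()
            if feat.lower() == "intercept":
                intercept = float(row.weight)
                continue
            if not _VALID_SEQ.match(feat.upper()) or len(feat) not in (1, 2):
                raise ValueError(f"unparseable feature {feat!r} in coefficient table")
            try:
                pos = int(row.position)
            except (TypeError, ValueError) as exc:
                raise ValueError(f"feature {feat!r} has non-integer position {row.position!r}") from exc
            weights[(pos, feat.upper())] = float(row.weight)
        return cls(weights=weights, intercept=intercept, scale=scale, offset=offset)

    def linear_predictor(self, context35: str) -> float:
        seq = _check_seq(context35, ACTIVITY_WINDOW, "context35")
        lp = self.intercept
        for (pos, kmer), w in self.weights.items():
            if seq[pos : pos + len(kmer)] == kmer:
                lp += w
        return lp


def activity_score(context35: str, model: ActivityModel) -> float:
    """Score a 35-nt window on the 0-100 activity scale (deterministic)."""
    raw = model.offset + model.scale * model.linear_predictor(context35)
    return float(min(100.0, max(0.0, raw)))


# ---------------------------------------------------------------------------
# Built-in microhomology outcome heuristic


@dataclass(frozen=True)
class MHPredictorParams:
    """Tuning knobs of the built-in repair-outcome heuristic.

    ``length_decay``: exponential penalty per deleted base (longer deletions
    are rarer).  ``mh_gamma``: exponent of the ``(1 + mu)`` microhomology
    bonus; larger values shift mass toward microhomology-mediated deletions.
    ``ins_base_weight`` / ``ins_dup_weight``: unnormalized weights of the
    four 1-bp insertion channels; the base duplicating the nucleotide 5' of
    the cut gets the larger ``ins_dup_weight``, mirroring the templated-
    insertion bias of staggered Cas9 cuts.
    """

    max_deletion: int = 30
    length_decay: float = 0.25
    mh_gamma: float = 2.0
    ins_base_weight: float = 0.01
    ins_dup_weight: float = 0.25


def _spanning_deletions(context: str, cut: int, max_len: int):
    """Enumerate unique deletion products spanning the cut.

    Candidates are intervals [s, s+L) with s <= cut <= s+L.  Microhomology-
    shifted intervals yield the same edited sequence; they are collapsed to
    the left-most (smallest s) representative and mu = (#equivalent
    representations - 1), the length of the flanking microhomology.
    Returns tuples (length, canonical_start_offset, mu, product).
    """
    out = []
    for L in range(1, max_len + 1):
        products: dict[str, list[int]] = {}
        for s in range(max(0, cut - L), min(cut, len(context) - L) + 1):
            prod = context[:s] + context[s + L :]
            products.setdefault(prod, []).append(s)
        for prod, starts in products.items():
            s0 = min(starts)
            out.append((L, s0 - cut, len(starts) - 1, prod))
    return out


def predict_outcomes_mh(
    context80: str,
    params: MHPredictorParams | None = None,
    cut: int | None = None,
    guide_id: str = "",
) -> OutcomeDistribution:
    """Predict a mutant outcome spectrum from sequence context alone.

    Every deletion spanning the cut up to ``params.max_deletion`` bp is
    weighted ``exp(-length_decay * L) * (1 + mu)**mh_gamma`` where mu is its
    flanking microhomology length; four 1-bp insertion channels are added
    with base-dependent weights; the result is normalized to 1.  Each
    deletion entry carries its mu annotation.  Deterministic for fixed
    parameters.
    """
    params = params or MHPredictorParams()
    seq = context80.upper()
    if not _VALID_SEQ.match(seq):
        raise ValueError("context contains non-ACGT characters")
    if cut is None:
        cut = len(seq) // 2
    if len(seq) < 2 * params.max_deletion:
        raise ValueError(
            f"context of {len(seq)} nt shorter than 2 * max_deletion = {2 * params.max_deletion}"
        )
    entries: list[tuple[EditingOutcome, float]] = []
    for L, start, mu, _ in _spanning_deletions(seq, cut, params.max_deletion):
        w = math.exp(-params.length_decay * L) * (1.0 + mu) ** params.mh_gamma
        entries.append(
            (
                EditingOutcome(
                    OutcomeKind.DELETION, length=L, del_start=start, microhomology=mu
                ),
                w,
            )
        )
    base5 = seq[cut - 1]
    for base in "ACGT":
        w = params.ins_dup_weight if base == base5 else params.ins_base_weight
        entries.append((EditingOutcome(OutcomeKind.INSERTION, length=1, ins_bases=base), w))
    dist = OutcomeDistribution(
        guide_id=guide_id,
        source="predicted",
        method="mh-heuristic",
        entries=entries,
        metadata={"params": params.__dict__.copy(), "cut": cut},
    )
    return dist.normalized()


def deletion_microhomology(context: str, cut: int, del_start: int, length: int) -> int:
    """Microhomology length of one deletion, by counting shift-equivalent
    representations of its product within the context."""
    s = cut + del_start
    if not 0 <= s <= len(context) - length:
        raise ValueError("deletion interval outside context")
    prod = context[:s] + context[s + length :]
    count = 0
    for s2 in range(max(0, s - length), min(len(context) - length, s + length) + 1):
        if context[:s2] + context[s2 + length :] == prod:
            count += 1
    return count - 1


def mmej_fraction(
    dist: OutcomeDistribution,
    mu_min: int = 2,
    context: str | None = None,
    cut: int | None = None,
) -> float:
    """Fraction of mutant mass repaired through microhomology-mediated
    end joining: deletions with microhomology >= ``mu_min``.

    Deletions must carry mu annotations; when absent, they are computed
    against ``context`` (cut defaulting to the context midpoint), and a
    missing annotation with no context raises.
    """
    tot = dist.total()
    if tot <= 0:
        raise ValueError("empty distribution")
    mass = 0.0
    for o, f in dist.entries:
        if o.kind is not OutcomeKind.DELETION:
            continue
        mu = o.microhomology
        if mu is None:
            if context is None:
                raise ValueError(
                    f"deletion {o.genotype_key} lacks a microhomology annotation "
                    "and no context was supplied"
                )
            c = cut if cut is not None else len(context) // 2
            mu = deletion_microhomology(context.upper(), c, o.del_start, o.length)
        if mu >= mu_min:
            mass += f
    return mass / tot


# ---------------------------------------------------------------------------
# Ingestion of externally computed prediction tables

_GENOTYPE_RE = re.compile(r"^(WT|I(?P<ilen>\d+)\+(?P<ibases>[ACGT]+)|D(?P<dlen>\d+)@(?P<dstart>-?\d+))$")


def _parse_genotype(g: str) -> EditingOutcome:
    m = _GENOTYPE_RE.match(g.strip().upper())
    if not m:
        raise ValueError(
            f"unparseable genotype {g!r}; expected WT, I<len>+<bases> or D<len>@<start>"
        )
    if m.group(0) == "WT":
        return EditingOutcome(OutcomeKind.WILDTYPE)
    if m.group("ilen"):
        return EditingOutcome(
            OutcomeKind.INSERTION, length=int(m.group("ilen")), ins_bases=m.group("ibases")
        )
    return EditingOutcome(
        OutcomeKind.DELETION, length=int(m.group("dlen")), del_start=int(m.group("dstart"))
    )


def load_predictions(
    path: str | Path, dialect: str, guide_id: str | None = None
) -> dict[str, OutcomeDistribution]:
    """Load predictor exports into validated distributions, keyed by guide.

    Dialects (never sniffed; chosen by flag):

    * ``"indelphi"`` — columns ``Category`` (ins/del), ``Genotype position``,
      ``Inserted Bases``, ``Length``, ``Predicted frequency`` (percent).
      ``Genotype position`` is the deletion start offset relative to the cut.
    * ``"lindel"`` / ``"forecast"`` — columns ``genotype`` (``WT``,
      ``I<len>+<bases>`` or ``D<len>@<start>``) and ``frequency`` (percent).
    * ``"native"`` — this package's outcome-table CSV (fractions).

    Per-guide frequency totals off 100% by more than 0.1 are renormalized
    with a logged warning.
    """
    dialect = dialect.lower()
    if dialect == "native":
        from .outcome_core import read_outcome_table

        return {d.guide_id: d for d in read_outcome_table(path)}
    if dialect not in ("indelphi", "lindel", "forecast"):
        raise ValueError(f"unknown prediction dialect {dialect!r}")

    df = pd.read_csv(path, sep=None, engine="python", keep_default_na=False)
    df.columns = [str(c).strip() for c in df.columns]
    if "guide_id" in df.columns:
        groups = list(df.groupby("guide_id", sort=False))
    else:
        if guide_id is None:
            raise ValueError("table has no guide_id column; pass guide_id explicitly")
        groups = [(guide_id, df)]

    out: dict[str, OutcomeDistribution] = {}
    for gid, grp in groups:
        acc: dict[str, tuple[EditingOutcome, float]] = {}
        for _, row in grp.iterrows():
            if dialect == "indelphi":
                cat = str(row["Category"]).strip().lower()
                length = int(row["Length"])
                freq = float(row["Predicted frequency"]) / 100.0
                if cat == "ins":
                    bases = str(row.get("Inserted Bases", "")).strip()
                    o = EditingOutcome(
                        OutcomeKind.INSERTION, length=length, ins_bases=bases.upper()
                    )
                elif cat == "del":
                    start = int(float(row["Genotype position"]))
                    o = EditingOutcome(OutcomeKind.DELETION, length=length, del_start=start)
                else:
                    raise ValueError(f"unknown Category {cat!r} in indelphi table")
            else:
                o = _parse_genotype(str(row["genotype"]))
                freq = float(row["frequency"]) / 100.0
            if o.genotype_key in acc:  # merge duplicated classes additively
                prev_o, prev_f = acc[o.genotype_key]
                acc[o.genotype_key] = (prev_o, prev_f + freq)
            else:
                acc[o.genotype_key] = (o, freq)
        entries = list(acc.values())
        tot = sum(f for _, f in entries)
        if abs(tot - 1.0) > 0.001:
            logger.warning(
                "guide %s: %s frequencies sum to %.2f%%, renormalizing",
                gid,
                dialect,
                100 * tot,
            )
        dist = OutcomeDistribution(
            guide_id=str(gid), source="predicted", method=dialect, entries=entries
        )
        out[str(gid)] = dist.normalized()
    return out
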