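"""Canonical representation of CRISPR/Cas9 editing outcomes.

Cas9 double-strand breaks are repaired by error-prone end joining, producing
a spectrum of deletions, small insertions and unedited (wild-type) reads at
the target site.  This module defines the in-memory containers for such
spectra (:class:`EditingOutcome`, :class:`OutcomeDistribution`) together
with the arithmetic that downstream analyses rely on: frameshift
classification, the knockout score, the wild-type / long-insertion filter
applied to sequencing observations, and the 99%-cumulative curation that
restricts observed spectra to the outcome classes a predictor actually
models.

Conventions
-----------
* The cut site sits between protospacer positions 17 and 18, i.e. 3 bp
  5' of the NGG PAM.  Deletion start coordinates (``del_start``) are 0-based
  offsets relative to that cut, so a deletion covering the 3 bases
  immediately 5' of the cut has ``del_start = -3`` and ``length = 3``.
* Frequencies are fractions in [0, 1].  After any ``normalize_*`` or
  ``curate_*`` operation they sum to 1 within 1e-9.
* Microhomology-shifted representations of the same deletion product are
  collapsed to a single left-aligned genotype key whenever sequence context
  is available (predictors do this at enumeration time).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "OutcomeKind",
    "EditingOutcome",
    "OutcomeDistribution",
    "is_frameshift",
    "cumulative_frameshift",
    "ko_score",
    "ko_score_percent",
    "normalize_observed",
    "curate_to_reference_classes",
    "match_outcomes",
    "read_outcome_table",
    "write_outcome_table",
]

#: tolerance for "sums to 100%" checks on ingested third-party tables
FREQ_SUM_TOL = 1e-6


class OutcomeKind(str, enum.Enum):
    DELETION = "deletion"
    INSERTION = "insertion"
    WILDTYPE = "wildtype"


@dataclass(frozen=True)
class EditingOutcome:
    """One repair product: a deletion, an insertion, or the unedited allele.

    Parameters
    ----------
    kind:
        Outcome class.
    length:
        Number of bases deleted or inserted; 0 for wild type.
    del_start:
        Deletion start offset relative to the cut site (0-based; deletions
        only).  Left-aligned by convention when a sequence context allowed
        canonicalization.
    ins_bases:
        Inserted nucleotides (insertions only).
    microhomology:
        Length of flanking microhomology for deletions, when known; ``None``
        when the annotation is unavailable.
    genotype_key:
        Canonical string identifying the post-edit local sequence.  Two
        outcomes share a key iff they produce the same edited sequence
        within the context window.  Auto-derived from the other fields if
        not supplied.
    """

    kind: OutcomeKind
    length: int = 0
    del_start: int | None = None
    ins_bases: str = ""
    microhomology: int | None = None
    genotype_key: str = field(default="")

    def __post_init__(self) -> None:
        kind = OutcomeKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if kind is OutcomeKind.WILDTYPE:
            if self.length != 0:
                raise ValueError("wild-type outcome must have length 0")
        else:
            if self.length <= 0:
                raise ValueError(f"{kind.value} outcome requires length > 0")
        if kind is OutcomeKind.INSERTION:
            if self.ins_bases and len(self.ins_bases) != self.length:
                raise ValueError(
                    f"ins_bases {self.ins_bases!r} inconsistent with length {self.length}"
                )
        if kind is OutcomeKind.DELETION and self.del_start is None:
            raise ValueError("deletion outcome requires del_start")
        if not self.genotype_key:
            object.__setattr__(self, "genotype_key", self._default_key())

    def _default_key(self) -> str:
        if self.kind is OutcomeKind.WILDTYPE:
            return "wt"
        if self.kind is OutcomeKind.INSERTION:
            bases = self.ins_bases or "N" * self.length
            return f"ins:{self.length}:{bases}"
        return f"del:{self.length}@{self.del_start}"

    @property
    def net_length_change(self) -> int:
        """Signed change in allele length: +len for insertions, -len for deletions."""
        if self.kind is OutcomeKind.INSERTION:
            return self.length
        if self.kind is OutcomeKind.DELETION:
            return -self.length
        return 0


def is_frameshift(outcome: EditingOutcome) -> bool:
    """True iff the outcome shifts the reading frame.

    A net coding-length change not divisible by 3 disrupts the frame,
    typically creating a premature stop codon; wild type is never a
    frameshift.
    """
    return outcome.net_length_change % 3 != 0


@dataclass
class OutcomeDistribution:
    """A guide's editing-outcome frequencies, predicted or observed.

    ``entries`` pairs each :class:`EditingOutcome` with its frequency.
    Genotype keys must be unique within a distribution; frequencies are
    non-negative and, after normalization, sum to 1.
    ``metadata`` carries provenance (seeds, read counts, generator
    parameters); the ``n_reads`` key, when present, feeds the
    underpowered-guide rule in the concordance harness.
    """

    guide_id: str
    source: str  # "predicted" | "observed"
    method: str = ""
    entries: list[tuple[EditingOutcome, float]] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.source not in ("predicted", "observed"):
            raise ValueError(f"source must be 'predicted' or 'observed', got {self.source!r}")
        keys = [o.genotype_key for o, _ in self.entries]
        if len(keys) != len(set(keys)):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate genotype keys in distribution: {dupes}")
        for o, f in self.entries:
            if f < 0:
                raise ValueError(f"negative frequency {f} for {o.genotype_key}")

    def total(self) -> float:
        return float(sum(f for _, f in self.entries))

    def as_dict(self) -> dict[str, float]:
        return {o.genotype_key: f for o, f in self.entries}

    def outcome(self, key: str) -> EditingOutcome:
        for o, _ in self.entries:
            if o.genotype_key == key:
                return o
        raise KeyError(key)

    def normalized(self) -> "OutcomeDistribution":
        """Rescale frequencies to sum to 1 (requires positive total mass)."""
        tot = self.total()
        if tot <= 0:
            raise ValueError(f"cannot normalize zero-mass distribution for {self.guide_id}")
        return replace(
            self, entries=[(o, f / tot) for o, f in self.entries], metadata=dict(self.metadata)
        )

    def __len__(self) -> int:
        return len(self.entries)


def cumulative_frameshift(dist: OutcomeDistribution) -> float:
    """Total frequency of frameshift outcomes in a mutant-only distribution.

    The distribution must be normalized over mutant outcomes (no wild-type
    entries, frequencies summing to 1): this is the per-guide frameshift
    frequency *f* that the knockout score squares.
    """
    for o, _ in dist.entries:
        if o.kind is OutcomeKind.WILDTYPE:
            raise ValueError(
                f"distribution for {dist.guide_id} contains wild-type entries; "
                "apply normalize_observed first"
            )
    tot = dist.total()
    if abs(tot - 1.0) > FREQ_SUM_TOL:
        raise ValueError(
            f"distribution for {dist.guide_id} is not normalized: "
            f"total {tot:.8f} deviates from 1 by {abs(tot - 1.0):.3g}"
        )
    return float(sum(f for o, f in dist.entries if is_frameshift(o)))


def ko_score(frameshift_freq: float) -> float:
    """Knockout score on the 0-1 scale: the square of the frameshift frequency.

    With both alleles cut and repaired independently, the probability that a
    biallelic-edited cell carries frameshifts on *both* alleles is f**2 — the
    predicted fraction of full protein-knockout cells among edited cells.
    """
    if not 0.0 <= frameshift_freq <= 1.0:
        raise ValueError(f"frameshift frequency must be in [0, 1], got {frameshift_freq}")
    return frameshift_freq * frameshift_freq


def ko_score_percent(frameshift_freq: float) -> float:
    """Knockout score on the 0-100 scale used for reporting."""
    return 100.0 * ko_score(frameshift_freq)


def normalize_observed(raw: OutcomeDistribution) -> OutcomeDistribution:
    """Filter an observed spectrum down to predictor-comparable classes.

    Wild-type reads and insertions longer than 1 bp are removed and the
    residual frequencies rescaled to sum to 1.  Raises ``ValueError`` when
    no mutant signal survives the filter.
    """
    kept = [
        (o, f)
        for o, f in raw.entries
        if o.kind is not OutcomeKind.WILDTYPE
        and not (o.kind is OutcomeKind.INSERTION and o.length > 1)
    ]
    if not kept or sum(f for _, f in kept) <= 0:
        raise ValueError(f"no editable signal for guide {raw.guide_id!r} after filtering")
    out = replace(raw, entries=kept, metadata=dict(raw.metadata))
    return out.normalized()


def _curation_limit(reference: OutcomeDistribution) -> int:
    """Maximal deletion length retained under the 99%-cumulative rule.

    Scanning the reference's +1-insertion mass plus deletions in order of
    increasing length, returns the smallest deletion length at which the
    cumulative probability first exceeds 0.99.
    """
    plus1 = sum(
        f
        for o, f in reference.entries
        if o.kind is OutcomeKind.INSERTION and o.length == 1
    )
    by_len: dict[int, float] = {}
    for o, f in reference.entries:
        if o.kind is OutcomeKind.DELETION:
            by_len[o.length] = by_len.get(o.length, 0.0) + f
    cum = plus1
    for length in sorted(by_len):
        cum += by_len[length]
        if cum > 0.99:
            return length
    raise ValueError(
        f"reference for {reference.guide_id!r} never reaches 99% cumulative mass "
        f"over +1 insertions and deletions (total {cum:.4f})"
    )


def curate_to_reference_classes(
    dist: OutcomeDistribution, reference: OutcomeDistribution
) -> OutcomeDistribution:
    """Restrict ``dist`` to the outcome classes the reference predictor models.

    The reference (a predicted distribution) fixes a maximal deletion length
    L* by the 99%-cumulative scan; ``dist`` then retains only +1 insertions
    and deletions of length <= L*, renormalized to 1.  This prevents rare
    large deletions from dominating prediction-observation correlations.
    """
    lim = _curation_limit(reference)
    kept = [
        (o, f)
        for o, f in dist.entries
        if (o.kind is OutcomeKind.INSERTION and o.length == 1)
        or (o.kind is OutcomeKind.DELETION and o.length <= lim)
    ]
    if not kept or sum(f for _, f in kept) <= 0:
        raise ValueError(
            f"no outcomes of guide {dist.guide_id!r} survive curation at L*={lim}"
        )
    out = replace(dist, entries=kept, metadata=dict(dist.metadata))
    out.metadata["curation_max_deletion"] = lim
    return out.normalized()


def match_outcomes(
    pred: OutcomeDistribution, obs: OutcomeDistribution
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Zero-filled paired frequency vectors over the union of genotype keys.

    Both distributions must describe the same guide.  Returns
    ``(keys, pred_vec, obs_vec)`` with keys sorted for deterministic order.
    """
    if pred.guide_id != obs.guide_id:
        raise ValueError(
            f"cannot match distributions of different guides: "
            f"{pred.guide_id!r} vs {obs.guide_id!r}"
        )
    pd_, od = pred.as_dict(), obs.as_dict()
    keys = sorted(set(pd_) | set(od))
    pvec = np.array([pd_.get(k, 0.0) for k in keys])
    ovec = np.array([od.get(k, 0.0) for k in keys])
    return keys, pvec, ovec


# ---------------------------------------------------------------------------
# Plain-text outcome tables

_CATEGORY = {
    "del": OutcomeKind.DELETION,
    "ins": OutcomeKind.INSERTION,
    "wt": OutcomeKind.WILDTYPE,
}
_CATEGORY_INV = {v: k for k, v in _CATEGORY.items()}


def write_outcome_table(
    dists: Iterable[OutcomeDistribution] | OutcomeDistribution, path: str | Path
) -> None:
    """Write distributions to the native CSV dialect (one row per outcome)."""
    if isinstance(dists, OutcomeDistribution):
        dists = [dists]
    rows = []
    for dist in dists:
        for o, f in dist.entries:
            rows.append(
                {
                    "guide_id": dist.guide_id,
                    "source": dist.source,
                    "method": dist.method,
                    "category": _CATEGORY_INV[o.kind],
                    "length": o.length,
                    "del_start": "" if o.del_start is None else o.del_start,
                    "ins_bases": o.ins_bases,
                    "microhomology": "" if o.microhomology is None else o.microhomology,
                    "frequency": repr(float(f)),
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "guide_id",
            "source",
            "method",
            "category",
            "length",
            "del_start",
            "ins_bases",
            "microhomology",
            "frequency",
        ],
    ).to_csv(path, index=False)


def read_outcome_table(path: str | Path) -> list[OutcomeDistribution]:
    """Read a native outcome-table CSV back into distributions.

    Validates the container invariants (unique keys, non-negative
    frequencies); frequencies round-trip bit-exactly because the writer
    prints full-precision decimals.
    """
    df = pd.read_csv(
        path,
        dtype={"ins_bases": str},
        keep_default_na=False,
        float_precision="round_trip",
    )
    dists: list[OutcomeDistribution] = []
    for (guide_id, source, method), grp in df.groupby(
        ["guide_id", "source", "method"], sort=False, dropna=False
    ):
        entries = []
        for row in grp.itertuples(index=False):
            kind = _CATEGORY[row.category]
            outcome = EditingOutcome(
                kind=kind,
                length=int(row.length),
                del_start=int(row.del_start) if str(row.del_start) != "" else None,
                ins_bases=str(row.ins_bases) if kind is OutcomeKind.INSERTION else "",
                microhomology=(
                    int(row.microhomology) if str(row.microhomology) != "" else None
                ),
            )
            entries.append((outcome, float(row.frequency)))
        dists.append(
            OutcomeDistribution(
                guide_id=str(guide_id),
                source=str(source),
                method=str(method) if str(method) != "nan" else "",
                entries=entries,
            )
        )
    return dists
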