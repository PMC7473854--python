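"""Mosaic F0 embryo models of biallelic knockout penetrance.

CRISPR/Cas9 reagents injected into an early embryo act independently in
each cell, so an F0 animal is a mosaic of repair outcomes.  With a
per-allele editing probability *e* and a per-edited-allele frameshift
probability *f* (alleles and cells independent), a single cell is a full
protein knockout — biallelic frameshift — with probability ``(e*f)**2``.
This non-linearity is the core of the model: a guide with an 80%
frameshift spectrum and perfect efficiency still leaves 36% of cells with
at least one in-frame, potentially functional allele.

The module provides the closed-form cell-class expectations, a seeded
Monte-Carlo simulator (optionally sampling alleles from a full outcome
distribution instead of a scalar *f*), and the pushforward transform that
maps a prior over frameshift frequencies — e.g. the spectrum of all
possible guide designs — into the distribution of the biallelic-frameshift
cell fraction in a mosaic, whose upper tail quantifies how likely a
randomly designed guide is to give a highly penetrant knockout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .outcome_core import OutcomeDistribution, is_frameshift

__all__ = [
    "MosaicConfig",
    "MosaicSummary",
    "FrameshiftPrior",
    "CellFractionDistribution",
    "biallelic_frameshift_prob",
    "expected_mosaic",
    "simulate_mosaic",
    "transform_prior",
    "tail_probability",
]

CLASSES = (
    "biallelic_frameshift",
    "biallelic_with_inframe",
    "monoallelic_edited",
    "unedited",
)


def _check_unit(x: float, name: str) -> float:
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {x}")
    return float(x)


@dataclass
class MosaicConfig:
    """Parameters of one simulated mosaic embryo.

    ``frameshift`` is either a scalar probability or a full
    :class:`OutcomeDistribution`, in which case each edited allele samples
    an outcome and its frameshift status follows from the outcome.
    """

    n_cells: int
    efficiency: float
    frameshift: float | OutcomeDistribution
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        _check_unit(self.efficiency, "efficiency")
        if not isinstance(self.frameshift, OutcomeDistribution):
            _check_unit(self.frameshift, "frameshift")


@dataclass
class MosaicSummary:
    """Cell-class composition of a (simulated or expected) mosaic.

    Classes partition the cells: biallelic frameshift (full knockout),
    biallelic edited retaining at least one in-frame allele, monoallelic
    edited, unedited.  Fractions sum to 1; counts sum to ``n_cells``
    (counts are expectations, hence fractional, in the analytic mode).
    """

    n_cells: int
    fractions: dict[str, float]
    counts: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.fractions) != set(CLASSES):
            raise ValueError(f"fractions must cover classes {CLASSES}")
        if abs(sum(self.fractions.values()) - 1.0) > 1e-9:
            raise ValueError("class fractions must sum to 1")

    @property
    def biallelic_frameshift(self) -> float:
        return self.fractions["biallelic_frameshift"]


def biallelic_frameshift_prob(e: float, f: float) -> float:
    """Probability that one cell is biallelic frameshift mutant: ``(e*f)**2``.

    Each allele is independently edited with probability *e* and, if
    edited, carries a frameshift with probability *f*.  At full efficiency
    this reduces to ``f**2`` — e.g. f = 0.80 gives 0.64.
    """
    _check_unit(e, "e")
    _check_unit(f, "f")
    return (e * f) ** 2


def expected_mosaic(e: float, f: float, n_cells: int = 100) -> MosaicSummary:
    """Closed-form expected cell-class composition of a mosaic embryo.

    Per-cell class probabilities: biallelic frameshift ``(e*f)**2``;
    biallelic edited with >= 1 in-frame allele ``e**2 - (e*f)**2`` (so the
    biallelic classes total ``e**2``); monoallelic ``2*e*(1-e)``; unedited
    ``(1-e)**2``.
    """
    _check_unit(e, "e")
    _check_unit(f, "f")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    p_bi_fs = (e * f) ** 2
    fractions = {
        "biallelic_frameshift": p_bi_fs,
        "biallelic_with_inframe": e * e - p_bi_fs,
        "monoallelic_edited": 2 * e * (1 - e),
        "unedited": (1 - e) ** 2,
    }
    counts = {k: v * n_cells for k, v in fractions.items()}
    return MosaicSummary(n_cells=n_cells, fractions=fractions, counts=counts)


def simulate_mosaic(config: MosaicConfig) -> tuple[MosaicSummary, np.ndarray]:
    """Stochastic realization of a mosaic embryo (reproducible per seed).

    Each of ``n_cells`` cells draws two independent allele states: edited
    with probability ``efficiency``; an edited allele is frameshift either
    with probability ``frameshift`` (scalar mode) or according to an
    outcome sampled from the supplied distribution.  Returns the realized
    class summary and a ``(n_cells, 2)`` integer array of per-cell allele
    states (0 unedited, 1 in-frame edit, 2 frameshift edit).
    """
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_cells
    edited = rng.random((n, 2)) < config.efficiency

    if isinstance(config.frameshift, OutcomeDistribution):
        dist = config.frameshift.normalized()
        probs = np.array([f for _, f in dist.entries])
        fs_flags = np.array([is_frameshift(o) for o, _ in dist.entries])
        idx = rng.choice(len(probs), size=(n, 2), p=probs)
        frameshift = fs_flags[idx]
    else:
        frameshift = rng.random((n, 2)) < config.frameshift

    alleles = np.where(edited, np.where(frameshift, 2, 1), 0).astype(np.int8)

    n_edited = (alleles > 0).sum(axis=1)
    n_fs = (alleles == 2).sum(axis=1)
    counts = {
        "biallelic_frameshift": int(np.sum(n_fs == 2)),
        "biallelic_with_inframe": int(np.sum((n_edited == 2) & (n_fs < 2))),
        "monoallelic_edited": int(np.sum(n_edited == 1)),
        "unedited": int(np.sum(n_edited == 0)),
    }
    fractions = {k: v / n for k, v in counts.items()}
    return MosaicSummary(n_cells=n, fractions=fractions, counts=counts), alleles


# ---------------------------------------------------------------------------
# Priors over frameshift frequency and their mosaic pushforward


@dataclass
class FrameshiftPrior:
    """Discrete distribution over a guide's frameshift frequency f in [0, 1].

    Represents what a designer faces before choosing a guide: the spectrum
    of frameshift frequencies across all candidate target sites.  Stored as
    atoms (values, masses); histogram and sample constructors provided.
    """

    values: np.ndarray
    masses: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.values.size == 0:
            raise ValueError("empty prior")
        if self.values.shape != self.masses.shape:
            raise ValueError("values and masses must have identical shapes")
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("prior support must lie in [0, 1]")
        if np.any(self.masses < 0) or abs(self.masses.sum() - 1.0) > 1e-9:
            raise ValueError("prior masses must be non-negative and sum to 1")

    @classmethod
    def point_mass(cls, f: float) -> "FrameshiftPrior":
        return cls(np.array([f]), np.array([1.0]))

    @classmethod
    def uniform(cls, n_atoms: int = 10_000) -> "FrameshiftPrior":
        """Uniform prior on [0, 1] discretized at bin midpoints."""
        edges = np.linspace(0.0, 1.0, n_atoms + 1)
        mids = 0.5 * (edges[:-1] + edges[1:])
        return cls(mids, np.full(n_atoms, 1.0 / n_atoms))

    @classmethod
    def from_histogram(cls, edges: np.ndarray, masses: np.ndarray) -> "FrameshiftPrior":
        edges = np.asarray(edges, dtype=float)
        mids = 0.5 * (edges[:-1] + edges[1:])
        masses = np.asarray(masses, dtype=float)
        return cls(mids, masses / masses.sum())

    @classmethod
    def from_samples(cls, samples: np.ndarray, n_bins: int = 100) -> "FrameshiftPrior":
        hist, edges = np.histogram(np.asarray(samples, dtype=float), bins=n_bins, range=(0, 1))
        return cls.from_histogram(edges, hist.astype(float))


@dataclass
class CellFractionDistribution:
    """Distribution of the biallelic-frameshift cell fraction in a mosaic."""

    values: np.ndarray
    masses: np.ndarray
    n_cells: int | None = None  # None marks the infinite-cells pushforward

    def tail_probability(self, threshold: float) -> float:
        return tail_probability(self, threshold)


def transform_prior(
    prior: FrameshiftPrior, e: float, n_cells: int | None = 100
) -> CellFractionDistribution:
    """Push a frameshift-frequency prior through the mosaic model.

    Each prior atom *f* gives a per-cell biallelic-frameshift probability
    ``p = (e*f)**2``.  With ``n_cells`` finite the output is the mixture
    over the prior of ``Binomial(n_cells, p) / n_cells`` — the realized
    knockout-cell fraction in an embryo of that many cells (the default
    100 mirrors a schematic 100-cell mosaic).  With ``n_cells=None`` the
    infinite-cells pushforward of the prior under ``f -> (e*f)**2`` is
    returned.
    """
    _check_unit(e, "e")
    p = (e * prior.values) ** 2
    if n_cells is None:
        # aggregate duplicate pushforward atoms
        vals, inv = np.unique(np.round(p, 15), return_inverse=True)
        masses = np.zeros_like(vals)
        np.add.at(masses, inv, prior.masses)
        return CellFractionDistribution(vals, masses, n_cells=None)
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1 or None")
    k = np.arange(n_cells + 1)
    pmf = stats.binom.pmf(k[None, :], n_cells, p[:, None])  # (atoms, n+1)
    masses = prior.masses @ pmf
    return CellFractionDistribution(k / n_cells, masses, n_cells=n_cells)


def tail_probability(dist: CellFractionDistribution, threshold: float) -> float:
    """Probability mass at or above ``threshold`` (inclusive boundary)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    return float(dist.masses[dist.values >= threshold].sum())
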