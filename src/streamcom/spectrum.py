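"""Community size spectrum: allocating abundance and biomass by body size.

Abundance in a community declines with mean body weight as a negative
power law, ``abundance ∝ W**(-β)`` with a size-dependent thinning
exponent ``β = 0.5 * W**0.06`` clamped to [0.5, 0.75] (0.5 at or below
1 g, 0.75 at or above 1000 g).  Species whose observed density deviates
from the size trend carry a residual ε; their exponent is adjusted to
``β* = β − Δ`` with ``Δ = 0.15·ε/(3σ)`` (σ = 0.65 by default), so a
species denser than its size predicts (ε > 0) gets a smaller exponent
and hence a larger share of the community.

Given per-species mean weights and a total abundance, the spectrum
normalises the per-species indices ``W**(-β_eff)`` into relative
abundances, counts and biomasses.  Total biomass is linear in total
abundance at fixed relative abundances, so a biomass target is solved
in closed form.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BETA_MIN",
    "BETA_MAX",
    "DEFAULT_SIGMA",
    "SpectrumSpecies",
    "CommunitySpectrum",
    "thinning_exponent",
    "adjusted_exponent",
    "community_spectrum",
    "solve_total_abundance_for_biomass",
]

BETA_MIN = 0.5
BETA_MAX = 0.75
#: Standard deviation of the density residuals in the reference
#: dataset the Δ adjustment was calibrated on.
DEFAULT_SIGMA = 0.65

SPECTRUM_COLUMNS = [
    "species_id",
    "mean_weight_g",
    "beta_effective",
    "abundance_index",
    "relative_abundance",
    "count",
    "count_int",
    "biomass_g",
]


def thinning_exponent(mean_weight_g: float) -> float:
    """Weight-based thinning exponent β, clamped to [0.5, 0.75].

    ``β = 0.5 * W**0.06`` for W between 1 and 1000 g; 0.5 below 1 g,
    0.75 above 1000 g.  The map is continuous at both clamp points.
    """
    if not mean_weight_g > 0:
        raise ValueError(f"mean_weight_g must be positive, got {mean_weight_g!r}")
    beta = 0.5 * mean_weight_g**0.06
    return float(min(max(beta, BETA_MIN), BETA_MAX))


def adjusted_exponent(
    beta: float, epsilon: float, sigma: float = DEFAULT_SIGMA
) -> float:
    """Residual-adjusted exponent ``β* = β − Δ`` with ``Δ = 0.15·ε/(3σ)``.

    ε is the species' density residual about the community size trend;
    σ its standard deviation in the calibration dataset.  A residual of
    ±3σ shifts β by ∓0.15.  The result is deliberately not re-clamped:
    staying within [0.5, 0.75] is guidance, not a hard bound.
    """
    if not sigma > 0:
        raise ValueError(f"sigma must be positive, got {sigma!r}")
    delta = 0.15 * epsilon / (3.0 * sigma)
    return beta - delta


@dataclass(frozen=True)
class SpectrumSpecies:
    """Input row for the spectrum: a species' mean weight, with an
    optional verbatim β override and optional density residual ε."""

    species_id: str
    mean_weight_g: float
    beta: float | None = None
    epsilon: float | None = None

    def __post_init__(self) -> None:
        if not self.mean_weight_g > 0:
            raise ValueError(
                f"{self.species_id}: mean_weight_g must be positive"
            )

    def effective_beta(self, sigma: float = DEFAULT_SIGMA) -> float:
        """β override verbatim if given; else the weight-based exponent,
        residual-adjusted when ε is stored."""
        if self.beta is not None:
            if not BETA_MIN <= self.beta <= BETA_MAX:
                warnings.warn(
                    f"{self.species_id}: beta override {self.beta} outside "
                    f"[{BETA_MIN}, {BETA_MAX}]",
                    stacklevel=2,
                )
            return self.beta
        base = thinning_exponent(self.mean_weight_g)
        if self.epsilon is not None:
            return adjusted_exponent(base, self.epsilon, sigma)
        return base


@dataclass
class CommunitySpectrum:
    """Per-species abundance/biomass allocation plus totals.

    ``table`` has one row per species with columns species_id,
    mean_weight_g, beta_effective, abundance_index, relative_abundance,
    count, count_int, biomass_g.  Counts are continuous; ``count_int``
    is a banker's-rounded integer view for display.
    """

    table: pd.DataFrame
    total_abundance: float
    total_biomass_g: float = field(init=False)

    def __post_init__(self) -> None:
        self.total_biomass_g = float(self.table["biomass_g"].sum())


def _as_species(
    species: Iterable[SpectrumSpecies | tuple]
) -> list[SpectrumSpecies]:
    out = []
    for sp in species:
        out.append(sp if isinstance(sp, SpectrumSpecies) else SpectrumSpecies(*sp))
    return out


def community_spectrum(
    species: Sequence[SpectrumSpecies | tuple],
    total_abundance: float,
    sigma: float = DEFAULT_SIGMA,
) -> CommunitySpectrum:
    """Allocate ``total_abundance`` fish across a community by the
    size-spectrum power law.

    Per species: ``index = W**(-β_eff)``; relative abundance is the
    index normalised over the community; count = relative abundance ×
    total abundance; biomass = count × mean weight.
    """
    rows = _as_species(species)
    if not rows:
        raise ValueError("community_spectrum requires at least one species")
    if not total_abundance > 0:
        raise ValueError("total_abundance must be positive")

    weights = np.array([sp.mean_weight_g for sp in rows], dtype=float)
    betas = np.array([sp.effective_beta(sigma) for sp in rows], dtype=float)
    index = weights ** (-betas)
    rel = index / index.sum()
    counts = rel * total_abundance
    table = pd.DataFrame(
        {
            "species_id": [sp.species_id for sp in rows],
            "mean_weight_g": weights,
            "beta_effective": betas,
            "abundance_index": index,
            "relative_abundance": rel,
            "count": counts,
            "count_int": np.rint(counts).astype(int),
            "biomass_g": counts * weights,
        },
        columns=SPECTRUM_COLUMNS,
    )
    return CommunitySpectrum(table=table, total_abundance=float(total_abundance))


def solve_total_abundance_for_biomass(
    species: Sequence[SpectrumSpecies | tuple],
    target_biomass_g: float,
    sigma: float = DEFAULT_SIGMA,
) -> float:
    """Total abundance whose spectrum attains ``target_biomass_g``.

    At fixed relative abundances total biomass is linear in total
    abundance, so the exact answer is
    ``target / Σ(relative_abundance_i · W_i)``.
    """
    if not target_biomass_g > 0:
        raise ValueError("target_biomass_g must be positive")
    probe = community_spectrum(species, 1.0, sigma)
    biomass_per_fish = probe.total_biomass_g  # Σ rel_i · W_i
    return float(target_biomass_g / biomass_per_fish)


def solve_total_abundance_bisection(
    species: Sequence[SpectrumSpecies | tuple],
    target_biomass_g: float,
    sigma: float = DEFAULT_SIGMA,
    rel_tol: float = 1e-9,
    max_iter: int = 200,
) -> float:
    """Bisection fallback for the biomass target; kept for any future
    extension where biomass stops being linear in total abundance."""
    if not target_biomass_g > 0:
        raise ValueError("target_biomass_g must be positive")

    def biomass(n: float) -> float:
        return community_spectrum(species, n, sigma).total_biomass_g

    lo, hi = 1e-12, 1.0
    while biomass(hi) < target_biomass_g:
        hi *= 2.0
        if hi > 1e30:
            raise RuntimeError("bisection bracket expansion failed")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if biomass(mid) < target_biomass_g:
            lo = mid
        else:
            hi = mid
        if (hi - lo) <= rel_tol * hi:
            break
    return 0.5 * (lo + hi)
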