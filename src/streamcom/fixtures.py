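"""Seeded synthetic fixtures: species tables, HUC grids and surveys.

Real inputs to the estimator are national databases (species ranges by
HUC8, tens of thousands of electrofishing surveys).  This module
builds fully synthetic stand-ins with known ground truth so every
pipeline stage is testable offline:

* a rectangular grid of unit-square HUC8 polygons joined by a single
  directed flow chain;
* species ranges as contiguous HUC blocks along that chain;
* surveys whose covariates follow a multivariate normal with a
  realistic mean/covariance (IWI and BMMI clipped to [0, 1]) and whose
  catches are Bernoulli draws from a per-species logistic function of
  the standardised covariates — zero outside the species' range.

Everything is deterministic under a fixed root seed; each component
draws from its own spawned substream, so adding a generator never
perturbs existing fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from shapely.geometry import box

from . import allometry
from .geo import HucLayer
from .species import (
    ALL_TRIBES,
    TRAIT_CATEGORIES,
    DistributionTable,
    Origin,
    SpeciesRecord,
    StreamCovariates,
    SurveyRecord,
)

__all__ = [
    "FixtureSpec",
    "GridGroundTruth",
    "SurveyGroundTruth",
    "Fixture",
    "gen_huc_grid",
    "gen_species_table",
    "gen_surveys",
    "gen_fixture",
]

#: Default covariate distribution: means and standard deviations for
#: (drainage area km^2, elevation m, slope %, IWI, BMMI), with modest
#: correlations — steeper streams at higher elevation and smaller
#: drainages, and IWI/BMMI positively coupled.
COVARIATE_MEANS = np.array([500.0, 400.0, 2.0, 0.6, 0.5])
COVARIATE_SDS = np.array([400.0, 250.0, 1.5, 0.2, 0.25])
_CORR = np.array(
    [
        [1.0, 0.0, -0.3, 0.0, 0.0],
        [0.0, 1.0, 0.4, 0.0, 0.0],
        [-0.3, 0.4, 1.0, 0.0, 0.0],
        [0.0, 0.0, 0.0, 1.0, 0.5],
        [0.0, 0.0, 0.0, 0.5, 1.0],
    ]
)
COVARIATE_COV = np.diag(COVARIATE_SDS) @ _CORR @ np.diag(COVARIATE_SDS)

#: Rarity distribution skewed toward common species, with a thin tail
#: of rare and extinct-in-range ones.
DEFAULT_RARITY_WEIGHTS = (
    0.15, 0.15, 0.20, 0.15, 0.10, 0.08, 0.07, 0.05, 0.03, 0.02
)

_SUBSTREAMS = {"species": 0, "grid": 1, "covariates": 2, "catches": 3}


@dataclass
class FixtureSpec:
    """Parameters of a synthetic fixture.

    The defaults define the "demo" fixture: 20 species on a 5x5 HUC
    grid with 3,000 surveys, sized to exercise the whole pipeline
    quickly.  ``coefficient_range`` bounds the absolute per-species
    logistic slopes on the standardised covariates; the default
    (1.0, 2.5) gives strongly structured occurrence patterns so that
    model-recovery tests have signal to find.
    """

    seed: int = 0
    n_species: int = 20
    grid_shape: tuple[int, int] = (5, 5)
    n_surveys: int = 3000
    covariate_means: np.ndarray = field(
        default_factory=lambda: COVARIATE_MEANS.copy()
    )
    covariate_cov: np.ndarray = field(
        default_factory=lambda: COVARIATE_COV.copy()
    )
    coefficient_range: tuple[float, float] = (1.0, 2.5)
    intercept_range: tuple[float, float] = (-0.5, 0.5)
    range_size_fraction: tuple[float, float] = (0.4, 1.0)
    rarity_weights: Sequence[float] = DEFAULT_RARITY_WEIGHTS
    #: explicit logistic parameters override the random draws
    logistic_coefficients: np.ndarray | None = None
    logistic_intercepts: np.ndarray | None = None

    @property
    def n_hucs(self) -> int:
        return self.grid_shape[0] * self.grid_shape[1]

    def species_ids(self) -> list[str]:
        width = len(str(self.n_species))
        return [f"sp{str(i + 1).zfill(width)}" for i in range(self.n_species)]

    def _rng(self, component: str) -> np.random.Generator:
        children = np.random.SeedSequence(self.seed).spawn(len(_SUBSTREAMS))
        return np.random.default_rng(children[_SUBSTREAMS[component]])


@dataclass
class GridGroundTruth:
    """Bookkeeping for the generated grid: each species' range as the
    exact set of HUC ids it was assigned."""

    ranges: dict[str, set[str]]
    huc_order: list[str]


@dataclass
class SurveyGroundTruth:
    """Generator bookkeeping for the surveys.

    ``probabilities`` holds the logistic occurrence probability of
    every (survey, species) pair ignoring range; ``in_range`` flags
    whether the survey's HUC lies in the species' range.  The actual
    catch probability is their product.
    """

    probabilities: np.ndarray  # (n_surveys, n_species)
    in_range: np.ndarray  # (n_surveys, n_species) bool
    coefficients: np.ndarray  # (n_species, 5)
    intercepts: np.ndarray  # (n_species,)
    species_ids: list[str]


@dataclass
class Fixture:
    """A complete synthetic dataset with its ground truth."""

    spec: FixtureSpec
    species: list[SpeciesRecord]
    layer: HucLayer
    distribution: DistributionTable
    surveys: list[SurveyRecord]
    grid_truth: GridGroundTruth
    survey_truth: SurveyGroundTruth


def _huc_ids(shape: tuple[int, int]) -> list[str]:
    n = shape[0] * shape[1]
    width = max(2, len(str(n)))
    return [f"huc{str(i + 1).zfill(width)}" for i in range(n)]


def gen_huc_grid(
    spec: FixtureSpec,
) -> tuple[HucLayer, DistributionTable, GridGroundTruth]:
    """Unit-square HUC grid with a row-major flow chain, plus species
    ranges as contiguous blocks of consecutive HUCs along the chain."""
    rows, cols = spec.grid_shape
    if rows < 1 or cols < 1:
        raise ValueError(f"grid dimensions must be >= 1, got {spec.grid_shape}")
    ids = _huc_ids(spec.grid_shape)
    polygons = {}
    for i, huc_id in enumerate(ids):
        r, c = divmod(i, cols)
        polygons[huc_id] = box(c, r, c + 1, r + 1)
    downstream = {ids[i]: ids[i + 1] for i in range(len(ids) - 1)}
    layer = HucLayer(polygons=polygons, downstream=downstream)

    rng = spec._rng("grid")
    lo, hi = spec.range_size_fraction
    ranges: dict[str, set[str]] = {}
    records: list[tuple[str, str]] = []
    for sid in spec.species_ids():
        size = int(rng.integers(
            max(1, round(lo * len(ids))), max(2, round(hi * len(ids)) + 1)
        ))
        size = min(size, len(ids))
        start = int(rng.integers(0, len(ids) - size + 1))
        block = set(ids[start:start + size])
        ranges[sid] = block
        records.extend((sid, h) for h in sorted(block))
    truth = GridGroundTruth(ranges=ranges, huc_order=ids)
    return layer, DistributionTable(records), truth


def gen_species_table(spec: FixtureSpec) -> list[SpeciesRecord]:
    """Synthetic species records: log-normal maximum lengths, tribes
    and habitat traits sampled from the category vocabularies, rarity
    from the configured distribution; demographic fields filled by the
    allometric regressions."""
    rng = spec._rng("species")
    tribes = sorted(ALL_TRIBES)
    weights = np.asarray(spec.rarity_weights, dtype=float)
    weights = weights / weights.sum()
    records = []
    for i, sid in enumerate(spec.species_ids()):
        max_length = float(np.exp(rng.normal(np.log(12.0), 0.6)))
        traits = {
            category: frozenset(
                rng.choice(values, size=rng.integers(1, 3), replace=False)
            )
            for category, values in TRAIT_CATEGORIES.items()
        }
        records.append(
            SpeciesRecord(
                species_id=sid,
                scientific_name=f"Simulus fictus{i + 1:03d}",
                common_name=f"Synthetic Shiner {i + 1}",
                tribe=str(rng.choice(tribes)),
                origin=Origin.native if rng.random() < 0.85 else Origin.introduced,
                rarity=int(rng.choice(np.arange(1, 11), p=weights)),
                max_length_cm=max_length,
                lw_a=float(np.exp(rng.normal(np.log(allometry.DEFAULT_LW.a), 0.3))),
                lw_b=float(rng.normal(allometry.DEFAULT_LW.b, 0.1)),
                traits=traits,
            )
        )
    return records


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def gen_surveys(
    spec: FixtureSpec, grid_truth: GridGroundTruth
) -> tuple[list[SurveyRecord], SurveyGroundTruth]:
    """Synthetic surveys with known logistic occurrence structure.

    Covariates are multivariate-normal draws (Cholesky-based) with IWI
    and BMMI clipped to [0, 1], drainage area floored at 0.1 km^2 and
    slope at 0.  Each species is caught at an in-range site with
    probability ``logistic(intercept + coef . z)`` where ``z`` are the
    covariates standardised by the spec's nominal means and SDs, and
    is never caught outside its range.
    """
    rng_cov = spec._rng("covariates")
    rng_catch = spec._rng("catches")
    ids = spec.species_ids()

    chol = np.linalg.cholesky(np.asarray(spec.covariate_cov, dtype=float))
    raw = spec.covariate_means + rng_cov.standard_normal(
        (spec.n_surveys, 5)
    ) @ chol.T
    sds = np.sqrt(np.diag(spec.covariate_cov))
    z = (raw - spec.covariate_means) / sds
    clipped = raw.copy()
    clipped[:, 0] = np.maximum(clipped[:, 0], 0.1)
    clipped[:, 2] = np.maximum(clipped[:, 2], 0.0)
    clipped[:, 3] = np.clip(clipped[:, 3], 0.0, 1.0)
    clipped[:, 4] = np.clip(clipped[:, 4], 0.0, 1.0)

    if spec.logistic_coefficients is not None:
        coefs = np.asarray(spec.logistic_coefficients, dtype=float)
    else:
        lo, hi = spec.coefficient_range
        coefs = rng_catch.uniform(lo, hi, size=(spec.n_species, 5))
        coefs *= rng_catch.choice([-1.0, 1.0], size=coefs.shape)
    if spec.logistic_intercepts is not None:
        intercepts = np.asarray(spec.logistic_intercepts, dtype=float)
    else:
        intercepts = rng_catch.uniform(*spec.intercept_range, size=spec.n_species)

    probs = _logistic(intercepts + z @ coefs.T)  # (n_surveys, n_species)

    huc_of_site = rng_cov.choice(grid_truth.huc_order, size=spec.n_surveys)
    in_range = np.column_stack(
        [np.isin(huc_of_site, sorted(grid_truth.ranges[sid])) for sid in ids]
    )
    caught = (rng_catch.random(probs.shape) < probs) & in_range

    surveys = []
    for i in range(spec.n_surveys):
        surveys.append(
            SurveyRecord(
                site_id=f"site{i + 1:05d}",
                huc8_id=str(huc_of_site[i]),
                covariates=StreamCovariates(*clipped[i]),
                caught=frozenset(
                    sid for j, sid in enumerate(ids) if caught[i, j]
                ),
            )
        )
    truth = SurveyGroundTruth(
        probabilities=probs,
        in_range=in_range,
        coefficients=coefs,
        intercepts=intercepts,
        species_ids=list(ids),
    )
    return surveys, truth


def gen_fixture(spec: FixtureSpec | None = None) -> Fixture:
    """Generate a complete fixture (species, grid, distribution,
    surveys) from one spec; the default spec is the demo fixture."""
    spec = spec or FixtureSpec()
    species = gen_species_table(spec)
    layer, distribution, grid_truth = gen_huc_grid(spec)
    distribution = DistributionTable(
        distribution.records, {r.species_id: r for r in species}
    )
    surveys, survey_truth = gen_surveys(spec, grid_truth)
    return Fixture(
        spec=spec,
        species=species,
        layer=layer,
        distribution=distribution,
        surveys=surveys,
        grid_truth=grid_truth,
        survey_truth=survey_truth,
    )
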