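"""Species and distribution data model.

The geographic backbone of the estimator is a table of
(species, HUC8) records — a HUC8 is an 8-digit Hydrologic Unit Code
subbasin — plus a species table carrying rarity, body size, tribe,
habitat traits and length-weight coefficients.  Survey records (one
sampling event with five stream covariates and the set of species
caught) are the evidence base for occurrence modelling and for
auditing the distribution table for errors of omission.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Iterable, Mapping

from . import allometry

__all__ = [
    "RARITY_SCALE",
    "StreamCovariates",
    "SpeciesRecord",
    "DistributionTable",
    "SurveyRecord",
    "BeneficialUse",
    "UseCategory",
    "Origin",
    "rarity_to_numeric",
    "classify_beneficial_use",
    "assemblage_for_huc",
    "query_species",
    "find_omission_errors",
]

#: Ordinal rarity scale: 1 = abundant everywhere in range, 10 = extinct
#: in range.  Rarity describes detectability within the range, not
#: range size.
RARITY_SCALE: dict[str, int] = {
    "abundant": 1,
    "abundant/common": 2,
    "common": 3,
    "fairly common": 4,
    "common/uncommon": 5,
    "uncommon": 6,
    "uncommon/rare": 7,
    "rare": 8,
    "extremely rare": 9,
    "extinct": 10,
}

#: The 48 recognised tribes (taxonomic rank between genus and family),
#: partitioned by predominant beneficial use.
SPORT_TRIBES = frozenset(
    {
        "Black Bass", "Bowfin", "Burbot", "Carp", "Catfish", "Cichlid",
        "Cod", "Drum", "Eel", "Flounder", "Gar", "Paddlefish", "Perch",
        "Pike", "Salmon/Trout", "Shad/Herring", "Skipjack", "Snakehead",
        "Stingray", "Sturgeon", "Sucker", "Sunfish", "White Bass",
        "Whitefish",
    }
)
NON_GAME_TRIBES = frozenset(
    {
        "Anchovy", "Cavefish", "Darter", "Goby", "Knifefish", "Lamprey",
        "Livebearer", "Loach", "Madtom", "Minnow", "Mudminnow", "Mullet",
        "Pipefish", "Pupfish", "Pygmy Sunfish", "Sculpin", "Silverside",
        "Smelt", "Splitfin", "Stickleback", "Surfperch", "Tetra",
        "Topminnow", "Trout-Perch",
    }
)
ALL_TRIBES = SPORT_TRIBES | NON_GAME_TRIBES

#: Tribes harvested for subsistence (members may be sport or non-game).
SUBSISTENCE_TRIBES = frozenset(
    {
        "Anchovy", "Bowfin", "Burbot", "Catfish", "Cod", "Drum", "Eel",
        "Gar", "Lamprey", "Minnow", "Mullet", "Paddlefish", "Perch",
        "Pike", "Salmon/Trout", "Shad/Herring", "Smelt", "Sturgeon",
        "Sucker", "Trout-Perch", "White Bass", "Whitefish",
    }
)

#: Tribes exclusively exotic to the conterminous US.  The Rio Grande
#: Cichlid is the one native member of an otherwise exotic tribe.
EXOTIC_TRIBES = frozenset(
    {"Carp", "Cichlid", "Knifefish", "Loach", "Snakehead", "Tetra"}
)
EXOTIC_TRIBE_EXCEPTIONS = frozenset({"Herichthys cyanoguttatus"})

#: Sport-fish size cutoffs (cm, strict "over").  Salmonids and the
#: centrarchid tribes mature small relative to their desirability as
#: game, hence the lower cutoffs.
SPORT_LENGTH_THRESHOLDS_CM: dict[str, float] = {
    "Salmon/Trout": 20.0,
    "Sunfish": 15.0,
    "Black Bass": 15.0,
}
DEFAULT_SPORT_LENGTH_CM = 25.0
SPORT_RARITY_CUTOFF = 7

#: Trait category vocabularies for habitat preference descriptors.
TRAIT_CATEGORIES: dict[str, tuple[str, ...]] = {
    "systems": (
        "Caves", "Springs", "Headwaters", "Creeks", "Small Rivers",
        "Medium Rivers", "Large Rivers",
        "Lakes/Impoundments/Ponds/Canals/Ditches", "Swamp/Marsh/Bayou",
        "Coastal/Ocean",
    ),
    "lotic_habitat": ("Riffles", "Runs/Flowing Pools", "Pools/Backwaters"),
    "location": ("Benthic", "Surface", "Nearshore/Littoral", "Pelagic"),
    "substrate": (
        "Mud/Silt/Detritus", "Sand", "Gravel", "Rocks/Rubble/Boulders",
        "Vegetation", "Woody Debris/Brush",
    ),
    "water": (
        "Clear", "Turbid", "Warm", "Cool", "Cold", "Lowland", "Upland",
    ),
}


class Origin(str, Enum):
    native = "native"
    introduced = "introduced"


class UseCategory(str, Enum):
    sport = "sport"
    non_game = "non_game"


@dataclass(frozen=True)
class BeneficialUse:
    """Beneficial-use classification: sport/non-game by the size-and-
    rarity rule, plus tribe-level subsistence and exotic flags."""

    category: UseCategory
    subsistence: bool
    exotic: bool


@dataclass(frozen=True)
class StreamCovariates:
    """The five stream covariates driving occurrence models.

    drainage_area_km2
        Upstream drainage area of the segment (km^2).
    elevation_m
        Mean catchment elevation (m).
    slope_pct
        Stream slope (%).
    iwi
        Index of Watershed Integrity, in [0, 1].
    bmmi
        Probability the segment has a good benthic invertebrate
        multimetric index, in [0, 1].
    """

    drainage_area_km2: float
    elevation_m: float
    slope_pct: float
    iwi: float
    bmmi: float

    FIELDS = ("drainage_area_km2", "elevation_m", "slope_pct", "iwi", "bmmi")

    def __post_init__(self) -> None:
        if not self.drainage_area_km2 > 0:
            raise ValueError("drainage_area_km2 must be positive")
        if self.slope_pct < 0:
            raise ValueError("slope_pct must be non-negative")
        for name in ("iwi", "bmmi"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (
            self.drainage_area_km2,
            self.elevation_m,
            self.slope_pct,
            self.iwi,
            self.bmmi,
        )


@dataclass
class SpeciesRecord:
    """One species: identity, rarity, body size, tribe, habitat traits
    and length-weight coefficients.

    ``mean_weight_g``, ``mean_length_cm`` and ``max_age_yr`` are filled
    from the fixed allometric regressions when absent; filled fields
    are listed in ``derived_fields``.
    """

    species_id: str
    scientific_name: str
    common_name: str
    tribe: str
    origin: Origin
    rarity: int
    max_length_cm: float
    mean_weight_g: float | None = None
    mean_length_cm: float | None = None
    max_age_yr: float | None = None
    lw_a: float = allometry.DEFAULT_LW.a
    lw_b: float = allometry.DEFAULT_LW.b
    density_residual: float | None = None
    traits: dict[str, frozenset[str]] = field(default_factory=dict)
    derived_fields: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.rarity not in range(1, 11):
            raise ValueError(f"rarity must be in 1..10, got {self.rarity}")
        if not self.max_length_cm > 0:
            raise ValueError("max_length_cm must be positive")
        if not (self.lw_a > 0 and self.lw_b > 0):
            raise ValueError("length-weight coefficients must be positive")
        self.origin = Origin(self.origin)
        derived = set(self.derived_fields)
        if self.mean_weight_g is None:
            self.mean_weight_g = allometry.mean_weight_from_max_length(
                self.max_length_cm
            )
            derived.add("mean_weight_g")
        if self.mean_length_cm is None:
            self.mean_length_cm = allometry.mean_length_from_mean_weight(
                self.mean_weight_g
            )
            derived.add("mean_length_cm")
        if self.max_age_yr is None:
            self.max_age_yr = allometry.max_age_from_max_length(
                self.max_length_cm
            )
            derived.add("max_age_yr")
        self.derived_fields = frozenset(derived)
        self.traits = {k: frozenset(v) for k, v in self.traits.items()}

    @property
    def extinct_in_range(self) -> bool:
        return self.rarity == 10


class DistributionTable:
    """Set of (species_id, huc8_id) occurrence records.

    Duplicate pairs collapse; every species_id must resolve to a
    known :class:`SpeciesRecord` when a species index is supplied.
    """

    def __init__(
        self,
        records: Iterable[tuple[str, str]],
        species: Mapping[str, SpeciesRecord] | None = None,
    ) -> None:
        self.records: frozenset[tuple[str, str]] = frozenset(
            (str(s), str(h)) for s, h in records
        )
        self.species: dict[str, SpeciesRecord] = dict(species or {})
        if self.species:
            unknown = {s for s, _ in self.records} - set(self.species)
            if unknown:
                raise ValueError(
                    f"distribution records reference unknown species: {sorted(unknown)}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.records

    def hucs_for_species(self, species_id: str) -> set[str]:
        return {h for s, h in self.records if s == species_id}

    def union(self, extra: Iterable[tuple[str, str]]) -> "DistributionTable":
        return DistributionTable(
            self.records | set(extra), self.species or None
        )


@dataclass(frozen=True)
class SurveyRecord:
    """One sampling event: site, watershed, covariates and catch."""

    site_id: str
    huc8_id: str
    covariates: StreamCovariates
    caught: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "caught", frozenset(self.caught))


def rarity_to_numeric(descriptor: str) -> int:
    """Map a rarity label to its 1-10 ordinal value.

    Matching is case-insensitive with surrounding/internal whitespace
    normalised; compound labels ("Abundant/Common") are matched
    verbatim.  Unknown labels raise ``ValueError``.
    """
    key = " ".join(descriptor.strip().lower().split())
    try:
        return RARITY_SCALE[key]
    except KeyError:
        raise ValueError(f"unknown rarity descriptor: {descriptor!r}") from None


def classify_beneficial_use(species: SpeciesRecord) -> BeneficialUse:
    """Classify a species as sport or non-game, with subsistence and
    exotic tribe flags.

    A species is a sport fish when its maximum length strictly exceeds
    the tribe's size cutoff (25 cm generally, 20 cm for Salmon/Trout,
    15 cm for Sunfish and Black Bass) and its rarity is below 7;
    otherwise it is non-game.
    """
    if not species.tribe:
        raise ValueError(f"species {species.species_id} has no tribe")
    threshold = SPORT_LENGTH_THRESHOLDS_CM.get(
        species.tribe, DEFAULT_SPORT_LENGTH_CM
    )
    is_sport = (
        species.max_length_cm > threshold
        and species.rarity < SPORT_RARITY_CUTOFF
    )
    exotic = (
        species.tribe in EXOTIC_TRIBES
        and species.scientific_name not in EXOTIC_TRIBE_EXCEPTIONS
    )
    return BeneficialUse(
        category=UseCategory.sport if is_sport else UseCategory.non_game,
        subsistence=species.tribe in SUBSISTENCE_TRIBES,
        exotic=exotic,
    )


def _sort_key(db: DistributionTable) -> Callable[[str], tuple[str, str]]:
    def key(species_id: str) -> tuple[str, str]:
        rec = db.species.get(species_id)
        return (rec.scientific_name if rec else "", species_id)

    return key


def assemblage_for_huc(db: DistributionTable, huc8_id: str) -> list[str]:
    """All species with a distribution record for ``huc8_id``, sorted
    by scientific name then species_id.  Unknown HUCs yield []."""
    ids = {s for s, h in db.records if h == huc8_id}
    return sorted(ids, key=_sort_key(db))


_QUERYABLE_FIELDS = frozenset(
    {
        "species_id", "scientific_name", "common_name", "tribe", "origin",
        "rarity", "max_length_cm", "mean_weight_g", "mean_length_cm",
        "max_age_yr", "lw_a", "lw_b", "density_residual",
    }
    | set(TRAIT_CATEGORIES)
)


def query_species(
    db: DistributionTable,
    filters: Mapping[str, object] | None = None,
) -> list[str]:
    """Select species matching the conjunction of field filters.

    Each filter maps a field name to either a plain value (equality;
    trait categories test set membership) or a one-argument predicate.
    Unknown field names raise ``ValueError``.  Result is sorted by
    scientific name then species_id.
    """
    filters = dict(filters or {})
    unknown = set(filters) - _QUERYABLE_FIELDS
    if unknown:
        raise ValueError(f"unknown query fields: {sorted(unknown)}")

    def matches(rec: SpeciesRecord) -> bool:
        for name, crit in filters.items():
            if name in TRAIT_CATEGORIES:
                value: object = rec.traits.get(name, frozenset())
                if callable(crit):
                    if not crit(value):
                        return False
                elif crit not in value:  # membership for trait sets
                    return False
                continue
            value = getattr(rec, name)
            if callable(crit):
                if not crit(value):
                    return False
            elif value != crit:
                return False
        return True

    hits = [sid for sid, rec in db.species.items() if matches(rec)]
    return sorted(hits, key=_sort_key(db))


def find_omission_errors(
    db: DistributionTable, surveys: Iterable[SurveyRecord]
) -> set[tuple[str, str]]:
    """Species caught by a survey in a HUC8 that lacks a distribution
    record for them — errors of omission.  Duplicates collapse."""
    omissions: set[tuple[str, str]] = set()
    for survey in surveys:
        for sid in survey.caught:
            pair = (sid, survey.huc8_id)
            if pair not in db.records:
                omissions.add(pair)
    return omissions
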