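"""Readers and writers for the package's file formats.

All tables are UTF-8, comma-delimited CSV with a mandatory header row;
floats are written with 17 significant digits so every table
round-trips bit-exactly.  Multi-valued fields (caught species, trait
sets) are semicolon-delimited within a cell.  HUC layers travel as
GeoJSON FeatureCollections whose features carry ``huc8_id`` and an
optional ``downstream`` property; trained models as a directory of
per-species XGBoost JSON files plus a manifest.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from shapely.geometry import mapping, shape
from xgboost import XGBClassifier

from .geo import HucLayer
from .occurrence import OccurrenceModel, ThresholdStats
from .species import (
    TRAIT_CATEGORIES,
    DistributionTable,
    SpeciesRecord,
    StreamCovariates,
    SurveyRecord,
)
from .spectrum import SPECTRUM_COLUMNS, CommunitySpectrum

FLOAT_FORMAT = "%.17g"

SPECIES_COLUMNS = [
    "species_id", "scientific_name", "common_name", "tribe", "origin",
    "rarity", "max_length_cm", "mean_weight_g", "mean_length_cm",
    "max_age_yr", "lw_a", "lw_b", "density_residual", "derived_fields",
] + [f"trait_{c}" for c in TRAIT_CATEGORIES]

SURVEY_COLUMNS = [
    "site_id", "huc8_id", "drainage_area_km2", "elevation_m", "slope_pct",
    "iwi", "bmmi", "caught",
]

METRICS_COLUMNS = ["species_id", "ubiquity", "extent", "tolerance", "robustness"]


def _require_columns(frame: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{what} is missing required columns: {missing}")


def _join_set(values: Iterable[str]) -> str:
    return ";".join(sorted(values))


def _split_set(cell: object) -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
        return frozenset()
    return frozenset(str(cell).split(";"))


# ---------------------------------------------------------------- species

def write_species_csv(records: Sequence[SpeciesRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row = {
            "species_id": r.species_id,
            "scientific_name": r.scientific_name,
            "common_name": r.common_name,
            "tribe": r.tribe,
            "origin": r.origin.value,
            "rarity": r.rarity,
            "max_length_cm": r.max_length_cm,
            "mean_weight_g": r.mean_weight_g,
            "mean_length_cm": r.mean_length_cm,
            "max_age_yr": r.max_age_yr,
            "lw_a": r.lw_a,
            "lw_b": r.lw_b,
            "density_residual": r.density_residual,
            "derived_fields": _join_set(r.derived_fields),
        }
        for category in TRAIT_CATEGORIES:
            row[f"trait_{category}"] = _join_set(r.traits.get(category, ()))
        rows.append(row)
    pd.DataFrame(rows, columns=SPECIES_COLUMNS).to_csv(
        path, index=False, float_format=FLOAT_FORMAT
    )


def read_species_csv(path: str | Path) -> list[SpeciesRecord]:
    frame = pd.read_csv(path, float_precision="round_trip")
    _require_columns(
        frame, [c for c in SPECIES_COLUMNS if not c.startswith("trait_")],
        f"species table {path}",
    )
    records = []
    for idx, row in frame.iterrows():
        try:
            traits = {
                category: _split_set(row.get(f"trait_{category}"))
                for category in TRAIT_CATEGORIES
                if f"trait_{category}" in frame.columns
            }
            records.append(
                SpeciesRecord(
                    species_id=str(row["species_id"]),
                    scientific_name=str(row["scientific_name"]),
                    common_name=str(row["common_name"]),
                    tribe=str(row["tribe"]),
                    origin=str(row["origin"]),
                    rarity=int(row["rarity"]),
                    max_length_cm=float(row["max_length_cm"]),
                    mean_weight_g=(
                        None if pd.isna(row["mean_weight_g"])
                        else float(row["mean_weight_g"])
                    ),
                    mean_length_cm=(
                        None if pd.isna(row["mean_length_cm"])
                        else float(row["mean_length_cm"])
                    ),
                    max_age_yr=(
                        None if pd.isna(row["max_age_yr"])
                        else float(row["max_age_yr"])
                    ),
                    lw_a=float(row["lw_a"]),
                    lw_b=float(row["lw_b"]),
                    density_residual=(
                        None if pd.isna(row["density_residual"])
                        else float(row["density_residual"])
                    ),
                    traits=traits,
                    derived_fields=_split_set(row.get("derived_fields")),
                )
            )
        except (ValueError, KeyError) as err:
            raise ValueError(f"species table {path}, row {idx + 2}: {err}") from err
    return records


# ----------------------------------------------------------- distribution

def write_distribution_csv(db: DistributionTable, path: str | Path) -> None:
    frame = pd.DataFrame(sorted(db.records), columns=["species_id", "huc8_id"])
    frame.to_csv(path, index=False)


def read_distribution_csv(
    path: str | Path,
    species: Mapping[str, SpeciesRecord] | None = None,
) -> DistributionTable:
    frame = pd.read_csv(path, dtype=str)
    _require_columns(frame, ["species_id", "huc8_id"], f"distribution table {path}")
    return DistributionTable(
        frame.itertuples(index=False, name=None), species
    )


# ---------------------------------------------------------------- surveys

def write_surveys_csv(surveys: Sequence[SurveyRecord], path: str | Path) -> None:
    rows = []
    for s in surveys:
        c = s.covariates
        rows.append(
            {
                "site_id": s.site_id,
                "huc8_id": s.huc8_id,
                "drainage_area_km2": c.drainage_area_km2,
                "elevation_m": c.elevation_m,
                "slope_pct": c.slope_pct,
                "iwi": c.iwi,
                "bmmi": c.bmmi,
                "caught": _join_set(s.caught),
            }
        )
    pd.DataFrame(rows, columns=SURVEY_COLUMNS).to_csv(
        path, index=False, float_format=FLOAT_FORMAT
    )


def read_surveys_csv(path: str | Path) -> list[SurveyRecord]:
    frame = pd.read_csv(path, float_precision="round_trip")
    _require_columns(frame, SURVEY_COLUMNS, f"survey table {path}")
    surveys = []
    for idx, row in frame.iterrows():
        try:
            surveys.append(
                SurveyRecord(
                    site_id=str(row["site_id"]),
                    huc8_id=str(row["huc8_id"]),
                    covariates=StreamCovariates(
                        drainage_area_km2=float(row["drainage_area_km2"]),
                        elevation_m=float(row["elevation_m"]),
                        slope_pct=float(row["slope_pct"]),
                        iwi=float(row["iwi"]),
                        bmmi=float(row["bmmi"]),
                    ),
                    caught=_split_set(row["caught"]),
                )
            )
        except ValueError as err:
            raise ValueError(f"survey table {path}, row {idx + 2}: {err}") from err
    return surveys


# --------------------------------------------------------------- spectrum

def write_spectrum_csv(spectrum: CommunitySpectrum, path: str | Path) -> None:
    spectrum.table.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_spectrum_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, float_precision="round_trip")
    _require_columns(frame, SPECTRUM_COLUMNS, f"spectrum table {path}")
    return frame


# ---------------------------------------------------------------- geojson

def write_huc_layer_geojson(layer: HucLayer, path: str | Path) -> None:
    features = []
    for huc_id in sorted(layer.polygons):
        props: dict[str, object] = {"huc8_id": huc_id}
        if huc_id in layer.downstream:
            props["downstream"] = layer.downstream[huc_id]
        features.append(
            {
                "type": "Feature",
                "properties": props,
                "geometry": mapping(layer.polygons[huc_id]),
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )


def read_huc_layer_geojson(path: str | Path) -> HucLayer:
    return HucLayer.from_geojson(json.loads(Path(path).read_text()))


def read_polygon_geojson(path: str | Path):
    """Read a single range polygon from a GeoJSON Feature, geometry
    object, or the first feature of a FeatureCollection."""
    data = json.loads(Path(path).read_text())
    if data.get("type") == "FeatureCollection":
        data = data["features"][0]
    if data.get("type") == "Feature":
        data = data["geometry"]
    return shape(data)


# ------------------------------------------------------------ model bundle

def save_model_bundle(
    models: Mapping[str, OccurrenceModel], directory: str | Path
) -> None:
    """Serialize models as one XGBoost-JSON file per species plus a
    ``manifest.json`` holding threshold statistics and metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for sid in sorted(models):
        m = models[sid]
        fname = f"{sid}.model.json"
        m.booster.get_booster().save_model(str(directory / fname))
        manifest[sid] = {
            "file": fname,
            "threshold_stats": {
                "p1_mean": m.threshold_stats.p1_mean,
                "p0_mean": m.threshold_stats.p0_mean,
                "p1_sd": m.threshold_stats.p1_sd,
            },
            "n_present": m.n_present,
            "n_absent": m.n_absent,
            "hyperparameters": m.hyperparameters,
            "seed": m.seed,
        }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_model_bundle(directory: str | Path) -> dict[str, OccurrenceModel]:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    models: dict[str, OccurrenceModel] = {}
    for sid, meta in manifest.items():
        clf = XGBClassifier()
        clf.load_model(str(directory / meta["file"]))
        models[sid] = OccurrenceModel(
            species_id=sid,
            booster=clf,
            threshold_stats=ThresholdStats(**meta["threshold_stats"]),
            n_present=meta["n_present"],
            n_absent=meta["n_absent"],
            hyperparameters=meta.get("hyperparameters", {}),
            seed=meta.get("seed", 0),
        )
    return models
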