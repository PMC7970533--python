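"""Assigning a species range polygon to HUC8 watershed units.

A hand-drawn range polygon is imprecise at its edges, so membership of
a HUC8 subbasin is decided by areal overlap plus hydrologic
connectivity rather than simple intersection:

1. if the polygon touches only a few HUCs (``small_polygon_limit``,
   default 3), every intersecting HUC is included — small ranges would
   otherwise vanish;
2. otherwise a HUC is included when at least half its area falls
   inside the polygon;
3. a HUC with positive but sub-half overlap is added when it lies one
   directed flow edge up- or downstream of a HUC included by step 2.

All geometry is planar (projected coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from shapely.geometry import shape
from shapely.geometry.base import BaseGeometry
from shapely.validation import explain_validity

__all__ = ["HucLayer", "overlap_fractions", "hucs_from_polygon"]

DEFAULT_SMALL_POLYGON_LIMIT = 3


def _check_geometry(geom: BaseGeometry, name: str) -> None:
    if not geom.is_valid:
        raise ValueError(f"invalid geometry for {name}: {explain_validity(geom)}")
    if geom.area <= 0:
        raise ValueError(f"geometry for {name} has non-positive area")


@dataclass
class HucLayer:
    """Planar HUC8 polygons plus directed flow edges.

    ``polygons`` maps huc8_id -> shapely geometry; ``downstream`` maps
    huc8_id -> the id of the HUC directly downstream (absent for
    terminal basins).
    """

    polygons: dict[str, BaseGeometry]
    downstream: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for huc_id, geom in self.polygons.items():
            _check_geometry(geom, f"HUC {huc_id}")
        for src, dst in self.downstream.items():
            if src not in self.polygons or dst not in self.polygons:
                raise ValueError(
                    f"connectivity edge {src}->{dst} references unknown HUC"
                )

    def neighbours(self, huc_id: str) -> set[str]:
        """HUCs one directed edge away, in either flow direction."""
        out = set()
        dst = self.downstream.get(huc_id)
        if dst is not None:
            out.add(dst)
        out.update(src for src, d in self.downstream.items() if d == huc_id)
        return out

    @classmethod
    def from_geojson(cls, data: Mapping) -> "HucLayer":
        """Build from a GeoJSON FeatureCollection whose features carry
        ``huc8_id`` and optional ``downstream`` properties."""
        polygons: dict[str, BaseGeometry] = {}
        downstream: dict[str, str] = {}
        for feature in data["features"]:
            props = feature.get("properties", {})
            huc_id = str(props["huc8_id"])
            polygons[huc_id] = shape(feature["geometry"])
            if props.get("downstream"):
                downstream[huc_id] = str(props["downstream"])
        return cls(polygons=polygons, downstream=downstream)


def overlap_fractions(
    polygon: BaseGeometry, layer: HucLayer
) -> dict[str, float]:
    """Fraction of each HUC's area inside the range polygon.

    Only HUCs with strictly positive intersection appear in the result.
    """
    _check_geometry(polygon, "range polygon")
    fractions: dict[str, float] = {}
    for huc_id, huc_geom in layer.polygons.items():
        inter = huc_geom.intersection(polygon).area
        if inter > 0:
            fractions[huc_id] = inter / huc_geom.area
    return fractions


def hucs_from_polygon(
    polygon: BaseGeometry,
    layer: HucLayer,
    small_polygon_limit: int = DEFAULT_SMALL_POLYGON_LIMIT,
    majority_fraction: float = 0.5,
) -> set[str]:
    """HUC8 ids assigned to a species range polygon.

    Applies the small-polygon, majority-overlap and one-hop
    connectivity rules described in the module docstring.  The
    majority cutoff is inclusive (>= 0.5) and connectivity is a single
    directed edge in either direction, never followed transitively.
    """
    fractions = overlap_fractions(polygon, layer)
    if len(fractions) <= small_polygon_limit:
        return set(fractions)

    core = {h for h, f in fractions.items() if f >= majority_fraction}
    partial = {h for h, f in fractions.items() if 0 < f < majority_fraction}
    adjacent = {
        h for h in partial if layer.neighbours(h) & core
    }
    return core | adjacent
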