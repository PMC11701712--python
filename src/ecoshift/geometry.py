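"""Spatial box geometry for the simulator.

The model domain is a set of contiguous polygonal boxes laid out along a
coastline strip.  Every piece of state in the simulator (temperature forcing,
group numbers/biomass, fleet footprints) is indexed by box id.  Boxes carry a
maximum-depth class, a surface area, an adjacency set, and a position along
the coast (``latitudinal_axis``) that fixes the meaning of "northward".

The synthetic generator builds a rectangular alongshore x offshore grid with
higher resolution (smaller boxes) near the coast, mimicking shelf-resolved
ecosystem-model geometries.  Geometry round-trips losslessly through a
GeoJSON FeatureCollection.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
from shapely.geometry import Polygon

__all__ = [
    "Box",
    "ModelGeometry",
    "GeometryError",
    "GeometryFormatError",
    "DEPTH_BANDS",
    "build_synthetic_geometry",
    "cce_like_geometry",
    "read_geometry",
    "write_geometry",
]

#: Maximum-depth classes, shallow to deep (metres; last band is open ocean).
DEPTH_BANDS = ("50", "100", "200", "550", "1200", "oceanic")

KM_PER_DEG_LAT = 111.32


class GeometryError(ValueError):
    """Invalid geometry construction arguments or invariant violation."""


class GeometryFormatError(GeometryError):
    """Malformed geometry file; carries the offending feature index."""

    def __init__(self, message: str, feature_index: int | None = None):
        super().__init__(message)
        self.feature_index = feature_index


@dataclass(frozen=True)
class Box:
    """One polygonal model box."""

    id: int
    polygon: tuple[tuple[float, float], ...]  # (lon, lat) vertices, CCW, open ring
    depth_band: str
    area_km2: float
    neighbors: frozenset[int]
    is_boundary: bool = False

    def shapely(self) -> Polygon:
        return Polygon(self.polygon)

    def centroid(self) -> tuple[float, float]:
        c = self.shapely().centroid
        return (c.x, c.y)

    def validate(self) -> None:
        if self.area_km2 <= 0:
            raise GeometryError(f"box {self.id}: area must be positive")
        if self.depth_band not in DEPTH_BANDS:
            raise GeometryError(f"box {self.id}: unknown depth band {self.depth_band!r}")
        poly = self.shapely()
        if not poly.is_valid:
            raise GeometryError(f"box {self.id}: self-intersecting polygon")


@dataclass
class ModelGeometry:
    """A full box geometry plus the alongshore coordinate of every box."""

    boxes: list[Box]
    latitudinal_axis: np.ndarray  # per-box scalar; larger = further north
    name: str = "geometry"

    def __post_init__(self):
        self.latitudinal_axis = np.asarray(self.latitudinal_axis, dtype=float)

    # -- basic introspection -------------------------------------------------
    @property
    def n_boxes(self) -> int:
        return len(self.boxes)

    @property
    def areas_km2(self) -> np.ndarray:
        return np.array([b.area_km2 for b in self.boxes])

    @property
    def total_area_km2(self) -> float:
        return float(self.areas_km2.sum())

    def box(self, box_id: int) -> Box:
        return self.boxes[box_id]

    def centroids(self) -> np.ndarray:
        return np.array([b.centroid() for b in self.boxes])

    def validate(self) -> None:
        ids = [b.id for b in self.boxes]
        if ids != list(range(len(self.boxes))):
            raise GeometryError("box ids must be contiguous from 0")
        if self.latitudinal_axis.shape != (len(self.boxes),):
            raise GeometryError("latitudinal_axis must cover every box")
        for b in self.boxes:
            b.validate()
            for n in b.neighbors:
                if not (0 <= n < len(self.boxes)):
                    raise GeometryError(f"box {b.id}: neighbor {n} out of range")
                if b.id not in self.boxes[n].neighbors:
                    raise GeometryError(
                        f"neighbor relation not symmetric between {b.id} and {n}"
                    )

    def __eq__(self, other) -> bool:
        if not isinstance(other, ModelGeometry):
            return NotImplemented
        return (
            self.name == other.name
            and self.boxes == other.boxes
            and np.array_equal(self.latitudinal_axis, other.latitudinal_axis)
        )


def _quad_area_km2(lon_w: float, lon_e: float, lat_s: float, lat_n: float) -> float:
    """Area of a small lon/lat rectangle on a spherical-ish earth."""
    lat_mid = math.radians(0.5 * (lat_s + lat_n))
    dx = (lon_e - lon_w) * KM_PER_DEG_LAT * math.cos(lat_mid)
    dy = (lat_n - lat_s) * KM_PER_DEG_LAT
    return dx * dy


def build_synthetic_geometry(
    n_alongshore: int,
    n_offshore_bands: int,
    seed: int = 0,
    lat_south: float = 32.0,
    row_height_deg: float = 1.5,
    coast_lon: float = -118.0,
) -> ModelGeometry:
    """Build a rectangular coastline-strip geometry.

    Boxes form an ``n_alongshore`` (south to north) by ``n_offshore_bands``
    (coast to open ocean) grid.  Band widths grow geometrically away from the
    coast, so nearshore boxes have smaller areas, as in shelf-resolved
    ecosystem models.  ``seed`` drives a small reproducible jitter of the row
    heights; the result is deterministic for a given seed.
    """
    if n_alongshore < 1 or n_offshore_bands < 1:
        raise GeometryError("n_alongshore and n_offshore_bands must be >= 1")
    rng = np.random.default_rng(seed)
    row_heights = row_height_deg * (1.0 + 0.1 * rng.uniform(-1, 1, size=n_alongshore))
    lat_edges = lat_south + np.concatenate([[0.0], np.cumsum(row_heights)])
    # geometric widening offshore guarantees nearshore areas < offshore areas
    band_widths = 0.4 * (2.0 ** np.arange(n_offshore_bands))
    lon_edges = coast_lon - np.concatenate([[0.0], np.cumsum(band_widths)])

    boxes: list[Box] = []
    lat_axis = []

    def bid(row: int, band: int) -> int:
        return row * n_offshore_bands + band

    for row in range(n_alongshore):
        for band in range(n_offshore_bands):
            lat_s, lat_n = lat_edges[row], lat_edges[row + 1]
            lon_e, lon_w = lon_edges[band], lon_edges[band + 1]
            poly = ((lon_e, lat_s), (lon_e, lat_n), (lon_w, lat_n), (lon_w, lat_s))
            nbrs = set()
            if row > 0:
                nbrs.add(bid(row - 1, band))
            if row < n_alongshore - 1:
                nbrs.add(bid(row + 1, band))
            if band > 0:
                nbrs.add(bid(row, band - 1))
            if band < n_offshore_bands - 1:
                nbrs.add(bid(row, band + 1))
            boundary = (
                row in (0, n_alongshore - 1) or band == n_offshore_bands - 1
            )
            boxes.append(
                Box(
                    id=bid(row, band),
                    polygon=poly,
                    depth_band=DEPTH_BANDS[min(band, len(DEPTH_BANDS) - 1)],
                    area_km2=_quad_area_km2(lon_w, lon_e, lat_s, lat_n),
                    neighbors=frozenset(nbrs),
                    is_boundary=boundary,
                )
            )
            lat_axis.append(0.5 * (lat_s + lat_n))
    geom = ModelGeometry(
        boxes=boxes,
        latitudinal_axis=np.array(lat_axis),
        name=f"synthetic-{n_alongshore}x{n_offshore_bands}",
    )
    geom.validate()
    return geom


def cce_like_geometry(seed: int = 0) -> ModelGeometry:
    """Full-scale structural geometry: 89 boxes.

    A 17-row x 5-band shelf grid (85 boxes, depth bands 50-1200 m) plus four
    large open-ocean boxes offshore, each spanning several rows.  Structural
    preset only: box counts and adjacency are realistic in shape, the
    coordinates are schematic.
    """
    base = build_synthetic_geometry(17, 5, seed=seed)
    boxes = [replace(b) for b in base.boxes]
    lat_axis = list(base.latitudinal_axis)
    lat_edges = sorted({v for b in base.boxes for _, v in b.polygon})
    lon_w_shelf = min(x for b in base.boxes for x, _ in b.polygon)
    lon_w_ocean = lon_w_shelf - 4.0
    n_ocean = 4
    rows_per = [5, 4, 4, 4]  # 17 rows split among 4 oceanic boxes
    # rebuild mutable neighbor sets
    nbr: dict[int, set[int]] = {b.id: set(b.neighbors) for b in boxes}
    new_boxes: list[Box] = []
    row0 = 0
    for k in range(n_ocean):
        oid = 85 + k
        rows = list(range(row0, row0 + rows_per[k]))
        lat_s, lat_n = lat_edges[rows[0]], lat_edges[rows[-1] + 1]
        poly = (
            (lon_w_shelf, lat_s),
            (lon_w_shelf, lat_n),
            (lon_w_ocean, lat_n),
            (lon_w_ocean, lat_s),
        )
        onbrs = set()
        for r in rows:
            outer = r * 5 + 4  # outermost shelf band in this row
            onbrs.add(outer)
            nbr.setdefault(outer, set()).add(oid)
        if k > 0:
            onbrs.add(85 + k - 1)
            nbr.setdefault(85 + k - 1, set()).add(oid)
        nbr[oid] = onbrs
        new_boxes.append(
            Box(
                id=oid,
                polygon=poly,
                depth_band="oceanic",
                area_km2=_quad_area_km2(lon_w_ocean, lon_w_shelf, lat_s, lat_n),
                neighbors=frozenset(),
                is_boundary=True,
            )
        )
        lat_axis.append(0.5 * (lat_s + lat_n))
        row0 += rows_per[k]
    all_boxes = [
        replace(b, neighbors=frozenset(nbr[b.id])) for b in boxes + new_boxes
    ]
    geom = ModelGeometry(
        boxes=all_boxes, latitudinal_axis=np.array(lat_axis), name="cce-like-89"
    )
    geom.validate()
    return geom


# -- GeoJSON I/O -------------------------------------------------------------

def geometry_to_geojson(geom: ModelGeometry) -> dict:
    features = []
    for b, lat in zip(geom.boxes, geom.latitudinal_axis):
        ring = list(b.polygon) + [b.polygon[0]]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {
                    "id": b.id,
                    "depth_band": b.depth_band,
                    "area_km2": b.area_km2,
                    "neighbors": sorted(b.neighbors),
                    "boundary": b.is_boundary,
                    "latitudinal_axis": lat,
                },
            }
        )
    return {"type": "FeatureCollection", "name": geom.name, "features": features}


def geometry_from_geojson(doc: dict) -> ModelGeometry:
    feats = doc.get("features", [])
    if not feats:
        raise GeometryFormatError("empty feature collection")
    boxes = {}
    lat_axis = {}
    for i, f in enumerate(feats):
        try:
            props = f["properties"]
            bid = int(props["id"])
            ring = f["geometry"]["coordinates"][0]
        except (KeyError, TypeError, IndexError) as exc:
            raise GeometryFormatError(f"malformed feature {i}: {exc}", i) from exc
        if bid in boxes:
            raise GeometryFormatError(f"duplicate box id {bid} at feature {i}", i)
        poly = tuple((float(x), float(y)) for x, y in ring[:-1])
        boxes[bid] = Box(
            id=bid,
            polygon=poly,
            depth_band=str(props["depth_band"]),
            area_km2=float(props["area_km2"]),
            neighbors=frozenset(int(n) for n in props["neighbors"]),
            is_boundary=bool(props.get("boundary", False)),
        )
        lat_axis[bid] = float(props["latitudinal_axis"])
    ids = sorted(boxes)
    if ids != list(range(len(ids))):
        raise GeometryFormatError("box ids not contiguous from 0")
    geom = ModelGeometry(
        boxes=[boxes[i] for i in ids],
        latitudinal_axis=np.array([lat_axis[i] for i in ids]),
        name=doc.get("name", "geometry"),
    )
    geom.validate()
    return geom


def write_geometry(geom: ModelGeometry, path) -> None:
    with open(path, "w") as fh:
        json.dump(geometry_to_geojson(geom), fh, indent=1)


def read_geometry(path, format: str = "geojson") -> ModelGeometry:
    if format != "geojson":
        raise GeometryFormatError(f"unsupported format {format!r}")
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise GeometryFormatError(f"not valid JSON: {exc}") from exc
    return geometry_from_geojson(doc)
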