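"""Geography handling: polygons, centroids, distance bands, adjacency.

All geometry is planar and carried in a projected CRS with metric units;
distance-band construction buffers in metres, so geographic (lon/lat)
coordinates are refused — reproject upstream before loading.  Geometries
are shapely objects; files move as GeoJSON.

An :class:`AreaGeography` holds one polygon per area with a geometric
centroid (recomputed on load) and, optionally, a population-weighted
centroid supplied as data.  Distance bands around one or more putative
pollution sources are half-open annuli ``[lower, upper)`` of distance to
the *nearest* source; an area is assigned to the band containing its
chosen centroid.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from shapely.geometry import Point, mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

__all__ = [
    "AreaGeography",
    "SourceSet",
    "BandScheme",
    "AdjacencyGraph",
    "build_bands",
    "select_areas",
    "build_adjacency",
    "read_geojson_areas",
    "write_geojson_areas",
    "write_geojson_bands",
    "read_adjacency",
    "write_adjacency",
    "CRSError",
]

CENTROID_TOL = 1e-6  # relative tolerance for supplied-centroid checks


class CRSError(ValueError):
    """Coordinate-reference-system mismatch or unusable (geographic) CRS."""


_GEOGRAPHIC_NAMES = {"epsg:4326", "wgs84", "crs84", "ogc:crs84", "lonlat"}


def _check_planar(crs: str | None, geoms) -> None:
    if crs and crs.lower().replace(" ", "") in _GEOGRAPHIC_NAMES:
        raise CRSError(
            f"CRS {crs!r} is geographic; distance bands need a projected "
            "metric CRS — reproject before loading"
        )
    if crs is None:
        # Heuristic: coordinates that all fit in lon/lat ranges are suspect.
        bounds = np.array([g.bounds for g in geoms])
        if len(bounds) and np.all(np.abs(bounds[:, [0, 2]]) <= 180) and np.all(
            np.abs(bounds[:, [1, 3]]) <= 90
        ):
            warnings.warn(
                "coordinates look like lon/lat degrees; distances assume metres",
                stacklevel=3,
            )


@dataclass
class AreaGeography:
    """Polygon, centroid(s) and identifier per study area."""

    area_ids: list[str]
    polygons: list[BaseGeometry]
    crs: str | None = None
    population_weighted_centroids: dict[str, Point] | None = None
    geometric_centroids: dict[str, Point] = field(init=False)

    def __post_init__(self):
        if len(self.area_ids) != len(self.polygons):
            raise ValueError("area_ids and polygons differ in length")
        if len(set(self.area_ids)) != len(self.area_ids):
            dupes = {a for a in self.area_ids if self.area_ids.count(a) > 1}
            raise ValueError(f"duplicate area_ids: {sorted(dupes)}")
        for aid, poly in zip(self.area_ids, self.polygons):
            if not poly.is_valid:
                raise ValueError(f"invalid polygon for area {aid!r}")
        _check_planar(self.crs, self.polygons)
        self.geometric_centroids = {
            aid: poly.centroid for aid, poly in zip(self.area_ids, self.polygons)
        }

    def __len__(self):
        return len(self.area_ids)

    def polygon(self, area_id: str) -> BaseGeometry:
        return self.polygons[self.area_ids.index(area_id)]

    def centroid(self, area_id: str, method: str = "geometric_centroid") -> Point:
        if method == "geometric_centroid":
            return self.geometric_centroids[area_id]
        if method == "population_weighted_centroid":
            if not self.population_weighted_centroids or area_id not in (
                self.population_weighted_centroids
            ):
                raise ValueError(
                    f"no population-weighted centroid supplied for area {area_id!r}"
                )
            return self.population_weighted_centroids[area_id]
        raise ValueError(f"unknown centroid method {method!r}")


@dataclass
class SourceSet:
    """One or more putative source geometries (points, lines or polygons)."""

    geometries: list[BaseGeometry]
    labels: list[str] | None = None
    crs: str | None = None

    def __post_init__(self):
        if not self.geometries:
            raise ValueError("source set is empty")
        if self.labels is None:
            self.labels = [f"source_{i}" for i in range(len(self.geometries))]
        if len(self.labels) != len(self.geometries):
            raise ValueError("labels and geometries differ in length")
        _check_planar(self.crs, self.geometries)

    @property
    def union(self) -> BaseGeometry:
        return unary_union(self.geometries)


@dataclass(frozen=True)
class BandScheme:
    """Strictly increasing distance breaks (metres) defining half-open rings.

    Breaks ``(d1, d2, ...)`` define band 1 = ``[0, d1)``, band 2 =
    ``[d1, d2)``, etc.  A point exactly at a break belongs to the outer band.
    """

    breaks: tuple[float, ...]

    def __post_init__(self):
        b = tuple(float(x) for x in self.breaks)
        if not b:
            raise ValueError("band scheme needs at least one break")
        if b[0] <= 0 or any(b2 <= b1 for b1, b2 in zip(b, b[1:])):
            raise ValueError(f"breaks must be positive and strictly increasing: {b}")
        object.__setattr__(self, "breaks", b)

    @property
    def n_bands(self) -> int:
        return len(self.breaks)

    def band_of(self, distance: float) -> int | None:
        """1-based band index for a distance to the nearest source, or None."""
        for k, upper in enumerate(self.breaks, start=1):
            if distance < upper:
                return k
        return None

    def midpoints_km(self) -> list[float]:
        lowers = (0.0,) + self.breaks[:-1]
        return [(lo + hi) / 2 / 1000.0 for lo, hi in zip(lowers, self.breaks)]


def build_bands(sources: SourceSet, scheme: BandScheme) -> list[BaseGeometry]:
    """Annular band regions of distance-to-nearest-source.

    Band k is ``{x : d_(k-1) <= dist(x, nearest source) < d_k}``; with
    several sources this is the union of buffers minus the inner buffer,
    because distance to the union is distance to the nearest member.
    Returned regions are pairwise disjoint (up to shared boundaries) and
    their union out to break k equals the distance-<=d_k region.
    """
    src = sources.union
    discs = [src.buffer(d) for d in scheme.breaks]
    bands = [discs[0]]
    for inner, outer in zip(discs, discs[1:]):
        bands.append(outer.difference(inner))
    return bands


def select_areas(sources: SourceSet, scheme: BandScheme, areas: AreaGeography,
                 method: str = "geometric_centroid") -> dict[str, int | None]:
    """Assign each area to the distance band containing its centroid.

    Assignment is by exact centroid-to-nearest-source distance (not polygon
    containment), so the half-open convention is honoured exactly: a
    centroid at distance d_k falls in the outer band.  Centroids beyond the
    outermost break map to ``None`` (outside the study bands).
    """
    if areas.crs is not None and sources.crs is not None and areas.crs != sources.crs:
        raise CRSError(f"area CRS {areas.crs!r} != source CRS {sources.crs!r}")
    src = sources.union
    out: dict[str, int | None] = {}
    for aid in areas.area_ids:
        c = areas.centroid(aid, method)
        out[aid] = scheme.band_of(c.distance(src))
    return out


# ---------------------------------------------------------------------------
# Adjacency
# ---------------------------------------------------------------------------

@dataclass
class AdjacencyGraph:
    """Symmetric neighbour lists per area; no self-loops.

    Isolated areas are permitted (islands) and listed in ``isolated``.
    """

    neighbours: dict[str, list[str]]

    def __post_init__(self):
        for a, nbrs in self.neighbours.items():
            if a in nbrs:
                raise ValueError(f"self-loop at area {a!r}")
            for b in nbrs:
                if b not in self.neighbours or a not in self.neighbours[b]:
                    raise ValueError(f"asymmetric adjacency: {a!r} -> {b!r}")
        self.neighbours = {a: sorted(n) for a, n in self.neighbours.items()}

    @property
    def area_ids(self) -> list[str]:
        return list(self.neighbours)

    @property
    def isolated(self) -> list[str]:
        return [a for a, n in self.neighbours.items() if not n]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.neighbours)
        for a, nbrs in self.neighbours.items():
            g.add_edges_from((a, b) for b in nbrs)
        return g

    def connected_components(self) -> list[set[str]]:
        return [set(c) for c in nx.connected_components(self.to_networkx())]


def build_adjacency(areas: AreaGeography, rule: str = "queen") -> AdjacencyGraph:
    """Contiguity adjacency from polygons.

    queen: any shared boundary point; rook: a shared edge of positive
    length.  Isolated areas are flagged with a warning but retained.
    """
    if rule not in ("queen", "rook"):
        raise ValueError(f"unknown contiguity rule {rule!r}")
    from shapely.strtree import STRtree

    ids = areas.area_ids
    polys = areas.polygons
    tree = STRtree(polys)
    nbrs: dict[str, set[str]] = {a: set() for a in ids}
    for i, poly in enumerate(polys):
        for j in tree.query(poly, predicate="intersects"):
            j = int(j)
            if j <= i:
                continue
            inter = poly.intersection(polys[j])
            if inter.is_empty:
                continue
            if rule == "rook" and inter.length == 0:
                continue
            nbrs[ids[i]].add(ids[j])
            nbrs[ids[j]].add(ids[i])
    graph = AdjacencyGraph({a: sorted(n) for a, n in nbrs.items()})
    if graph.isolated:
        warnings.warn(f"isolated areas (no neighbours): {graph.isolated}", stacklevel=2)
    return graph


# ---------------------------------------------------------------------------
# GeoJSON and neighbour-list I/O
# ---------------------------------------------------------------------------

def read_geojson_areas(path, id_property: str = "area_id",
                       weighted_centroid_property: str | None = "pw_centroid",
                       crs: str | None = None) -> AreaGeography:
    """Load an area geography from a GeoJSON FeatureCollection.

    Each feature needs an ``area_id`` property and a (multi)polygon
    geometry.  A population-weighted centroid may be supplied per feature
    as a ``[x, y]`` property — it is data, never computed here.
    """
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValueError("expected a GeoJSON FeatureCollection")
    ids, polys, pw = [], [], {}
    for feat in gj["features"]:
        props = feat.get("properties") or {}
        if id_property not in props:
            raise ValueError(f"feature missing {id_property!r} property")
        aid = str(props[id_property])
        ids.append(aid)
        polys.append(shape(feat["geometry"]))
        if weighted_centroid_property and props.get(weighted_centroid_property):
            x, y = props[weighted_centroid_property]
            pw[aid] = Point(x, y)
    file_crs = crs or _geojson_crs(gj)
    return AreaGeography(ids, polys, crs=file_crs,
                         population_weighted_centroids=pw or None)


def _geojson_crs(gj: dict) -> str | None:
    crs = gj.get("crs")
    if isinstance(crs, dict):
        return crs.get("properties", {}).get("name")
    return crs


def write_geojson_areas(areas: AreaGeography, path,
                        properties: dict[str, dict] | None = None) -> None:
    """Write areas (optionally annotated with per-area result properties)."""
    feats = []
    for aid, poly in zip(areas.area_ids, areas.polygons):
        props = {"area_id": aid}
        if properties and aid in properties:
            props.update(properties[aid])
        feats.append({"type": "Feature", "properties": props,
                      "geometry": mapping(poly)})
    fc = {"type": "FeatureCollection", "features": feats}
    if areas.crs:
        fc["crs"] = {"type": "name", "properties": {"name": areas.crs}}
    with open(path, "w") as fh:
        json.dump(fc, fh)


def write_geojson_bands(bands: list[BaseGeometry], scheme: BandScheme, path,
                        crs: str | None = None) -> None:
    lowers = (0.0,) + scheme.breaks[:-1]
    feats = [
        {
            "type": "Feature",
            "properties": {"band": k + 1, "lower_m": lo, "upper_m": hi},
            "geometry": mapping(geom),
        }
        for k, (geom, lo, hi) in enumerate(zip(bands, lowers, scheme.breaks))
    ]
    fc = {"type": "FeatureCollection", "features": feats}
    if crs:
        fc["crs"] = {"type": "name", "properties": {"name": crs}}
    with open(path, "w") as fh:
        json.dump(fc, fh)


def read_sources_geojson(path, crs: str | None = None) -> SourceSet:
    """Load a SourceSet from a GeoJSON FeatureCollection of any geometry type."""
    with open(path) as fh:
        gj = json.load(fh)
    geoms, labels = [], []
    for i, feat in enumerate(gj["features"]):
        geoms.append(shape(feat["geometry"]))
        labels.append(str((feat.get("properties") or {}).get("label", f"source_{i}")))
    return SourceSet(geoms, labels, crs=crs or _geojson_crs(gj))


def write_adjacency(graph: AdjacencyGraph, path) -> None:
    """Neighbour-list text: one line per area — ``area_id n nbr1 nbr2 ...``."""
    with open(path, "w") as fh:
        for a in graph.area_ids:
            nbrs = graph.neighbours[a]
            fh.write(" ".join([a, str(len(nbrs))] + nbrs) + "\n")


def read_adjacency(path) -> AdjacencyGraph:
    nbrs: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            a, n = parts[0], int(parts[1])
            nbrs[a] = parts[2:2 + n]
    return AdjacencyGraph(nbrs)
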