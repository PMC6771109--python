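"""Binary first-order adjacency structure shared by the incidence and survival models.

Areas are adjacent when they share a boundary of positive length (rook
contiguity); point touches do not count.  Areas left with zero neighbours
("islands") are repaired by linking them to a nominated mainland area, or
failing that the nearest one by centroid distance, so that every modelled
area participates in the spatial smoothing.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import networkx as nx
import scipy.sparse as sp

__all__ = [
    "AreaGraph",
    "build_adjacency",
    "adjacency_from_polygons",
    "adjacency_from_edges",
    "repair_islands",
    "apply_exclusions",
    "read_edge_csv",
    "read_geojson_polygons",
]


@dataclass
class AreaGraph:
    """Area identifiers, symmetric binary adjacency and centroids.

    ``W`` is dense (desk scale); ``csr()`` exposes a cached sparse view for
    the samplers.  ``neighbour_counts`` is the diagonal of D.
    """

    area_ids: list
    W: np.ndarray
    centroids: np.ndarray | None = None
    _csr: sp.csr_matrix | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        n = len(self.area_ids)
        if self.W.shape != (n, n):
            raise ValueError(f"W shape {self.W.shape} does not match {n} areas")
        if len(set(self.area_ids)) != n:
            raise ValueError("duplicate area ids")
        if np.any(self.W.diagonal() != 0):
            raise ValueError("W must have a zero diagonal")
        if not np.array_equal(self.W, self.W.T):
            raise ValueError("W must be symmetric")
        if not np.all(np.isin(self.W, (0.0, 1.0))):
            raise ValueError("W must be binary")
        if self.centroids is not None:
            self.centroids = np.asarray(self.centroids, dtype=float)
            if self.centroids.shape != (n, 2):
                raise ValueError("centroids must be (n, 2)")

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def neighbour_counts(self) -> np.ndarray:
        return self.W.sum(axis=1)

    def csr(self) -> sp.csr_matrix:
        if self._csr is None:
            self._csr = sp.csr_matrix(self.W)
        return self._csr

    def islands(self) -> np.ndarray:
        """Indices of areas with no neighbours."""
        return np.flatnonzero(self.neighbour_counts == 0)

    def edges(self) -> list[tuple]:
        ii, jj = np.nonzero(np.triu(self.W))
        return [(self.area_ids[i], self.area_ids[j]) for i, j in zip(ii, jj)]

    def colour_classes(self) -> list[np.ndarray]:
        """Partition of areas into mutually non-adjacent index sets.

        Areas within a class share no edge, so their Leroux full
        conditionals depend only on areas outside the class; the samplers
        update each class as one vectorised block.
        """
        g = nx.from_numpy_array(self.W)
        colours = nx.greedy_color(g, strategy="largest_first")
        n_col = max(colours.values()) + 1 if colours else 0
        return [
            np.array(sorted(i for i, c in colours.items() if c == k), dtype=int)
            for k in range(n_col)
        ]

    def index_of(self, area_id) -> int:
        return self.area_ids.index(area_id)

    def write_edges_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["id_a", "id_b"])
            for a, b in self.edges():
                w.writerow([a, b])

    def summary(self) -> dict:
        return {
            "n_areas": self.n_areas,
            "n_edges": int(self.W.sum() // 2),
            "n_islands": int(len(self.islands())),
        }


def adjacency_from_polygons(polygons: Mapping) -> AreaGraph:
    """Rook adjacency from shapely polygons: shared boundary of positive length.

    A polygon wholly enclosed within another shares its full boundary with
    the enclosing ring and therefore has exactly one neighbour; corner
    touches yield zero-length intersections and do not connect.
    """
    ids = list(polygons.keys())
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate area ids")
    geoms = [polygons[a] for a in ids]
    n = len(ids)
    W = np.zeros((n, n))
    tree = None
    try:
        from shapely.strtree import STRtree

        tree = STRtree(geoms)
    except Exception:  # pragma: no cover - STRtree always available with shapely 2
        pass
    for i, gi in enumerate(geoms):
        if tree is not None:
            cand = [int(j) for j in tree.query(gi)]
        else:  # pragma: no cover
            cand = range(n)
        for j in cand:
            if j <= i:
                continue
            inter = gi.boundary.intersection(geoms[j].boundary)
            if inter.length > 0:
                W[i, j] = W[j, i] = 1.0
    cents = np.array([[g.centroid.x, g.centroid.y] for g in geoms])
    return AreaGraph(ids, W, cents)


def adjacency_from_edges(
    edges: Iterable[tuple], area_ids: Sequence, centroids=None
) -> AreaGraph:
    """Adjacency from an explicit edge list over ``area_ids``."""
    ids = list(area_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate area ids")
    idx = {a: i for i, a in enumerate(ids)}
    W = np.zeros((len(ids), len(ids)))
    for a, b in edges:
        if a == b:
            raise ValueError(f"self-edge on area {a!r}")
        if a not in idx or b not in idx:
            raise ValueError(f"edge ({a!r}, {b!r}) references unknown area")
        W[idx[a], idx[b]] = W[idx[b], idx[a]] = 1.0
    return AreaGraph(ids, W, centroids)


def build_adjacency(source, area_ids=None, centroids=None) -> AreaGraph:
    """Build an :class:`AreaGraph` from polygons (mapping id -> geometry) or
    an edge list (requires ``area_ids``)."""
    if isinstance(source, Mapping):
        return adjacency_from_polygons(source)
    if area_ids is None:
        raise ValueError("edge-list mode requires area_ids")
    return adjacency_from_edges(source, area_ids, centroids)


def repair_islands(graph: AreaGraph, manual_links: Mapping | None = None) -> AreaGraph:
    """Link every zero-neighbour area to at least one mainland area.

    ``manual_links`` maps island id -> mainland id (bridge/ferry style
    assignments); otherwise the nearest non-island area by centroid
    distance is used, ties broken by lowest area id.  Idempotent; existing
    adjacency is never altered.
    """
    islands = graph.islands()
    if len(islands) == 0:
        return graph
    if len(islands) == graph.n_areas:
        raise ValueError("graph consists only of islands; nothing to attach to")
    manual_links = dict(manual_links or {})
    W = graph.W.copy()
    island_set = set(islands.tolist())
    mainland = [i for i in range(graph.n_areas) if i not in island_set]
    for isl in islands:
        isl_id = graph.area_ids[isl]
        if isl_id in manual_links:
            target = graph.index_of(manual_links[isl_id])
            if target == isl:
                raise ValueError(f"manual link maps island {isl_id!r} to itself")
        else:
            if graph.centroids is None:
                raise ValueError("centroids required to repair islands without manual links")
            d = np.linalg.norm(
                graph.centroids[mainland] - graph.centroids[isl], axis=1
            )
            best = d.min()
            # tie-break on lowest area id for deterministic builds
            tied = [mainland[k] for k in np.flatnonzero(d == best)]
            target = min(tied, key=lambda k: str(graph.area_ids[k]))
        W[isl, target] = W[target, isl] = 1.0
    return AreaGraph(graph.area_ids, W, graph.centroids)


def apply_exclusions(fixture) -> list:
    """Drop every flagged record; return the retained area ids."""
    return [rec.area_id for rec in fixture.records if rec.flag is None]


def read_edge_csv(path) -> list[tuple[str, str]]:
    edges = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            edges.append((row["id_a"], row["id_b"]))
    return edges


def read_geojson_polygons(path) -> dict:
    """Read a GeoJSON FeatureCollection into a mapping id -> shapely geometry."""
    from shapely.geometry import shape

    with open(path) as fh:
        gj = json.load(fh)
    out = {}
    for feat in gj["features"]:
        fid = feat.get("id", feat.get("properties", {}).get("id"))
        if fid is None:
            raise ValueError("feature without an id")
        out[fid] = shape(feat["geometry"])
    return out
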