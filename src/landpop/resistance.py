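"""Resistance surfaces and least-cost distances over raster landscapes.

Terrain resistance follows the occurrence-anchored quantile tier scheme:
cells whose Terrain Ruggedness Index (TRI) falls in the central 70% of
the occurrence TRI distribution cost 1, the adjacent 5% quantile bands
cost 2, 4 and 8 outward, and TRI outside the occupied range costs 16.
Habitat and stability resistance are one minus suitability. Movement is
modelled on a 16-neighbour ("knight and one-cell queen move") graph whose
edge weights are great-circle lengths between cell centers times the mean
resistance of the two cells; least-cost distances are Dijkstra shortest
paths between snapped locality centroids.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.csgraph import dijkstra
from shapely.geometry import MultiPoint, Point

from .geo import haversine_km
from .matrices import DistanceMatrix
from .raster import Raster
from .synthetic import LocalityTable

__all__ = [
    "CostSurface",
    "TransitionGraph",
    "terrain_ruggedness",
    "elevation_mask",
    "tri_cost_surface",
    "suitability_cost_surface",
    "build_transition_graph",
    "least_cost_distances",
]

TIER_COSTS = (1.0, 2.0, 4.0, 8.0, 16.0)

# queen (8) plus knight (8) moves
_MOVES = [
    (-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1),
    (-2, -1), (-2, 1), (-1, -2), (-1, 2), (1, -2), (1, 2), (2, -1), (2, 1),
]


@dataclass
class CostSurface:
    raster: Raster
    provenance: str                 # terrain-tier | one-minus-suitability | one-minus-stability
    tier_table: dict | None = None  # tier -> (lo, hi) TRI interval, when tiered


@dataclass
class TransitionGraph:
    weights: csr_matrix             # passable-cell x passable-cell symmetric weights
    node_rows: np.ndarray
    node_cols: np.ndarray
    raster: Raster                  # the cost raster the graph was built from

    @property
    def n_nodes(self) -> int:
        return self.node_rows.size

    def node_index(self) -> np.ndarray:
        """Grid of node ids, -1 at impassable cells."""
        idx = np.full(self.raster.shape, -1, dtype=int)
        idx[self.node_rows, self.node_cols] = np.arange(self.n_nodes)
        return idx

    def degree(self, row: int, col: int) -> int:
        idx = self.node_index()
        node = idx[row, col]
        if node < 0:
            raise ValueError("cell is impassable")
        return int((self.weights[node].toarray() > 0).sum())


# ---------------------------------------------------------------------------


def terrain_ruggedness(elevation: Raster, variant: str = "riley") -> Raster:
    """Terrain Ruggedness Index over the 8-neighbourhood.

    riley: sqrt(sum of squared neighbour differences) — the classic form.
    mean_abs: mean absolute neighbour difference. Edge cells use the
    neighbours that exist; nodata propagates.
    """
    if elevation.shape[0] < 3 or elevation.shape[1] < 3:
        raise ValueError("TRI needs at least a 3x3 grid")
    vals = elevation.masked_values()
    if np.all(np.isnan(vals)):
        raise ValueError("elevation raster is entirely nodata")
    acc = np.zeros_like(vals)
    cnt = np.zeros_like(vals)
    rows, cols = vals.shape
    for dr, dc in _MOVES[:8]:
        shifted = np.full_like(vals, np.nan)
        r0, r1 = max(dr, 0), rows + min(dr, 0)
        c0, c1 = max(dc, 0), cols + min(dc, 0)
        shifted[r0:r1, c0:c1] = vals[r0 - dr : r1 - dr, c0 - dc : c1 - dc]
        diff = shifted - vals
        ok = ~np.isnan(diff)
        if variant == "riley":
            acc[ok] += diff[ok] ** 2
        elif variant == "mean_abs":
            acc[ok] += np.abs(diff[ok])
        else:
            raise ValueError(f"unknown TRI variant '{variant}'")
        cnt[ok] += 1
    with np.errstate(invalid="ignore"):
        tri = np.sqrt(acc) if variant == "riley" else acc / np.where(cnt == 0, 1, cnt)
    tri[np.isnan(vals)] = np.nan
    return elevation.with_values(tri, "tri")


def elevation_mask(
    raster: Raster,
    occurrences: np.ndarray,
    occurrence_elevations: np.ndarray,
    elevation: Raster | None = None,
    hull_buffer_deg: float = 0.4,
    elev_margin_m: float = 100.0,
    lower_bound_zero: bool = False,
) -> Raster:
    """Mask cells outside the buffered occurrence convex hull or outside the
    occupied elevation band (min - margin, max + margin).

    ``lower_bound_zero`` drops the lower restriction (used for past-climate
    stability surfaces, where elevation zones may have shifted downward).
    """
    pts = np.asarray(occurrences, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 occurrences for a convex hull")
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull.buffer(hull_buffer_deg)
    if hull.is_empty or hull.area == 0:
        raise ValueError("occurrences are collinear; hull is degenerate")
    elev = elevation if elevation is not None else raster
    occ_elev = np.asarray(occurrence_elevations, dtype=float)
    lo = -np.inf if lower_bound_zero else occ_elev.min() - elev_margin_m
    hi = occ_elev.max() + elev_margin_m

    lon_grid, lat_grid = raster.cell_centers()
    inside = np.zeros(raster.shape, dtype=bool)
    prepared = hull  # shapely 2: covers() includes the boundary (closed hull)
    flat = np.column_stack([lon_grid.ravel(), lat_grid.ravel()])
    from shapely import points as shp_points, covers as shp_covers
    inside = shp_covers(prepared, shp_points(flat)).reshape(raster.shape)
    band = (elev.values >= lo) & (elev.values <= hi)
    mask = raster.nodata_mask | ~inside | ~band
    if mask.all():
        raise ValueError("elevation/hull mask leaves no passable cell")
    vals = raster.values.copy()
    vals[mask] = np.nan
    return Raster(vals, raster.west, raster.north, raster.cell_size, mask, raster.name)


def tri_cost_surface(tri: Raster, occurrence_tri: np.ndarray) -> CostSurface:
    """Quantile-tiered cost surface anchored on the occurrence TRI distribution.

    Costs: 1 on [q15, q85] (central 70%), 2 on [q10,q15) and (q85,q90],
    4 on [q5,q10) and (q90,q95], 8 on [q0,q5) and (q95,q100], 16 outside
    the occupied range. Boundary ties resolve to the cheaper tier.
    """
    occ = np.asarray(occurrence_tri, dtype=float)
    occ = occ[~np.isnan(occ)]
    if occ.size < 20:
        raise ValueError("need at least 20 occurrence TRI values")
    q = np.quantile(occ, [0, 0.05, 0.10, 0.15, 0.85, 0.90, 0.95, 1.0])
    q0, q5, q10, q15, q85, q90, q95, q100 = q
    v = tri.values
    if q0 == q100:
        warnings.warn("occurrence TRI is constant; degenerate tier rule applied")
        cost = np.where(v == q0, 1.0, 16.0)
    else:
        cost = np.full(tri.shape, 16.0)
        cost[(v >= q0) & (v < q5)] = 8.0
        cost[(v > q95) & (v <= q100)] = 8.0
        cost[(v >= q5) & (v < q10)] = 4.0
        cost[(v > q90) & (v <= q95)] = 4.0
        cost[(v >= q10) & (v < q15)] = 2.0
        cost[(v > q85) & (v <= q90)] = 2.0
        cost[(v >= q15) & (v <= q85)] = 1.0
    cost[np.isnan(v) | tri.nodata_mask] = np.nan
    table = {
        1.0: (q15, q85), 2.0: (q10, q90), 4.0: (q5, q95),
        8.0: (q0, q100), 16.0: (-math.inf, math.inf),
    }
    return CostSurface(tri.with_values(cost, "cost_terrain"), "terrain-tier", table)


def suitability_cost_surface(suitability: Raster, provenance: str = "one-minus-suitability") -> CostSurface:
    """Resistance = 1 - suitability (0 = low cost, 1 = high cost)."""
    v = suitability.values
    ok = ~np.isnan(v)
    if np.any((v[ok] < 0) | (v[ok] > 1)):
        raise ValueError("suitability values must lie in [0, 1]")
    return CostSurface(suitability.with_values(1.0 - v, "cost_suitability"), provenance)


# ---------------------------------------------------------------------------


def build_transition_graph(
    cost: CostSurface,
    epsilon: float = 1e-6,
    mean: str = "resistance",
) -> TransitionGraph:
    """16-neighbour movement graph with geo-corrected, resistance-weighted edges.

    Edge weight = great-circle length between the two cell centers times the
    arithmetic mean of their resistances (floored at epsilon); ``mean=
    "conductance"`` uses the harmonic mean of resistances instead, matching
    transition tools that average conductance.
    """
    raster = cost.raster
    passable = ~raster.nodata_mask & ~np.isnan(raster.values)
    if not passable.any():
        raise ValueError("no passable cell")
    rows, cols = raster.shape
    idx = np.full((rows, cols), -1, dtype=np.int64)
    node_rows, node_cols = np.nonzero(passable)
    idx[node_rows, node_cols] = np.arange(node_rows.size)
    lon_grid, lat_grid = raster.cell_centers()
    cvals = raster.values

    src_list, dst_list, w_list = [], [], []
    for dr, dc in _MOVES:
        r0, r1 = max(dr, 0), rows + min(dr, 0)
        c0, c1 = max(dc, 0), cols + min(dc, 0)
        if r0 >= r1 or c0 >= c1:
            continue
        a = idx[r0 - dr : r1 - dr, c0 - dc : c1 - dc]
        b = idx[r0:r1, c0:c1]
        ok = (a >= 0) & (b >= 0)
        if not ok.any():
            continue
        ai, bi = a[ok], b[ok]
        lon1 = lon_grid[r0 - dr : r1 - dr, c0 - dc : c1 - dc][ok]
        lat1 = lat_grid[r0 - dr : r1 - dr, c0 - dc : c1 - dc][ok]
        lon2 = lon_grid[r0:r1, c0:c1][ok]
        lat2 = lat_grid[r0:r1, c0:c1][ok]
        dist = haversine_km(lon1, lat1, lon2, lat2)
        ca = cvals[r0 - dr : r1 - dr, c0 - dc : c1 - dc][ok]
        cb = cvals[r0:r1, c0:c1][ok]
        if mean == "resistance":
            res = (ca + cb) / 2.0
        elif mean == "conductance":
            res = 2.0 / (1.0 / np.maximum(ca, epsilon) + 1.0 / np.maximum(cb, epsilon))
        else:
            raise ValueError(f"unknown edge mean '{mean}'")
        w = dist * np.maximum(res, epsilon)
        src_list.append(ai)
        dst_list.append(bi)
        w_list.append(w)
    src = np.concatenate(src_list)
    dst = np.concatenate(dst_list)
    w = np.concatenate(w_list)
    n = node_rows.size
    mat = coo_matrix((w, (src, dst)), shape=(n, n)).tocsr()
    return TransitionGraph(mat, node_rows, node_cols, raster)


def snap_to_passable(
    graph: TransitionGraph, lon: float, lat: float, snap_radius_cells: float = 2.0
) -> int:
    """Nearest passable node within snap_radius_cells cell-diagonals."""
    raster = graph.raster
    cell_km = haversine_km(0, 0, raster.cell_size, 0)
    radius_km = snap_radius_cells * cell_km * math.sqrt(2)
    lons = raster.west + (graph.node_cols + 0.5) * raster.cell_size
    lats = raster.north - (graph.node_rows + 0.5) * raster.cell_size
    d = haversine_km(lon, lat, lons, lats)
    best = int(np.argmin(d))
    if d[best] > radius_km:
        raise ValueError(
            f"no passable cell within {radius_km:.2f} km of ({lon:.4f}, {lat:.4f})"
        )
    return best


def least_cost_distances(
    graph: TransitionGraph,
    localities: LocalityTable,
    snap_radius_cells: float = 2.0,
    kind: str = "",
) -> DistanceMatrix:
    """Pairwise least-accumulative-cost distances between locality centroids.

    Centroids snap to the nearest passable cell within the snap radius;
    unreachable pairs come back infinite.
    """
    names = localities.names
    cent = localities.centroids()
    nodes = []
    for name, (lon, lat) in zip(names, cent):
        try:
            nodes.append(snap_to_passable(graph, lon, lat, snap_radius_cells))
        except ValueError as exc:
            raise ValueError(f"locality {name}: {exc}") from exc
    dist = dijkstra(graph.weights, directed=False, indices=nodes)
    out = dist[:, nodes]
    out = (out + out.T) / 2.0        # symmetrize away float round-off
    np.fill_diagonal(out, 0.0)
    if np.isinf(out).any():
        warnings.warn("some locality pairs are unreachable (infinite distance)")
    return DistanceMatrix(list(names), out, kind)
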