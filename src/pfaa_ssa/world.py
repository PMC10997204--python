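"""Gridded ocean world: provinces, concentration scenarios, cell masks.

The global ocean is partitioned into biogeochemical provinces (after
Longhurst's classification) which act as the spatial units for seawater
PFAA concentrations.  Field measurements are aggregated to grid-cell
medians, then to per-province scenario triples (median / Q1 / Q3), with
the following completion rules:

* provinces with measurements in fewer than three grid cells are merged
  into the adjacent province with the most occupied cells;
* provinces with no data copy the scenario triple of an adjacent
  noncoastal province with data, or failing that of the Atlantic
  province whose latitude band overlaps theirs most;
* for deposition, coastal-province concentrations are extended inland
  by two grid cells (queen-neighbour dilation) and remaining inland
  cells take the closest noncoastal province's concentrations.

Land, coast and inland cells are classified by intersecting grid-cell
boxes with land polygons and coastline polylines; "land" comprises
"coast" and "inland".
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, box
from shapely.prepared import prep

logger = logging.getLogger(__name__)

EARTH_RADIUS_M = 6.371e6

Provenance = str  # measured | merged | neighbor_fallback | latitude_fallback


@dataclass(frozen=True)
class GridSpec:
    """A global latitude-longitude grid.

    ``lat_edges`` spans -90..90 and ``lon_edges`` -180..180; cell areas
    follow the spherical formula A = R^2 * dlam * (sin(top) - sin(bot))
    so they sum to the full sphere.
    """

    lat_edges: np.ndarray
    lon_edges: np.ndarray

    @classmethod
    def regular(cls, nlat: int, nlon: int) -> "GridSpec":
        return cls(
            lat_edges=np.linspace(-90.0, 90.0, nlat + 1),
            lon_edges=np.linspace(-180.0, 180.0, nlon + 1),
        )

    @classmethod
    def noresm(cls) -> "GridSpec":
        """The 1.9 degree (lat) x 2.5 degree (lon) Earth-system-model grid."""
        return cls.regular(96, 144)

    @property
    def nlat(self) -> int:
        return len(self.lat_edges) - 1

    @property
    def nlon(self) -> int:
        return len(self.lon_edges) - 1

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nlat, self.nlon)

    @property
    def lat_centers(self) -> np.ndarray:
        return 0.5 * (self.lat_edges[:-1] + self.lat_edges[1:])

    @property
    def lon_centers(self) -> np.ndarray:
        return 0.5 * (self.lon_edges[:-1] + self.lon_edges[1:])

    def cell_areas(self) -> np.ndarray:
        """Per-cell area in m^2, shape (nlat, nlon)."""
        phi = np.radians(self.lat_edges)
        dlam = np.radians(np.diff(self.lon_edges))
        band = EARTH_RADIUS_M**2 * np.diff(np.sin(phi))
        return band[:, None] * dlam[None, :]

    def cell_box(self, i: int, j: int):
        return box(
            self.lon_edges[j], self.lat_edges[i],
            self.lon_edges[j + 1], self.lat_edges[i + 1],
        )

    def cell_of(self, lat: float, lon: float) -> tuple[int, int]:
        lon = ((lon + 180.0) % 360.0) - 180.0
        i = int(np.clip(np.searchsorted(self.lat_edges, lat, side="right") - 1, 0, self.nlat - 1))
        j = int(np.clip(np.searchsorted(self.lon_edges, lon, side="right") - 1, 0, self.nlon - 1))
        return i, j

    def neighbors(self, i: int, j: int, *, queen: bool = False) -> list[tuple[int, int]]:
        """Adjacent cells; longitude wraps at the dateline, latitude does not."""
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
        if queen:
            steps += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
        out = []
        for di, dj in steps:
            ni = i + di
            if not 0 <= ni < self.nlat:
                continue
            out.append((ni, (j + dj) % self.nlon))
        return out


@dataclass(frozen=True)
class Province:
    id: int
    name: str
    coastal: bool
    basin: str = ""


@dataclass
class ProvinceRaster:
    """Grid-cell -> province map plus per-province scenario concentrations.

    ``province_id`` is -1 for cells without a province (interior land).
    ``concentrations`` has columns
    ``province_id, homolog, mean, low, high, provenance`` (pg/L).
    """

    grid: GridSpec
    province_id: np.ndarray
    provinces: dict[int, Province]
    concentrations: pd.DataFrame | None = None
    merged_from: dict[int, int] = field(default_factory=dict)

    def cells_of(self, pid: int) -> list[tuple[int, int]]:
        ii, jj = np.nonzero(self.province_id == pid)
        return list(zip(ii.tolist(), jj.tolist()))

    def latitude_band(self, pid: int) -> tuple[float, float]:
        """Latitude extent (degrees) of a province's cells."""
        cells = self.cells_of(pid)
        if not cells:
            raise KeyError(f"province {pid} has no cells")
        lats_lo = [self.grid.lat_edges[i] for i, _ in cells]
        lats_hi = [self.grid.lat_edges[i + 1] for i, _ in cells]
        return float(min(lats_lo)), float(max(lats_hi))


@dataclass(frozen=True)
class CellMask:
    """Per-cell land / coast / inland booleans.

    ``inland`` = land and not coast; "land" covers both coast-on-land
    and inland cells.
    """

    land: np.ndarray
    coast: np.ndarray

    @property
    def inland(self) -> np.ndarray:
        return self.land & ~self.coast

    def __post_init__(self) -> None:
        if self.land.shape != self.coast.shape:
            raise ValueError("mask shapes differ")


def rasterize_provinces(
    geoms: Mapping[int, object],
    provinces: Mapping[int, Province],
    grid: GridSpec,
    ocean_mask: np.ndarray | None = None,
) -> ProvinceRaster:
    """Assign each ocean cell the province containing its centre.

    Cells whose centre is covered by several polygons (boundary cases)
    or by none take the province with the largest areal overlap of the
    cell box; an ocean cell overlapping no polygon at all is assigned
    the nearest province and logged.
    """
    if ocean_mask is None:
        ocean_mask = np.ones(grid.shape, dtype=bool)
    pid = np.full(grid.shape, -1, dtype=int)
    prepared = {k: prep(g) for k, g in geoms.items()}
    order = sorted(geoms)
    for i in range(grid.nlat):
        for j in range(grid.nlon):
            if not ocean_mask[i, j]:
                continue
            pt = Point(grid.lon_centers[j], grid.lat_centers[i])
            covering = [k for k in order if prepared[k].covers(pt)]
            if len(covering) == 1:
                pid[i, j] = covering[0]
                continue
            cell = grid.cell_box(i, j)
            cands = covering if covering else order
            overlaps = [(geoms[k].intersection(cell).area, -k) for k in cands]
            best_area, neg_k = max(overlaps)
            if best_area > 0:
                pid[i, j] = -neg_k
            else:
                dists = [(geoms[k].distance(pt), k) for k in order]
                _, k = min(dists)
                pid[i, j] = k
                logger.warning(
                    "ocean cell (%d, %d) covered by no province; assigned nearest %d",
                    i, j, k,
                )
    return ProvinceRaster(grid, pid, dict(provinces))


def cell_medians(measurements: pd.DataFrame, grid: GridSpec) -> pd.DataFrame:
    """Collapse located measurements to one value per occupied cell.

    ``measurements`` columns: lat, lon, homolog, value (pg/L; values
    below a study's detection limit are expected to arrive already
    substituted by that study's MDL).  Returns columns
    ``i, j, homolog, value`` with the median per cell and homolog.
    """
    rows = []
    for _, r in measurements.iterrows():
        i, j = grid.cell_of(r["lat"], r["lon"])
        rows.append((i, j, r["homolog"], float(r["value"])))
    df = pd.DataFrame(rows, columns=["i", "j", "homolog", "value"])
    return (
        df.groupby(["i", "j", "homolog"], as_index=False)["value"].median()
    )


def occupied_cell_counts(cell_med: pd.DataFrame, raster: ProvinceRaster) -> dict[int, int]:
    """Number of distinct occupied grid cells per province."""
    counts = {pid: 0 for pid in raster.provinces}
    for (i, j), _ in cell_med.groupby(["i", "j"]):
        pid = int(raster.province_id[i, j])
        if pid in counts:
            counts[pid] += 1
    return counts


def province_adjacency(raster: ProvinceRaster) -> dict[int, set[int]]:
    """Provinces sharing at least one raster cell edge (longitude wraps)."""
    adj: dict[int, set[int]] = {pid: set() for pid in raster.provinces}
    g = raster.grid
    for i in range(g.nlat):
        for j in range(g.nlon):
            a = int(raster.province_id[i, j])
            if a < 0:
                continue
            for ni, nj in g.neighbors(i, j):
                b = int(raster.province_id[ni, nj])
                if b >= 0 and b != a:
                    adj[a].add(b)
                    adj[b].add(a)
    return adj


def merge_sparse_provinces(
    raster: ProvinceRaster, counts: Mapping[int, int], *, min_cells: int = 3
) -> tuple[ProvinceRaster, dict[int, int]]:
    """Merge provinces with data in fewer than ``min_cells`` cells.

    Each sparse province (with at least one occupied cell) is absorbed
    by the adjacent province with the greatest number of occupied
    cells; ties break to the smaller id.  Repeats until no mergeable
    province remains.  Data-free provinces are left for the fallback
    rules.  Returns the updated raster and a map old id -> absorbing id.
    """
    counts = dict(counts)
    pid = raster.province_id.copy()
    provinces = dict(raster.provinces)
    merges: dict[int, int] = {}
    work = ProvinceRaster(raster.grid, pid, provinces)
    while True:
        adj = province_adjacency(work)
        sparse = sorted(
            p for p, c in counts.items() if 0 < c < min_cells and p in provinces
        )
        did_merge = False
        for p in sparse:
            cands = [q for q in adj.get(p, ()) if counts.get(q, 0) > 0]
            if not cands:
                continue
            target = min(cands, key=lambda q: (-counts[q], q))
            pid[pid == p] = target
            counts[target] += counts.pop(p)
            provinces.pop(p)
            merges[p] = target
            did_merge = True
            break
        if not did_merge:
            break
    # resolve chains a->b->c
    for old in list(merges):
        t = merges[old]
        while t in merges:
            t = merges[t]
        merges[old] = t
    return ProvinceRaster(raster.grid, pid, provinces, merged_from=merges), merges


def province_concentrations(
    cell_med: pd.DataFrame,
    raster: ProvinceRaster,
    *,
    min_cells: int = 3,
) -> pd.DataFrame:
    """Scenario triples per province from occupied-cell values.

    mean = median, low = first quartile, high = third quartile of the
    occupied-cell concentrations (linear-interpolation quartiles).
    Provinces that still hold data in fewer than ``min_cells`` cells
    must have been merged beforehand; reaching this step unmerged is an
    error.  Data-free provinces are absent from the result (the
    fallback rules complete them).
    """
    counts = occupied_cell_counts(cell_med, raster)
    rows = []
    pid_of_cell = {
        (i, j): int(raster.province_id[i, j])
        for (i, j), _ in cell_med.groupby(["i", "j"])
    }
    for p in sorted(raster.provinces):
        c = counts.get(p, 0)
        if c == 0:
            continue
        if c < min_cells:
            adj = province_adjacency(raster)
            if any(counts.get(q, 0) > 0 for q in adj.get(p, ())):
                raise ValueError(
                    f"province {p} has data in only {c} cells and was not merged"
                )
            # isolated sparse province with no richer neighbour: use as-is
            logger.warning(
                "province %d kept with only %d occupied cells (no mergeable neighbour)",
                p, c,
            )
        sub = cell_med[[pid_of_cell[(i, j)] == p for i, j in zip(cell_med["i"], cell_med["j"])]]
        provenance = "merged" if p in set(raster.merged_from.values()) else "measured"
        for h, grpv in sub.groupby("homolog"):
            vals = grpv["value"].to_numpy()
            lo, mid, hi = np.percentile(vals, [25, 50, 75])
            rows.append((p, h, mid, lo, hi, provenance))
    return pd.DataFrame(
        rows, columns=["province_id", "homolog", "mean", "low", "high", "provenance"]
    )


def fallback_concentrations(
    raster: ProvinceRaster, conc: pd.DataFrame
) -> pd.DataFrame:
    """Complete the scenario table for data-free provinces.

    A province without data copies the scenario triple of an adjacent
    noncoastal province that has data (smallest id among candidates);
    provinces still unresolved take the triple of the Atlantic province
    whose latitude band overlaps theirs most.  Provenance is recorded
    as ``neighbor_fallback`` or ``latitude_fallback``.
    """
    conc = conc.copy()
    have = set(conc["province_id"].unique())
    missing = sorted(p for p in raster.provinces if p not in have)
    adj = province_adjacency(raster)

    def copy_triple(src: int, dst: int, provenance: Provenance) -> pd.DataFrame:
        block = conc[conc["province_id"] == src].copy()
        block["province_id"] = dst
        block["provenance"] = provenance
        return block

    # pass 1..k: adjacent noncoastal provinces with data (earlier-resolved
    # provinces become valid sources for later passes)
    resolved_from: dict[int, Provenance] = {}
    changed = True
    while changed and missing:
        changed = False
        for p in list(missing):
            cands = sorted(
                q for q in adj.get(p, ())
                if q in have and not raster.provinces[q].coastal
            )
            if cands:
                conc = pd.concat(
                    [conc, copy_triple(cands[0], p, "neighbor_fallback")],
                    ignore_index=True,
                )
                have.add(p)
                missing.remove(p)
                resolved_from[p] = "neighbor_fallback"
                changed = True

    # latitude fallback against Atlantic provinces with non-fallback data
    atlantic = [
        q for q in sorted(have)
        if raster.provinces.get(q) is not None
        and raster.provinces[q].basin == "atlantic"
        and q not in resolved_from
    ]
    for p in list(missing):
        lo, hi = raster.latitude_band(p)
        best = None
        for q in atlantic:
            qlo, qhi = raster.latitude_band(q)
            overlap = min(hi, qhi) - max(lo, qlo)
            key = (overlap, -q)
            if overlap > 0 and (best is None or key > best[0]):
                best = (key, q)
        if best is None:
            raise ValueError(
                f"province {p} has no data, no noncoastal neighbour with data, "
                "and no overlapping Atlantic province"
            )
        conc = pd.concat(
            [conc, copy_triple(best[1], p, "latitude_fallback")], ignore_index=True
        )
        missing.remove(p)
    return conc.sort_values(["province_id", "homolog"]).reset_index(drop=True)


def classify_cells(
    grid: GridSpec,
    land_geoms: Iterable[object],
    coastline_geoms: Iterable[object],
) -> CellMask:
    """Land / coast / inland classification by cell-box intersection.

    A cell intersecting any land polygon is a land cell; a cell
    intersecting any coastline geometry is a coast cell; land cells not
    touching the coastline are inland cells.
    """
    land = np.zeros(grid.shape, dtype=bool)
    coast = np.zeros(grid.shape, dtype=bool)
    land_prep = [prep(g) for g in land_geoms]
    coast_prep = [prep(g) for g in coastline_geoms]
    for i in range(grid.nlat):
        for j in range(grid.nlon):
            cell = grid.cell_box(i, j)
            land[i, j] = any(g.intersects(cell) for g in land_prep)
            coast[i, j] = any(g.intersects(cell) for g in coast_prep)
    return CellMask(land=land, coast=coast)


def extend_coastal(
    raster: ProvinceRaster, mask: CellMask, n: int = 2
) -> np.ndarray:
    """Province-id source map for deposition concentrations.

    Ocean cells keep their own province.  Land cells within ``n``
    queen-neighbour dilation steps of a coastal-province cell take that
    province's concentrations (nearest source wins; ties break to the
    smaller province id).  Remaining land cells take the closest
    noncoastal province (same BFS metric and tie-break).
    """
    if n < 0:
        raise ValueError("dilation depth must be >= 0")
    g = raster.grid
    source = raster.province_id.copy()
    land = mask.land

    def bfs(seeds: list[tuple[int, int, int]], targets: np.ndarray, max_depth: int | None):
        """Multi-source BFS over queen moves onto ``targets`` cells."""
        dist = np.full(g.shape, -1, dtype=int)
        assign = np.full(g.shape, -1, dtype=int)
        q: deque[tuple[int, int]] = deque()
        for i, j, pid in sorted(seeds, key=lambda s: (s[2],)):
            if dist[i, j] == -1 or pid < assign[i, j]:
                dist[i, j] = 0
                assign[i, j] = pid
                q.append((i, j))
        while q:
            i, j = q.popleft()
            d = dist[i, j]
            if max_depth is not None and d >= max_depth:
                continue
            for ni, nj in g.neighbors(i, j, queen=True):
                if not targets[ni, nj]:
                    continue
                if dist[ni, nj] == -1:
                    dist[ni, nj] = d + 1
                    assign[ni, nj] = assign[i, j]
                    q.append((ni, nj))
                elif dist[ni, nj] == d + 1 and assign[i, j] < assign[ni, nj]:
                    assign[ni, nj] = assign[i, j]
                    q.append((ni, nj))
        return assign, dist

    coastal_seeds = [
        (i, j, int(source[i, j]))
        for i in range(g.nlat) for j in range(g.nlon)
        if source[i, j] >= 0 and raster.provinces[int(source[i, j])].coastal
    ]
    if coastal_seeds and n > 0:
        assign, dist = bfs(coastal_seeds, land, n)
        took = (assign >= 0) & land & (dist > 0)
        source[took] = assign[took]

    noncoastal_seeds = [
        (i, j, int(raster.province_id[i, j]))
        for i in range(g.nlat) for j in range(g.nlon)
        if raster.province_id[i, j] >= 0
        and not raster.provinces[int(raster.province_id[i, j])].coastal
    ]
    remaining = land & (source < 0)
    if noncoastal_seeds and remaining.any():
        assign, dist = bfs(noncoastal_seeds, np.ones(g.shape, bool), None)
        source[remaining] = assign[remaining]
    return source


def concentration_field(
    raster: ProvinceRaster,
    conc: pd.DataFrame,
    homolog: str,
    scenario: str,
    source_id: np.ndarray | None = None,
) -> np.ndarray:
    """Per-cell concentration (pg/L) for one homolog and scenario.

    ``source_id`` overrides the cell -> province map (used for the
    coastal-extension deposition raster); cells without a source get 0.
    """
    if scenario not in ("mean", "low", "high"):
        raise ValueError(f"unknown scenario {scenario!r}")
    ids = raster.province_id if source_id is None else source_id
    table = conc[conc["homolog"] == homolog].set_index("province_id")[scenario]
    out = np.zeros(ids.shape)
    for pid, value in table.items():
        if value < 0:
            raise ValueError(f"negative concentration for province {pid}")
        out[ids == pid] = value
    return out
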