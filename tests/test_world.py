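"""Gridded world: rasterization, concentration rules, masks, extension."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point, box

import pfaa_ssa as P
from pfaa_ssa.world import (
    EARTH_RADIUS_M,
    GridSpec,
    Province,
    ProvinceRaster,
    cell_medians,
    classify_cells,
    concentration_field,
    extend_coastal,
    fallback_concentrations,
    merge_sparse_provinces,
    occupied_cell_counts,
    province_adjacency,
    province_concentrations,
    rasterize_provinces,
)


class TestGridSpec:
    @pytest.mark.parametrize("nlat,nlon", [(10, 10), (24, 36), (96, 144)])
    def test_areas_sum_to_sphere(self, nlat, nlon):
        grid = GridSpec.regular(nlat, nlon)
        sphere = 4 * np.pi * EARTH_RADIUS_M**2
        assert grid.cell_areas().sum() == pytest.approx(sphere, rel=1e-9)
        assert (grid.cell_areas() > 0).all()

    def test_longitude_wraps_in_neighbors(self):
        grid = GridSpec.regular(10, 12)
        nb = grid.neighbors(5, 0)
        assert (5, 11) in nb

    def test_cell_lookup_round_trip(self):
        grid = GridSpec.regular(24, 36)
        for i, j in [(0, 0), (12, 18), (23, 35)]:
            lat, lon = grid.lat_centers[i], grid.lon_centers[j]
            assert grid.cell_of(lat, lon) == (i, j)


class TestRasterize:
    def _two_provinces(self):
        geoms = {
            0: box(-180, -90, 180, 0),
            1: box(-180, 0, 180, 90),
        }
        provinces = {
            0: Province(0, "SOUTH", False),
            1: Province(1, "NORTH", False),
        }
        return geoms, provinces

    def test_split_at_equator(self):
        geoms, provinces = self._two_provinces()
        grid = GridSpec.regular(10, 8)
        raster = rasterize_provinces(geoms, provinces, grid)
        south = raster.province_id[grid.lat_centers < 0]
        north = raster.province_id[grid.lat_centers > 0]
        assert (south == 0).all()
        assert (north == 1).all()

    def test_matches_point_in_polygon_brute_force(self):
        rng = np.random.default_rng(8)
        grid = GridSpec.regular(10, 10)
        # random vertical/horizontal partition into 4 rectangles
        lat_cut = float(rng.uniform(-40, 40))
        lon_cut = float(rng.uniform(-90, 90))
        geoms = {
            0: box(-180, -90, lon_cut, lat_cut),
            1: box(lon_cut, -90, 180, lat_cut),
            2: box(-180, lat_cut, lon_cut, 90),
            3: box(lon_cut, lat_cut, 180, 90),
        }
        provinces = {k: Province(k, f"P{k}", False) for k in geoms}
        raster = rasterize_provinces(geoms, provinces, grid)
        for i in range(grid.nlat):
            for j in range(grid.nlon):
                pt = Point(grid.lon_centers[j], grid.lat_centers[i])
                oracle = [k for k, g in geoms.items() if g.covers(pt)]
                if len(oracle) == 1:
                    assert raster.province_id[i, j] == oracle[0]

    def test_boundary_center_resolved_by_overlap(self):
        """A centre exactly on a boundary goes to the largest-overlap
        province, deterministically."""
        grid = GridSpec.regular(4, 4)  # centers at lat +-22.5, +-67.5
        geoms = {
            0: box(-180, -90, 180, 22.5),   # boundary through row-2 centers
            1: box(-180, 22.5, 180, 90),
        }
        provinces = {k: Province(k, f"P{k}", False) for k in geoms}
        raster = rasterize_provinces(geoms, provinces, grid)
        # cell rows: edges at -90,-45,0,45,90; row 2 spans 0..45, centre 22.5
        # overlap: province 0 covers 0..22.5 (half), province 1 covers 22.5..45
        # equal overlap -> smaller id wins
        assert raster.province_id[2, 0] == 0
        again = rasterize_provinces(geoms, provinces, grid)
        assert np.array_equal(raster.province_id, again.province_id)


class TestCellMedians:
    def test_singleton(self):
        grid = GridSpec.regular(10, 10)
        m = pd.DataFrame({"lat": [5.0], "lon": [5.0], "homolog": ["PFOA"], "value": [42.0]})
        out = cell_medians(m, grid)
        assert len(out) == 1
        assert out["value"].iloc[0] == 42.0

    def test_median_of_three(self):
        grid = GridSpec.regular(10, 10)
        m = pd.DataFrame(
            {"lat": [5.0] * 3, "lon": [5.0] * 3, "homolog": ["PFOA"] * 3,
             "value": [10.0, 20.0, 90.0]}
        )
        out = cell_medians(m, grid)
        assert out["value"].iloc[0] == 20.0

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(3)
        grid = GridSpec.regular(6, 6)
        lats = rng.uniform(-80, 80, 50)
        lons = rng.uniform(-170, 170, 50)
        vals = rng.uniform(1, 100, 50)
        m = pd.DataFrame({"lat": lats, "lon": lons, "homolog": "PFOA", "value": vals})
        out = cell_medians(m, grid).set_index(["i", "j"])["value"]
        cells = {}
        for lat, lon, v in zip(lats, lons, vals):
            cells.setdefault(grid.cell_of(lat, lon), []).append(v)
        for cell, vs in cells.items():
            vs = sorted(vs)
            n = len(vs)
            oracle = vs[n // 2] if n % 2 else 0.5 * (vs[n // 2 - 1] + vs[n // 2])
            assert out[cell] == pytest.approx(oracle)


def _strip_raster(counts_by_province, nlon=None, coastal=None, basins=None):
    """One province per latitude row; row r has `counts` measured cells."""
    n = len(counts_by_province)
    nlon = nlon or max(max(counts_by_province) + 1, 6)
    grid = GridSpec.regular(n, nlon)
    pid = np.repeat(np.arange(n)[:, None], nlon, axis=1)
    coastal = coastal or {}
    basins = basins or {}
    provinces = {
        k: Province(k, f"P{k}", coastal.get(k, False), basins.get(k, ""))
        for k in range(n)
    }
    raster = ProvinceRaster(grid, pid, provinces)
    rows = []
    for k, c in enumerate(counts_by_province):
        for j in range(c):
            rows.append((float(grid.lat_centers[k]), float(grid.lon_centers[j]),
                         "PFOA", 10.0 * (k + 1) + j))
    meas = pd.DataFrame(rows, columns=["lat", "lon", "homolog", "value"])
    return grid, raster, meas


class TestProvinceConcentrations:
    def test_median_and_quartiles_five_cells(self):
        grid, raster, _ = _strip_raster([5])
        med = pd.DataFrame(
            {"i": 0, "j": range(5), "homolog": "PFOA", "value": [1.0, 2.0, 3.0, 4.0, 5.0]}
        )
        out = province_concentrations(med, raster)
        row = out.iloc[0]
        assert (row["mean"], row["low"], row["high"]) == (3.0, 2.0, 4.0)

    def test_constant_cells(self):
        grid, raster, _ = _strip_raster([4])
        med = pd.DataFrame({"i": 0, "j": range(4), "homolog": "PFOA", "value": 7.0})
        row = province_concentrations(med, raster).iloc[0]
        assert row["mean"] == row["low"] == row["high"] == 7.0

    def test_quartile_convention_matches_numpy_linear(self):
        grid, raster, _ = _strip_raster([4])
        vals = [2.0, 4.0, 8.0, 16.0]
        med = pd.DataFrame({"i": 0, "j": range(4), "homolog": "PFOA", "value": vals})
        row = province_concentrations(med, raster).iloc[0]
        lo, mid, hi = np.percentile(vals, [25, 50, 75])
        assert row["mean"] == pytest.approx(mid)
        assert row["low"] == pytest.approx(lo)
        assert row["high"] == pytest.approx(hi)
        assert row["mean"] == pytest.approx(6.0)

    def test_unmerged_sparse_province_raises(self):
        grid, raster, meas = _strip_raster([2, 8])
        med = cell_medians(meas, grid)
        with pytest.raises(ValueError, match="not merged"):
            province_concentrations(med, raster)

    def test_scale_equivariance(self):
        """Multiplying all measurements by k multiplies every triple by k."""
        grid, raster, meas = _strip_raster([5, 6])
        base = province_concentrations(cell_medians(meas, grid), raster)
        scaled_meas = meas.assign(value=meas["value"] * 3.5)
        scaled = province_concentrations(cell_medians(scaled_meas, grid), raster)
        for col in ("mean", "low", "high"):
            assert np.allclose(scaled[col], base[col] * 3.5)


class TestMerging:
    def test_sparse_merges_into_richest_neighbour(self):
        grid, raster, meas = _strip_raster([2, 10, 4])
        counts = occupied_cell_counts(cell_medians(meas, grid), raster)
        merged, merges = merge_sparse_provinces(raster, counts)
        assert merges == {0: 1}
        assert (merged.province_id[0] == 1).all()
        assert 0 not in merged.provinces

    def test_all_rich_is_identity(self):
        grid, raster, meas = _strip_raster([4, 5, 6])
        counts = occupied_cell_counts(cell_medians(meas, grid), raster)
        merged, merges = merge_sparse_provinces(raster, counts)
        assert merges == {}
        assert np.array_equal(merged.province_id, raster.province_id)

    def test_chain_of_sparse_provinces_reaches_fixed_point(self):
        grid, raster, meas = _strip_raster([1, 2, 2, 9])
        counts = occupied_cell_counts(cell_medians(meas, grid), raster)
        merged, merges = merge_sparse_provinces(raster, counts)
        final_counts = occupied_cell_counts(cell_medians(meas, grid), merged)
        assert all(c == 0 or c >= 3 for c in final_counts.values())
        # merge targets resolve to surviving provinces
        assert all(t in merged.provinces for t in merges.values())

    def test_data_free_province_left_for_fallback(self):
        grid, raster, meas = _strip_raster([0, 5])
        counts = occupied_cell_counts(cell_medians(meas, grid), raster)
        merged, merges = merge_sparse_provinces(raster, counts)
        assert merges == {}
        assert 0 in merged.provinces


class TestFallback:
    def test_coastal_copies_adjacent_open_province(self):
        grid, raster, meas = _strip_raster([0, 5], coastal={0: True})
        med = cell_medians(meas, grid)
        conc = province_concentrations(med, raster)
        full = fallback_concentrations(raster, conc)
        got = full[full["province_id"] == 0].iloc[0]
        src = full[full["province_id"] == 1].iloc[0]
        assert got["provenance"] == "neighbor_fallback"
        assert (got["mean"], got["low"], got["high"]) == (
            src["mean"], src["low"], src["high"])

    def test_all_populated_is_identity(self):
        grid, raster, meas = _strip_raster([5, 6])
        conc = province_concentrations(cell_medians(meas, grid), raster)
        full = fallback_concentrations(raster, conc)
        pd.testing.assert_frame_equal(
            full.reset_index(drop=True),
            conc.sort_values(["province_id", "homolog"]).reset_index(drop=True),
        )

    def test_latitude_fallback_picks_max_overlap_atlantic(self):
        """A data-free province with no populated neighbours takes the
        Atlantic province with the largest latitude-band overlap."""
        # rows: 0-1 atlantic with data, 2 empty (adjacent to 1 -> neighbour),
        # instead build disconnected columns: left = pacific, right = atlantic
        grid = GridSpec.regular(4, 5)
        pid = np.full((4, 5), -1)
        pid[:, 0] = [0, 0, 1, 1]        # pacific provinces, no data
        pid[:, 2:4] = np.array([[2, 2], [2, 2], [3, 3], [3, 3]])  # atlantic
        provinces = {
            0: Province(0, "PAC_S", False, "pacific"),
            1: Province(1, "PAC_N", False, "pacific"),
            2: Province(2, "ATL_S", False, "atlantic"),
            3: Province(3, "ATL_N", False, "atlantic"),
        }
        raster = ProvinceRaster(grid, pid, provinces)
        rows = []
        for k, band in ((2, (0, 1)), (3, (2, 3))):
            for i in band:
                for col in (2, 3):
                    rows.append((float(grid.lat_centers[i]),
                                 float(grid.lon_centers[col]), "PFOA",
                                 100.0 * k + i + col))
        med = cell_medians(pd.DataFrame(rows, columns=["lat", "lon", "homolog", "value"]), grid)
        conc = province_concentrations(med, raster)
        full = fallback_concentrations(raster, conc)
        south = full[full["province_id"] == 0].iloc[0]
        north = full[full["province_id"] == 1].iloc[0]
        assert south["provenance"] == "latitude_fallback"
        assert south["mean"] == full[full["province_id"] == 2].iloc[0]["mean"]
        assert north["mean"] == full[full["province_id"] == 3].iloc[0]["mean"]

    def test_unreachable_province_raises(self):
        grid = GridSpec.regular(2, 2)
        pid = np.array([[0, 0], [-1, -1]])
        provinces = {0: Province(0, "LONELY", False, "pacific")}
        raster = ProvinceRaster(grid, pid, provinces)
        with pytest.raises(ValueError, match="LONELY|no data|0"):
            fallback_concentrations(raster, pd.DataFrame(
                columns=["province_id", "homolog", "mean", "low", "high", "provenance"]))


class TestClassifyCells:
    def test_three_by_three_island(self):
        """Land box covering the centre cell fully and the ring partially:
        1 inland cell, 8 coast cells."""
        grid = GridSpec.regular(9, 9)
        # centre cell spans lat 0..20? edges: -90..90 step 20 -> cell (4,4)
        lat0, lat1 = grid.lat_edges[4], grid.lat_edges[5]
        lon0, lon1 = grid.lon_edges[4], grid.lon_edges[5]
        dlat, dlon = lat1 - lat0, lon1 - lon0
        land = box(lon0 - dlon / 2, lat0 - dlat / 2, lon1 + dlon / 2, lat1 + dlat / 2)
        mask = classify_cells(grid, [land], [land.boundary])
        assert mask.land.sum() == 9
        assert mask.coast.sum() == 8
        assert mask.inland.sum() == 1
        assert mask.inland[4, 4]

    def test_all_ocean_world(self):
        grid = GridSpec.regular(4, 4)
        mask = classify_cells(grid, [], [])
        assert not mask.land.any()
        assert not mask.coast.any()
        assert not mask.inland.any()

    def test_matches_brute_force_intersection(self):
        rng = np.random.default_rng(5)
        grid = GridSpec.regular(8, 8)
        shapes = [
            box(*sorted(rng.uniform(-170, 170, 2)), *sorted(rng.uniform(-80, 80, 2)))
            for _ in range(3)
        ]
        shapes = [box(b.bounds[0], b.bounds[1], b.bounds[2], b.bounds[3]) for b in shapes]
        coasts = [s.boundary for s in shapes]
        mask = classify_cells(grid, shapes, coasts)
        for i in range(grid.nlat):
            for j in range(grid.nlon):
                cell = grid.cell_box(i, j)
                assert mask.land[i, j] == any(s.intersects(cell) for s in shapes)
                assert mask.coast[i, j] == any(c.intersects(cell) for c in coasts)

    def test_masks_partition_land(self, toy_world):
        mask = toy_world.mask
        assert not (mask.inland & mask.coast).any()
        assert ((mask.inland | (mask.coast & mask.land)) == mask.land).all()


def _bfs_oracle(grid, seeds, allowed, depth):
    """Queen-move BFS reachable set within `depth` steps."""
    from collections import deque

    dist = {s: 0 for s in seeds}
    q = deque(seeds)
    while q:
        c = q.popleft()
        if dist[c] >= depth:
            continue
        for nb in grid.neighbors(*c, queen=True):
            if allowed[nb] and nb not in dist:
                dist[nb] = dist[c] + 1
                q.append(nb)
    return {c for c, d in dist.items() if d > 0}


class TestExtendCoastal:
    def _world(self):
        grid = GridSpec.regular(9, 9)
        pid = np.full((9, 9), -1)
        land = np.zeros((9, 9), bool)
        land[3:6, 3:6] = True
        # coastal province 0 around the island, open province 1 elsewhere
        for i in range(9):
            for j in range(9):
                if land[i, j]:
                    continue
                ring = max(abs(i - 4), abs(j - 4)) == 2
                pid[i, j] = 0 if ring else 1
        provinces = {0: Province(0, "COAST", True), 1: Province(1, "OPEN", False)}
        coast = np.zeros((9, 9), bool)
        coast[3:6, 3:6] = True
        coast[4, 4] = False
        mask = P.CellMask(land=land, coast=coast)
        return grid, ProvinceRaster(grid, pid, provinces), mask

    def test_zero_depth_gives_no_coastal_on_land(self):
        grid, raster, mask = self._world()
        src = extend_coastal(raster, mask, 0)
        on_land = src[mask.land]
        assert not (on_land == 0).any()
        # remaining land took the nearest noncoastal province
        assert (on_land == 1).all()

    def test_dilation_matches_bfs_oracle(self):
        grid, raster, mask = self._world()
        src = extend_coastal(raster, mask, 2)
        seeds = [tuple(c) for c in np.argwhere(raster.province_id == 0)]
        reach = _bfs_oracle(grid, seeds, mask.land, 2)
        for i in range(9):
            for j in range(9):
                if mask.land[i, j]:
                    expected = 0 if (i, j) in reach else 1
                    assert src[i, j] == expected

    def test_equidistant_tie_breaks_to_smaller_id(self):
        grid = GridSpec.regular(3, 5)
        pid = np.full((3, 5), -1)
        pid[:, 0] = 0
        pid[:, 4] = 1
        land = np.zeros((3, 5), bool)
        land[:, 1:4] = True
        provinces = {0: Province(0, "A", True), 1: Province(1, "B", True)}
        raster = ProvinceRaster(grid, pid, provinces)
        mask = P.CellMask(land=land, coast=land.copy())
        src = extend_coastal(raster, mask, 2)
        assert (src[:, 2] == 0).all()  # equidistant middle column

    def test_ocean_cells_keep_their_province(self, prepared_world):
        world, _ = prepared_world
        src = extend_coastal(world.raster, world.mask, 2)
        ocean = ~world.mask.land
        assert np.array_equal(src[ocean], world.raster.province_id[ocean])


class TestConcentrationField:
    def test_unknown_scenario_raises(self, prepared_world):
        world, conc = prepared_world
        with pytest.raises(ValueError):
            concentration_field(world.raster, conc, "PFOA", "median")

    def test_every_ocean_cell_has_concentration(self, prepared_world):
        world, conc = prepared_world
        field = concentration_field(world.raster, conc, "PFOA", "mean")
        ocean = ~world.mask.land
        assert (field[ocean] > 0).all()
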