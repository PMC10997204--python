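"""Synthetic chamber experiments and a toy gridded world.

The generators emulate the statistical structure the analysis assumes,
so every pipeline stage is testable without external data:

* chamber experiments: per-experiment seawater concentrations drawn
  log-uniformly, SSA concentrations produced from known true EFs with
  multiplicative log-normal noise (default geometric standard
  deviation 1.5) and left-censoring at configurable detection limits;
  19 experiments by default, matching a ship-transect campaign;
* a toy world: a coarse global grid with one rectangular continent,
  ocean provinces laid out as basin x latitude-band rectangles plus
  coastal provinces ringing the continent, a salt-emission field
  peaking at mid-latitudes, and wet/dry deposition fields constructed
  so the world is closed (global salt deposition equals emission).

Every generator draws from one seeded ``numpy.random.Generator`` and
returns the ground truth alongside the fixture, so parameter-recovery
tests need no re-derivation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import box

from .chamber import ChamberExperiment
from .impactor import SizeFractionScheme
from .source_function import SourceMode, default_modes, mode_mass_fractions
from .world import (
    CellMask,
    GridSpec,
    Province,
    ProvinceRaster,
    classify_cells,
    rasterize_provinces,
)
from .fluxes import Constants, FluxField


# ---------------------------------------------------------------------------
# chamber experiments


@dataclass
class SyntheticChamberConfig:
    """Study conditions for the synthetic chamber campaign."""

    seed: int = 0
    n_experiments: int = 19
    homologs: tuple[str, ...] = ("PFOA", "L-PFOS", "B-PFOS")
    ef_range: tuple[float, float] = (1e3, 1e6)  # true EFs, log-uniform
    noise_gsd: float = 1.5  # multiplicative noise on SSA concentrations
    water_rep_gsd: float = 1.05  # triplicate cartridge scatter
    water_conc_range: tuple[float, float] = (25.0, 250.0)  # pg/L, log-uniform
    water_na_g_per_l: float = 10.8
    mdl_water: float = 1.0  # pg/L
    mdl_ssa_rel: float = 0.0  # MDL_SSA as a fraction of the median SSA signal
    diameter_power: float | None = None  # EF ~ d_p^power instead of iid draws
    scheme: SizeFractionScheme = field(default_factory=SizeFractionScheme)

    def __post_init__(self) -> None:
        if self.noise_gsd < 1 or self.water_rep_gsd < 1:
            raise ValueError("noise GSD must be >= 1")


def _fraction_salt_weights(scheme: SizeFractionScheme) -> np.ndarray:
    """Relative salt mass per impactor fraction under the default
    three-mode source function (sets realistic SSA Na+ masses)."""
    w = np.zeros(scheme.n_fractions)
    for m in default_modes():
        w += m.mass_weight * mode_mass_fractions(m, scheme)
    return w / w.sum()


def gen_chamber_experiments(
    cfg: SyntheticChamberConfig,
) -> tuple[list[ChamberExperiment], dict]:
    """Generate a chamber campaign and its ground truth.

    Returns ``(experiments, truth)`` where ``truth`` holds the true EF
    per homolog x fraction, the per-experiment true water
    concentrations, and the planted censoring counts.
    """
    rng = np.random.default_rng(cfg.seed)
    scheme = cfg.scheme
    fracs = scheme.fractions
    lo, hi = cfg.ef_range

    ef_true = pd.DataFrame(index=list(cfg.homologs), columns=fracs, dtype=float)
    for h in cfg.homologs:
        if cfg.diameter_power is None:
            ef_true.loc[h] = np.exp(
                rng.uniform(np.log(lo), np.log(hi), len(fracs))
            )
        else:
            base = np.exp(rng.uniform(np.log(lo), np.log(hi)))
            d_ref = scheme.d_p(fracs[-1])
            ef_true.loc[h] = [
                base * (scheme.d_p(f) / d_ref) ** cfg.diameter_power for f in fracs
            ]

    salt_w = _fraction_salt_weights(scheme)
    sigma = np.log(cfg.noise_gsd)
    sigma_w = np.log(cfg.water_rep_gsd)

    experiments: list[ChamberExperiment] = []
    water_true = pd.DataFrame(index=range(cfg.n_experiments), columns=list(cfg.homologs), dtype=float)
    n_water_below = 0
    n_ssa_below = 0
    lats = np.linspace(50, -50, cfg.n_experiments)
    for e in range(cfg.n_experiments):
        water_na = cfg.water_na_g_per_l
        # total Na+ collected per fraction (g, arbitrary air-volume basis)
        ssa_na = pd.Series(1e-3 * salt_w, index=fracs)

        water_rows = []
        ssa_rows = []
        mdl_ssa = pd.DataFrame(0.0, index=list(cfg.homologs), columns=fracs)
        for h in cfg.homologs:
            c_true = np.exp(
                rng.uniform(np.log(cfg.water_conc_range[0]), np.log(cfg.water_conc_range[1]))
            )
            water_true.loc[e, h] = c_true
            for rep in range(3):
                v = c_true * np.exp(rng.normal(0.0, sigma_w)) if sigma_w > 0 else c_true
                if v < cfg.mdl_water:
                    n_water_below += 1
                water_rows.append((h, rep, v, False, False))
            for f in fracs:
                signal = ef_true.at[h, f] * (c_true / water_na) * ssa_na[f]
                v = signal * np.exp(rng.normal(0.0, sigma)) if sigma > 0 else signal
                mdl = cfg.mdl_ssa_rel * ef_true.at[h, f] * (
                    np.sqrt(cfg.water_conc_range[0] * cfg.water_conc_range[1]) / water_na
                ) * ssa_na[f]
                mdl_ssa.at[h, f] = mdl
                if v < mdl:
                    n_ssa_below += 1
                ssa_rows.append((h, f, v, False, False))

        experiments.append(
            ChamberExperiment(
                exp_id=f"E{e + 1:02d}",
                water=pd.DataFrame(
                    water_rows, columns=["homolog", "replicate", "value", "censored", "substituted"]
                ),
                water_na=water_na,
                ssa=pd.DataFrame(
                    ssa_rows, columns=["homolog", "fraction", "value", "censored", "excluded"]
                ),
                ssa_na=ssa_na,
                mdl_water=pd.Series(cfg.mdl_water, index=list(cfg.homologs)),
                mdl_ssa=mdl_ssa,
                lat_start=float(lats[e]),
                lon_start=-25.0,
                lat_end=float(lats[e]),
                lon_end=-25.0,
                water_temp_c=float(25.0 - 0.3 * abs(lats[e])),
                salinity_psu=35.0,
            )
        )

    truth = {
        "ef_true": ef_true,
        "water_true": water_true,
        "n_water_below_mdl": n_water_below,
        "n_ssa_below_mdl": n_ssa_below,
    }
    return experiments, truth


# ---------------------------------------------------------------------------
# toy gridded world


@dataclass
class SyntheticWorldConfig:
    """Layout and magnitudes of the toy world.

    The continent spans ``land_lon`` x ``land_lat``; coastal provinces
    form a ring of width ``coastal_ring_deg`` around it, split at the
    equator.  Open-ocean provinces tile the rest as basin x latitude
    band rectangles (the continent's basin is "atlantic", the far side
    "pacific").  ``measured_cells`` sets how many distinct grid cells
    carry measurements per province name; provinces absent from the map
    get none (exercising the merge and fallback rules).
    """

    seed: int = 0
    nlat: int = 24
    nlon: int = 36
    land_lon: tuple[float, float] = (-60.0, -20.0)
    land_lat: tuple[float, float] = (-35.0, 35.0)
    coastal_ring_deg: float = 10.0
    lat_bands: tuple[float, ...] = (-90.0, -45.0, 0.0, 45.0, 90.0)
    species: tuple[str, ...] = ("PFOA", "PFOS")
    coastal_conc: float = 150.0  # pg/L, true value in coastal provinces
    open_conc_base: float = 25.0  # pg/L in open-ocean provinces
    measurement_gsd: float = 1.4
    measured_cells: Mapping[str, int] | None = None
    salt_total_kg: float = 3.0e12  # global annual salt emission
    wet_fraction: float = 0.6
    smoothing_passes: int = 3
    modes: tuple[SourceMode, ...] = field(default_factory=default_modes)


@dataclass
class ToyWorld:
    """Bundle of everything the flux pipeline consumes."""

    grid: GridSpec
    raster: ProvinceRaster
    mask: CellMask
    salt_emission: list[FluxField]  # one per mode
    salt_wet_dep: list[FluxField]
    salt_dry_dep: list[FluxField]
    measurements: pd.DataFrame
    truth: dict
    geoms: dict


def _province_layout(cfg: SyntheticWorldConfig):
    """Build province polygons, metadata and land/coast geometry."""
    land = box(cfg.land_lon[0], cfg.land_lat[0], cfg.land_lon[1], cfg.land_lat[1])
    ring_outer = box(
        cfg.land_lon[0] - cfg.coastal_ring_deg,
        max(cfg.land_lat[0] - cfg.coastal_ring_deg, -90.0),
        cfg.land_lon[1] + cfg.coastal_ring_deg,
        min(cfg.land_lat[1] + cfg.coastal_ring_deg, 90.0),
    )
    ring = ring_outer.difference(land)
    coast_s = ring.intersection(box(-180, -90, 180, 0))
    coast_n = ring.difference(box(-180, -90, 180, 0))

    mid = 0.5 * (cfg.land_lon[0] + cfg.land_lon[1])
    atl = box(mid - 90.0, -90.0, mid + 90.0, 90.0)

    geoms: dict[int, object] = {}
    provinces: dict[int, Province] = {}
    pid = 0
    for poly, name in ((coast_s, "COAST_S"), (coast_n, "COAST_N")):
        geoms[pid] = poly
        provinces[pid] = Province(pid, name, coastal=True, basin="atlantic")
        pid += 1
    for b in range(len(cfg.lat_bands) - 1):
        band = box(-180.0, cfg.lat_bands[b], 180.0, cfg.lat_bands[b + 1])
        for basin_name, basin_geom in (("atlantic", atl), ("pacific", atl)):
            g = band.intersection(basin_geom) if basin_name == "atlantic" else band.difference(atl)
            g = g.difference(ring_outer)
            if g.is_empty or g.area == 0:
                continue
            geoms[pid] = g
            provinces[pid] = Province(
                pid, f"{basin_name.upper()[:3]}_B{b}", coastal=False, basin=basin_name
            )
            pid += 1
    return land, geoms, provinces


def _smooth(values: np.ndarray, grid: GridSpec, passes: int) -> np.ndarray:
    """Queen-neighbour area-weighted smoothing (spreads salt onto land)."""
    areas = grid.cell_areas()
    out = values.copy()
    for _ in range(passes):
        mass = out * areas
        new = np.zeros_like(mass)
        for i in range(grid.nlat):
            for j in range(grid.nlon):
                nbrs = grid.neighbors(i, j, queen=True) + [(i, j)]
                share = mass[i, j] / len(nbrs)
                for ni, nj in nbrs:
                    new[ni, nj] += share
        out = new / areas
    return out


def gen_grid_world(cfg: SyntheticWorldConfig) -> ToyWorld:
    """Generate the toy gridded world and its ground truth."""
    rng = np.random.default_rng(cfg.seed)
    grid = GridSpec.regular(cfg.nlat, cfg.nlon)
    land, geoms, provinces = _province_layout(cfg)
    coastline = land.boundary

    mask = classify_cells(grid, [land], [coastline])
    raster = rasterize_provinces(geoms, provinces, grid, ocean_mask=~mask.land)

    # true province concentrations
    true_conc: dict[tuple[str, int], float] = {}
    for p in sorted(provinces):
        prov = provinces[p]
        for k, sp in enumerate(cfg.species):
            if prov.coastal:
                c = cfg.coastal_conc * (1.0 + 0.2 * k)
            else:
                band = int(prov.name.split("_B")[-1]) if "_B" in prov.name else 0
                c = cfg.open_conc_base * (1.0 + 0.5 * band) * (1.0 + 0.2 * k)
            true_conc[(sp, p)] = c

    # measurements: default layout exercises merge (sparse) and fallback
    # (data-free) provinces
    if cfg.measured_cells is None:
        measured: dict[int, int] = {}
        for p in sorted(provinces):
            prov = provinces[p]
            if prov.name == "COAST_S":
                measured[p] = 5
            elif prov.name == "COAST_N":
                measured[p] = 0  # neighbour fallback
            elif prov.basin == "pacific":
                measured[p] = 0  # latitude fallback
            else:
                measured[p] = 2 if prov.name.endswith("_B0") else 6
    else:
        name_to_id = {prov.name: p for p, prov in provinces.items()}
        measured = {p: 0 for p in provinces}
        for name, k in cfg.measured_cells.items():
            measured[name_to_id[name]] = k

    rows = []
    sigma = np.log(cfg.measurement_gsd)
    for p, k in sorted(measured.items()):
        cells = raster.cells_of(p)
        if not cells or k == 0:
            continue
        k = min(k, len(cells))
        chosen = [cells[i] for i in rng.choice(len(cells), size=k, replace=False)]
        for i, j in chosen:
            for sp in cfg.species:
                v = true_conc[(sp, p)] * np.exp(rng.normal(0.0, sigma))
                rows.append(
                    (float(grid.lat_centers[i]), float(grid.lon_centers[j]), sp, v, 2019)
                )
    measurements = pd.DataFrame(rows, columns=["lat", "lon", "homolog", "value", "year"])

    # salt fields: mid-latitude emission peaks, closed-world deposition
    lat = grid.lat_centers
    profile = np.exp(-(((np.abs(lat) - 40.0) / 18.0) ** 2)) + 0.05
    emis = np.tile(profile[:, None], (1, grid.nlon))
    emis[mask.land] = 0.0
    areas = grid.cell_areas()
    emis *= cfg.salt_total_kg / float((emis * areas).sum())

    dep = _smooth(emis, grid, cfg.smoothing_passes)
    dep *= cfg.salt_total_kg / float((dep * areas).sum())

    validate = sum(m.mass_weight for m in cfg.modes)
    if abs(validate - 1.0) > 1e-9:
        raise ValueError("mode mass weights must sum to 1")
    salt_emission = [
        FluxField(grid, "emission", "salt", emis * m.mass_weight, mode=k)
        for k, m in enumerate(cfg.modes)
    ]
    salt_wet = [
        FluxField(grid, "wet_dep", "salt", dep * cfg.wet_fraction * m.mass_weight, mode=k)
        for k, m in enumerate(cfg.modes)
    ]
    salt_dry = [
        FluxField(grid, "dry_dep", "salt", dep * (1 - cfg.wet_fraction) * m.mass_weight, mode=k)
        for k, m in enumerate(cfg.modes)
    ]

    truth = {
        "true_conc": true_conc,
        "measured_cells": measured,
        "salt_total_kg": cfg.salt_total_kg,
        "wet_fraction": cfg.wet_fraction,
    }
    return ToyWorld(
        grid=grid,
        raster=raster,
        mask=mask,
        salt_emission=salt_emission,
        salt_wet_dep=salt_wet,
        salt_dry_dep=salt_dry,
        measurements=measurements,
        truth=truth,
        geoms={"land": land, "coastline": coastline, "provinces": geoms},
    )
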