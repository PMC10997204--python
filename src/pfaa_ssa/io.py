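"""File formats for chamber tables and gridded rasters.

Chamber experiments travel as two CSVs (a long-form data table and an
MDL table); gridded worlds as a NetCDF raster (classic format via
xarray's scipy backend) plus CSV side tables for province metadata and
concentrations.  The synthetic generators write the same formats the
pipeline reads, so generated fixtures are drop-in inputs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .chamber import ChamberExperiment
from .synthetic import ToyWorld
from .world import CellMask, GridSpec, Province, ProvinceRaster
from .fluxes import FluxField

# ---------------------------------------------------------------------------
# chamber experiments
#
# data CSV columns:
#   exp_id, matrix (water|ssa), homolog, replicate, fraction, value,
#   censored, na  (na = water Na+ g/L on water rows, per-fraction SSA
#   Na+ on ssa rows)
# MDL CSV columns: homolog, matrix, fraction (empty for water), mdl


def experiments_to_csv(
    experiments: Sequence[ChamberExperiment], data_path: Path, mdl_path: Path
) -> None:
    rows = []
    mdl_rows = {}
    for exp in experiments:
        for _, r in exp.water.iterrows():
            rows.append(
                (exp.exp_id, "water", r["homolog"], int(r["replicate"]), "",
                 r["value"], bool(r["censored"]), exp.water_na)
            )
            mdl_rows[(r["homolog"], "water", "")] = exp.mdl_water[r["homolog"]]
        for _, r in exp.ssa.iterrows():
            f = int(r["fraction"])
            rows.append(
                (exp.exp_id, "ssa", r["homolog"], "", f,
                 r["value"], bool(r["censored"]), exp.ssa_na[f])
            )
            mdl_rows[(r["homolog"], "ssa", f)] = exp.mdl_ssa.at[r["homolog"], f]
    pd.DataFrame(
        rows,
        columns=["exp_id", "matrix", "homolog", "replicate", "fraction",
                 "value", "censored", "na"],
    ).to_csv(data_path, index=False)
    pd.DataFrame(
        [(h, m, f, v) for (h, m, f), v in sorted(mdl_rows.items(), key=str)],
        columns=["homolog", "matrix", "fraction", "mdl"],
    ).to_csv(mdl_path, index=False)


def experiments_from_csv(data_path: Path, mdl_path: Path) -> list[ChamberExperiment]:
    data = pd.read_csv(data_path)
    mdl = pd.read_csv(mdl_path)
    mdl_water = (
        mdl[mdl["matrix"] == "water"].set_index("homolog")["mdl"]
    )
    mdl_ssa_long = mdl[mdl["matrix"] == "ssa"].copy()
    mdl_ssa_long["fraction"] = mdl_ssa_long["fraction"].astype(int)
    mdl_ssa = mdl_ssa_long.pivot(index="homolog", columns="fraction", values="mdl")

    experiments = []
    for exp_id, grp in data.groupby("exp_id", sort=True):
        w = grp[grp["matrix"] == "water"]
        s = grp[grp["matrix"] == "ssa"]
        water = pd.DataFrame(
            {
                "homolog": w["homolog"].values,
                "replicate": w["replicate"].astype(int).values,
                "value": w["value"].values,
                "censored": w["censored"].astype(bool).values,
                "substituted": False,
            }
        )
        ssa = pd.DataFrame(
            {
                "homolog": s["homolog"].values,
                "fraction": s["fraction"].astype(int).values,
                "value": s["value"].values,
                "censored": s["censored"].astype(bool).values,
                "excluded": False,
            }
        )
        ssa_na = s.groupby(s["fraction"].astype(int))["na"].first()
        experiments.append(
            ChamberExperiment(
                exp_id=str(exp_id),
                water=water,
                water_na=float(w["na"].iloc[0]),
                ssa=ssa,
                ssa_na=ssa_na,
                mdl_water=mdl_water,
                mdl_ssa=mdl_ssa,
            )
        )
    return experiments


# ---------------------------------------------------------------------------
# gridded world


def save_world(world: ToyWorld, outdir: Path) -> None:
    """Write the world as a NetCDF raster + CSV/JSON side tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    g = world.grid
    data = {
        "province_id": (("lat", "lon"), world.raster.province_id),
        "land": (("lat", "lon"), world.mask.land.astype(np.int8)),
        "coast": (("lat", "lon"), world.mask.coast.astype(np.int8)),
    }
    for name, fields in (
        ("salt_emission", world.salt_emission),
        ("salt_wet_dep", world.salt_wet_dep),
        ("salt_dry_dep", world.salt_dry_dep),
    ):
        stacked = np.stack([f.values for f in fields])
        data[name] = (("mode", "lat", "lon"), stacked)
    ds = xr.Dataset(
        data,
        coords={
            "lat": g.lat_centers,
            "lon": g.lon_centers,
            "mode": np.arange(len(world.salt_emission)),
            "lat_edges": ("lat_edge", g.lat_edges),
            "lon_edges": ("lon_edge", g.lon_edges),
        },
        attrs={"salt_units": "kg m-2 yr-1"},
    )
    ds.to_netcdf(outdir / "world.nc", engine="scipy")
    pd.DataFrame(
        [
            (p.id, p.name, p.coastal, p.basin)
            for p in world.raster.provinces.values()
        ],
        columns=["province_id", "name", "coastal", "basin"],
    ).to_csv(outdir / "provinces.csv", index=False)
    world.measurements.to_csv(outdir / "measurements.csv", index=False)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(
            {
                "true_conc": {f"{sp}|{p}": v for (sp, p), v in world.truth["true_conc"].items()},
                "salt_total_kg": world.truth["salt_total_kg"],
                "wet_fraction": world.truth["wet_fraction"],
            },
            fh,
            indent=1,
        )


def load_world(outdir: Path) -> ToyWorld:
    """Read a world written by :func:`save_world` (geometry-free)."""
    outdir = Path(outdir)
    ds = xr.open_dataset(outdir / "world.nc", engine="scipy")
    grid = GridSpec(
        lat_edges=ds["lat_edges"].values, lon_edges=ds["lon_edges"].values
    )
    prov_df = pd.read_csv(outdir / "provinces.csv")
    provinces = {
        int(r.province_id): Province(
            int(r.province_id), r.name, bool(r.coastal), r.basin
        )
        for r in prov_df.itertuples()
    }
    raster = ProvinceRaster(grid, ds["province_id"].values.astype(int), provinces)
    mask = CellMask(
        land=ds["land"].values.astype(bool), coast=ds["coast"].values.astype(bool)
    )

    def fields(name: str, kind: str) -> list[FluxField]:
        arr = ds[name].values
        return [
            FluxField(grid, kind, "salt", arr[k], mode=k) for k in range(arr.shape[0])
        ]

    with open(outdir / "truth.json") as fh:
        raw = json.load(fh)
    truth = {
        "true_conc": {
            (k.split("|")[0], int(k.split("|")[1])): v
            for k, v in raw["true_conc"].items()
        },
        "salt_total_kg": raw["salt_total_kg"],
        "wet_fraction": raw["wet_fraction"],
    }
    world = ToyWorld(
        grid=grid,
        raster=raster,
        mask=mask,
        salt_emission=fields("salt_emission", "emission"),
        salt_wet_dep=fields("salt_wet_dep", "wet_dep"),
        salt_dry_dep=fields("salt_dry_dep", "dry_dep"),
        measurements=pd.read_csv(outdir / "measurements.csv"),
        truth=truth,
        geoms={},
    )
    ds.close()
    return world
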