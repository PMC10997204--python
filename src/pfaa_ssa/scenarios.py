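"""End-to-end mean/low/high scenario runs.

A scenario pairs the EF central value with the concentration median
(mean scenario) or the EF 95% CI bounds with the concentration
quartiles (low: CI-low with Q1; high: CI-high with Q3).  EF bounds and
concentration quartiles co-vary jointly; no cross-combinations are
formed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chamber import EFRecord
from .fluxes import Constants, FluxField, breakdowns, global_total, net_difference, pfaa_flux_field
from .impactor import SizeFractionScheme
from .source_function import SCENARIOS, Scenario, SourceMode, mode_ef_table
from .synthetic import ToyWorld
from .world import (
    cell_medians,
    concentration_field,
    extend_coastal,
    fallback_concentrations,
    merge_sparse_provinces,
    occupied_cell_counts,
    province_concentrations,
)


def prepare_world_concentrations(world: ToyWorld) -> tuple[ToyWorld, pd.DataFrame]:
    """Build the completed province concentration table for a world.

    Aggregates measurements to cell medians, merges sparse provinces
    into the raster, derives scenario triples and completes data-free
    provinces by the neighbour/latitude fallback rules.  Returns the
    world with the merged raster and the completed table.
    """
    med = cell_medians(world.measurements, world.grid)
    counts = occupied_cell_counts(med, world.raster)
    merged_raster, _ = merge_sparse_provinces(world.raster, counts)
    conc = province_concentrations(med, merged_raster)
    conc = fallback_concentrations(merged_raster, conc)
    new_world = ToyWorld(
        grid=world.grid,
        raster=merged_raster,
        mask=world.mask,
        salt_emission=world.salt_emission,
        salt_wet_dep=world.salt_wet_dep,
        salt_dry_dep=world.salt_dry_dep,
        measurements=world.measurements,
        truth=world.truth,
        geoms=world.geoms,
    )
    return new_world, conc

logger = logging.getLogger(__name__)


@dataclass
class ScenarioResult:
    """Totals and breakdown percentages for one scenario."""

    scenario: Scenario
    species: dict[str, dict[str, float]]
    salt_emission_total_kg: float
    salt_breakdowns: dict[str, float]
    provenance: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sp, vals in sorted(self.species.items()):
            row = {"scenario": self.scenario, "species": sp}
            row.update(vals)
            rows.append(row)
        return pd.DataFrame(rows)


def _config_hash(payload: dict) -> str:
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_scenario(
    records: Sequence[EFRecord],
    modes: Sequence[SourceMode],
    scheme: SizeFractionScheme,
    world: ToyWorld,
    conc_table: pd.DataFrame,
    scenario: Scenario,
    *,
    species: Sequence[str] | None = None,
    constants: Constants = Constants(),
    coastal_extension_cells: int = 2,
) -> ScenarioResult:
    """Run the full flux pipeline for one scenario.

    ``conc_table`` is the completed per-province scenario table
    (columns province_id, homolog, mean, low, high, provenance);
    ``records`` are the fitted size-fraction EFs.  Species present in
    both the EF records and the concentration table are processed.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    efs = mode_ef_table(records, modes, scheme)
    ef_species = {h for (h, _, _) in efs}
    conc_species = set(conc_table["homolog"].unique())
    if species is None:
        species = sorted(ef_species & conc_species)
    missing = [sp for sp in species if sp not in ef_species or sp not in conc_species]
    if missing:
        raise ValueError(f"missing upstream artifacts (EFs or concentrations) for {missing}")

    raster = world.raster
    mask = world.mask
    dep_source = extend_coastal(raster, mask, coastal_extension_cells)

    areas = world.grid.cell_areas()
    salt_emis_total = float(
        sum((f.values * areas).sum() for f in world.salt_emission)
    )
    salt_wet_total = float(sum((f.values * areas).sum() for f in world.salt_wet_dep))
    salt_dry_total = float(sum((f.values * areas).sum() for f in world.salt_dry_dep))
    coastal_cells = np.zeros(world.grid.shape, dtype=bool)
    for pid, prov in raster.provinces.items():
        if prov.coastal:
            coastal_cells |= raster.province_id == pid
    salt_coastal = float(
        sum((f.values * areas)[coastal_cells].sum() for f in world.salt_emission)
    )
    salt_submicron = float(
        sum(
            (f.values * areas).sum() * float(modes[k].cdf(1.0))
            for k, f in enumerate(world.salt_emission)
        )
    )
    salt_bd = {
        "coastal_pct": 100.0 * salt_coastal / salt_emis_total,
        "submicron_pct": 100.0 * salt_submicron / salt_emis_total,
        "dry_pct": 100.0 * salt_dry_total / (salt_wet_total + salt_dry_total),
    }

    out: dict[str, dict[str, float]] = {}
    for sp in species:
        mode_efs = {m: efs[(sp, m, scenario)] for m in range(len(modes))}
        conc_emis = concentration_field(raster, conc_table, sp, scenario)
        conc_dep = concentration_field(raster, conc_table, sp, scenario, source_id=dep_source)

        emission_by_mode = {
            k: pfaa_flux_field(
                {k: mode_efs[k]}, [world.salt_emission[k]], conc_emis,
                constants, species=sp,
            )
            for k in range(len(modes))
        }
        emission = FluxField(
            world.grid, "emission", sp,
            sum(f.values for f in emission_by_mode.values()),
        )
        wet = pfaa_flux_field(mode_efs, world.salt_wet_dep, conc_dep, constants, species=sp)
        dry = pfaa_flux_field(mode_efs, world.salt_dry_dep, conc_dep, constants, species=sp)
        total_dep = FluxField(world.grid, "wet_dep", sp, wet.values + dry.values)

        bd = breakdowns(emission_by_mode, wet, dry, mask, raster, modes, constants)
        bd["net_difference_mean_ng_m2_yr"] = float(net_difference(emission, total_dep).mean())
        bd["emission_total_t"] = global_total(emission, constants)
        bd["deposition_total_t"] = global_total(wet, constants) + global_total(dry, constants)
        out[sp] = bd
        logger.info(
            "scenario=%s species=%s emission=%.3g t/yr deposition=%.3g t/yr",
            scenario, sp, bd["emission_total_t"], bd["deposition_total_t"],
        )

    provenance = {
        "config_hash": _config_hash(
            {
                "scenario": scenario,
                "species": list(species),
                "modes": [(m.median_um, m.gsd, m.mass_weight) for m in modes],
                "coastal_extension_cells": coastal_extension_cells,
                "constants": [constants.na_fraction, constants.na_seawater_g_per_l],
            }
        ),
        "n_ef_records": len(records),
        "n_provinces": len(raster.provinces),
    }
    return ScenarioResult(
        scenario=scenario,
        species=out,
        salt_emission_total_kg=salt_emis_total,
        salt_breakdowns=salt_bd,
        provenance=provenance,
    )


def run_all_scenarios(
    records: Sequence[EFRecord],
    modes: Sequence[SourceMode],
    scheme: SizeFractionScheme,
    world: ToyWorld,
    conc_table: pd.DataFrame,
    **kwargs,
) -> dict[Scenario, ScenarioResult]:
    """Run the mean, low and high scenarios; returns one result each."""
    return {
        sc: run_scenario(records, modes, scheme, world, conc_table, sc, **kwargs)
        for sc in SCENARIOS
    }


def results_frame(results: Mapping[Scenario, ScenarioResult]) -> pd.DataFrame:
    """Consolidated results table across scenarios."""
    return pd.concat([r.to_frame() for r in results.values()], ignore_index=True)
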