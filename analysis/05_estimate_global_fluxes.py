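"""Estimate global PFAA emission and deposition under three scenarios.

Runs the flux pipeline (EF x Na+ flux x concentration/Na+) on the toy
world for the mean, low and high scenarios; writes the consolidated
summary table (results/flux_summary.csv) and the per-cell
deposition-minus-emission difference field for the mean scenario
(results/net_difference_<species>.csv, positive = net deposition).
"""

from pathlib import Path

import numpy as np
import pandas as pd

import pfaa_ssa as P
from pfaa_ssa import io as pio
from pfaa_ssa.chamber import records_from_frame
from pfaa_ssa.fluxes import FluxField, net_difference, pfaa_flux_field
from pfaa_ssa.scenarios import (
    prepare_world_concentrations,
    results_frame,
    run_all_scenarios,
)
from pfaa_ssa.source_function import default_modes, mode_ef_table
from pfaa_ssa.world import concentration_field, extend_coastal

base = Path(__file__).resolve().parent.parent / "results"
scheme = P.SizeFractionScheme()
modes = default_modes()

world = pio.load_world(base / "inputs" / "world")
world, conc = prepare_world_concentrations(world)
records = records_from_frame(pd.read_csv(base / "ef_records.csv"))

results = run_all_scenarios(records, modes, scheme, world, conc)
summary = results_frame(results)
summary.to_csv(base / "flux_summary.csv", index=False)

for sc in ("mean", "low", "high"):
    for sp, vals in sorted(results[sc].species.items()):
        print(f"{sc:>5} {sp}: emission {vals['emission_total_t']:8.1f} t/yr, "
              f"deposition {vals['deposition_total_t']:8.1f} t/yr, "
              f"coastal {vals['coastal_pct']:.0f}%, "
              f"submicron {vals['submicron_pct']:.0f}%, "
              f"dry dep {vals['dry_pct']:.0f}%")
salt = results["mean"].salt_breakdowns
print(f"      salt: emission {results['mean'].salt_emission_total_kg:.2e} kg/yr, "
      f"coastal {salt['coastal_pct']:.0f}%, submicron {salt['submicron_pct']:.1f}%, "
      f"dry dep {salt['dry_pct']:.0f}%")

# mean-scenario net difference fields (positive = net deposition)
efs = mode_ef_table(records, modes, scheme)
dep_source = extend_coastal(world.raster, world.mask, 2)
for sp in sorted(results["mean"].species):
    mode_efs = {m: efs[(sp, m, "mean")] for m in range(len(modes))}
    c_em = concentration_field(world.raster, conc, sp, "mean")
    c_dep = concentration_field(world.raster, conc, sp, "mean", source_id=dep_source)
    em = pfaa_flux_field(mode_efs, world.salt_emission, c_em, species=sp)
    wet = pfaa_flux_field(mode_efs, world.salt_wet_dep, c_dep, species=sp)
    dry = pfaa_flux_field(mode_efs, world.salt_dry_dep, c_dep, species=sp)
    dep = FluxField(world.grid, "wet_dep", sp, wet.values + dry.values)
    diff = net_difference(em, dep)
    pd.DataFrame(diff, index=world.grid.lat_centers,
                 columns=world.grid.lon_centers).to_csv(
        base / f"net_difference_{sp}.csv")
    frac_net_dep = float((diff > 0).mean())
    print(f"{sp}: net-deposition cells {frac_net_dep:.0%} "
          f"(mean difference {diff.mean():+.1f} ng/m2/yr)")
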