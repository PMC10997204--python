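# pfaa-ssa

Enrichment of perfluoroalkyl acids (PFAAs) in sea spray aerosol (SSA) and
the resulting secondary emission of PFAAs from the oceans.

PFAAs — perfluoroalkyl carboxylic acids such as PFOA and perfluoroalkane
sulfonic acids such as PFOS — are highly persistent pollutants that
accumulate in the surface ocean. Bursting bubbles scavenge them from
seawater and eject them into the air on sea spray, strongly enriched
relative to the water. This package implements the full estimation chain
for that pathway, aimed at environmental chemists and contaminant-fate
modellers:

1. **Enrichment factors from chamber experiments** (`pfaa_ssa.chamber`).
   The enrichment factor of a homolog in an aerosol size fraction is

       EF = ([PFAA]_SSA / [Na+]_SSA) / ([PFAA]_seawater / [Na+]_seawater)

   with sodium as the conservative sea-salt tracer. Across a campaign of
   chamber runs the mean EF is the slope of the through-origin total
   least squares regression of the SSA ratio on the seawater ratio when
   the correlation is significant (p < 0.05), and the geometric mean of
   per-experiment EFs otherwise. Water values below the method detection
   limit (MDL) are substituted by the MDL; SSA values below the MDL are
   excluded; homologs detected in ≤ 30 % of water samples are not
   estimated.
2. **Projection onto a source function** (`pfaa_ssa.source_function`).
   The emitted salt mass-size distribution is a sum of three log-normal
   modes (median dry diameters 0.095, 0.6, 1.5 μm); each mode's EF is the
   mass-weighted mean of the size-fraction EFs it overlaps.
3. **A gridded ocean world** (`pfaa_ssa.world`). Seawater concentrations
   are organised by biogeochemical ocean province: grid-cell medians →
   per-province median/Q1/Q3 scenario triples, with sparse provinces
   (< 3 occupied cells) merged into their richest neighbour and data-free
   provinces completed from adjacent noncoastal provinces or the Atlantic
   province at matching latitude. Land/coast/inland cells are classified
   by intersecting grid cells with land and coastline geometry.
4. **Flux estimation** (`pfaa_ssa.fluxes`, `pfaa_ssa.scenarios`). The
   central scaling relation converts gridded salt fluxes (emission, or
   wet/dry deposition) into PFAA fluxes:

       Flux_PFAA = EF × Flux_Na+ × [PFAA]_seawater / [Na+]_seawater

   with Flux_Na+ = 0.307 × Flux_salt and [Na+]_seawater = 10.8 g/L; salt
   in kg m⁻² yr⁻¹ and concentrations in pg/L give PFAA fluxes in
   ng m⁻² yr⁻¹ with no extra constants. Scenarios pair EF CI bounds with
   concentration quartiles (mean/median, low/Q1, high/Q3). For
   deposition on land, coastal-province concentrations are extended two
   grid cells inland; remaining inland cells use the nearest noncoastal
   province.

Because no measurement campaign ships with the package, a first-class
synthetic-data module (`pfaa_ssa.synthetic`) generates chamber campaigns
with known true EFs and a closed toy world (global salt deposition equals
emission) so every stage is testable end to end.

## Worked example

The analysis is organised as numbered drivers over the library:

```sh
python analysis/01_simulate_inputs.py
python analysis/02_fit_enrichment_factors.py
python analysis/03_project_modes.py
python analysis/04_build_world_concentrations.py
python analysis/05_estimate_global_fluxes.py
```

which prints, for the default seed:

```
chamber campaign: 19 experiments, 24 true EFs written
toy world: 24x36 grid, 10 provinces (2 coastal), 50 seawater measurements
16 EF records fitted (12 slope, 4 gmean)
EF range 3.9e+03 - 9.55e+05
salt mass below 1 um: 26.5%
provinces: 10 before merging, 9 after (1 sparse provinces absorbed)
 mean PFOA: emission    830.2 t/yr, deposition    838.4 t/yr, coastal 10%, submicron 21%, dry dep 40%
 mean PFOS: emission   1086.6 t/yr, deposition   1098.8 t/yr, coastal 10%, submicron 24%, dry dep 40%
```

Reading the output: the 19 synthetic chamber runs yield EFs of ~10³–10⁶
(PFAAs are enriched thousands- to a million-fold in spray relative to
water). On the toy world those EFs, the province concentration scenarios
and the 3.0 × 10¹² kg/yr salt emission produce global PFAA emission and
deposition totals in t/yr, with deposition slightly above emission
because concentrations are applied at the deposition location (the origin
of deposited spray is untracked). The percentage rows break totals down
by coastal provinces, submicron particles, and wet vs dry deposition.
The same stages are scriptable via the `pfaa-ssa` CLI (`simulate`,
`ef-fit`, `modes`, `estimate`, `run`).

Toy-world magnitudes depend on the synthetic province concentrations and
province layout; they are internally consistent but not estimates for the
real ocean. Global estimates require the original Earth-system-model salt
fields, measured EF tables and province concentration tables, supplied in
the same file formats (`pfaa_ssa.io`).

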