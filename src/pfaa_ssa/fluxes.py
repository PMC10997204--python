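"""Gridded PFAA emission and deposition fluxes from sea spray.

The central scaling relation converts a sea-salt flux into a PFAA flux
through the enrichment factor and the sodium-normalised seawater
concentration:

    Flux_PFAA = EF * Flux_Na+ * [PFAA]_seawater / [Na+]_seawater

with Flux_Na+ = 0.307 * Flux_salt (sodium's share of dry sea-salt
mass) and [Na+]_seawater = 10.8 g/L.  With salt fluxes in
kg m^-2 yr^-1 and concentrations in pg/L the unit algebra
(kg * pg / g = ng) makes the PFAA flux ng m^-2 yr^-1 with no extra
constant.  Deposition fluxes use the same relation with wet/dry salt
deposition fields and the deposition concentration raster; since the
concentration is applied at the deposition location, the origin of the
deposited salt is untracked and global deposition can slightly exceed
emission.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np

from .source_function import SourceMode, validate_modes
from .world import CellMask, GridSpec, ProvinceRaster

Kind = Literal["emission", "wet_dep", "dry_dep"]

#: Day count per month in a no-leap model calendar.
DAYS_PER_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31], float)


@dataclass(frozen=True)
class Constants:
    """Physical constants and unit conversions for the flux scaling."""

    na_fraction: float = 0.307  # Na+ share of dry sea-salt mass
    na_seawater_g_per_l: float = 10.8
    seconds_per_year: float = 365.0 * 86400.0  # no-leap model calendar
    ng_to_tonnes: float = 1e-15

    def __post_init__(self) -> None:
        if not 0 < self.na_fraction < 1:
            raise ValueError("Na+ fraction must lie in (0, 1)")
        if self.na_seawater_g_per_l <= 0:
            raise ValueError("seawater Na+ must be > 0")


@dataclass
class FluxField:
    """A gridded flux: sea salt in kg m^-2 yr^-1, PFAA in ng m^-2 yr^-1."""

    grid: GridSpec
    kind: Kind
    species: str  # "salt" or a homolog id
    values: np.ndarray
    mode: int | None = None

    @property
    def units(self) -> str:
        return "kg m-2 yr-1" if self.species == "salt" else "ng m-2 yr-1"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.shape != self.grid.shape:
            raise ValueError("field shape does not match grid")
        if (self.values < 0).any():
            raise ValueError("flux values must be >= 0")


def annualize(
    monthly: np.ndarray, constants: Constants = Constants()
) -> np.ndarray:
    """Day-weighted annual mean flux from monthly means.

    ``monthly`` has shape (12, nlat, nlon) or (nyears, 12, nlat, nlon)
    in kg m^-2 s^-1; the result is the multi-year mean annual flux in
    kg m^-2 yr^-1.
    """
    monthly = np.asarray(monthly, float)
    if monthly.ndim == 3:
        monthly = monthly[None]
    if monthly.ndim != 4 or monthly.shape[1] != 12:
        raise ValueError("expected 12 monthly fields per year")
    w = DAYS_PER_MONTH / DAYS_PER_MONTH.sum()
    annual = np.tensordot(w, monthly, axes=(0, 1))  # (nyears, nlat, nlon)
    return annual.mean(axis=0) * constants.seconds_per_year


def _check_grids(*fields: FluxField) -> GridSpec:
    grid = fields[0].grid
    for f in fields[1:]:
        if f.grid.shape != grid.shape:
            raise ValueError("flux fields are on different grids")
    return grid


def split_by_modes(
    salt: FluxField, modes: Sequence[SourceMode]
) -> list[FluxField]:
    """Split a total salt field across modes by their mass weights."""
    validate_modes(modes)
    return [
        FluxField(salt.grid, salt.kind, "salt", salt.values * m.mass_weight, mode=k)
        for k, m in enumerate(modes)
    ]


def pfaa_flux_field(
    mode_efs: Mapping[int, float],
    salt_fields: Sequence[FluxField],
    conc_pg_per_l: np.ndarray,
    constants: Constants = Constants(),
    *,
    species: str,
) -> FluxField:
    """PFAA flux (ng m^-2 yr^-1) summed over source modes.

    ``mode_efs`` maps mode index -> EF for the chosen scenario;
    ``salt_fields`` holds one salt flux per mode (kg m^-2 yr^-1) of a
    single kind; ``conc_pg_per_l`` is the per-cell seawater (or
    deposition-source) concentration.
    """
    grid = _check_grids(*salt_fields)
    conc = np.asarray(conc_pg_per_l, float)
    if conc.shape != grid.shape:
        raise ValueError("concentration raster does not match the flux grid")
    if (conc < 0).any():
        raise ValueError("negative concentration")
    kinds = {f.kind for f in salt_fields}
    if len(kinds) != 1:
        raise ValueError("salt fields mix flux kinds")
    total = np.zeros(grid.shape)
    for f in salt_fields:
        if f.mode is None or f.mode not in mode_efs:
            raise ValueError(f"no EF for mode {f.mode}")
        na_flux = constants.na_fraction * f.values
        total += mode_efs[f.mode] * na_flux * conc / constants.na_seawater_g_per_l
    return FluxField(grid, salt_fields[0].kind, species, total)


def deposition_flux_fields(
    mode_efs: Mapping[int, float],
    wet_salt: Sequence[FluxField],
    dry_salt: Sequence[FluxField],
    dep_conc_pg_per_l: np.ndarray,
    constants: Constants = Constants(),
    *,
    species: str,
) -> tuple[FluxField, FluxField]:
    """Wet and dry PFAA deposition fields (same scaling as emission)."""
    wet = pfaa_flux_field(mode_efs, wet_salt, dep_conc_pg_per_l, constants, species=species)
    dry = pfaa_flux_field(mode_efs, dry_salt, dep_conc_pg_per_l, constants, species=species)
    return wet, dry


def global_total(field: FluxField, constants: Constants = Constants()) -> float:
    """Area-integrated total in t/yr (PFAA) or kg/yr (salt)."""
    areas = field.grid.cell_areas()
    total = float((field.values * areas).sum())
    if field.species == "salt":
        return total  # kg/yr
    return total * constants.ng_to_tonnes


def net_difference(emission: FluxField, deposition: FluxField) -> np.ndarray:
    """Per-cell deposition minus emission (positive = net deposition)."""
    if emission.grid.shape != deposition.grid.shape:
        raise ValueError("fields are on different grids")
    return deposition.values - emission.values


def breakdowns(
    emission_by_mode: Mapping[int, FluxField],
    wet_dep: FluxField,
    dry_dep: FluxField,
    mask: CellMask,
    raster: ProvinceRaster,
    modes: Sequence[SourceMode],
    constants: Constants = Constants(),
) -> dict[str, float]:
    """Table-1-style percentages for one species and scenario.

    * coastal % of emission: share emitted from cells of coastal
      provinces;
    * submicron % of emission: per-mode emission totals weighted by
      each mode's mass share below 1 um;
    * inland / coastline % of total deposition over the cell masks;
    * dry % of total deposition.
    """
    areas = emission_by_mode[next(iter(emission_by_mode))].grid.cell_areas()
    emis_total = sum(
        float((f.values * areas).sum()) for f in emission_by_mode.values()
    )
    coastal_cells = np.zeros(mask.land.shape, dtype=bool)
    for pid, prov in raster.provinces.items():
        if prov.coastal:
            coastal_cells |= raster.province_id == pid
    coastal = sum(
        float((f.values * areas)[coastal_cells].sum())
        for f in emission_by_mode.values()
    )
    submicron = sum(
        float((emission_by_mode[k].values * areas).sum()) * float(modes[k].cdf(1.0))
        for k in sorted(emission_by_mode)
    )

    dep_total_field = wet_dep.values + dry_dep.values
    dep_total = float((dep_total_field * areas).sum())
    inland = float((dep_total_field * areas)[mask.inland].sum())
    coastline = float((dep_total_field * areas)[mask.coast].sum())
    dry = float((dry_dep.values * areas).sum())

    def pct(num: float, den: float) -> float:
        return 100.0 * num / den if den > 0 else 0.0

    return {
        "coastal_pct": pct(coastal, emis_total),
        "submicron_pct": pct(submicron, emis_total),
        "inland_pct": pct(inland, dep_total),
        "coastline_pct": pct(coastline, dep_total),
        "dry_pct": pct(dry, dep_total),
        "emission_total_t": emis_total * constants.ng_to_tonnes,
        "deposition_total_t": dep_total * constants.ng_to_tonnes,
    }
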