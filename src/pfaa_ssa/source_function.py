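"""Three-mode log-normal sea spray aerosol source function.

The emitted sea-salt mass-size distribution is represented as a sum of
three log-normal modes with median dry diameters 0.095, 0.6 and 1.5 um.
Each mode carries a geometric standard deviation and a fraction of the
total emitted salt mass.  Size-fraction EFs from the chamber
experiments are projected onto the modes by weighting each fraction's
EF with the share of the mode's mass that falls inside the fraction's
diameter bounds.

The mode GSDs and mass weights are configuration parameters: the
chamber-derived source function publication gives GSDs of 2.10, 1.72
and 1.60 for the three modes; the default mass weights put most of the
salt mass in the coarse mode, as observed for sea spray.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import stats

from .chamber import EFRecord
from .impactor import SizeFractionScheme

Scenario = Literal["mean", "low", "high"]
SCENARIOS: tuple[Scenario, ...] = ("mean", "low", "high")


@dataclass(frozen=True)
class SourceMode:
    """One log-normal mode of the SSA mass-size distribution."""

    median_um: float
    gsd: float
    mass_weight: float

    def __post_init__(self) -> None:
        if self.median_um <= 0:
            raise ValueError("median diameter must be > 0")
        if self.gsd <= 1:
            raise ValueError("GSD must be > 1")
        if not 0 <= self.mass_weight <= 1:
            raise ValueError("mass weight must lie in [0, 1]")

    def cdf(self, d_um: float | np.ndarray) -> float | np.ndarray:
        """Mass fraction of this mode below diameter ``d_um``."""
        dist = stats.lognorm(s=np.log(self.gsd), scale=self.median_um)
        return dist.cdf(d_um)


def default_modes() -> tuple[SourceMode, SourceMode, SourceMode]:
    """The three-mode source function with default GSDs and weights."""
    return (
        SourceMode(0.095, 2.10, 0.01),
        SourceMode(0.6, 1.72, 0.10),
        SourceMode(1.5, 1.60, 0.89),
    )


def validate_modes(modes: Sequence[SourceMode]) -> None:
    total = sum(m.mass_weight for m in modes)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"mode mass weights must sum to 1, got {total}")


@dataclass(frozen=True)
class ModeEF:
    """EF of a homolog aggregated to one source mode and scenario."""

    homolog: str
    mode: int
    scenario: Scenario
    ef: float

    def __post_init__(self) -> None:
        if not self.ef > 0:
            raise ValueError("mode EF must be positive")


def mode_mass_fractions(
    mode: SourceMode, scheme: SizeFractionScheme
) -> np.ndarray:
    """Share of a mode's emitted mass in each impactor size fraction.

    Integrates the mode's log-normal mass-size distribution between
    each fraction's diameter bounds (the outermost fractions extend to
    0 and +inf), normalised by the total mode mass.
    """
    weights = np.empty(scheme.n_fractions)
    for f in scheme.fractions:
        lo, hi = scheme.integration_bounds(f)
        if lo >= hi:
            raise ValueError(f"degenerate bounds for fraction {f}")
        weights[f - 1] = mode.cdf(hi) - mode.cdf(lo)
    return weights


def _scenario_value(record: EFRecord, scenario: Scenario) -> float:
    if scenario == "mean":
        return record.ef_mean
    if scenario == "low":
        return record.ci_low
    if scenario == "high":
        return record.ci_high
    raise ValueError(f"unknown scenario {scenario!r}")


def mode_ef(
    records: Mapping[int, EFRecord],
    weights: np.ndarray,
    scenario: Scenario,
    *,
    homolog: str | None = None,
    mode_index: int = 0,
    min_weight: float = 0.01,
) -> ModeEF:
    """Project per-fraction EFs onto one mode.

    The mode EF is the mass-weighted mean of the per-fraction EFs,
    taking each fraction's mean EF in the mean scenario and its 95% CI
    bounds in the low/high scenarios.  Weights are renormalised over
    the fractions that have an EF; a missing fraction carrying more
    than ``min_weight`` of the mode's mass is an error.
    """
    covered = {
        f: r for f, r in records.items()
        if r.method != "not_calculated" and np.isfinite(_scenario_value(r, scenario))
    }
    for f, w in enumerate(weights, start=1):
        if w > min_weight and f not in covered:
            raise ValueError(
                f"fraction {f} carries weight {w:.3f} but has no EF"
            )
    w_cov = np.array([weights[f - 1] for f in covered])
    if w_cov.sum() <= 0:
        raise ValueError("no covered fraction with positive weight")
    vals = np.array([_scenario_value(r, scenario) for r in covered.values()])
    ef = float(vals @ (w_cov / w_cov.sum()))
    hid = homolog if homolog is not None else next(iter(records.values())).homolog
    return ModeEF(hid, mode_index, scenario, ef)


def mode_ef_table(
    records: Sequence[EFRecord],
    modes: Sequence[SourceMode],
    scheme: SizeFractionScheme,
) -> dict[tuple[str, int, Scenario], float]:
    """All mode EFs: (homolog, mode index, scenario) -> EF."""
    validate_modes(modes)
    by_homolog: dict[str, dict[int, EFRecord]] = {}
    for r in records:
        by_homolog.setdefault(r.homolog, {})[r.fraction] = r
    out: dict[tuple[str, int, Scenario], float] = {}
    for h, recs in sorted(by_homolog.items()):
        if all(r.method == "not_calculated" for r in recs.values()):
            continue
        for m, mode in enumerate(modes):
            w = mode_mass_fractions(mode, scheme)
            for sc in SCENARIOS:
                out[(h, m, sc)] = mode_ef(
                    recs, w, sc, homolog=h, mode_index=m
                ).ef
    return out


def submicron_mass_share(
    modes: Sequence[SourceMode], cutoff_um: float = 1.0
) -> float:
    """Fraction of total emitted salt mass below ``cutoff_um``."""
    validate_modes(modes)
    return float(sum(m.mass_weight * m.cdf(cutoff_um) for m in modes))
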