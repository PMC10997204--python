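"""Cascade-impactor size-fraction scheme.

The chamber headspace aerosol is sampled with a 14-stage cascade
impactor whose stage cutoff diameters (d50, the aerodynamic diameter at
50% collection efficiency) span 0.015-9.91 um.  After sampling, stages
1-6 are pooled into one fraction and stages 7-8 into another; the
remaining six stages are kept individually, yielding eight size
fractions.  Stage k collects particles between its own d50 and the next
stage's d50; the top stage collects everything above its d50 up to the
inlet cut.

Aerodynamic diameters are treated as dry diameters (the sampling line
dries the aerosol below 40% RH), so no shape-factor conversion is
applied when fractions are matched to the source-function modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Nominal stage d50 cutoffs (um) for the 14-stage low-pressure impactor.
DEFAULT_STAGE_CUTOFFS: tuple[float, ...] = (
    0.015, 0.029, 0.055, 0.092, 0.15, 0.25, 0.38,
    0.60, 0.94, 1.57, 2.38, 3.59, 5.29, 9.91,
)

#: Stage pooling: stages 1-6 -> fraction 1, stages 7-8 -> fraction 2,
#: stages 9-14 individually -> fractions 3-8.  1-based stage numbers.
DEFAULT_POOLING: dict[int, int] = {
    1: 1, 2: 1, 3: 1, 4: 1, 5: 1, 6: 1,
    7: 2, 8: 2,
    9: 3, 10: 4, 11: 5, 12: 6, 13: 7, 14: 8,
}

#: Upper collection bound (um) of the top stage, set by the inlet.
DEFAULT_INLET_CUT = 15.0


@dataclass(frozen=True)
class SizeFractionScheme:
    """Maps impactor stages to pooled size fractions.

    ``bounds`` holds each fraction's lower/upper aerodynamic-diameter
    bounds in um; ``d_p`` is the representative diameter of a fraction,
    the geometric mean of its bounds.
    """

    stage_cutoffs: tuple[float, ...] = DEFAULT_STAGE_CUTOFFS
    pooling: dict[int, int] = field(default_factory=lambda: dict(DEFAULT_POOLING))
    inlet_cut: float = DEFAULT_INLET_CUT

    def __post_init__(self) -> None:
        cuts = np.asarray(self.stage_cutoffs, dtype=float)
        if not np.all(np.diff(cuts) > 0):
            raise ValueError("stage cutoffs must be strictly increasing")
        if sorted(self.pooling) != list(range(1, len(cuts) + 1)):
            raise ValueError("pooling map must cover every stage exactly once")
        fracs = sorted(set(self.pooling.values()))
        if fracs != list(range(1, len(fracs) + 1)):
            raise ValueError("fractions must be numbered contiguously from 1")
        # fractions must pool contiguous stages
        for f in fracs:
            stages = sorted(s for s, v in self.pooling.items() if v == f)
            if stages != list(range(stages[0], stages[-1] + 1)):
                raise ValueError(f"fraction {f} pools non-contiguous stages")

    @property
    def n_fractions(self) -> int:
        return len(set(self.pooling.values()))

    @property
    def fractions(self) -> list[int]:
        return list(range(1, self.n_fractions + 1))

    def bounds(self, fraction: int) -> tuple[float, float]:
        """Lower/upper collection diameters (um) of a pooled fraction."""
        stages = sorted(s for s, f in self.pooling.items() if f == fraction)
        if not stages:
            raise KeyError(f"no such fraction: {fraction}")
        lo = self.stage_cutoffs[stages[0] - 1]
        top = stages[-1]
        if top == len(self.stage_cutoffs):
            hi = self.inlet_cut
        else:
            hi = self.stage_cutoffs[top]
        if lo >= hi:
            raise ValueError(f"degenerate bounds for fraction {fraction}")
        return lo, hi

    def integration_bounds(self, fraction: int) -> tuple[float, float]:
        """Bounds for source-function integration.

        The outermost fractions extend to 0 and +inf so the eight
        fractions tile the full diameter axis.
        """
        lo, hi = self.bounds(fraction)
        if fraction == 1:
            lo = 0.0
        if fraction == self.n_fractions:
            hi = np.inf
        return lo, hi

    def d_p(self, fraction: int) -> float:
        """Representative diameter (um): geometric mean of the bounds."""
        lo, hi = self.bounds(fraction)
        return float(np.sqrt(lo * hi))

    def supermicron_fractions(self) -> list[int]:
        """Fractions whose representative diameter exceeds 1 um."""
        return [f for f in self.fractions if self.d_p(f) > 1.0]
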