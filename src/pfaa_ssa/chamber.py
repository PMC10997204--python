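"""Enrichment-factor (EF) estimation from sea-spray chamber experiments.

The EF of a PFAA in a given aerosol size fraction is the ratio of its
sodium-normalised concentration in sea spray aerosol (SSA) to its
sodium-normalised concentration in the seawater that generated the
spray:

    EF = ([PFAA]_SSA / [Na+]_SSA) / ([PFAA]_seawater / [Na+]_seawater)

Sodium acts as a conservative sea-salt tracer, so the sampled air
volume cancels and the EF is dimensionless.

Estimation follows three rules:

* left-censored data: water concentrations below the method detection
  limit (MDL) are substituted by the MDL; SSA samples below their MDL
  are excluded from all regressions and per-experiment EFs;
* a detection-frequency gate: EFs are only estimated for homologs
  detected in strictly more than 30% of the chamber water samples;
* estimator selection: if the correlation between the water and SSA
  normalised concentrations across experiments is significant
  (two-sided p < 0.05) the EF is the slope of a through-origin total
  least squares regression; otherwise it is the geometric mean of the
  per-experiment EFs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .impactor import SizeFractionScheme

logger = logging.getLogger(__name__)

Method = Literal["slope", "gmean", "not_calculated"]


@dataclass
class ChamberExperiment:
    """One ~30-hour chamber run.

    ``water`` is a long-form table with columns
    ``homolog, replicate, value, censored, substituted`` (pg/L, one row
    per SPE cartridge); ``ssa`` has columns
    ``homolog, fraction, value, censored, excluded`` (mass per sampled
    air volume); ``ssa_na`` maps fraction -> Na+ mass on the same
    air-volume basis; MDL tables use the same units as the data they
    censor.
    """

    exp_id: str
    water: pd.DataFrame
    water_na: float  # g/L
    ssa: pd.DataFrame
    ssa_na: pd.Series  # indexed by fraction
    mdl_water: pd.Series  # indexed by homolog, pg/L
    mdl_ssa: pd.DataFrame  # index homolog, columns fraction
    lat_start: float = np.nan
    lon_start: float = np.nan
    lat_end: float = np.nan
    lon_end: float = np.nan
    water_temp_c: float = np.nan
    salinity_psu: float = np.nan

    def __post_init__(self) -> None:
        if self.water_na <= 0:
            raise ValueError(f"{self.exp_id}: water Na+ must be > 0")
        if (self.ssa_na <= 0).any():
            raise ValueError(f"{self.exp_id}: SSA Na+ must be > 0 in every fraction")
        for df, name in ((self.water, "water"), (self.ssa, "ssa")):
            if (df["value"] < 0).any():
                raise ValueError(f"{self.exp_id}: negative {name} concentration")


@dataclass
class EFRecord:
    """EF estimate for one homolog x size fraction."""

    homolog: str
    fraction: int
    method: Method
    ef_mean: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    pearson_r: float = np.nan
    p_value: float = np.nan
    n_points: int = 0
    per_experiment_efs: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.method != "not_calculated":
            if not self.ef_mean > 0:
                raise ValueError("EF must be positive")
            if not (self.ci_low <= self.ef_mean <= self.ci_high):
                raise ValueError("CI must bracket the mean EF")


def substitute_censored(exp: ChamberExperiment) -> ChamberExperiment:
    """Apply the censoring rules to one experiment.

    Water values below MDL_water are replaced by MDL_water and flagged
    ``substituted``; SSA values below MDL_SSA are flagged ``excluded``
    (they are dropped from regressions and per-experiment EFs, not set
    to zero).  Uncensored values pass through unchanged.
    """
    water = exp.water.copy()
    ssa = exp.ssa.copy()

    for i, row in water.iterrows():
        mdl = exp.mdl_water.get(row["homolog"], np.nan)
        below = bool(row.get("censored", False)) or (
            np.isfinite(mdl) and row["value"] < mdl
        )
        if below:
            if not np.isfinite(mdl):
                raise ValueError(
                    f"{exp.exp_id}: censored water value for {row['homolog']} "
                    "has no MDL_water"
                )
            water.at[i, "value"] = mdl
            water.at[i, "substituted"] = True
            water.at[i, "censored"] = True
    if "substituted" not in water:
        water["substituted"] = False
    water["substituted"] = water["substituted"].fillna(False).astype(bool)

    for i, row in ssa.iterrows():
        try:
            mdl = exp.mdl_ssa.at[row["homolog"], row["fraction"]]
        except KeyError:
            mdl = np.nan
        below = bool(row.get("censored", False)) or (
            np.isfinite(mdl) and row["value"] < mdl
        )
        if below:
            if not np.isfinite(mdl):
                raise ValueError(
                    f"{exp.exp_id}: censored SSA value for {row['homolog']} "
                    f"fraction {row['fraction']} has no MDL_SSA"
                )
            ssa.at[i, "excluded"] = True
            ssa.at[i, "censored"] = True
    if "excluded" not in ssa:
        ssa["excluded"] = False
    ssa["excluded"] = ssa["excluded"].fillna(False).astype(bool)

    return replace(exp, water=water, ssa=ssa)


def detection_frequency_gate(
    detected: dict[str, int], total: dict[str, int], threshold: float = 0.30
) -> set[str]:
    """Homologs whose water detection frequency strictly exceeds ``threshold``.

    ``detected`` and ``total`` count water samples per homolog.  The
    inequality is strict: a homolog detected in exactly 30% of samples
    is not eligible.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    eligible: set[str] = set()
    for h, n_tot in total.items():
        if n_tot == 0:
            raise ValueError(f"zero water samples for {h}")
        if detected.get(h, 0) / n_tot > threshold:
            eligible.add(h)
    return eligible


def water_detection_counts(
    experiments: Sequence[ChamberExperiment],
) -> tuple[dict[str, int], dict[str, int]]:
    """Count detected (uncensored) and total water samples per homolog."""
    detected: dict[str, int] = {}
    total: dict[str, int] = {}
    for exp in experiments:
        for _, row in exp.water.iterrows():
            h = row["homolog"]
            total[h] = total.get(h, 0) + 1
            if not bool(row.get("censored", False)):
                detected[h] = detected.get(h, 0) + 1
    return detected, total


def water_ratio(exp: ChamberExperiment, homolog: str) -> float:
    """Sodium-normalised water concentration for one experiment.

    The experiment's water concentration is the mean of the triplicate
    cartridges after MDL substitution.
    """
    vals = exp.water.loc[exp.water["homolog"] == homolog, "value"]
    if vals.empty:
        raise KeyError(f"{exp.exp_id}: no water data for {homolog}")
    return float(vals.mean()) / exp.water_na


def per_experiment_ef(exp: ChamberExperiment, homolog: str, fraction: int) -> float | None:
    """EF for one experiment, homolog and fraction; None if the SSA
    sample is excluded (below MDL)."""
    rows = exp.ssa[(exp.ssa["homolog"] == homolog) & (exp.ssa["fraction"] == fraction)]
    if rows.empty:
        return None
    row = rows.iloc[0]
    if bool(row.get("excluded", False)):
        return None
    ssa_ratio = row["value"] / exp.ssa_na[fraction]
    wr = water_ratio(exp, homolog)
    if wr <= 0:
        raise ValueError(f"{exp.exp_id}: nonpositive water ratio for {homolog}")
    return float(ssa_ratio / wr)


def tls_slope_point(x: np.ndarray, y: np.ndarray) -> float:
    """Closed-form through-origin total least squares slope.

    Minimises the summed squared orthogonal distances
    sum((y_i - s x_i)^2) / (1 + s^2) over s for a line through the
    origin.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    sxx = float(x @ x)
    syy = float(y @ y)
    sxy = float(x @ y)
    if sxy == 0.0:
        if sxx > syy:
            return 0.0
        raise ValueError("degenerate TLS problem: vertical best-fit line")
    disc = np.sqrt((syy - sxx) ** 2 + 4.0 * sxy**2)
    # the two stationary points; pick the one with lower objective
    s1 = ((syy - sxx) + disc) / (2.0 * sxy)
    s2 = ((syy - sxx) - disc) / (2.0 * sxy)

    def obj(s: float) -> float:
        return (syy - 2 * s * sxy + s * s * sxx) / (1.0 + s * s)

    return s1 if obj(s1) <= obj(s2) else s2


def tls_slope(
    x: Sequence[float],
    y: Sequence[float],
    *,
    n_bootstrap: int = 2000,
    seed: int | np.random.Generator | None = 0,
    alpha: float = 0.05,
    log_pearson: bool = False,
) -> tuple[float, float, float, float, float]:
    """Through-origin orthogonal regression of SSA on water ratios.

    Returns ``(slope, ci_low, ci_high, pearson_r, p_value)``.  The 95%
    CI is a nonparametric percentile bootstrap over experiments
    (paired points); Pearson's r and its two-sided p come from a t-test
    with n-2 degrees of freedom on the paired values (optionally
    log10-transformed).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError(f"need >= 3 paired points, got {len(x)}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("x and y must be finite")
    if np.any(x <= 0):
        raise ValueError("water ratios must be positive")
    if np.ptp(x) == 0:
        raise ValueError("degenerate regression: all water ratios identical")

    slope = tls_slope_point(x, y)
    if log_pearson:
        r, p = stats.pearsonr(np.log10(x), np.log10(np.maximum(y, np.finfo(float).tiny)))
    else:
        r, p = stats.pearsonr(x, y)

    rng = np.random.default_rng(seed)
    n = len(x)
    idx = rng.integers(0, n, size=(n_bootstrap, n))
    xb, yb = x[idx], y[idx]
    sxx = np.einsum("bi,bi->b", xb, xb)
    syy = np.einsum("bi,bi->b", yb, yb)
    sxy = np.einsum("bi,bi->b", xb, yb)
    with np.errstate(divide="ignore", invalid="ignore"):
        disc = np.sqrt((syy - sxx) ** 2 + 4.0 * sxy**2)
        s1 = ((syy - sxx) + disc) / (2.0 * sxy)
        s2 = ((syy - sxx) - disc) / (2.0 * sxy)
        f1 = (syy - 2 * s1 * sxy + s1**2 * sxx) / (1.0 + s1**2)
        f2 = (syy - 2 * s2 * sxy + s2**2 * sxx) / (1.0 + s2**2)
    boots = np.where(f1 <= f2, s1, s2)
    degenerate = (sxy == 0) | (np.ptp(xb, axis=1) == 0)
    boots = boots[np.isfinite(boots) & ~degenerate]
    lo, hi = np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(slope), float(lo), float(hi), float(r), float(p)


def geometric_mean_ef(
    efs: Sequence[float], *, alpha: float = 0.05
) -> tuple[float, float, float]:
    """Geometric mean EF with a 95% CI.

    The CI is a Student-t interval for the mean of ln(EF),
    back-transformed to the EF scale.
    """
    efs = np.asarray(efs, float)
    if np.any(efs <= 0):
        raise ValueError("all EFs must be positive for a geometric mean")
    logs = np.log(efs)
    gmean = float(np.exp(logs.mean()))
    n = len(efs)
    if n < 2:
        return gmean, gmean, gmean
    se = logs.std(ddof=1) / np.sqrt(n)
    t = stats.t.ppf(1 - alpha / 2, n - 1)
    return gmean, float(np.exp(logs.mean() - t * se)), float(np.exp(logs.mean() + t * se))


def select_ef(
    homolog: str,
    fraction: int,
    x: Sequence[float],
    y: Sequence[float],
    efs: Sequence[float],
    *,
    gate_passed: bool,
    alpha: float = 0.05,
    n_bootstrap: int = 2000,
    seed: int | np.random.Generator | None = 0,
    log_pearson: bool = False,
) -> EFRecord:
    """Build the EFRecord for one homolog x fraction.

    Uses the TLS slope when the water-SSA correlation is significant
    (p strictly below ``alpha``), otherwise the geometric mean of the
    per-experiment EFs.  A failed detection-frequency gate yields
    method ``not_calculated``.
    """
    if not gate_passed:
        return EFRecord(homolog, fraction, "not_calculated")
    efs = tuple(float(e) for e in efs)
    if len(x) >= 3 and np.ptp(np.asarray(x, float)) > 0:
        slope, lo, hi, r, p = tls_slope(
            x, y, n_bootstrap=n_bootstrap, seed=seed, alpha=alpha,
            log_pearson=log_pearson,
        )
    else:
        slope, lo, hi, r, p = np.nan, np.nan, np.nan, np.nan, np.nan
    if np.isfinite(p) and p < alpha and slope > 0:
        return EFRecord(
            homolog, fraction, "slope",
            ef_mean=slope, ci_low=min(lo, slope), ci_high=max(hi, slope),
            pearson_r=r, p_value=p, n_points=len(x), per_experiment_efs=efs,
        )
    if not efs:
        return EFRecord(homolog, fraction, "not_calculated")
    g, glo, ghi = geometric_mean_ef(efs, alpha=alpha)
    return EFRecord(
        homolog, fraction, "gmean",
        ef_mean=g, ci_low=glo, ci_high=ghi,
        pearson_r=r, p_value=p, n_points=len(efs), per_experiment_efs=efs,
    )


def pool_isomers(
    experiments: Sequence[ChamberExperiment],
    isomer_ids: Sequence[str],
    pooled_id: str,
) -> list[ChamberExperiment]:
    """Relabel isomer homologs (e.g. linear and branched PFOS) to one
    pooled id so their data enter the EF estimate collectively."""
    out = []
    mapping = {i: pooled_id for i in isomer_ids}
    for exp in experiments:
        water = exp.water.copy()
        ssa = exp.ssa.copy()
        water["homolog"] = water["homolog"].replace(mapping)
        ssa["homolog"] = ssa["homolog"].replace(mapping)
        mdl_w = exp.mdl_water.rename(index=mapping)
        mdl_w = mdl_w.groupby(level=0).max()
        mdl_s = exp.mdl_ssa.rename(index=mapping).groupby(level=0).max()
        out.append(replace(exp, water=water, ssa=ssa, mdl_water=mdl_w, mdl_ssa=mdl_s))
    return out


def fit_ef_records(
    experiments: Sequence[ChamberExperiment],
    scheme: SizeFractionScheme,
    *,
    alpha: float = 0.05,
    df_threshold: float = 0.30,
    n_bootstrap: int = 2000,
    seed: int = 0,
    log_pearson: bool = False,
) -> list[EFRecord]:
    """Full EF estimation over a set of chamber experiments.

    Applies censoring substitution, the detection-frequency gate, and
    per-fraction estimator selection; returns one EFRecord per
    homolog x fraction present in the data.
    """
    exps = [substitute_censored(e) for e in experiments]
    detected, total = water_detection_counts(exps)
    eligible = detection_frequency_gate(detected, total, df_threshold)
    homologs = sorted(total)

    rng = np.random.default_rng(seed)
    records: list[EFRecord] = []
    for h in homologs:
        for f in scheme.fractions:
            if h not in eligible:
                records.append(EFRecord(h, f, "not_calculated"))
                continue
            xs, ys, efs = [], [], []
            for exp in exps:
                ef = per_experiment_ef(exp, h, f)
                if ef is None:
                    continue
                wr = water_ratio(exp, h)
                row = exp.ssa[
                    (exp.ssa["homolog"] == h) & (exp.ssa["fraction"] == f)
                ].iloc[0]
                xs.append(wr)
                ys.append(row["value"] / exp.ssa_na[f])
                efs.append(ef)
            records.append(
                select_ef(
                    h, f, xs, ys, efs,
                    gate_passed=True, alpha=alpha, n_bootstrap=n_bootstrap,
                    seed=rng, log_pearson=log_pearson,
                )
            )
    return records


def ef_vs_diameter_regression(
    records: Sequence[EFRecord], scheme: SizeFractionScheme
) -> tuple[float, float, float, float]:
    """Log-log regression of EF on representative diameter.

    Ordinary least squares of log10(EF) on log10(d_p) over the
    supermicrometre fractions of one homolog.  Returns
    ``(slope, intercept, pearson_r, p_value)``.
    """
    supers = set(scheme.supermicron_fractions())
    pts = [
        (scheme.d_p(r.fraction), r.ef_mean)
        for r in records
        if r.fraction in supers and r.method != "not_calculated"
        and np.isfinite(r.ef_mean)
    ]
    if len(pts) < 3:
        raise ValueError(f"need >= 3 supermicron EFs, got {len(pts)}")
    d = np.log10([p[0] for p in pts])
    e = np.log10([p[1] for p in pts])
    res = stats.linregress(d, e)
    return float(res.slope), float(res.intercept), float(res.rvalue), float(res.pvalue)


def records_to_frame(records: Sequence[EFRecord]) -> pd.DataFrame:
    """EFRecords as a tidy table (one row per homolog x fraction)."""
    return pd.DataFrame(
        {
            "homolog": [r.homolog for r in records],
            "fraction": [r.fraction for r in records],
            "method": [r.method for r in records],
            "ef_mean": [r.ef_mean for r in records],
            "ci_low": [r.ci_low for r in records],
            "ci_high": [r.ci_high for r in records],
            "pearson_r": [r.pearson_r for r in records],
            "p_value": [r.p_value for r in records],
            "n_points": [r.n_points for r in records],
        }
    )


def records_from_frame(df: pd.DataFrame) -> list[EFRecord]:
    """Inverse of :func:`records_to_frame` (per-experiment EFs are not
    round-tripped)."""
    return [
        EFRecord(
            row.homolog, int(row.fraction), row.method,
            ef_mean=row.ef_mean, ci_low=row.ci_low, ci_high=row.ci_high,
            pearson_r=row.pearson_r, p_value=row.p_value,
            n_points=int(row.n_points),
        )
        for row in df.itertuples()
    ]
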