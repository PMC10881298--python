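"""Bioavailable B1 from an auxotrophic-reporter growth bioassay.

A thiamin-auxotrophic reporter strain (e.g. *Vibrio anguillarum* PF430-3
ΔthiE) is grown in filtered sample water diluted 1:10 into vitamin-free
medium. Final cell yields respond linearly to added B1 over the working
range, so an internal standard curve (e.g. 5-75 pM plus negative
controls) calibrates yield against picomolar B1 and the sample's in-tube
concentration is read off by inversion, then multiplied by the dilution
factor. Uncertainty comes from a nonparametric bootstrap over sample
replicates and standard-curve points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


class AssayError(ValueError):
    """Standard curve unusable (too few levels, non-positive slope, ...)."""


@dataclass
class BioassayCurve:
    """Fitted standard curve: yield = intercept + slope * pM (in tube)."""

    slope: float
    intercept: float
    residual_sd: float
    standard_levels: tuple[float, ...]
    dilution_factor: float = 10.0
    n_points: int = 0
    #: the (level, yield) points the curve was fitted on, kept for bootstrap
    points: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)


@dataclass(frozen=True)
class BioassayEstimate:
    estimate_pM: float
    ci_low: float
    ci_high: float
    in_tube_pM: float
    flag: str  # "ok" | "below_assay_floor" | "extrapolated"
    n_boot: int


def _fit_line(levels: np.ndarray, yields: np.ndarray) -> tuple[float, float]:
    res = sps.linregress(levels, yields)
    return float(res.slope), float(res.intercept)


def fit_standard_curve(
    standards: pd.DataFrame, dilution_factor: float = 10.0
) -> BioassayCurve:
    """Least-squares line through the standard yields.

    ``standards`` needs columns ``level_pM`` and ``growth_yield``; rows at
    level 0 (negative controls) are included in the fit. Requires >= 3
    distinct levels and a positive slope (a non-positive slope means the
    assay failed).
    """
    if standards.empty:
        raise AssayError("no standard rows supplied")
    levels = standards["level_pM"].astype(float).to_numpy()
    yields = standards["growth_yield"].astype(float).to_numpy()
    if len(np.unique(levels)) < 3:
        raise AssayError(f"need >=3 distinct standard levels, got {len(np.unique(levels))}")
    slope, intercept = _fit_line(levels, yields)
    if slope <= 0:
        raise AssayError("standard-curve slope <= 0: assay failure")
    resid = yields - (intercept + slope * levels)
    dof = max(len(yields) - 2, 1)
    return BioassayCurve(
        slope=slope,
        intercept=intercept,
        residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
        standard_levels=tuple(sorted(set(levels))),
        dilution_factor=dilution_factor,
        n_points=len(yields),
        points=standards[["level_pM", "growth_yield"]].reset_index(drop=True),
    )


def invert(
    sample_yields,
    curve: BioassayCurve,
    n_boot: int = 200,
    seed: int | None = None,
    ci: float = 0.95,
) -> BioassayEstimate:
    """Bioavailable B1 (pM, undiluted sample) from sample tube yields.

    Point estimate: ``(mean yield - intercept) / slope * dilution``.
    The bootstrap resamples the standard-curve points stratified within
    level and refits the curve each draw; the sample-mean component uses
    a Student-t draw (``ybar + s/sqrt(n) * t_{n-1}``) because replicate
    counts are tiny (typically 4) and a pure nonparametric resample of
    the mean is known to undercover there. The interval is the
    percentile interval of the resulting estimates.

    Flags: ``below_assay_floor`` when the mean yield falls below the
    fitted intercept (concentration would be negative; reported as 0),
    ``extrapolated`` when the implied in-tube concentration exceeds the
    calibrated range.
    """
    if curve.slope <= 0:
        raise AssayError("cannot invert a curve with non-positive slope")
    y = np.asarray(sample_yields, dtype=float)
    if y.size == 0:
        raise AssayError("no sample yields supplied")
    rng = np.random.default_rng(seed)

    def point_estimate(ybar: float, slope: float, intercept: float) -> float:
        return (ybar - intercept) / slope * curve.dilution_factor

    est_tube = (float(np.mean(y)) - curve.intercept) / curve.slope
    flag = "ok"
    if est_tube < 0:
        flag = "below_assay_floor"
        est_tube = 0.0
    elif est_tube > max(curve.standard_levels):
        flag = "extrapolated"
    estimate = est_tube * curve.dilution_factor

    pts = curve.points
    by_level = [grp.to_numpy() for _, grp in pts.groupby("level_pM")["growth_yield"]]
    levels_rep = np.concatenate(
        [np.full(len(g), lev) for (lev, _), g in zip(pts.groupby("level_pM"), by_level)]
    )
    ybar = float(np.mean(y))
    sem = float(np.std(y, ddof=1) / np.sqrt(y.size)) if y.size > 1 else 0.0
    dof = max(y.size - 1, 1)
    draws = np.empty(n_boot)
    for b in range(n_boot):
        ybar_b = ybar + sem * float(rng.standard_t(dof)) if sem > 0 else ybar
        ystd = np.concatenate([rng.choice(g, size=len(g), replace=True) for g in by_level])
        try:
            slope_b, intercept_b = _fit_line(levels_rep, ystd)
            if slope_b <= 0:
                raise AssayError
        except (AssayError, ValueError):
            slope_b, intercept_b = curve.slope, curve.intercept
        draws[b] = point_estimate(ybar_b, slope_b, intercept_b)
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(draws, [alpha, 1.0 - alpha])
    return BioassayEstimate(
        estimate_pM=float(estimate),
        ci_low=float(lo),
        ci_high=float(hi),
        in_tube_pM=float(est_tube),
        flag=flag,
        n_boot=n_boot,
    )


def quantify_assay(
    table: pd.DataFrame,
    dilution_factor: float = 10.0,
    n_boot: int = 200,
    seed: int | None = None,
) -> BioassayEstimate:
    """Convenience wrapper: fit the curve and invert one growth table.

    ``table`` needs ``tube_type`` (``standard`` / ``negative_control`` /
    ``sample``), ``level_pM`` and ``growth_yield`` columns, as emitted by
    the synthetic bioassay generator.
    """
    standards = table[table["tube_type"].isin(["standard", "negative_control"])]
    curve = fit_standard_curve(standards, dilution_factor=dilution_factor)
    sample = table.loc[table["tube_type"] == "sample", "growth_yield"]
    return invert(sample.to_numpy(), curve, n_boot=n_boot, seed=seed)
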