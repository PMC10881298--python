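"""Targeted LC-MS quantification of B1 and vitamers.

Peak areas from a triple-quadrupole instrument are reduced to picomolar
concentrations per sample pool:

1. a calibration line (area vs spiked level) is fitted per compound and
   batch on curves run in the matrix of a quality-control (QC) sample;
2. limits of detection/quantitation are 3x / 10x the standard deviation
   of inter-sample blanks (dissolved pool: QC response variation);
3. sample responses are back-calculated through the calibration and
   corrected for extraction loss with the sample-specific recovery of the
   13C-labelled internal standard (B1) or a per-compound reference
   recovery (vitamers);
4. each measurement is reported as the mean of two technical injections,
   and only when both injections exceed the LOD; values between LOD and
   LOQ additionally require an explicit review annotation (standing in
   for visual chromatogram inspection).
"""

from __future__ import annotations

import logging
from collections.abc import Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

ROW_TYPES = ("blank", "qc", "calibration", "sample")
FLAGS = ("ok", "below_LOD", "LOD_to_LOQ", "single_injection_reject", "outlier_removed")

#: Recovery estimates outside this range indicate a failed extraction.
RECOVERY_BOUNDS = (0.0, 1.5)


@dataclass(frozen=True)
class CalibrationModel:
    """OLS calibration line: peak area = slope * level_pM + intercept."""

    compound: str
    slope: float
    intercept: float
    r_squared: float
    level_range: tuple[float, float]
    n_levels: int
    batch: str | None = None


@dataclass(frozen=True)
class LodLoq:
    """Detection/quantitation limits in area units and (optionally) pM."""

    compound: str
    lod_area: float
    loq_area: float
    sd: float
    n: int
    mode: str
    lod_pm: float = float("nan")
    loq_pm: float = float("nan")


def _require_columns(table: pd.DataFrame, cols) -> None:
    missing = set(cols) - set(table.columns)
    if missing:
        raise ValueError(f"peak table missing column(s): {sorted(missing)}")


def fit_calibration(
    table: pd.DataFrame, compound: str, batch: str | None = None
) -> CalibrationModel:
    """Fit the calibration line for one compound (and batch).

    Requires >= 3 distinct levels and a positive slope; otherwise the
    compound is not quantifiable in this batch and a ``ValueError`` is
    raised.
    """
    _require_columns(table, ["compound", "row_type", "level_pM", "peak_area"])
    rows = table[(table["compound"] == compound) & (table["row_type"] == "calibration")]
    if batch is not None:
        rows = rows[rows["batch"] == batch]
    levels = rows["level_pM"].astype(float)
    if levels.nunique() < 3:
        raise ValueError(
            f"calibration for {compound} needs >=3 distinct levels, got {levels.nunique()}"
        )
    res = sps.linregress(levels.to_numpy(), rows["peak_area"].astype(float).to_numpy())
    if res.slope <= 0:
        raise ValueError(f"non-quantifiable: calibration slope <= 0 for {compound}")
    return CalibrationModel(
        compound=compound,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        level_range=(float(levels.min()), float(levels.max())),
        n_levels=int(levels.nunique()),
        batch=batch,
    )


def compute_lod_loq(
    table: pd.DataFrame,
    compound: str,
    mode: str = "blanks",
    calibration: CalibrationModel | None = None,
) -> LodLoq:
    """LOD = 3x and LOQ = 10x the response variation.

    ``mode="blanks"`` uses inter-sample blank rows; ``mode="qc_variation"``
    uses QC rows (the dissolved-pool convention). Variation is the sample
    standard deviation (ddof=1). A calibration converts the limits to pM
    via the slope.
    """
    _require_columns(table, ["compound", "row_type", "peak_area"])
    row_type = {"blanks": "blank", "qc_variation": "qc"}.get(mode)
    if row_type is None:
        raise ValueError(f"unknown mode {mode!r}")
    rows = table[(table["compound"] == compound) & (table["row_type"] == row_type)]
    if len(rows) < 3:
        raise ValueError(
            f"need >=3 {row_type} rows for {compound}, got {len(rows)}"
        )
    sd = float(rows["peak_area"].astype(float).std(ddof=1))
    lod, loq = 3.0 * sd, 10.0 * sd
    lod_pm = loq_pm = float("nan")
    if calibration is not None:
        lod_pm, loq_pm = lod / calibration.slope, loq / calibration.slope
    return LodLoq(
        compound=compound, lod_area=lod, loq_area=loq, sd=sd, n=len(rows),
        mode=mode, lod_pm=lod_pm, loq_pm=loq_pm,
    )


def recovery_correct(
    sample_rows: pd.DataFrame, is_expected_area: float
) -> pd.DataFrame:
    """Per-sample internal-standard recovery from 13C-B1 peak areas.

    ``recovery = mean(is_area over injections) / is_expected_area``.
    Samples with recovery outside ``(0, 1.5]`` are flagged ``excluded``
    (failed extraction); corrected concentrations elsewhere divide by the
    recovery. Returns a frame indexed by sample with ``recovery`` and
    ``recovery_flag`` columns.
    """
    _require_columns(sample_rows, ["sample_id", "is_area"])
    if is_expected_area <= 0:
        raise ValueError("is_expected_area must be > 0")
    if sample_rows["is_area"].isna().any():
        raise ValueError("is_area required on every sample row for recovery correction")
    rec = sample_rows.groupby("sample_id")["is_area"].mean() / is_expected_area
    flag = pd.Series(
        np.where((rec > RECOVERY_BOUNDS[0]) & (rec <= RECOVERY_BOUNDS[1]), "ok", "excluded"),
        index=rec.index,
    )
    n_bad = int((flag == "excluded").sum())
    if n_bad:
        logger.warning("%d sample(s) excluded for out-of-range recovery", n_bad)
    return pd.DataFrame({"recovery": rec, "recovery_flag": flag})


def quantify(
    table: pd.DataFrame,
    compound: str,
    calibration: CalibrationModel,
    lodloq: LodLoq,
    recovery: pd.Series | float | None = None,
    review: Mapping[str, str] | None = None,
    exclusions: set | frozenset = frozenset(),
) -> pd.DataFrame:
    """Back-calculate per-sample concentrations with flags.

    Parameters
    ----------
    table
        Peak table; rows with ``row_type == "sample"`` and the requested
        compound are used. Exactly two technical injections are expected
        per sample (one -> ``single_injection_reject``, more -> error).
    recovery
        Per-sample recovery fractions (B1: from :func:`recovery_correct`)
        or a single reference fraction (vitamers). ``None`` applies no
        correction.
    review
        ``sample_id -> "accept" | "reject"`` annotations for measurements
        between LOD and LOQ; unreviewed borderline values get the
        ``LOD_to_LOQ`` flag but no concentration (default-reject).
    exclusions
        ``sample_id`` values whose measurement is removed as a declared
        outlier (flag ``outlier_removed``).

    Returns one row per sample: ``sample_id, compound, concentration_pM,
    flag, recovery_applied, n_injections, review_status``.
    """
    _require_columns(table, ["sample_id", "compound", "row_type", "peak_area", "replicate_injection"])
    rows = table[(table["compound"] == compound) & (table["row_type"] == "sample")]
    review = dict(review or {})
    records = []
    for sample_id, grp in rows.groupby("sample_id"):
        n_inj = len(grp)
        if n_inj > 2:
            raise ValueError(f"sample {sample_id}/{compound}: {n_inj} injections, expected 2")
        rec = float(recovery.get(sample_id, np.nan)) if isinstance(recovery, pd.Series) else (
            float(recovery) if recovery is not None else 1.0
        )
        record = {
            "sample_id": sample_id,
            "compound": compound,
            "concentration_pM": np.nan,
            "flag": None,
            "recovery_applied": rec,
            "n_injections": n_inj,
            "review_status": "",
        }
        if sample_id in exclusions:
            record["flag"] = "outlier_removed"
        elif n_inj < 2:
            record["flag"] = "single_injection_reject"
        else:
            areas = grp["peak_area"].astype(float).to_numpy()
            if (areas <= lodloq.lod_area).any():
                record["flag"] = "below_LOD"
            else:
                if not np.isfinite(rec) or rec <= 0:
                    raise ValueError(f"invalid recovery {rec} for sample {sample_id}")
                conc = (areas - calibration.intercept) / calibration.slope / rec
                mean_conc = float(np.mean(conc))
                if areas.mean() >= lodloq.loq_area:
                    record.update(flag="ok", concentration_pM=mean_conc)
                else:
                    status = review.get(sample_id, "unreviewed")
                    record["flag"] = "LOD_to_LOQ"
                    record["review_status"] = status
                    if status == "accept":
                        record["concentration_pM"] = mean_conc
        records.append(record)
    return pd.DataFrame(
        records,
        columns=["sample_id", "compound", "concentration_pM", "flag",
                 "recovery_applied", "n_injections", "review_status"],
    )


def pool_summaries(
    records: pd.DataFrame,
    poc: pd.Series | None = None,
    compounds: tuple[str, ...] = ("B1", "HET", "HMP", "FAMP"),
) -> pd.DataFrame:
    """Combined-pool sums per sample, optionally normalized to POC.

    Sums the mean concentrations of the listed compounds per sample.
    Compounds flagged ``below_LOD`` (or otherwise lacking a concentration)
    contribute 0 and are counted in ``n_missing`` (logged). When ``poc``
    (particulate organic carbon, µM C per sample) is given, a
    ``combined_per_poc`` column is added; a sample without POC is an
    error.
    """
    use = records[records["compound"].isin(compounds)]
    rows = []
    for sample_id, grp in use.groupby("sample_id"):
        conc = grp["concentration_pM"]
        n_missing = int(conc.isna().sum())
        if n_missing:
            logger.info("sample %s: %d compound(s) without value treated as 0", sample_id, n_missing)
        combined = float(conc.fillna(0.0).sum())
        row = {"sample_id": sample_id, "combined_pM": combined, "n_missing": n_missing}
        if poc is not None:
            if sample_id not in poc.index or not np.isfinite(poc[sample_id]):
                raise ValueError(f"POC missing for sample {sample_id}")
            row["combined_per_poc"] = combined / float(poc[sample_id])
        rows.append(row)
    return pd.DataFrame(rows)
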