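"""Normalization of gene and transcript counts, and community B1 statistics.

The normalization chain mirrors common metagenome practice:

raw counts -> RPKM -> marker-normalized (per-genome-equivalent) ->
transcript activity (metatranscriptome relative to gene dosage).

RPKM divides counts by feature length (kb) and per-sample mapped reads
(millions). Marker normalization divides every RPKM value by the median
RPKM of a set of universal single-copy marker genes in the same sample,
so a value of 1 means "one copy per genome equivalent". Transcript
activity relates metatranscriptome RPKM to the community gene dosage,
either via the metatranscriptome's own marker median (``mode="marker"``)
or by elementwise division with the marker-normalized metagenome
(``mode="metagenome"``); both conventions appear in the literature, so
the mode is explicit and recorded in the output metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STATES = ("raw", "rpkm", "marker_normalized", "transcript_activity")


@dataclass
class AbundanceMatrix:
    """Feature x sample abundance values with a normalization state.

    Attributes
    ----------
    values
        DataFrame, features as rows and samples as columns. Non-negative;
        NaN marks values dropped during normalization (logged).
    state
        One of ``raw | rpkm | marker_normalized | transcript_activity``;
        transitions only move forward in that order.
    gene_lengths
        Feature lengths in bp (required for RPKM).
    mapped_reads
        Per-sample totals of mapped reads (required for RPKM).
    marker_ids
        Feature ids of the single-copy marker genes.
    feature_meta
        Optional per-feature metadata (``gene_label``, ``genome_id`` /
        ``cluster_id``) used for label-level aggregation.
    meta
        Free-form provenance (normalization mode, ground truth, ...).
    """

    values: pd.DataFrame
    state: str = "raw"
    gene_lengths: pd.Series | None = None
    mapped_reads: pd.Series | None = None
    marker_ids: tuple[str, ...] = ()
    feature_meta: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}; expected one of {STATES}")
        if (self.values.to_numpy(dtype=float, na_value=0.0) < 0).any():
            raise ValueError("abundance values must be non-negative")

    def _advance(self, new_state: str, values: pd.DataFrame, **meta) -> "AbundanceMatrix":
        if STATES.index(new_state) <= STATES.index(self.state):
            raise ValueError(f"cannot move state {self.state!r} -> {new_state!r}")
        return replace(self, values=values, state=new_state, meta={**self.meta, **meta})


def rpkm(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Reads Per Kilobase per Million mapped reads.

    ``value' = count / ((length/1000) * (mapped_reads/1e6))``.
    """
    if matrix.state != "raw":
        raise ValueError(f"rpkm expects raw counts, got state {matrix.state!r}")
    if matrix.gene_lengths is None or matrix.mapped_reads is None:
        raise ValueError("rpkm requires gene_lengths and mapped_reads")
    missing = set(matrix.values.index) - set(matrix.gene_lengths.index)
    if missing:
        raise ValueError(f"missing gene length for feature(s): {sorted(missing)}")
    lengths = matrix.gene_lengths.reindex(matrix.values.index)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be > 0")
    reads = matrix.mapped_reads.reindex(matrix.values.columns)
    if reads.isna().any() or (reads <= 0).any():
        raise ValueError("mapped_reads must be > 0 for every sample")
    vals = matrix.values.div(lengths / 1_000.0, axis=0).div(reads / 1_000_000.0, axis=1)
    return matrix._advance("rpkm", vals)


def marker_normalize(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Divide each sample by the median RPKM of its single-copy markers."""
    if matrix.state != "rpkm":
        raise ValueError(f"marker_normalize expects rpkm, got {matrix.state!r}")
    markers = list(matrix.marker_ids)
    if not markers:
        raise ValueError("marker_ids is empty")
    absent = set(markers) - set(matrix.values.index)
    if absent:
        raise ValueError(f"marker feature(s) not in matrix: {sorted(absent)}")
    med = matrix.values.loc[markers].median(axis=0)
    zero = med == 0
    if zero.any():
        logger.warning(
            "zero marker median in sample(s) %s; values set to missing",
            list(med.index[zero]),
        )
        med = med.replace(0, np.nan)
    vals = matrix.values.div(med, axis=1)
    return matrix._advance("marker_normalized", vals)


def transcript_activity(
    metat_rpkm: AbundanceMatrix,
    metag_marker_normalized: AbundanceMatrix | None = None,
    mode: str = "marker",
) -> AbundanceMatrix:
    """Express metatranscriptome RPKM as relative transcript activity.

    ``mode="marker"``: divide by the metatranscriptome's own per-sample
    marker median (relative transcripts per sample). ``mode="metagenome"``:
    divide elementwise by the marker-normalized metagenome, i.e. per gene
    dosage. Zero denominators become missing values (logged).
    """
    if metat_rpkm.state != "rpkm":
        raise ValueError("transcript_activity expects a metatranscriptome RPKM matrix")
    if mode == "marker":
        normalized = marker_normalize(metat_rpkm)
        return replace(
            normalized,
            state="transcript_activity",
            meta={**normalized.meta, "mode": "marker"},
        )
    if mode == "metagenome":
        if metag_marker_normalized is None or metag_marker_normalized.state != "marker_normalized":
            raise ValueError("mode='metagenome' requires a marker-normalized metagenome")
        denom = metag_marker_normalized.values.reindex(
            index=metat_rpkm.values.index, columns=metat_rpkm.values.columns
        )
        if denom.isna().any().any():
            raise ValueError("metagenome matrix does not cover metatranscriptome features/samples")
        zero = denom == 0
        if zero.any().any():
            logger.warning("zero metagenome dosage for %d cells; set to missing", int(zero.sum().sum()))
            denom = denom.mask(zero)
        vals = metat_rpkm.values / denom
        return metat_rpkm._advance("transcript_activity", vals, mode="metagenome")
    raise ValueError(f"unknown mode {mode!r}; expected 'marker' or 'metagenome'")


def aggregate_labels(matrix: AbundanceMatrix) -> pd.DataFrame:
    """Sum values per gene label across ORFs (RPKM-or-later states only).

    Summing per-ORF RPKM is equivalent to length-weighted pooling of the
    underlying counts; a single effective length for pooled raw counts is
    ill-defined, so raw matrices are refused.
    """
    if matrix.state == "raw":
        raise ValueError("aggregate after RPKM normalization, not on raw counts")
    if matrix.feature_meta is None or "gene_label" not in matrix.feature_meta.columns:
        raise ValueError("feature_meta with a gene_label column is required")
    labels = matrix.feature_meta["gene_label"].reindex(matrix.values.index)
    return matrix.values.groupby(labels).sum(min_count=1)


def gene_ratio(
    matrix: AbundanceMatrix, numerator: str, denominator: str
) -> tuple[pd.Series, float]:
    """Ratio of two genes' summed normalized abundances.

    Returns ``(per_sample_series, study_wide_ratio)``; the study-wide
    ratio pools all samples. Zero denominators yield missing values.
    """
    by_label = aggregate_labels(matrix)
    zero = pd.Series(0.0, index=by_label.columns)
    # a label with no ORF anywhere has zero abundance, not an error
    num = by_label.loc[numerator] if numerator in by_label.index else zero
    den = by_label.loc[denominator] if denominator in by_label.index else zero
    per_sample = num / den.where(den != 0)
    total_den = den.sum()
    overall = float(num.sum() / total_den) if total_den > 0 else float("nan")
    return per_sample, overall


def thic_contribution(activities: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster percent contribution to total *thiC* transcription.

    ``activities`` is cluster x timepoint (non-negative). Each timepoint's
    total is scaled to 100%; all-zero timepoints become NaN and are listed
    in ``result.attrs['all_zero_timepoints']``.
    """
    if (activities.to_numpy(dtype=float, na_value=0.0) < 0).any():
        raise ValueError("activities must be non-negative")
    totals = activities.sum(axis=0)
    zero_cols = list(totals.index[totals == 0])
    if zero_cols:
        logger.warning("no thiC transcription at timepoint(s) %s", zero_cols)
    pct = activities.div(totals.where(totals != 0), axis=1) * 100.0
    pct.attrs["all_zero_timepoints"] = zero_cols
    return pct
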