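"""Curation of B1 gene annotations from profile-search hits.

Raw hmmsearch hits against B1-related profiles are noisy: one protein can
match several profiles, and weak matches need profile-specific bit-score
cutoffs. :func:`filter_hits` applies the cutoffs and a best-hit rule so
every protein keeps at most one gene label; manual false-positive
overrides are retained but flagged so genotyping can exclude them.
:func:`detect_riboswitch_adjacency` links genes to nearby TDP riboswitches
(THI-box), which supports a B1-related function for putative transporters.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

HIT_COLUMNS = ("protein_id", "profile_id", "bit_score", "e_value", "mag_id")

#: Default adjacency window: operonic TPP riboswitches sit within a few
#: hundred bp of the regulated gene.
DEFAULT_WINDOW_BP = 500


@dataclass(frozen=True)
class HmmHit:
    """One profile-search hit of a protein against a B1-related profile."""

    protein_id: str
    profile_id: str
    bit_score: float
    e_value: float
    mag_id: str = ""

    def __post_init__(self):
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")


def hits_to_frame(hits: Iterable[HmmHit] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(hits, pd.DataFrame):
        df = hits.copy()
    else:
        df = pd.DataFrame([h.__dict__ for h in hits])
    missing = set(HIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"hit table missing column(s): {sorted(missing)}")
    return df


def read_tblout(path, profile_to_gene: Mapping[str, str] | None = None, mag_id: str = "") -> pd.DataFrame:
    """Read an hmmsearch ``--tblout`` file into a hit table.

    ``profile_to_gene`` optionally renames profile accessions/names to
    gene labels of the B1 vocabulary; unmapped profiles keep their name.
    """
    from Bio import SearchIO

    rows = []
    for qresult in SearchIO.parse(str(path), "hmmer3-tab"):
        profile = qresult.id
        for hit in qresult.hits:
            rows.append(
                {
                    "protein_id": hit.id,
                    "profile_id": (profile_to_gene or {}).get(profile, profile),
                    "bit_score": float(hit.bitscore),
                    "e_value": float(hit.evalue),
                    "mag_id": mag_id,
                }
            )
    return pd.DataFrame(rows, columns=list(HIT_COLUMNS))


def filter_hits(
    hits: Iterable[HmmHit] | pd.DataFrame,
    cutoffs: Mapping[str, float],
    overrides: Iterable[str] = (),
    default_cutoff: float = 25.0,
) -> pd.DataFrame:
    """Reduce raw hits to curated gene calls, one label per protein.

    A hit survives if its bit score passes the profile's cutoff
    (``default_cutoff`` when the profile is absent from the table, which
    is logged). Among surviving hits of one protein the highest bit score
    wins; ties break on lower e-value, then lexicographic profile id.
    Proteins listed in ``overrides`` are kept with ``fp_override=True`` so
    downstream genotyping can exclude them.

    Returns a frame with columns ``protein_id, mag_id, gene_label,
    bit_score, e_value, curated, fp_override``.
    """
    df = hits_to_frame(hits)
    dup = df.duplicated(["protein_id", "profile_id"], keep=False)
    if dup.any():
        bad = df.loc[dup, ["protein_id", "profile_id"]].drop_duplicates()
        raise ValueError(
            "duplicate (protein, profile) hit rows: "
            + "; ".join(f"{p}/{q}" for p, q in bad.itertuples(index=False))
        )
    if df.empty:
        return pd.DataFrame(
            columns=["protein_id", "mag_id", "gene_label", "bit_score", "e_value", "curated", "fp_override"]
        )
    missing_profiles = set(df["profile_id"]) - set(cutoffs)
    for prof in sorted(missing_profiles):
        logger.info("profile %s not in cutoff table; using default %.1f", prof, default_cutoff)
    thr = df["profile_id"].map(lambda p: float(cutoffs.get(p, default_cutoff)))
    passing = df[df["bit_score"] >= thr].copy()
    # best hit per protein: max bit score, tie -> min e-value, tie -> profile id
    passing = passing.sort_values(
        ["protein_id", "bit_score", "e_value", "profile_id"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    best = passing.drop_duplicates("protein_id", keep="first").copy()
    override_set = set(overrides)
    best["gene_label"] = best.pop("profile_id")
    best["curated"] = True
    best["fp_override"] = best["protein_id"].isin(override_set)
    cols = ["protein_id", "mag_id", "gene_label", "bit_score", "e_value", "curated", "fp_override"]
    return best[cols].reset_index(drop=True)


def feature_gap_bp(start_a: int, end_a: int, start_b: int, end_b: int) -> int:
    """End-to-start distance between two intervals; 0 if they overlap."""
    return max(0, max(start_a, start_b) - min(end_a, end_b))


def detect_riboswitch_adjacency(
    features: pd.DataFrame,
    window_bp: int = DEFAULT_WINDOW_BP,
    riboswitch_label: str = "riboswitch_TDP",
) -> pd.DataFrame:
    """Associate genes with TDP riboswitches on the same contig.

    A gene is riboswitch-associated iff a riboswitch feature lies on the
    same contig (and MAG, when a ``mag_id`` column is present) with an
    end-to-start gap <= ``window_bp``. The gap is symmetric and
    strand-agnostic. Returns one row per (gene, riboswitch) association
    with the gap in bp; empty input yields an empty table.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    cols = ["mag_id", "contig_id", "gene_label", "gene_start", "gene_end",
            "riboswitch_start", "riboswitch_end", "gap_bp"]
    if features.empty:
        return pd.DataFrame(columns=cols)
    feats = features.copy()
    if "mag_id" not in feats.columns:
        feats["mag_id"] = ""
    ribo = feats[feats["gene_label"] == riboswitch_label]
    genes = feats[feats["gene_label"] != riboswitch_label]
    rows = []
    for (mag, contig), gsub in genes.groupby(["mag_id", "contig_id"], sort=True):
        rsub = ribo[(ribo["mag_id"] == mag) & (ribo["contig_id"] == contig)]
        for g in gsub.itertuples(index=False):
            for r in rsub.itertuples(index=False):
                gap = feature_gap_bp(g.start, g.end, r.start, r.end)
                if gap <= window_bp:
                    rows.append(
                        {
                            "mag_id": mag,
                            "contig_id": contig,
                            "gene_label": g.gene_label,
                            "gene_start": g.start,
                            "gene_end": g.end,
                            "riboswitch_start": r.start,
                            "riboswitch_end": r.end,
                            "gap_bp": gap,
                        }
                    )
    return pd.DataFrame(rows, columns=cols)
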