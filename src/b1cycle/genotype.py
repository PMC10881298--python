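"""B1 genotype classification of MAG clusters.

A 95%-ANI cluster of metagenome-assembled genomes (MAGs) is screened for
the 13 B1-related genes and assigned exactly one physiology category:

* ``PROTOTROPH`` — carries all three de novo synthesis genes
  (*thiC*, *thiG*, *thiE*);
* ``PYRIMIDINE_AUXOTROPH`` — lacks *thiC* but has *thiG* and *thiE*
  (can condense B1 from a salvaged/transported pyrimidine);
* ``THIAZOLE_AUXOTROPH`` — lacks *thiG* but has *thiC* and *thiE*;
* ``AUXOTROPH_B1_TRANSPORT`` — no synthesis route, but transports intact
  B1 (*thiB* or *thiT*);
* ``AUXOTROPH_PUTATIVE_TRANSPORT`` — no synthesis route, only putative
  B1/vitamer transporters (*thiV*, *thiY*, *cytX*, *ykoF*, *thiPerm*,
  *omr1*);
* ``NO_KNOWN_ROUTE`` — none of the above.

Salvage genes (*tenA*, *thiM*) are reported in the acquisition repertoire
but never change the category. Absence-based categories are only trusted
when the cluster contains at least one high-quality MAG (>=90% complete,
<5% contaminated); otherwise the call is flagged ``low_completeness``.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .vocab import ACQUISITION_GENES, B1_GENES, PUTATIVE_TRANSPORT_GENES

logger = logging.getLogger(__name__)

CATEGORIES: tuple[str, ...] = (
    "PROTOTROPH",
    "PYRIMIDINE_AUXOTROPH",
    "THIAZOLE_AUXOTROPH",
    "AUXOTROPH_B1_TRANSPORT",
    "AUXOTROPH_PUTATIVE_TRANSPORT",
    "NO_KNOWN_ROUTE",
)

# Quality tiers: (min completeness %, max contamination %), exclusive upper
# bound on contamination.
MEDIUM_TIER = (50.0, 10.0)
HIGH_TIER = (90.0, 5.0)


def quality_tier(completeness: float, contamination: float) -> str:
    """Tier a MAG: ``high`` (>=90%, <5%), ``medium`` (>=50%, <10%), else
    ``below_medium``. Completeness/contamination in percent."""
    if not 0.0 <= completeness <= 100.0:
        raise ValueError(f"completeness must be in [0, 100], got {completeness}")
    if completeness >= HIGH_TIER[0] and contamination < HIGH_TIER[1]:
        return "high"
    if completeness >= MEDIUM_TIER[0] and contamination < MEDIUM_TIER[1]:
        return "medium"
    return "below_medium"


def classify_gene_set(present: Iterable[str]) -> str:
    """Map a set of present B1 genes to its physiology category.

    The rule cascade is total: every subset of the 13-gene vocabulary maps
    to exactly one category. *thiE* is required for any synthesis-based
    category; a genome with *thiC* and *thiG* but no *thiE* falls through
    to the transport rules.
    """
    p = set(present)
    unknown = p - set(B1_GENES)
    if unknown:
        raise ValueError(f"unknown gene label(s) in presence set: {sorted(unknown)}")
    has = p.__contains__
    if has("thiE") and has("thiG"):
        return "PROTOTROPH" if has("thiC") else "PYRIMIDINE_AUXOTROPH"
    if has("thiE") and has("thiC"):
        return "THIAZOLE_AUXOTROPH"
    if has("thiB") or has("thiT"):
        return "AUXOTROPH_B1_TRANSPORT"
    if p & set(PUTATIVE_TRANSPORT_GENES):
        return "AUXOTROPH_PUTATIVE_TRANSPORT"
    return "NO_KNOWN_ROUTE"


@dataclass(frozen=True)
class GenotypeCall:
    """A cluster's inferred B1 physiology."""

    cluster_id: str
    category: str
    repertoire: tuple[str, ...]
    confidence: str  # "callable" | "low_completeness"


def cluster_gene_presence(
    features: pd.DataFrame,
    cluster_map: Mapping[str, str] | pd.Series,
    quality: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-cluster presence fractions for every B1 gene.

    Parameters
    ----------
    features
        Curated gene features with columns ``mag_id``, ``gene_label`` and
        (optionally) ``fp_override``. Features flagged as manual false
        positives are excluded. Non-B1 labels (markers, riboswitches) are
        ignored.
    cluster_map
        ``mag_id -> cluster_id`` for every MAG in the analysis, including
        MAGs without any B1 feature (they count in the denominator).
    quality
        Optional table with ``mag_id`` and ``completeness`` used to report
        ``max_completeness`` per cluster.

    Returns
    -------
    DataFrame indexed by ``cluster_id`` with one column per B1 gene
    (fraction of the cluster's MAGs carrying the gene), plus ``n_mags``
    and ``max_completeness``.
    """
    cmap = pd.Series(dict(cluster_map)) if not isinstance(cluster_map, pd.Series) else cluster_map
    if cmap.empty:
        raise ValueError("cluster map is empty")
    feats = features.copy()
    unmapped = set(feats["mag_id"]) - set(cmap.index)
    if unmapped:
        raise ValueError(f"MAG(s) in feature set missing from cluster map: {sorted(unmapped)}")
    if "fp_override" in feats.columns:
        feats = feats[~feats["fp_override"].fillna(False).astype(bool)]
    feats = feats[feats["gene_label"].isin(B1_GENES)]

    n_mags = cmap.groupby(cmap).size()
    out = pd.DataFrame(0.0, index=n_mags.index, columns=list(B1_GENES))
    if not feats.empty:
        carriers = (
            feats.assign(cluster_id=feats["mag_id"].map(cmap))
            .drop_duplicates(["mag_id", "gene_label"])
            .groupby(["cluster_id", "gene_label"], observed=True)
            .size()
            .unstack(fill_value=0)
        )
        for gene in carriers.columns:
            out.loc[carriers.index, gene] = carriers[gene] / n_mags.loc[carriers.index]
    out["n_mags"] = n_mags
    if quality is not None:
        q = quality.set_index("mag_id") if "mag_id" in quality.columns else quality
        maxc = q["completeness"].groupby(q.index.map(cmap)).max()
        out["max_completeness"] = maxc.reindex(out.index)
    else:
        out["max_completeness"] = np.nan
    out.index.name = "cluster_id"
    return out


def _cluster_has_high_tier(quality: pd.DataFrame, cmap: pd.Series) -> pd.Series:
    q = quality.copy()
    if "mag_id" in q.columns:
        q = q.set_index("mag_id")
    tiers = [
        quality_tier(c, k) for c, k in zip(q["completeness"], q["contamination"])
    ]
    high = pd.Series([t == "high" for t in tiers], index=q.index)
    return high.groupby(q.index.map(cmap)).any()


def call_genotype(
    presence: pd.DataFrame,
    quality: pd.DataFrame,
    cluster_map: Mapping[str, str] | pd.Series,
    presence_threshold: float = 0.0,
) -> pd.DataFrame:
    """Assign one genotype per cluster from its presence-fraction table.

    A gene is "present" in the cluster iff its presence fraction exceeds
    ``presence_threshold`` (default 0: present in at least one MAG).
    Confidence is ``low_completeness`` iff the cluster has no high-tier
    MAG — absence cannot be trusted in incomplete genomes.
    """
    cmap = pd.Series(dict(cluster_map)) if not isinstance(cluster_map, pd.Series) else cluster_map
    high = _cluster_has_high_tier(quality, cmap)
    rows = []
    for cid, row in presence.iterrows():
        present = {g for g in B1_GENES if row.get(g, 0.0) > presence_threshold}
        category = classify_gene_set(present)
        repertoire = tuple(g for g in ACQUISITION_GENES if g in present)
        confidence = "callable" if bool(high.get(cid, False)) else "low_completeness"
        rows.append(
            {
                "cluster_id": cid,
                "category": category,
                "repertoire": ",".join(repertoire),
                "confidence": confidence,
            }
        )
    return pd.DataFrame(rows).set_index("cluster_id")


def community_genotype_summary(
    calls: pd.DataFrame,
    abundances: pd.DataFrame | None = None,
    include_low_completeness: bool = False,
) -> pd.DataFrame:
    """Per-timepoint fractions of clusters (and of community abundance) in
    each genotype category.

    Parameters
    ----------
    calls
        Output of :func:`call_genotype`, indexed by cluster.
    abundances
        Optional cluster x timepoint relative abundances; each column must
        sum to <= 1. When given, abundance-weighted fractions are computed
        with weights renormalized over the callable clusters.
    include_low_completeness
        Whether ``low_completeness`` clusters enter the summary (default:
        excluded — their absence-based categories are untrustworthy).

    Returns a tidy frame with columns ``timepoint``, ``category``,
    ``fraction_clusters``, ``fraction_abundance`` plus per-timepoint
    ``auxotroph`` rows (1 - prototroph fraction among callable clusters).
    """
    use = calls if include_low_completeness else calls[calls["confidence"] == "callable"]
    if use.empty:
        logger.warning("no callable clusters; empty genotype summary")
        out = pd.DataFrame(
            columns=["timepoint", "category", "fraction_clusters", "fraction_abundance"]
        )
        out.attrs["no_callable"] = True
        return out

    if abundances is not None:
        sums = abundances.sum(axis=0)
        if (sums > 1 + 1e-9).any():
            raise ValueError("cluster abundances at a timepoint exceed 1")
        timepoints = list(abundances.columns)
    else:
        timepoints = ["all"]

    n = len(use)
    frac_clusters = use["category"].value_counts() / n
    rows = []
    for tp in timepoints:
        if abundances is not None:
            w = abundances.loc[abundances.index.intersection(use.index), tp]
            w = w / w.sum() if w.sum() > 0 else w
            frac_ab = w.groupby(use.loc[w.index, "category"]).sum()
        else:
            frac_ab = frac_clusters
        for cat in CATEGORIES:
            rows.append(
                {
                    "timepoint": tp,
                    "category": cat,
                    "fraction_clusters": float(frac_clusters.get(cat, 0.0)),
                    "fraction_abundance": float(frac_ab.get(cat, 0.0)),
                }
            )
        rows.append(
            {
                "timepoint": tp,
                "category": "auxotroph",
                "fraction_clusters": 1.0 - float(frac_clusters.get("PROTOTROPH", 0.0)),
                "fraction_abundance": 1.0 - float(frac_ab.get("PROTOTROPH", 0.0)),
            }
        )
    return pd.DataFrame(rows)


def genotype_recovery_score(
    calls: pd.DataFrame, truth: Mapping[str, str]
) -> tuple[pd.DataFrame, float]:
    """Score genotype calls against known truth (validation harness).

    Returns ``(confusion, recovery_rate)`` where the confusion matrix is
    truth-category x called-category over callable clusters and the
    recovery rate is the fraction of callable clusters whose category
    matches the truth.
    """
    missing = set(calls.index) - set(truth)
    if missing:
        raise ValueError(f"ground truth missing for cluster(s): {sorted(missing)}")
    callable_calls = calls[calls["confidence"] == "callable"]
    conf = pd.DataFrame(0, index=list(CATEGORIES), columns=list(CATEGORIES))
    n_match = 0
    for cid, row in callable_calls.iterrows():
        conf.loc[truth[cid], row["category"]] += 1
        n_match += int(row["category"] == truth[cid])
    rate = n_match / len(callable_calls) if len(callable_calls) else float("nan")
    return conf, rate
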