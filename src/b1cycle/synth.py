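"""Synthetic community, MAG, count, LC-MS, and bioassay data with ground truth.

Every input the analysis pipeline consumes can be generated here with a
known answer key, so each downstream stage is testable without any
sequencing or instrument data:

* annotated genomes with a chosen B1 gene repertoire, single-copy marker
  genes, and TDP riboswitches placed adjacent to chosen genes;
* MAGs sampled from those genomes with Bernoulli gene loss at a requested
  completeness and optional foreign-gene contamination;
* metagenome/metatranscriptome count matrices with Poisson (optionally
  negative-binomial, or no) noise, expected counts proportional to
  genome abundance x gene length x sequencing depth;
* targeted LC-MS peak-area batches with blanks, calibration levels in a
  QC matrix, internal-standard areas scaled by per-sample recovery, and
  multiplicative log-normal noise (mean-1 parameterization, so areas are
  unbiased);
* reporter-strain bioassay growth yields with a linear standard curve.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abundance import AbundanceMatrix
from .genotype import classify_gene_set
from .vocab import (
    MARKER_LABEL,
    RIBOSWITCH_LABEL,
    RIBOSWITCH_LENGTH_BP,
    TYPICAL_GENE_LENGTH_BP,
    check_gene_labels,
)


class SpecConsistencyError(ValueError):
    """A genome spec's gene set contradicts its declared genotype."""


@dataclass(frozen=True)
class TrueGenomeSpec:
    """Ground-truth description of one synthetic genome.

    ``gene_set`` must map to ``true_genotype`` under the genotype rule
    cascade; inconsistent specs are refused (the generator never emits a
    genome whose answer key is wrong).
    """

    genome_id: str
    true_genotype: str
    gene_set: frozenset[str]
    n_marker_genes: int = 21
    genome_length: int = 2_000_000
    riboswitch_links: frozenset[str] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "gene_set", frozenset(self.gene_set))
        object.__setattr__(self, "riboswitch_links", frozenset(self.riboswitch_links))
        check_gene_labels(self.gene_set)
        if self.n_marker_genes < 1:
            raise ValueError("n_marker_genes must be >= 1")
        if not self.riboswitch_links <= self.gene_set:
            raise ValueError("riboswitch_links must be a subset of gene_set")
        implied = classify_gene_set(self.gene_set)
        if implied != self.true_genotype:
            raise SpecConsistencyError(
                f"genome {self.genome_id}: gene_set {sorted(self.gene_set)} "
                f"implies category {implied} under the rule cascade, "
                f"not {self.true_genotype}"
            )


def genome_spec(
    genome_id: str,
    gene_set: Iterable[str],
    riboswitch_links: Iterable[str] = (),
    n_marker_genes: int = 21,
    genome_length: int = 2_000_000,
) -> TrueGenomeSpec:
    """Build a spec whose declared genotype is derived from the gene set."""
    gs = frozenset(gene_set)
    return TrueGenomeSpec(
        genome_id=genome_id,
        true_genotype=classify_gene_set(gs),
        gene_set=gs,
        n_marker_genes=n_marker_genes,
        genome_length=genome_length,
        riboswitch_links=frozenset(riboswitch_links),
    )


def prototroph_spec(genome_id: str, **kwargs) -> TrueGenomeSpec:
    """A minimal prototroph: one copy each of thiC, thiG, thiE."""
    return genome_spec(genome_id, {"thiC", "thiG", "thiE"}, **kwargs)


def random_genome_spec(
    genome_id: str, rng: np.random.Generator, p_gene: float = 0.35
) -> TrueGenomeSpec:
    """A random (always self-consistent) genome spec.

    Each of the 13 B1 genes is included independently with probability
    ``p_gene``; the declared genotype is derived from the drawn set.
    """
    from .vocab import B1_GENES

    genes = frozenset(g for g in B1_GENES if rng.random() < p_gene)
    return genome_spec(genome_id, genes)


@dataclass
class CommunityScenario:
    """A synthetic community: genome specs plus per-timepoint abundances."""

    genomes: list[TrueGenomeSpec]
    abundances: pd.DataFrame  # genome x timepoint, columns sum to 1
    seed: int = 0
    completeness_range: tuple[float, float] = (0.5, 1.0)
    contamination_rate: float = 0.0
    depth: int = 1_000_000
    expression_sigma: float = 1.0

    def __post_init__(self):
        ids = [g.genome_id for g in self.genomes]
        if list(self.abundances.index) != ids:
            self.abundances = self.abundances.reindex(ids)
        vals = self.abundances.to_numpy(dtype=float)
        if np.isnan(vals).any() or (vals < 0).any():
            raise ValueError("abundances must be non-negative and cover all genomes")
        colsums = vals.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ValueError("abundance columns must each sum to 1 (within 1e-9)")

    @property
    def n_timepoints(self) -> int:
        return self.abundances.shape[1]


def random_scenario(
    specs: Sequence[TrueGenomeSpec],
    n_timepoints: int = 12,
    seed: int = 0,
    **kwargs,
) -> CommunityScenario:
    """Dirichlet relative abundances over ``n_timepoints`` samples."""
    rng = np.random.default_rng([seed, 101])
    ab = rng.dirichlet(np.ones(len(specs)), size=n_timepoints).T
    df = pd.DataFrame(
        ab,
        index=[s.genome_id for s in specs],
        columns=[f"t{i:02d}" for i in range(n_timepoints)],
    )
    return CommunityScenario(genomes=list(specs), abundances=df, seed=seed, **kwargs)


# ---------------------------------------------------------------------------
# genomes and MAGs

FEATURE_COLUMNS = ("contig_id", "feature_id", "gene_label", "start", "end", "strand", "length")


def _marker_length(i: int) -> int:
    # fixed per-marker lengths around a typical 900 bp single-copy gene
    return 750 + 25 * (i % 13)


def generate_genomes(
    specs: Sequence[TrueGenomeSpec],
    seed: int = 0,
    riboswitch_gap: tuple[int, int] = (20, 200),
) -> dict[str, pd.DataFrame]:
    """Lay out feature tables (1-based inclusive coordinates) per genome.

    Each genome gets one contig carrying one feature per gene in its
    ``gene_set``, ``n_marker_genes`` marker features, and one TDP
    riboswitch per gene in ``riboswitch_links`` placed upstream with an
    end-to-start gap drawn from ``riboswitch_gap`` (within the default
    adjacency window). Deterministic for a fixed seed.
    """
    out: dict[str, pd.DataFrame] = {}
    for gi, spec in enumerate(specs):
        rng = np.random.default_rng([seed, gi])
        contig = f"{spec.genome_id}_c1"
        rows = []
        cursor = 1_000
        labels = sorted(spec.gene_set) + [MARKER_LABEL] * spec.n_marker_genes
        marker_i = 0
        for label in labels:
            if label == MARKER_LABEL:
                marker_i += 1
                fid = f"{spec.genome_id}:marker_{marker_i:02d}"
                length = _marker_length(marker_i)
            else:
                fid = f"{spec.genome_id}:{label}"
                length = TYPICAL_GENE_LENGTH_BP[label]
            gap = int(rng.integers(200, 2001))
            start = cursor + gap
            end = start + length - 1
            strand = "+" if rng.random() < 0.5 else "-"
            if label in spec.riboswitch_links:
                rgap = int(rng.integers(riboswitch_gap[0], riboswitch_gap[1] + 1))
                rib_end = start - rgap
                rib_start = rib_end - RIBOSWITCH_LENGTH_BP + 1
                rows.append(
                    dict(contig_id=contig, feature_id=f"{fid}_THI", gene_label=RIBOSWITCH_LABEL,
                         start=rib_start, end=rib_end, strand=strand, length=RIBOSWITCH_LENGTH_BP)
                )
            rows.append(
                dict(contig_id=contig, feature_id=fid, gene_label=label,
                     start=start, end=end, strand=strand, length=length)
            )
            cursor = end
        out[spec.genome_id] = pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))
    return out


def sample_mags(
    genomes: Mapping[str, pd.DataFrame],
    completeness: float | Mapping[str, float],
    contamination_rate: float = 0.0,
    n_mags_per_genome: int = 1,
    seed: int = 0,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Sample MAGs from genomes by independent per-feature Bernoulli loss.

    Every feature of the source genome is retained with probability
    ``completeness``; foreign features from the other genomes are each
    inserted with probability ``contamination_rate``. Reported
    completeness/contamination are the realized percentages (retained /
    total source features; foreign / total source features). MAGs from
    the same source genome share a cluster (the 95%-ANI population).

    Returns ``(mag_features, quality)`` where ``quality`` has columns
    ``mag_id, cluster_id, source_genome, completeness, contamination``.
    """
    if n_mags_per_genome < 1:
        raise ValueError("n_mags_per_genome must be >= 1")
    if not 0.0 <= contamination_rate <= 1.0:
        raise ValueError("contamination_rate must be in [0, 1]")
    comp = completeness if isinstance(completeness, Mapping) else {
        gid: float(completeness) for gid in genomes
    }
    for gid, c in comp.items():
        if not 0.0 <= c <= 1.0:
            raise ValueError(f"completeness for {gid} must be in [0, 1], got {c}")
    mag_features: dict[str, pd.DataFrame] = {}
    qrows = []
    gids = list(genomes)
    for gi, gid in enumerate(gids):
        feats = genomes[gid]
        others = pd.concat([genomes[o] for o in gids if o != gid]) if len(gids) > 1 else None
        for m in range(n_mags_per_genome):
            rng = np.random.default_rng([seed, gi, m])
            mag_id = f"{gid}_mag{m + 1}"
            keep = rng.random(len(feats)) < comp[gid]
            kept = feats[keep].copy()
            n_foreign = 0
            if others is not None and contamination_rate > 0:
                take = rng.random(len(others)) < contamination_rate
                foreign = others[take].copy()
                n_foreign = len(foreign)
                if n_foreign:
                    foreign["feature_id"] = foreign["feature_id"] + f"@{mag_id}"
                    kept = pd.concat([kept, foreign], ignore_index=True)
            kept.insert(0, "mag_id", mag_id)
            kept["fp_override"] = False
            mag_features[mag_id] = kept.reset_index(drop=True)
            n_src = len(feats)
            qrows.append(
                {
                    "mag_id": mag_id,
                    "cluster_id": gid,
                    "source_genome": gid,
                    "completeness": 100.0 * keep.sum() / n_src,
                    "contamination": 100.0 * n_foreign / n_src,
                }
            )
    return mag_features, pd.DataFrame(qrows)


# ---------------------------------------------------------------------------
# counts


def simulate_counts(
    scenario: CommunityScenario,
    mode: str = "metagenome",
    noise: str = "poisson",
    nb_dispersion: float = 0.1,
) -> AbundanceMatrix:
    """Raw ORF-level count matrix for a community scenario.

    The expected count of ORF *g* of genome *i* in sample *t* is
    ``abundance[i, t] * depth * length_g / 1e6`` (so RPKM inverts to
    1000 x abundance, and single-copy markers track genome abundance).
    ``mode="metatranscriptome"`` multiplies by a per-ORF log-normal
    expression factor (markers keep factor 1) stored as ground truth in
    ``meta["expression_factors"]``. ``noise``: ``"poisson"`` (default),
    ``"nb"`` (negative binomial with gamma-mixture dispersion), or
    ``"none"`` (exact expectations, for closed-form checks).
    """
    if mode not in ("metagenome", "metatranscriptome"):
        raise ValueError(f"unknown mode {mode!r}")
    if noise not in ("poisson", "nb", "none"):
        raise ValueError(f"unknown noise model {noise!r}")
    if scenario.depth <= 0:
        raise ValueError("depth must be > 0")
    genomes = generate_genomes(scenario.genomes, seed=scenario.seed)
    feats = pd.concat(
        [df.assign(genome_id=gid) for gid, df in genomes.items()], ignore_index=True
    )
    feats = feats[feats["gene_label"] != RIBOSWITCH_LABEL].set_index("feature_id")

    rng = np.random.default_rng([scenario.seed, 7 if mode == "metagenome" else 8])
    expr = pd.Series(1.0, index=feats.index)
    if mode == "metatranscriptome":
        sigma = scenario.expression_sigma
        is_gene = feats["gene_label"] != MARKER_LABEL
        expr.loc[is_gene] = rng.lognormal(mean=0.0, sigma=sigma, size=int(is_gene.sum()))

    ab = scenario.abundances
    lam = (
        ab.loc[feats["genome_id"]].to_numpy()
        * (feats["length"].to_numpy()[:, None] / 1e6)
        * scenario.depth
        * expr.to_numpy()[:, None]
    )
    if noise == "poisson":
        counts = rng.poisson(lam)
    elif noise == "nb":
        shape = 1.0 / nb_dispersion
        counts = rng.poisson(rng.gamma(shape, lam / shape))
    else:
        counts = lam
    values = pd.DataFrame(counts, index=feats.index, columns=ab.columns, dtype=float)
    marker_ids = tuple(feats.index[feats["gene_label"] == MARKER_LABEL])
    return AbundanceMatrix(
        values=values,
        state="raw",
        gene_lengths=feats["length"].astype(float),
        mapped_reads=pd.Series(float(scenario.depth), index=ab.columns),
        marker_ids=marker_ids,
        feature_meta=feats[["gene_label", "genome_id"]].copy(),
        meta={
            "mode": mode,
            "noise": noise,
            "expression_factors": expr if mode == "metatranscriptome" else None,
        },
    )


# ---------------------------------------------------------------------------
# LC-MS peak areas

MS_COLUMNS = (
    "sample_id", "compound", "replicate_injection", "batch", "row_type",
    "level_pM", "peak_area", "is_area",
)


def _lognoise(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative log-normal factor with mean exactly 1."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=size)


def simulate_ms_dataset(
    true_concentrations: pd.DataFrame,
    calibration_levels: Sequence[float] = (1, 5, 10, 25, 50, 100, 250),
    recovery: float | pd.Series = 1.0,
    noise_cv: float = 0.15,
    n_blanks: int = 6,
    seed: int = 0,
    slope: float | Mapping[str, float] = 5_000.0,
    blank_sd: float = 50.0,
    is_expected_area: float = 100_000.0,
    n_qc: int = 3,
    batch: str = "batch1",
) -> tuple[pd.DataFrame, dict]:
    """Emit a synthetic targeted LC-MS batch plus its ground truth.

    ``true_concentrations`` is compound x sample (pM). Per sample and
    compound two technical-injection rows are emitted with
    ``peak_area = slope * concentration * recovery * lognormal(1, cv)``;
    internal-standard (13C-B1) areas are scaled by the same per-sample
    recovery. Blank rows have mean zero with a half-normal noise floor of
    scale ``blank_sd``; calibration rows sit at the stated levels in the
    QC matrix (no extraction loss); QC rows sit at the median sample
    concentration. Returns ``(peak_table, truth)`` with the truth dict
    holding concentrations, recoveries, and the slope used.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if (true_concentrations.to_numpy(dtype=float) < 0).any():
        raise ValueError("true concentrations must be >= 0")
    samples = list(true_concentrations.columns)
    rec = recovery if isinstance(recovery, pd.Series) else pd.Series(
        float(recovery), index=samples
    )
    if ((rec <= 0) | (rec > 1)).any():
        raise ValueError("recovery must satisfy 0 < recovery <= 1")
    slopes = slope if isinstance(slope, Mapping) else {
        c: float(slope) for c in true_concentrations.index
    }
    rng = np.random.default_rng([seed, 55])
    rows = []
    for compound in true_concentrations.index:
        k = slopes[compound]
        for b in range(n_blanks):
            rows.append(
                dict(sample_id=f"blank_{b + 1}", compound=compound, replicate_injection=1,
                     batch=batch, row_type="blank", level_pM=0.0,
                     peak_area=abs(rng.normal(0.0, blank_sd)) if blank_sd > 0 else 0.0,
                     is_area=is_expected_area * _lognoise(rng, noise_cv))
            )
        for level in calibration_levels:
            rows.append(
                dict(sample_id=f"cal_{level}", compound=compound, replicate_injection=1,
                     batch=batch, row_type="calibration", level_pM=float(level),
                     peak_area=k * level * _lognoise(rng, noise_cv),
                     is_area=is_expected_area * _lognoise(rng, noise_cv))
            )
        qc_conc = float(np.median(true_concentrations.loc[compound]))
        for q in range(n_qc):
            rows.append(
                dict(sample_id=f"qc_{q + 1}", compound=compound, replicate_injection=1,
                     batch=batch, row_type="qc", level_pM=np.nan,
                     peak_area=k * qc_conc * _lognoise(rng, noise_cv),
                     is_area=is_expected_area * _lognoise(rng, noise_cv))
            )
        for sample in samples:
            conc = float(true_concentrations.loc[compound, sample])
            r = float(rec[sample])
            for inj in (1, 2):
                rows.append(
                    dict(sample_id=sample, compound=compound, replicate_injection=inj,
                         batch=batch, row_type="sample", level_pM=np.nan,
                         peak_area=k * conc * r * _lognoise(rng, noise_cv),
                         is_area=is_expected_area * r * _lognoise(rng, noise_cv))
                )
    table = pd.DataFrame(rows, columns=list(MS_COLUMNS))
    truth = {
        "concentrations": true_concentrations.copy(),
        "recovery": rec.copy(),
        "slope": dict(slopes),
        "is_expected_area": is_expected_area,
    }
    return table, truth


# ---------------------------------------------------------------------------
# bioassay


def simulate_bioassay(
    true_b1_pm: float,
    slope: float = 20_000.0,
    intercept: float = 50_000.0,
    standards: Sequence[float] = (5, 10, 25, 50, 75),
    noise_sd: float = 0.0,
    n_replicates: int = 4,
    dilution_factor: float = 10.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Growth-yield table for a reporter-strain bioassay.

    Yields (cells ml^-1) follow ``intercept + slope * pM_in_tube`` plus
    Gaussian noise. Standards at the given in-tube levels, negative
    controls at 0, and sample tubes at ``true_b1_pm / dilution_factor``.
    Default curve parameters approximate reporter yields of a few times
    1e5 cells ml^-1 over a 5-75 pM working range.
    """
    standards = list(standards)
    if not standards:
        raise ValueError("standards must be non-empty")
    if any(s <= 0 for s in standards) or sorted(standards) != standards:
        raise ValueError("standards must be strictly positive and sorted ascending")
    rng = np.random.default_rng([seed, 99])
    rows = []

    def emit(tube_type: str, level: float):
        for r in range(1, n_replicates + 1):
            y = intercept + slope * level + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append(
                dict(tube_type=tube_type, level_pM=level, replicate=r, growth_yield=y)
            )

    for level in standards:
        emit("standard", float(level))
    emit("negative_control", 0.0)
    in_tube = true_b1_pm / dilution_factor
    emit("sample", float(in_tube))
    df = pd.DataFrame(rows)
    # samples' level_pM is ground truth, not an observable: mask it
    df.loc[df["tube_type"] == "sample", "level_pM"] = np.nan
    return df
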