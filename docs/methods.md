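# Methods

This note records the models behind `b1cycle`, the defaults that matter,
and what the synthetic generators do and do not emulate.

## Genotype model

A cluster's B1 physiology is a total function of its gene presence set,
evaluated as a first-match cascade:

1. *thiC* ∧ *thiG* ∧ *thiE* → `PROTOTROPH`
2. ¬*thiC* ∧ *thiG* ∧ *thiE* → `PYRIMIDINE_AUXOTROPH`
3. *thiC* ∧ ¬*thiG* ∧ *thiE* → `THIAZOLE_AUXOTROPH`
4. else *thiB* ∨ *thiT* → `AUXOTROPH_B1_TRANSPORT`
5. else any of {*thiV*, *thiY*, *cytX*, *ykoF*, *thiPerm*, *omr1*} →
   `AUXOTROPH_PUTATIVE_TRANSPORT`
6. else `NO_KNOWN_ROUTE`

*thiE* is treated as strictly required for a synthesis-based category:
a genome carrying *thiC* and *thiG* but no *thiE* cannot condense the
two moieties and falls through to the transport rules. Salvage genes
(*tenA*, *thiM*) appear in the reported acquisition repertoire but never
change the category — they describe what a cluster can use, not whether
it can synthesize.

"Present in a cluster" means present in at least one member MAG
(presence fraction > 0); the threshold is a parameter
(`presence_threshold`) for users who want a stricter consensus. Because
absence in an incomplete genome is weak evidence, absence-based calls
require at least one high-quality MAG (≥90% completeness, <5%
contamination, with the medium tier at ≥50%/<10%); clusters without one
are flagged `low_completeness` and excluded from community summaries by
default. Community summaries report both cluster-count fractions and
abundance-weighted fractions, since either convention may be wanted; the
auxotroph fraction is 1 minus the prototroph fraction among callable
clusters.

## Annotation curation

Hits are filtered per profile with bit-score cutoffs; profiles missing
from the cutoff table get a default (25 bits) and are logged. Each
protein keeps only its best surviving hit: highest bit score, ties
broken by lower e-value, then lexicographic profile id, making curation
deterministic and idempotent. Manual curation is declarative: an
override list marks proteins as false positives; they stay in the output
with `fp_override=True` and are excluded from genotyping.

Riboswitch adjacency uses the end-to-start gap between a gene and a TDP
riboswitch feature on the same contig, strand-agnostic, with a default
window of 500 bp — operonic TPP riboswitches sit within a few hundred bp
of the regulated gene, and the window is a parameter for other regimes.

## Abundance normalization

RPKM is `count / ((length/1000) · (mapped_reads/1e6))`. Marker
normalization divides each sample by the median RPKM over the supplied
single-copy marker feature set (the marker set is an input, typically
~21 universal profiles; an even count uses the midpoint of the two
central values). The result is copies per genome equivalent, invariant
to per-sample depth and to global per-sample scaling.

Two conventions exist for relating transcripts to the community:
dividing metatranscriptome RPKM by its own marker median
(`mode="marker"`, the default) or by the marker-normalized metagenome
dosage (`mode="metagenome"`). Both are implemented behind an explicit
flag and the mode is recorded in the output metadata. Gene-level
aggregation across ORFs sums per-ORF values at RPKM-or-later states
(equivalent to length-weighted pooling of counts); aggregation of raw
counts is refused because a pooled feature has no single length.

Gene ratios pool summed normalized abundances across samples; a label
with no ORF anywhere contributes zero rather than an error. Per-cluster
*thiC* contributions scale each timepoint's total to 100%; all-zero
timepoints become missing and are flagged.

## LC–MS quantification

Calibration is an OLS line of peak area vs level (≥3 distinct levels,
slope > 0 required), fitted per compound and batch on curves run in the
QC matrix. Detection limits follow the 3σ/10σ convention: LOD = 3× and
LOQ = 10× the sample standard deviation (ddof = 1) of inter-sample
blanks, or of QC responses for the dissolved pool
(`mode="qc_variation"`); "variation" is interpreted as the standard
deviation, the usual reading of the rule.

Internal-standard recovery is estimated per sample as the mean ¹³C-B1
area over the two injections divided by the expected (no-loss) area;
values outside (0, 1.5] flag a failed extraction. Corrected
concentration is the raw back-calculated value divided by the recovery
(per-sample for B1, per-compound reference constants for vitamers,
supplied in config). IS normalization of the B1 response is realized
through this recovery term: normalizing the response and then dividing
by recovery again would double-correct in the linear model, so
calibration is fit on raw areas and the correction is applied once.

A measurement is reported only when both technical injections exceed the
LOD (one missing injection → `single_injection_reject`; more than two is
an error). Values between LOD and LOQ carry the `LOD_to_LOQ` flag and
require an explicit accept annotation — the stand-in for visual
chromatogram inspection — before a concentration is reported; the
default is reject, so unreviewed borderline values never enter
summaries. Outlier handling is likewise declarative (an exclusion list,
flag `outlier_removed`); there is no automatic outlier rejection.
Combined-pool sums treat below-LOD compounds as 0 and log the count.

## Bioassay

The reporter's endpoint yield is modelled as linear in in-tube B1:
`yield = intercept + slope · pM`. The standard curve (default levels
5–75 pM plus negative controls at 0, four replicates each) is fitted by
OLS; a non-positive slope is an assay failure. Inversion reads the
sample mean yield off the line and multiplies by the dilution factor
(default 10, matching the 1:10 sample dilution). Uncertainty combines a
stratified nonparametric bootstrap of the standard-curve points with a
Student-t draw for the sample mean (`ȳ + s/√n · t_{n−1}`): with only
~4 sample replicates, resampling the mean nonparametrically is known to
undercover, while the t component restores near-nominal coverage. The
interval is the percentile interval over (default) 200 draws. Yields
below the fitted intercept are clamped to 0 and flagged
`below_assay_floor`; implied concentrations beyond the calibrated range
are flagged `extrapolated`.

## Correlation screening and biomass

Kendall's tau-b (tie-corrected) is used because environmental series
contain ties. For n ≤ 10 the two-sided p-value is exact: all n!
orderings of one series are enumerated and compared on the concordance
statistic S (the tau-b denominator is permutation-invariant, so ordering
by |S| equals ordering by |tau|); larger n uses the normal
approximation. Missing values are handled pairwise-complete with a
minimum of 3 shared observations. No multiplicity correction is applied;
the significance flag is exactly p < .05. Biomass conversion multiplies
cell counts by 20 fg C per cell and converts units
(10⁶ cells ml⁻¹ → 20 µg C l⁻¹).

## Synthetic generators: what they emulate

The generators reproduce the statistical structure the pipeline must
handle, with deliberate simplifications:

* **Genomes/MAGs.** One contig per genome; genes at typical bacterial
  lengths; TDP riboswitches placed 20–200 bp upstream of linked genes.
  Gene loss under incompleteness is independent Bernoulli per feature —
  the simplest model consistent with a completeness percentage — and
  contamination inserts foreign features at a per-feature rate. Realized
  completeness/contamination are reported, so quality tiers reflect the
  actual draw. Real MAG incompleteness is spatially correlated along
  contigs and contamination is phylogenetically biased; neither is
  modelled, so passing recovery tests bounds performance under random
  loss only.
* **Counts.** Expected count ∝ abundance × gene length × depth, Poisson
  by default (negative-binomial overdispersion available via
  `noise="nb"`, exact expectations via `noise="none"`). Mapping bias,
  multi-mapping and assembly fragmentation are not modelled.
* **LC–MS.** Peak areas are slope × concentration × recovery with
  multiplicative log-normal noise in the mean-1 parameterization
  (µ = −σ²/2), so areas are unbiased and bias found downstream is
  attributable to the estimator, not the generator. Blanks are
  half-normal around zero (scale `blank_sd`, default 50 area units);
  calibration rows carry no extraction loss (QC-matrix convention).
  Matrix effects, carryover and drift are not modelled.
* **Bioassay.** Linear yield response with Gaussian noise; defaults
  (slope 2×10⁴ cells ml⁻¹ pM⁻¹, intercept 5×10⁴ cells ml⁻¹, noise SD
  2×10⁴) put yields at a few 10⁵ cells ml⁻¹ over the 5–75 pM range,
  the scale typical of flow-cytometry reporter counts. Growth kinetics
  and saturation are not modelled (endpoint yields only).

Default study-scale settings: 12 timepoints, depth 10⁶ mapped reads per
sample, 21 markers per genome, completeness range 0.5–1.0, LC–MS noise
CV 15%, and a 24% internal-standard recovery regime for the dissolved
pool, reflecting seasonal coastal sampling with monthly resolution.
Validation experiments run at deliberately desk-scale sizes (e.g. 200
clusters × 3 MAGs for genotype recovery, 100 replicate batches/assays
for unbiasedness and coverage), chosen so the whole suite completes in
well under a minute while keeping Monte-Carlo error small relative to
the tested margins.

## Known limitations

* Genotype calls inherit annotation quality; the cutoff table is a user
  input and no attempt is made to learn cutoffs.
* Eukaryotic genotyping is out of scope (environmental eukaryote genome
  reconstruction is unreliable), as are read mapping, assembly, binning,
  ANI clustering and taxonomy — their outputs are consumed as tables.
* The exact permutation p-value is limited to n ≤ 10 (n! growth); at
  n = 10 a single pair takes a few seconds.
* AmMP, cHET and TMP are carried through flagging but typically sit
  below LOQ and are excluded from pool summaries by default.
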