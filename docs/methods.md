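# Methods

This note documents the statistical procedures implemented in
`streamarch`, the assumptions behind them, the tunable parameters and
their defaults, what the synthetic-data generator does and does not
emulate, and the numerical conventions chosen where several were
defensible.

## Two-tier classification model

The classification follows hierarchy theory: broad-scale (climate,
geology) features constrain the range of attainable reach-scale
(habitat) features, so streams are grouped top-down. Tier I clusters
*samples* — one row per (site, monitoring cycle) — on 8
catchment/watershed climate-geology features; Tier II re-clusters each
Tier-I region's samples on 19 reach-scale habitat features plus
alkalinity and conductivity cycle-medians. Working at the sample level
rather than aggregating repeated surveys is deliberate: habitat surveyed
in an anomalous (e.g. drought) cycle should be visible as a discrepant
label, not averaged away.

K-means assumes spherical, equal-variance clusters on the prepared
matrix and is scale-sensitive; all clustering/ordination matrices are
therefore z-scored per column (sample SD, `ddof=1`), with a switch to
disable. Right-skewed ratio/percentage features (`Cobble`, `Boulder`,
`W.D`, `WS_Area`, `Conductivity`, `Alkalinity`) are first transformed
`log10(x + 1)`; the +1 offset absorbs structural zeros in substrate
percentages. Missing data are handled by complete-case deletion per
analysis matrix — never imputation — and every dropped row is counted in
the matrix's `dropped_report`, reconciled in the run report
(`input = retained + dropped` at every stage).

K-means itself is Lloyd iteration with k-means++ starts, best of
`restarts` runs (default 25), max 100 iterations, deterministic under a
seed; this blunts the usual sensitivity to random centroid selection.

## Choosing k by validity-index voting

For each k in a range (default 2..15) one K-means fit is shared across a
suite of internal validity indices; each index nominates the k that
optimizes it under its documented rule, and the k with most votes is
chosen. Implemented indices and rules (W, B, T are within-, between-,
total sum of squares; d(i,j) Euclidean distances):

| index | definition | rule |
|---|---|---|
| Caliński–Harabasz | (B/(k−1))/(W/(n−k)) | max |
| silhouette | mean (b−a)/max(a,b); 0 for singletons | max |
| Davies–Bouldin | mean over clusters of worst (S_i+S_j)/M_ij | min |
| Dunn | min between-cluster distance / max diameter | max |
| C-index | (S_w − S_min)/(S_max − S_min) over within pairs | min |
| McClain–Rao | mean within-pair dist / mean between-pair dist | min |
| point-biserial | corr(d(i,j), 1{different cluster}) | max |
| Ball–Hall | W/k | largest drop vs k−1 |
| Hartigan | (W_k/W_{k+1} − 1)(n−k−1) | largest drop vs k−1 |
| Krzanowski–Lai | \|DIFF_k\|/\|DIFF_{k+1}\|, DIFF_k = (k−1)^{2/p}W_{k−1} − k^{2/p}W_k | max |
| Ratkowsky–Lance | mean_j sqrt(B_j/T_j) / sqrt(k) | max |
| gap statistic | E*[log W] − log W over B=50 uniform reference sets | smallest k with gap(k) ≥ gap(k+1) − s(k+1) |

"Largest drop" is an elbow rule: the index nominates the k at which its
value falls the most relative to k−1. Difference-based indices abstain
at grid edges; an index with no defined value abstains entirely, and
votes are tallied over non-abstaining indices only. The default voting
set is the eleven closed-form indices; the gap statistic is registered
and usable but opt-in because of its simulation cost. This index set is
a documented subset of the larger suites in common use, so *vote
counts* are not comparable across implementations — the chosen k is the
meaningful output, and any stage's k can be pinned with `fixed_k`.

Ties between equally-voted k go to the smaller k, and a
`parsimony_margin` (default 1) lets a smaller k win when its votes are
within the margin of the maximum. Both reflect the bioassessment goal
of the fewest groups necessary: more groups than distinguishable
assemblages only dilutes reference data.

## Modal site assignment and tree resolution

A site surveyed in several cycles can receive conflicting sample
labels. Each site gets the strict mode of its labels; a tie makes the
site *non-modal*. A classification tree trained on the modally-agreeing
samples (samples whose label equals their site's modal label) then
assigns each non-modal site: every sample of the site is predicted, the
strict mode of predictions is taken, and a residual tie is broken by a
single prediction on the site's feature-wise mean vector.

The tree is binary recursive partitioning on the Gini criterion with
rpart-style stopping: a node splits only if it holds ≥ `min_split`
rows (default 20), both children keep ≥ `min_bucket` rows (default 7),
and the split's impurity decrease, weighted by node fraction and
normalized by the root Gini, is ≥ `complexity` (default 0.01). Split
thresholds are midpoints between adjacent observed values of the chosen
feature; candidate ties break to the earlier feature, then the smaller
threshold; routing is `value < threshold → left`, equality right. Trees
are fitted on transformed (logged) but *unscaled* features so extracted
rule thresholds read in natural units (mm of rainfall, percent
substrate). One rule (a conjunction of threshold terms) is extracted
per leaf; the rules partition the feature space and serve as the
quantitative description of the groups.

Cluster integer labels are arbitrary, so stable names come from data:
Tier-I clusters are ordered by mean annual rainfall (with k=2 the
wetter cluster is "East"); Tier-II clusters are named by archetype
profile scores on raw percentages — rocky = Gravel+Cobble+Boulder+
Bedrock, valley = Silt+Pools, plains = Sand+Runs — the largest score
naming the archetype, with numeric suffixes when two clusters share one
and a config override map for expert renaming. Manual per-site label
overrides are applied last and marked `provenance = override`.

## Between-class analysis and permutation test

BCA is the special case of PCA in which a categorical factor is the
explanatory variable. With column-centred prepared data X (z-scored
upstream by default), class means m_g and frequencies f_g = n_g/n, the
between-class covariance B = Σ_g f_g m_g m_gᵀ is eigen-decomposed; rows
and class means are projected on the eigenvectors. Inertia uses the 1/n
variance convention so between + within = total holds exactly (checked
to 1e-8 in tests). The headline statistic is the between-class inertia
ratio, displayed as a whole percentage. A single class yields ratio 0
and no axes; classes with identical rows are allowed. Axis signs are
fixed by making the largest-magnitude loading positive.

The permutation test shuffles labels uniformly, recomputes the ratio,
and reports `p = (1 + #{ratio* ≥ ratio}) / (n_replicates + 1)` (default
999 replicates): exceedance with add-one smoothing guarantees valid,
never-zero p-values. Under a true null this p is uniform on its
support (verified by a Kolmogorov–Smirnov test in the suite).
Explanatory-power comparison of two partitions (stream groups vs
ecoregions) runs two independent BCAs and permutation tests on the
identical matrix; it is descriptive — no cross-partition test is
defined, matching how such comparisons are reported in practice.

The comparison matrix (`HABCHEM`) is the 19 Tier-II habitat features
plus the 12 post-hoc chemistry medians (31 columns). Chemistry beyond
alkalinity/conductivity is deliberately excluded from group *formation*
(it can be chronically influenced by land use) and used only in this
post-hoc comparison.

## Stressor span screen

A reference grouping must not be an artefact of degradation: if all
sites of a group sit at one end of a stressor gradient, the group
encodes land-use damage, not a natural stream type. The screen computes
unsupervised PCA axes of the 15-feature stressor matrix and, per group
and axis, the overlap between the group's [q10, q90] score interval and
the pooled [q10, q90] interval, `overlap = |intersection| / |pooled|`.
A group is flagged when overlap < `span_threshold` (default 0.5) on any
of the first `span_axes` (default 2) components. The quantitative rule
(quantiles, threshold, axis count) is this package's own
operationalization of the qualitative "each group should span the
stressor range" criterion; the raw intervals are always reported next
to the flags, and groups with fewer than 5 sites are marked
"insufficient n" rather than judged. Quantile intervals on ~tens of
sites are noisy — the screen is calibrated for groups of roughly 30+
sites; smaller groups can flag spuriously.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes,
with known ground truth:

* **Regions.** A bimodal annual-rainfall gradient: West ~ N(700, 120²)
  mm, East ~ N(1150, 120²) mm (planted boundary at the midpoint,
  925 mm). The other Tier-I features carry region shifts capped near
  1.5 SD so rainfall (≈3.8 SD between means) stays the primary regional
  discriminator, as a classification tree on the output confirms.
* **Archetypes.** Within-region habitat profiles via Dirichlet
  compositions (six-part substrate, three-part channel units; e.g.
  Plains substrate concentration (2, 12, 2, 1, 0.5, 0.5) led by Sand,
  Valley led by Silt, Rocky by Gravel/Cobble) and Normal continuous
  features (e.g. width:depth 26/8/15 for Plains/Valley/Rocky). Rocky is
  restricted to the East by default. Compositions close to 100 exactly.
* **Repeated surveys.** `cycles_per_site` (default 2) draws per site
  with per-cycle noise `survey_noise_sd` (a multiplier on each
  feature's within-group SD, default 1).
* **Non-modal sites.** Four times `nonmodal_fraction` (default 0.10) of
  sites are *boundary sites*: each cycle blends the site's habitat
  means toward a partner archetype of its region with a fresh weight in
  (0.1, 0.5), so cycle draws straddle the group boundary while the true
  archetype keeps the larger weight (ground truth stays single-valued).
  Whether a boundary site actually ends up non-modal depends on the
  clustering; at default noise the realized non-modal fraction is about
  half the configured target (≈5% of sites), so the parameter is a
  design target, not an exact rate.
* **Chemistry.** Long-format raw measurements (5 per analyte per
  cycle) around latent region- and mildly archetype-shifted medians;
  conductivity/alkalinity carry a large West offset (+650 µS/cm,
  +160 mg/L). A `chem_missing_fraction` (default 0.15) of (site, cycle)
  cells is omitted entirely, so chemistry-requiring matrices lose rows,
  exercising the explicit "excluded: incomplete chemistry" path.
* **Stressors.** Drawn independently of archetype conditional on
  region; region shifts are mild (cultivation somewhat more common in
  the dry West, hay/pasture in the East) so the dominant stressor axes
  are shared statewide. ICI/CCHEM are Beta(4, 2.5) integrity scores in
  [0, 1]. A `biased_stressor` mode deliberately links crop cover and
  low integrity to one archetype (default Plains) as a planted failure
  the span screen must detect.
* **Pseudo-ecoregions.** 13 labels from quantile bins of rainfall plus
  N(0, 150²) noise — a geography proxy whose bins mix archetypes, the
  scenario in which the planted groups should out-explain the
  ecoregions.

All draws flow through one `numpy.random.default_rng(seed)` (PCG64)
with fixed stage sub-streams; a fixed seed gives bit-identical tables.
A `zero_noise()` preset gives the degenerate well-separated limit (no
survey noise, near point-mass compositions, rainfall SD capped at 40,
Tier-I dispersions scaled by 0.25, no boundary sites, no missing
chemistry) in which the pipeline must recover ground truth exactly with
zero tree-resolved sites.

The numeric defaults reproduce the qualitative contrasts between
archetypes at plausible survey noise; they are generator settings, not
estimates fitted to any monitoring program's data. What passing the
synthetic tests shows is that the machinery — voting, modal/tree
assignment, BCA, screen — recovers structure of the assumed form at
realistic noise; it does not show that real streams have this
structure. Known non-emulated features of real data: no spatial stream
networks or spatial autocorrelation, no temporal autocorrelation
between cycles beyond shared site means, no correlated missingness, no
measurement-protocol drift across two decades, and Gaussian/Dirichlet
shapes rather than empirical distributions.

## Numerical conventions and degenerate inputs

* Medians of even-count measurement sets are the midpoint of the two
  central order statistics.
* A constant column under z-scoring keeps scale 1 with a warning, not
  an error; a matrix with zero complete-case rows is an error.
* k-means requires k ≤ rows and finite values; k = n gives zero
  within-SS; degenerate Tier-II clusterings (zero between-SS) are
  logged as warnings.
* Silhouette uses the s = 0 convention for singleton clusters; Dunn is
  undefined (abstains) when all diameters are zero.
* Eigenvalues of the between-class covariance are clipped at zero and
  sorted descending; axis percentages sum to 100 when between-inertia
  is positive.
* Tree training on a single class returns a stump predicting that
  class; rule extraction on a stump yields one rule with an empty
  conjunction.
* Run directories are named by an 8-hex-digit SHA-256 of the resolved
  configuration, which is itself always serialized alongside outputs.

## Parameters that matter

| parameter | default | units / range | why |
|---|---|---|---|
| `restarts` | 25 | fits | k-means initialization robustness |
| `k_range` | 2..15 | groups | voting grid |
| `parsimony_margin` | 1 | votes | fewest-groups preference |
| `fixed_k` | {tier1: 2} | per stage | pin k where the design dictates it |
| `min_split` / `min_bucket` / `complexity` | 20 / 7 / 0.01 | rows, rows, fraction | rpart-style tree stopping |
| `n_permutations` | 999 | replicates | p-value resolution 1/1000 |
| `span_threshold` / `span_axes` | 0.5 / 2 | fraction, axes | span-screen strictness |
| `survey_noise_sd` | 1.0 | within-group SD multiples | per-cycle habitat noise |
| `nonmodal_fraction` | 0.10 | fraction of sites | boundary-site design target |
| `chem_missing_fraction` | 0.15 | fraction of samples | chemistry completeness |

## Limitations

* The validity-index suite is a documented subset of the 30-index
  suites in wide use; chosen k agrees in the tested regimes but vote
  tallies will differ between implementations.
* The span screen's 0.5/2-axes rule is a pragmatic operationalization;
  it is exposed in config and reported with raw intervals so users can
  apply their own judgment, and it is underpowered below ~30 sites per
  group.
* Archetype naming by profile scores assumes the three planted
  profiles; novel stream types would need the override map.
* Boundary sites blur the subgroup ground truth by construction, so
  subgroup recovery saturates below ARI 1 at default noise (median
  ≈0.91 over 20 seeds); the zero-noise limit recovers exactly.
* No spatial analysis: assignments are independent across sites, and
  no smoothing or reassignment of boundary sites between groups is
  attempted.
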