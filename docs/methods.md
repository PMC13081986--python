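# Methods

This note documents the models, algorithms, parameter choices, and known
limitations of morphoscreen, in the order the pipeline runs them.

## SWC model and reconstruction QC

A reconstruction is a rooted tree of 3D nodes in the de-facto SWC dialect
(codes 1 = soma, 2 = axon, 3 = basal dendrite, 4 = apical dendrite; parent
−1 marks a root; coordinates in μm). The parser tolerates children appearing
before parents and rejects duplicate ids, unresolved parents, and cycles
with the offending line number. Axonal nodes are carried through I/O but
ignored by all dendritic metrics.

QC addresses three reconstruction artifacts:

* **Spurious short branches.** Terminal branches with path length < 1 μm
  (configurable) are pruned *iteratively*: removing a spur can expose a new
  sub-threshold terminal, so pruning runs to a fixed point. This makes
  `qc_repair` idempotent, which the tests assert.
* **Over-branched nodes** (> 2 daughters) are reported by default and only
  resolved under a flag (the two daughters closest to the node are moved
  onto an inserted zero-length intermediate, repeated until binary).
  Automatic resolution is lossy, so reporting is the default.
* **Disconnected components** are either reattached to the nearest
  main-component node within a tolerance (default 10 μm) or dropped, behind
  a flag — field practice varies and no single behavior is canonical.
  Pruning runs once before component handling (so strays cannot attach to a
  spur) and once after (reattachment can create new short terminals).

## Compartment segmentation

Basal dendrites are all type-3 subtrees. Within the apical subtree the trunk
is traced from the apical root by always descending into the daughter with
the largest total subtree path length. The **trunk terminus** is the first
bifurcation at which the second-largest daughter subtree reaches at least
`trunk_split_ratio` (default 0.33) of the largest — the signature of the
tuft's balanced split — otherwise the trunk runs to the end of the
maximal-length path. Tuft nodes are the strict descendants of the terminus;
obliques are the apical side subtrees branching off trunk-interior nodes.
The rule presumes pyramidal proportions (obliques short relative to the
remaining apical tree); on arbors violating that premise the terminus can
land at an oblique junction. A reconstruction without an apical subtree
yields empty trunk/oblique/tuft with a warning, not an error.

Labels partition the dendritic nodes, and each edge belongs to its child
node's compartment, so compartment path lengths sum exactly to the total
dendritic length (asserted to 1e-9 relative).

## Morphometric panel

Each metric is computed per compartment (basal, oblique, tuft, global, plus
trunk length) where sensible; metrics inapplicable to a neuron (tuft metrics
with an empty tuft) are missing, never zero. Conventions:

* **Branch** = maximal unbranched path of the compartment-restricted
  subgraph. The global branch count is the sum over compartments (the trunk
  path counts once); junctions with another compartment do not subdivide a
  branch. This convention is brute-force checkable by path enumeration and
  keeps the global/compartment bookkeeping additive.
* **Extents** (height/width/depth) are axis-aligned coordinate ranges;
  "height" is the configured cortical-depth axis (default y — the frame of
  deposited reconstructions is not standardized, so this is explicit
  config). Radial alternatives exist via max Euclidean distance from soma.
* **Bifurcation angle** is measured between vectors from a branch point to
  its immediate children (an endpoint-vector variant is available).
* **Sholl profiles** count crossings of concentric spheres (default step
  10 μm) centred on the soma. Each edge is split at its point of minimal
  distance to the soma so each piece is radially monotone; on a monotone
  piece a shell at radius r is crossed once iff min < r ≤ max (half-open, so
  a node sitting exactly on a sphere credits the inbound edge exactly once).
  This equals the endpoints-straddle rule on monotone edges and additionally
  counts genuine double crossings; it is verified against a 0.01 μm
  edge-sampling oracle. Summaries: peak radius (smallest maximiser),
  intersection-weighted centroid radius, and dispersion (weighted SD).
* Derived summary-statistic variants (min/median/max/SD of branch lengths)
  are computed but tagged `derived_variant` and excluded by
  `drop_derived_variants` before module detection.

Spine density is length-weighted: total spines / total crop length over
≥ 25 μm dendrite crops.

## Metric de-redundancy and typing

Missing values are imputed by k-NN (mean of the k nearest neurons on
z-scored metrics, k = 5) for module detection, or by column means before
k-means and NMF. Metrics are clustered by average linkage on distance
1 − |r|; absolute correlation is used because redundancy is sign-agnostic
(module structure is therefore invariant to metric sign flips). The adaptive
cut is a documented simplification of dynamic hybrid tree cutting: cut at
the largest gap in sorted merge heights, then merge clusters below the
minimum size (3) into their most-correlated module. Module separation is
scored as mean within-module |r| − mean between-module |r| and tested by
permuting each metric column independently
(p = (1 + #{null ≥ observed}) / (n_perm + 1)).

Panel selection takes the highest-preference metric per module, then fills
to the target size greedily minimizing the maximum within-panel |r| (ties
alphabetical). Subtypes come from k-means (k-means++ init, best of 25
restarts, seeded); reference type mapping uses an RBF-kernel SVM on scaled
metrics with strict feature-name alignment. Heatmap ordering ranks subtype
blocks by mean tuft branch number (descending), sorts neurons within a block
by mean z over that subtype's signature metrics, orders metric rows by
hierarchical clustering on 1 − r, and clips z-scores to ±3 with missing
values retained.

## Differential morphometry

Per metric, a random-intercept linear mixed model
`metric ~ perturbation + (1 | brain)` is fit by REML using a dedicated
profiled solver: the variance ratio λ = σ²_brain/σ²_resid is profiled out
(per-brain covariance I + λJ inverts in closed form), leaving a 1-D bounded
search. The solver is validated against statsmodels MixedLM in the tests
and reaches equal or higher restricted likelihood at ~100× the speed, which
is what makes the calibration simulations (thousands of fits) practical.
Wald t-tests use containment degrees of freedom, df = n_brains − rank(X),
which coincides with the Satterthwaite estimate on balanced nested designs;
simulated null screens put the empirical type-I error at ≈ 0.05.

Effect scale: the default reports the coefficient divided by the model's
total SD √(σ²_brain + σ²_resid) — a standardized mean difference that stays
unbiased under large effects. Z-scoring the metric over the whole cohort
first (available as `standardize="cohort"`) inflates the denominator by the
effect itself (≈ √(1 + d²/4) for two balanced arms, ~11% at d = 1), which
would bias recovery; the model-based scale avoids this while matching the
cohort z-score under the null. Raw units are available with
`standardize="none"`. Metrics with zero cohort variance, or residual
variance numerically zero relative to it, are skipped rather than reported
with meaningless standardized effects. When a group is confined to a single
brain that carries no other group, the brain variance is confounded with
the group effect and the fit falls back to OLS with a warning.

BH adjustment is applied across metrics within each contrast (cell type ×
perturbation family). Sholl radius-wise comparisons use two-sided Wilcoxon
rank-sum tests per radius (neurons as replicates, shorter profiles
zero-padded) with BH across radii. NMF metric modules z-score each metric,
shift it by its minimum to non-negativity (offset recorded), and run seeded
multiplicative updates (best of 5 restarts); the Frobenius objective is
non-increasing by construction and asserted over traces. Spine densities
use one-way ANOVA with Tukey HSD.

## Expression screen

Cell QC applies the screen gates as strict exclusions (boundary cells are
retained): < 250 detected genes, doublet score > 1.2, > 30,000 UMIs, > 2%
mitochondrial UMIs, or assignment to multiple perturbations; each filter's
exclusion count is reported separately since a cell can fail several.

Guide assignment consumes per-cell raw guide calls (the upstream caller is
out of scope): one called guide → singlet of that guide's vector; exactly
the two guides of one vector → singlet of that vector; any other multi-guide
set → multiplet; none → unassigned. The chance that an unrelated two-guide
cell happens to show a matched pair is
Σ_pairs 2 f_i f_j / Σ_{i≠j} f_i f_j over guide frequencies f — empirical
single-guide frequencies by default, uniform as an option (reducing to
1/(G−1)); both are cross-checked against Monte-Carlo and enumeration.

Differential expression fits a per-gene NB2 GLM with log link and log
size-factor offsets (median-of-ratios over genes positive in all units).
Dispersion is estimated by Cox–Reid adjusted profile maximum likelihood
(the −½ log|X′WX| adjustment removes the small-sample downward bias that
otherwise inflates Wald statistics at 6v6 samples), alternating with GLM
refits; a method-of-moments estimate is the fallback. Wald p-values use a t
reference with residual df and BH across genes. No empirical-Bayes
dispersion shrinkage is applied (a deliberate divergence from
DESeq2/glmGamPoi: the estimator stays self-contained and
property-verifiable); a tiny-fixture cross-check against an independent NB
MLE route guards the implementation. Cell-level gates (cells per
perturbation, detection fraction) are parameters. Non-converged genes are
flagged with p missing.

Temporal signatures take two effect tables (P14 vs P10, P28 vs P14):
eligibility requires early p_adj < 0.05 and log2FC > 0.3; classes use the
late log2FC with strict inequalities (> 0.3 Progressing, < −0.3 Transient,
between them Stabilizing). Genes exactly on a boundary belong to no class
and are reported as `Boundary` — the thresholds are printed as strict, so
forcing boundary genes into a class would invent behavior. Trajectories are
scaled per gene as (x − mean at P14)/SD across samples (zero-SD genes become
missing with a warning) and smoothed by tricube-weighted local linear
regression with span 0.3 (bandwidth = distance to the ⌈span·n⌉-th nearest
point; spans above 1 inflate the bandwidth so the fit approaches the global
least-squares line, the property the tests assert). Risk-gene enrichment is
a one-sided Fisher exact test per signature × gene set over the
filter-passing universe, BH across tests.

## Cross-modality concordance

TWI (transcriptome/morphome-wide impact) is the method-of-moments estimator
max(0, mean(effect² − se²)): since E[estimate²] = effect² + se², the mean of
(estimate² − se²) is unbiased for the mean squared true effect; flooring at
zero handles null contrasts. It scales quadratically (twi(c·e, c·se) =
c²·twi) and requires SEs by contract.

Energy distances use the V-statistic convention (all ordered pairs including
self-pairs), so E(A, A) = 0 exactly; with the squared-Euclidean kernel the
finite-sample identity E = 2‖mean(A) − mean(B)‖² holds exactly and the
plain-Euclidean kernel (a metric of negative type, hence non-negative) is
the option. Group matrices optionally batch-centre features first
(location–scale standardization per batch restoring pooled moments — the
empirical-Bayes shrinkage of full ComBat is not implemented) and reduce to
principal components (default 25 for expression; morphology uses the full
metric space); groups below a minimum size (default 5) are excluded and
reported. Cross-modality agreement is the Pearson r of per-perturbation
impact, with percent-of-maximum normalization per modality for display.

## Synthetic data

The generators define the study conditions and carry ground truth:

* **Arbors**: soma at the origin; basal roots tilted 50° below horizontal
  with binary branching; a straight trunk along the depth axis with evenly
  spaced oblique junctions; a balanced binary tuft at the top. Defaults
  (3 basal roots at depth 2, 25 μm segments, 180 μm trunk, 3 obliques,
  tuft depth 2, 40° branch angles, 1 μm positional jitter) give ~35-node
  arbors with pyramidal proportions under which the trunk-terminus rule
  recovers the constructed labels exactly at zero jitter. The construction
  record (branch counts, compartment lengths, extents) is computed by
  direct summation over the node table, independent of the metric engine.
* **Screen cohorts**: each of four metric knobs (basal height, tuft height,
  trunk length, oblique length) drives exactly one compartment's segment
  lengths through a per-neuron multiplier 1 + 0.15·t, where the latent
  trait t = effect + brain + residual with brain SD 0.3 and residual SD
  0.95 (total ≈ 1, so injected effects are in SD units and map one-to-one
  onto the driven metric). Effects are geometric — the trees are rescaled,
  never the metric table — so recovery exercises the full measurement path.
  Defaults: 6 brains × 10 neurons per arm, matching a realistic per-arm
  yield for in-vivo screens.
* **Counts**: NB via gamma-Poisson with mean = baseline · 2^log2FC ·
  exp(batch shift) and Var = μ + αμ² (α = 0 gives exact Poisson);
  pseudobulk defaults 6 samples per arm, baseline mean 50, dispersion 0.1.
* **Guides**: each cell carries one true dual-guide vector; both guides are
  called with the co-detection probability, a contaminating guide is added
  with the contamination probability.
* **Developmental series**: three ages × n samples of log2 expression;
  non-Flat genes rise +0.6 early; late change +0.6/0/−0.6 by class. At zero
  noise the derived effect tables use a zero-variance convention (p = 0
  when means differ exactly, else 1) so noiseless recovery is well defined.

What the generators do **not** emulate: imaging noise and tracing errors
beyond parametric jitter, realistic metric correlation structure (metrics
covary only through the shared knobs and geometry), cell-type mixtures,
UMI saturation, or guide-dependent expression knockdown. Passing tests
therefore demonstrate correctness of the estimators under the stated
models, not robustness to every failure mode of real data.

## Problem sizes and numerical choices

The simulation studies run at deliberately chosen sizes: 100 trees for the
oracle sweeps, 200 null screens of 36 metrics for mixed-model calibration,
2000 genes for DE null calibration, 20 seeds for demo power — large enough
for the asserted tolerances (binomial SE on a 0.05 rate over 7200 tests is
≈ 0.003) while keeping a full run on one CPU in minutes. Ties in k-means
and panel selection break deterministically (seeded restarts, alphabetical
order); Sholl grids end at the largest shell the arbor reaches; REML λ is
searched on a log grid in [1e-10, 1e6] with an explicit λ = 0 boundary
check.

## Known limitations

* The metric registry covers every metric named in the analyses plus an
  extension point; it does not reproduce any particular 170-metric
  catalogue.
* Containment df slightly differs from Satterthwaite on unbalanced designs;
  with few brains and strong imbalance p-values can be mildly conservative.
* The adaptive tree cut is a simplification of dynamicTreeCut's hybrid
  mode; parity is at the planted-structure-recovery level, not bit-for-bit.
* TWI approximates a deconvolution-based impact summary by its first two
  moments; it estimates the mean squared effect, not the full effect-size
  distribution.
* The NB GLM does not share dispersion information across genes; at very
  low counts its power is below that of shrinkage-based estimators.
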