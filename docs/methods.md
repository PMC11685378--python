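# Methods

## The model

The package treats a subject's brain as a **multiplex network**: three
weighted, undirected graphs (layers) over the same ordered node set, with
one-to-one node correspondence and no interlayer edges.  The layers encode
complementary views of the same anatomy:

* **Morphological covariance (MC).**  Regional gray-matter volumes are
  regressed on age, sex and total intracranial volume with coefficients
  estimated *in healthy controls only*, so that disease-related atrophy is
  not absorbed into the covariate model.  Each subject's residuals are
  scaled by the SD of the HC residuals, giving per-region z-scores of
  deviation from the healthy norm.  The edge weight
  `w_ij = exp(-(z_i - z_j)^2)` is near 1 when two regions deviate from the
  norm *together* and decays rapidly as their deviations diverge.  The
  formula yields 1 at `i = j`; the diagonal is nevertheless set to 0
  because self-edges contribute nothing meaningful to strength or coreness.
* **Structural connectivity (SC).**  Streamline-weight matrices are
  compressed with `log10(1 + w)`.  The `1 +` variant is chosen (over a bare
  `log10`) because streamline weights can be zero or below 1; it preserves
  zeros, nonnegativity and rank order while serving the same purpose of
  taming differences across orders of magnitude.
* **Functional connectivity (FC).**  BOLD correlation matrices are Fisher
  z-transformed and absolutized, `w = |atanh(r)|`, since anti-correlations
  carry information that plain positive thresholding would discard.

Before assembly, every layer is divided by its **largest singular value**
(spectral norm), so that no layer dominates the combined richness simply
through its average weight scale.  Among the possible readings of
"SVD normalization" we implement this spectral-norm variant; it is
idempotent, preserves rank order of edges within a layer, and makes the
layer scales exactly commensurate (top singular value 1).

## Core-periphery profiling

For each density `d` in a grid (default `0.01, 0.02, ..., 1.00`; the grid
is a tunable of the sweep, and coreness values are exact multiples of
`1/len(grid)`), each layer independently keeps its
`m = round(d * N(N-1)/2)` strongest edges, weights retained.  Node
**multiplex richness** is `mu_i = sum_a c_a * s_i^a`, the per-layer node
strengths combined with coefficients `c_a >= 0` (default 0.5 per layer,
expressing no prior preference among layers; a single layer with unit
coefficient gives the single-layer variant).  Nodes are ranked by
decreasing `mu` and the **richer-neighbor strength** `mu_plus_i` is the
combined strength of node `i` restricted to nodes ranked above it.  The
**rich core** is ranks `1..r*`, where `r*` maximizes `mu_plus`; an
edgeless graph has an empty core.

Tie rules are fixed and deterministic: edges tied at a density cutoff enter
in ascending `(i, j)` lexicographic order; richness ties rank the lower
node index first; boundary ties take the smallest rank (smallest core).
The sweep is implemented incrementally — edges are inserted in exactly the
order the per-density filter would select them — which makes a
114-node x 100-density profile cost ~30 ms; a test asserts bitwise
equivalence with explicit per-density filtering.

**Coreness** is the fraction of densities at which a node is in the core.
The **coreness disruption index** `kappa` is the OLS slope (with intercept)
of `subject_coreness - reference` on `reference`, where the reference is
the HC group's mean coreness profile.  `kappa = 0` for a subject identical
to the reference, `-1` for a subject with no core structure at all, and
negative values mean high-coreness nodes lose disproportionally — the
signature of a targeted attack.  Group-level `kappa` regresses the group's
*mean* coreness profile on the reference.  `kappa` is computed on raw
coreness; confounder adjustment (below) is applied to `kappa` afterwards.

## Harmonization

Multi-site features (regional volumes; vectorized SC/FC edge weights) are
harmonized with ComBat: per-feature location/scale site effects estimated
after standardizing on a grand model that includes age, sex and disease
group (so those associations are preserved), optionally shrunk with the
parametric empirical-Bayes priors (normal for locations, inverse-gamma for
scales, method-of-moments hyperparameters, iterative conditional
posteriors).  The implementation follows the standard reference algorithm
and matches `sva::ComBat` to ~1e-14 on a shared fixture (tested via
Rscript).  Volumes are harmonized *before* z-scoring/MC construction;
SC/FC edges after their transforms but *before* spectral normalization —
the stage at which values are closest to Gaussian and site effects are
plausibly location/scale.  Harmonized edge weights that land below zero
are clamped to zero (counted and logged).  A single-site cohort is passed
through as an exact identity, and features constant across subjects are
left untouched.

## Statistics

Confounders (age, sex) are removed from `kappa` and nodal coreness by
nuisance regression with HC-estimated weights, then standardized against
the HC corrected values: `z = (corrected - HC mean) / HC SD`.  The SD
convention is `ddof = 1` throughout (volumes and adjusted scores); nodes
whose coreness is constant across HC cannot be standardized and are
centered only (logged).

Group differences use two-sided permutation tests with the pooled-variance
t statistic: exhaustive enumeration when the number of group assignments
is at most 20,000 (p can then be an exact rational, never 0), otherwise
10,000 sampled assignments by default with the `(hits + 1)/(B + 1)`
convention.  Nodal tests share one permutation set across nodes and are
corrected with Benjamini-Hochberg at `q = 0.05` within the node family.
Effect sizes are Hedges' g (pooled-SD Cohen's d times
`J = 1 - 3/(4(n1+n2) - 9)`) with percentile bootstrap CIs over per-group
resampling (5000 resamples by default).  Phenotype effects use one-way
ANOVA with Tukey HSD post hoc.  Clinical dichotomies follow the standard
cutoffs: EDSS >= 4 (inclusive) for high disability, SDMT z < -1.5 (strict)
for impaired processing speed; subjects missing a score are excluded from
that comparison only (complete-case per analysis).

## Prediction

Disease status (HC vs MS), disability level and IPS impairment are
predicted from six features: `kappa` in the multiplex and the three
single-layer domains, age/sex-adjusted BPF z-scores, and `log(1 + TLV)`
(log because lesion volumes are strongly right-skewed; controls, having no
lesions, enter with 0).  Decision trees with per-split feature subsampling
are bagged; tree count, minimum leaf size and features-per-split are tuned
by a seeded random search over a documented grid minimizing 10-fold
stratified CV error (folds are reduced to the smallest class count when a
class is small).  Performance is out-of-bag accuracy; predictor relevance
is OOB permutation importance — the mean per-tree OOB accuracy drop when a
feature is shuffled within the tree's out-of-bag samples (repeats and
seeds fixed, so reports are bit-reproducible).

## The synthetic cohort generator

No public dataset provides per-subject MC/SC/FC matrices with clinical
annotation, so the generator plants exactly the structure the analysis is
designed to detect, and its defaults are the study conditions of every
recovery test:

* a core of 20 of 114 nodes; SC edge weights gamma-distributed with block
  means 40/12/4 (core-core/core-periphery/periphery-periphery), FC block
  correlations 0.5/0.25/0.10 with Gaussian jitter clipped into (-0.97,
  0.97) — clipping keeps draws in the valid correlation range directly, so
  no projection step is needed; downstream transforms use entries
  elementwise and do not require positive semidefiniteness;
* volumes linear in age (-0.02 ml/yr), sex (+0.5 ml) and TIV (+0.003
  ml/ml) with 0.4 ml node noise;
* a targeted attack for patients: every edge `(i, j)` scaled by
  `(1 - delta * max(a_i, a_j))` with node core affinity `a`, plus
  fractional core-node atrophy `0.3 * delta`.  Phenotype means of `delta`
  are 0.15 (CIS), 0.30 (RRMS), 0.55 (SPMS), 0.45 (PPMS) — ordered with
  PPMS intermediate, mirroring the clinical staging the analysis should
  recover;
* clinical scores monotone in `delta` (EDSS `2 + 5*delta` rounded to 0.5
  steps; SDMT z `-2.5*delta`; BPF decreasing; lesion volume increasing),
  with noise scales chosen so the links are present but far from
  deterministic — only orderings and signs are asserted downstream;
* optional per-site location/scale effects applied last (volumes additive
  + multiplicative; SC edges multiplicative, i.e. additive after the log
  transform; FC correlations shifted), matching where ComBat operates.

What the generator does *not* emulate: spatial autocorrelation of real
parcellations, non-Gaussian volume distributions, realistic
structure-function coupling, scanner-specific noise spectra, or
longitudinal change.  Passing tests therefore demonstrate that the
*estimators* recover planted structure under the stated model, not that
the pipeline reproduces any particular clinical effect size.

## Problem sizes and numerical choices

Recovery and calibration experiments run at: 114 nodes / 20 core nodes /
100-density grid (planted-core recovery, 20 seeds); 30 patients per attack
level over `delta in {0, 0.2, 0.4, 0.6}` with 40 HC; 2000 null simulations
at n = 30/30 for permutation-test calibration; 1000 simulations of 114
null nodes for FDR control; 500 simulations at n = 100/100 for effect-size
recovery; 50 two-site runs at n = 100/site for harmonization; cohorts of
40 HC / 60-120 MS for the prediction and phenotype analyses.  Edge counts
use round-half-up for platform independence.  Exactly-fitting nuisance
models are detected with a `sqrt(eps)`-scaled residual floor and rejected
as degenerate.  Zero-variance covariates are dropped from nuisance designs
(absorbed by the intercept) with a warning; genuinely collinear designs
raise.

## Known limitations

* The rich-core boundary is a global argmax; near-tied `mu_plus` profiles
  can flip core membership under small perturbations.  Coreness (the sweep
  average) smooths most of this, but individual-density cores are fragile.
* ComBat assumes location/scale site effects on roughly Gaussian features;
  heavy-tailed edge distributions violate this, and the clamp step is a
  pragmatic repair, not a model.
* OOB permutation importance splits credit between correlated features
  (e.g. multiplex kappa and its single-layer parents); importances are
  comparative, not causal attributions.
* With sampled permutations the smallest attainable p is `1/(B+1)`;
  BH at small q on few nodes is conservative in that regime.
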