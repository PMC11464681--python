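# Methods

This note documents the models implemented in `vwm_errnet`, the choices made
where the design was genuinely open, and what the synthetic-data experiments
do and do not establish.

## 1. Behavioral model: three-component mixture of circular errors

### Response space

Delayed-estimation responses live on circles: orientation is 180°-periodic,
location on a ring is 360°-periodic. Both are mapped to a common transformed
circle with 0° → 0 and ±90° → ±π radians (±1 in "πrad" units). Location
responses are first checked on the physical 360° ring: a response more than
90° from the target would indicate an uncued-hemifield ("hemifield-swap")
response; such trials are counted and rejected rather than folded, after
which location is treated identically to orientation. Nontarget offsets are
folded onto the same transformed circle.

The circular SD is reported as σ_vM = √(−2 ln A(κ)) with A(κ) = I₁(κ)/I₀(κ),
in **radians on the transformed circle**. On this scale an orientation-task
σ_vM of 0.74 corresponds to ≈ 21° of orientation space, the familiar
magnitude for delayed-estimation data; this is the scale on which all group
means in this package are stated.

### Likelihood

For a trial with error e and nontarget offsets δ₁…δ_m (m = 2 by default:
three items per cued hemifield, one probed),

    p(e) = P_T·φ_κ(e) + (P_NT/m)·Σᵢ φ_κ(e − δᵢ) + P_G/2π,

where φ_κ is the von Mises density with mean 0 and concentration κ shared by
all bell-shaped components. P_T, P_NT and P_G are the probabilities of
reporting the target, a nontarget (swap/misbinding), and guessing.

### Estimation

Maximum likelihood via EM:

* **E-step** — responsibilities over the 2 + m components.
* **M-step** — weights are mean responsibilities; κ is updated from the
  cosine moment of responsibility-weighted deviations (component means are
  fixed at the target/nontarget values) via Newton inversion of A(κ) from
  the Banerjee closed-form start.
* **Starts** — one moment-based start (κ from the resultant length of all
  errors) plus five stratified random simplex/κ draws; the best final
  log-likelihood wins. Mixture likelihoods here are multimodal enough that a
  single start is not reliable.
* **Convergence** — |Δ log L| < 1e-8 or 500 iterations, followed by a
  deterministic Nelder-Mead polish on the unconstrained parametrisation
  (weight log-ratios, log κ). The polish matters: EM's per-iteration gain
  decays geometrically on the weakly identified ridge between a broad von
  Mises and the uniform component, and plain EM can stop ~1e-2 log-units
  short of the optimum. EM+polish matches a multistart direct optimiser to
  < 1e-6 log-units on small datasets (asserted in the test suite).
* **Degenerate data** — when the fitted model beats the closed-form
  pure-guess log-likelihood, −n·ln 2π, by less than 2 (about the chance gain
  of three free parameters), the weight split between a κ→0 von Mises and
  the uniform is arbitrary; the estimator reports the parsimonious
  pure-guess solution (P_G = 1, κ = 0, σ_vM undefined). κ is capped at 1e4.

### Screening and comparisons

Participants whose error distribution cannot be distinguished from uniform
(Kolmogorov–Smirnov test, p ≥ 0.05 in either task) are flagged for
exclusion — data indistinguishable from guessing carry no memory signal.
Between-task comparisons use paired t-tests on σ_vM, P_T, P_NT, P_G with
Bonferroni adjustment (×4, capped at 1).

### Known finite-sample behavior

At the orientation-task operating point (κ ≈ 2.5, 240 trials, P_G ≈ 0.36),
maximum-likelihood estimates are biased: the broad von Mises absorbs part of
the uniform mass (group-recovered P_G low by ≈ 0.03–0.05, P_T high by
≈ 0.02, σ_vM high by ≈ 0.01–0.03). This is a property of ML in this regime,
not of the implementation — EM+polish provably attains the likelihood
optimum. At the location-task operating point (κ ≈ 6.8) biases are an order
of magnitude smaller. Recovery experiments must be read with this in mind.

## 2. Synthetic behavioral generator

Per subject, feature values (target, nontargets) are uniform on (−90°, 90°];
responses follow the mixture above. Between-subject variation:

* probability triplets ~ Dirichlet centred on the group means, with the
  concentration moment-matched (least squares over the three components) to
  the between-subject SDs. A Dirichlet preserves the group means exactly on
  the simplex; independent truncated normals with renormalisation do not
  (truncation at 0 alone would shift a mean of 0.03 to ≈ 0.08).
* σ_vM ~ truncated normal (bounds 0.05–2.5 rad), converted to κ.

Default conditions (the documented study-scale operating points): 72
subjects × 240 trials × 2 nontargets per task; orientation group means
(P_T, P_NT, P_G, σ_vM) = (0.61, 0.03, 0.36, 0.74); location =
(0.64, 0.34, 0.02, 0.40); between-subject SDs are the reported standard
errors scaled by √72 (orientation: 0.17, 0.085, 0.25, 0.25; location: 0.085
throughout). Timeout/no-response trials are not modelled, and no minimum
angular separation is imposed between display items.

What the generator does **not** emulate: sequential effects across trials,
response-time structure, oblique-orientation anisotropies, or any
stimulus-display constraint beyond item counts. Recovery results therefore
validate the estimation chain, not the full psychophysics of real data.

## 3. Connectivity model and network identification

Per-subject ROI×ROI connectivity is the Fisher-transformed Pearson
correlation of (denoised) time series; |r| is clipped at 1−1e-12 with a
warning, and the diagonal is undefined (NaN). The group matrix is the
across-subject mean **on the z scale** (variance-stabilised averaging).

The synthetic generator draws subject time series from a block-structured
Gaussian: correlation `within_corr` inside planted communities,
`between_corr` elsewhere (positive-semidefiniteness is checked and the
offending eigenvalue reported otherwise). Defaults: 37 ROIs in six
communities of sizes 3/11/4/4/10/5, within 0.5, between 0.1, 500
timepoints, 40 subjects. The shipped 37-ROI table (labels + MNI coordinates)
is a synthetic stand-in drafted from the anatomical composition of the six
networks; coordinates enter only the 5%-weighted anatomical term below.

### Hybrid distance and clustering

ROI pairs are compared by

    d(p,q) = r · Σⱼ (F̄_pj − F̄_qj)² + (1−r) · Σₖ (C_pk − C_qk)²,

with F̄ the group-mean FC profiles (the two undefined self-columns p, q are
excluded from the sum), C the MNI centroids, and r = 0.95. The functional
and anatomical squared-distance matrices are **each divided by their own
maximum** before the weighted sum; without a common scale, mm² distances
(~10⁴) would swamp z² distances (~10⁰) regardless of r. This scaling is a
package choice — the distance formula fixes the weights but not the units —
and is the main caveat when comparing with other toolboxes.

Agglomeration is complete linkage (inter-cluster distance = maximum member
pair distance), implemented directly with a deterministic tie rule (lowest
(id-a, id-b) pair wins) and cross-checked against an independent
implementation in the tests. Merge heights are monotone.

### Choosing the cut

The partition is read off at the **largest relative jump** between
successive merge heights (h[i+1]/h[i]), not the largest absolute gap.
Complete-linkage heights grow with cluster size, so on planted data the
absolute gap usually peaks at the final merges and returns 2–3 clusters;
the relative jump between the last within-community merge (noise-scale
height) and the first between-community merge is orders of magnitude larger
and identifies the planted partition essentially always. A degenerate
height profile (no usable jump) falls back to a user-supplied cluster count
with a warning; a fixed `n_clusters` bypasses the elbow entirely.

### Cluster-level statistics and features

For every network pair (including self-pairs), the subject × connection
matrix enters a multivariate one-sample test of zero mean connectivity:
Hotelling's T² when subjects exceed connections by ≥ 2, otherwise a max-|t|
omnibus statistic calibrated by sign-flip permutation (the cited parametric
method is under-determined in that regime). Benjamini–Hochberg FDR is
applied across pairs (α = 0.05); individual connections are listed at
uncorrected p < 0.05 as post hoc description. Per-subject features are the
plain averages FC_W(N) (within-network pairs; undefined for singletons) and
FC_B(N,N′) (all cross pairs), with no thresholding — the pair-count-weighted
mean of all features equals the off-diagonal grand mean (asserted).

## 4. Brain–behavior association

Each behavioral measure is modelled as

    y_st = β₀ + β_task·task + Σ β_f·FC_f + Σ β_{t×f}·task·FC_f + b_s + ε_st

with task coded 0 = orientation (reference), 1 = location, a subject random
intercept b_s, and FC features z-scored across subjects (coefficients are
response units per SD of connectivity; the printed effect magnitudes are
consistent with this standardisation). Responses are modelled untransformed.

* **Estimation** — REML via statsmodels MixedLM; ML refits feed
  likelihood-ratio tests.
* **Inference** — Satterthwaite denominator df computed from the REML
  information matrix of (σ²_subject, σ²_residual): for contrast c,
  df = 2·f²/(gᵀAg) with f = Var(cᵀβ̂), g its gradient in the variance
  components and A their asymptotic covariance. In the balanced paired
  design this reproduces the closed-form paired-t df (n−1), and it
  approaches the OLS df when the random-intercept variance vanishes.
* **Step-up selection** — candidates are the 21 FC main effects and their
  task interactions (an interaction proposed without its main effect is a
  joint two-term addition, and main effects are retained with significant
  interactions). Each round ranks candidate augmented models by REML
  log-likelihood and accepts the best-ranked addition whose ML likelihood-
  ratio test clears α = 0.05 (χ² with df = number of added terms); the
  search stops when nothing clears. Greedy forward search with ~42
  candidates at α = 0.05 per round has a substantial family-wise false-
  inclusion rate on null data; selection results are descriptive, not
  error-controlled.
* **Bootstrap** — parametric percentile CIs: simulate from the fitted model
  (fixed effects + Gaussian random intercepts + residual noise), refit,
  take 2.5/97.5 percentiles; 10,000 draws by default, seeded and
  bit-reproducible; > 5% refit failures abort.
* **Simple slopes** — orientation slope = focal main effect; location slope
  = main + interaction; SE and p from the coefficient covariance and
  Satterthwaite df of the contrast. These reproduce recoded-reference
  refits exactly.
* **Influence** — leave-one-subject-out refits; generalized Cook's distance
  D_i = Δβᵀ Cov(β̂)⁻¹ Δβ / k with threshold 4/n (the customary default; the
  diagnostic's originators do not fix a cutoff); flagged subjects are
  excluded and the model refitted for a before/after comparison.

### Linked-data generator

Subject-level FC features are standard normal; responses follow the mixed
model above with documented coefficient sets: the precision (σ_vM) model —
intercept 0.74, task −0.34, three connectivity terms (within-N6 −0.073,
N2–N4 −0.076, N3–N5 −0.077) with interactions chosen so the location-task
slopes are ≈ 0 (0.064, 0.062, 0.076) — and the guess (P_G) model —
intercept 0.36, task −0.34, N3–N5 0.058, interaction −0.052. Variance
components are residual SD 0.18 and random-intercept SD 0.10, back-solved
from the reported coefficient standard errors of the paired design
(SE(task) = √(2σ²_e/72) ≈ 0.03; SE(intercept) = √((σ²_b+σ²_e)/72) ≈ 0.02).

## 5. Recovery experiments and problem sizes

`vwm_errnet.experiments` closes the loop at the documented operating points:

* **Behavioral recovery** — 10 independent study-scale cohorts (each
  72 × 240 per task) are generated, fitted, and their recovered group means
  averaged. A single cohort estimates a group mean only to ±1 SEM (≈ 0.01–
  0.03), which is half the width of the recovery bands; cohort replication
  reports the same population quantity with less Monte-Carlo noise. σ_vM is
  averaged over subjects with finite precision estimates (pure-guess fits
  have no defined σ_vM, mirroring the exclusion of uniform responders).
* **Network recovery** — 40 subjects × 500 timepoints on the planted
  six-community structure; the elbow cut and adjusted Rand index against
  the planted partition are reported. Across 100 seeds the partition is
  recovered exactly (count 6, ARI 1) in ≥ 95 seeds (asserted).
* **Slope recovery** — 200 replicates of the 72-subject two-task linked
  design per response; each replicate fits the generating interaction model
  and records the orientation-task simple slope of the focal term.

These sizes keep the full suite and the acceptance script to a few minutes
on one CPU while leaving Monte-Carlo noise well below the recovery bands.

## 6. Numerical details and limitations

* κ inversion: Newton on A(κ) with Banerjee start, tolerance 1e-12; A(κ)
  evaluated with exponentially scaled Bessel functions for stability.
* Random numbers: every generator and stochastic procedure takes an integer
  seed (numpy Generator); the pipeline derives stage seeds from one root
  seed via SeedSequence, and reruns are byte-identical.
* The KS screen has limited power below ~100 trials per task; the demo
  pipeline at reduced trial counts excludes more subjects than study-scale
  runs do.
* Group-mean P_G recovery at the orientation operating point carries the
  finite-sample ML bias described in §1; bands for recovery checks must be
  read as bands on the ML estimate, not on the truth.
* The FNC permutation branch (few subjects) uses 2000 sign-flips by
  default; p-values below 1/2001 are not resolvable there.
* Only random intercepts are modelled (no random slopes), matching the
  within-subject two-task design; responses are untransformed even though
  two of them are probabilities — at the observed operating points their
  distributions are far from the [0,1] boundaries for precision and swaps,
  less so for orientation-task guessing.
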