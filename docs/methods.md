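# Methods

This note documents the models implemented in `gutmet`, the defaults and
why they were chosen, what the synthetic cohort generator does and does
not emulate, and the numerical decisions a maintainer should know about.

## NMR preprocessing

**PQN.** Urine concentration varies several-fold between voids; the
dominant nuisance is a per-sample multiplicative dilution factor. PQN
estimates it as the median of the pointwise quotients between a spectrum
and a reference over a quantification region. Defaults: reference =
pointwise cohort median; quotient region excludes residual water
(4.5–5.0 ppm) and the TSP chemical-shift reference (±0.05 ppm around 0),
the standard exclusions. PQN with a fixed reference is idempotent and
removes any multiplicative factor exactly (both are tested to 1e-12).
An all-zero spectrum has no defined quotient and is reported as a
per-sample error rather than silently propagated.

**SRV.** Adjacent spectral variables belonging to one resonance co-vary
across subjects. The landscape `cov(i,i+1)/corr(i,i+1) = sd_i·sd_{i+1}`
is scanned along the axis; segments are cut at its local minima,
segments shorter than `min_size` (default 5 points) are discarded as
noise, and contiguous segments whose mean-intensity representatives
correlate above `merge_threshold` (default 0.9) are merged into
superclusters. Constant columns make the landscape undefined; they are
assigned 0 and therefore act as boundaries. Both parameters are exposed;
the published algorithm is cited without parameter values, so the
defaults are conventional choices, not reproductions.

**Integration.** Targeted quantification uses trapezoidal areas on the
ppm grid. Hippurate = sum of three windows centred at 7.84, 7.64 and
7.55 ppm with a configurable half-width (default 0.03 ppm, wide enough
for a ~7.6 Hz multiplet at 600 MHz plus line width). Creatinine
adjustment divides each feature by the subject's creatinine value and
flags the table.

## O-PLS

Single-y O-PLS in the NIPALS style: per orthogonal component, the weight
`w ∝ X'y` defines the predictive direction, the component loading's
projection off `w` defines an orthogonal weight, and the corresponding
score/loading pair is deflated from X; one predictive component is fitted
on the deflated block. Orthogonal scores have exactly zero sample
covariance with y by construction. Columns are mean-centred; feature
tables are additionally unit-variance scaled (`scale="uv"`), while
full-resolution spectra default to centring only — the common
metabolomics practice. Binary responses are encoded −1/+1 and folds are
stratified. Defaults: `n_orth=1` (the source analysis does not report
its component count), sevenfold CV, 10 000 permutations (tests and the
acceptance script scale this to 999 or 99). The permutation p-value uses
the +1 correction and is never 0. With `n_orth=0` the model reduces
exactly to textbook single-component PLS1, which an independent oracle
verifies to 1e-8 in the tests.

Two points worth knowing. First, a single predictive component explains
a response that is linear in several correlated columns only up to the
cross-correlation structure; "perfect" recovery holds for orthogonal
designs, or with `n_orth = p−1`, which spans the predictor space. Second,
MWAS covariance is the raw covariance between cluster integral and
response (so a cluster equal to y has covariance var(y)); the
significance mask follows the p ≤ 0.01 convention of Manhattan
pseudo-spectra, with q-values attached separately.

## Metabolic modules

Definitions follow KEGG module syntax: space-separated steps,
comma-separated alternatives, `+`-joined complex subunits, `-`-prefixed
optional components, parenthesised groups. The parser produces a
disjunctive normal form per step (each alternative = a set of required
orthologs), so evaluation is `max` over alternatives of `min` over
requireds; optional components never gate a step. Serialisation emits a
sorted canonical DNF and reparsing it is a fixed point. Abundance
follows the Omixer-RPM conventions: module value = median over step
abundances when the fraction of covered steps reaches the detection
cutoff (default 2/3), else 0. All of AND=min, OR=max and median are
monotone, so module abundance is monotone in every ortholog abundance,
and global rescaling of the KO table leaves coverage/detection unchanged.

Prevalence filtering for associations is strict (`prevalence > 0.2`,
the ">20 %" rule); surviving modules are Spearman-correlated with the
response and FDR-adjusted (Storey by default). The 20 bundled module
definitions are syntactically valid synthetic stand-ins (their filenames
and docstrings say so); curated definitions are drop-in text files.

Gene richness counts table columns above a detection threshold (default
`> 0`); the conventional human-catalogue high/low cutoff of 480 000
genes is the default and should be replaced by a table-scale cutoff for
ortholog-level or synthetic data. Shannon diversity is reported in nats.

## Enterotyping

Genus counts are modelled as a mixture of Dirichlet-multinomials fitted
by EM: responsibilities from the component DM likelihoods, mixture
weights from their means, and component α vectors by Minka's fixed-point
update (5 inner iterations per M-step), initialised from k-means on
Hellinger-transformed counts plus method-of-moments α. The data
log-likelihood trace is non-decreasing (tested to 1e-9). Model selection
minimises the Laplace approximation to the negative log evidence with a
zero-mean Gaussian prior (variance 10) on λ = log α — without that prior
the penalty is too weak and the score overfits k. The Hessian is
evaluated blockwise per component in λ-space at the EM optimum;
parameters themselves are ML estimates (the prior is weak and the
fixed-point update ignores it).

DMM requires integer counts; the Hellinger transform belongs to the
visual/ordination layer only. PCoA is the classical Gower decomposition
of −D²/2 for Bray-Curtis D computed on the table as given; Bray-Curtis
is generally non-Euclidean, so negative eigenvalues occur and are
reported (coordinates use the positive part). Components are labelled by
their highest-α genus; components sharing a dominant genus (the two
Bacteroides types) are numbered by decreasing expected Shannon diversity
of their composition, so the diverse type is `…1` and the low-diversity
type `…2`. Enterotype-wise comparisons are Kruskal-Wallis followed by
joint-rank Dunn z-tests with tie correction and BH adjustment.

## Cohort statistics

- **Consensus k**: elbow (max second difference of within-cluster SS),
  silhouette (max mean width), and the gap statistic against 50 uniform
  bounding-box references with the one-standard-error rule; majority
  vote, ties toward smaller k.
- **K-means**: scikit-learn Lloyd with 25 random starts (the analysis
  this mirrors used R's Hartigan-Wong with 25 random sets; best-of-25
  Lloyd is the equivalent available route and is tested against a plain
  Lloyd oracle). High/low strata are labelled by cluster-centre order.
- **Probabilistic PCA**: on complete data the ML solution is closed-form
  (covariance eigendecomposition, σ² = mean discarded eigenvalue), so it
  matches classical PCA exactly; with missing entries an EM treats the
  missing coordinates as latent (per-column missingness cap 20 %).
  Loadings are re-orthonormalised and ordered after EM.
- **Stepwise rank regression**: response and continuous candidates get
  average ranks, binary candidates pass through; greedy forward
  selection minimising Gaussian AIC, stopping when no candidate lowers
  it; near-collinear candidates (R² > 0.999 with the selected set) are
  skipped with a note. The per-variable incremental R²×100 is the bar
  decomposition reported by the acceptance script. AIC is deliberately
  liberal: under an all-noise null most runs select something — the
  analytically expected behaviour, which the tests assert via the
  F-distribution oracle rather than wishing it away.
- **Partial Spearman**: rank x and y, residualise both on the ranked
  covariates by least squares, Pearson-correlate the residuals, t-test
  on n − k − 2 df. Reduces exactly to Spearman with no covariates
  (verified against an independent implementation). Rank-based
  partialling is not exact conditional independence for nonlinear
  relations; residual associations of |ρ| ≈ 0.02 at n = 2000 are normal.
- **FDR**: BH via statsmodels; Storey's q with π₀ from the cubic
  λ-smoother over λ = 0.05…0.95 evaluated at λ = 0.95, clipped to (0,1];
  with fewer than 20 tests the smoother is unstable and π₀ = 1 (BH) is
  used.
- **Group comparison**: D'Agostino-Pearson normality per group gates
  ANOVA + Tukey HSD versus Mann-Whitney (2 groups) or Kruskal-Wallis +
  Dunn (>2). Groups under 8 observations skip the normality test (it is
  unreliable there) and force the nonparametric branch, with a note; the
  chosen branch is always reported.
- **ROUT**: robust location/scale from median and MAD×1.4826, two-sided
  t-tail p-values of the standardised residuals, BH-type step-up at rate
  Q (default 1 %). This is a robust-location approximation of the
  proprietary robust-regression original, appropriate for the univariate
  group data it is applied to.
- **IPGTT**: AUC is the literal sum of sampled glucose values (the
  stated convention of the mirrored analysis); ΔG is the
  baseline-subtracted trapezoidal integral over the 120 min; the
  trapezoidal AUC is also reported for completeness.
- **Adjusted attribution**: the four partial correlations
  (a, a|b, b, b|a, each given the covariates) plus ρ(a,b); an
  association is "collapsed" when adjustment shrinks |ρ| below 50 %
  (configurable) of its unadjusted value.

Missing values: correlations use pairwise-complete rows, regressions
complete cases; both log the counts dropped.

## The synthetic cohort generator

A single latent richness factor `z ~ N(0,1)` drives the cohort.
Planted quantities: detected-ortholog count
`round(n_kos · clip(0.5 + 0.15 z))`; hippurate
`100 + 25·(effect·z + ε)/√(effect²+1)` (so corr(hippurate, richness) =
effect/√(effect²+1); default effect 0.8 → ρ ≈ 0.62); independent diet
axis; log-normal dilution (sd 0.3). Spectra are Lorentzian multiplets
(half-width 0.003 ppm, 1:1 doublets, 1:2:1 triplets, J = 0.0127 ppm) for
hippurate, creatinine (3.05/4.06 ppm singlets), TSP, and six distractor
metabolites — one (citrate-like) with two multiplets sharing a single
area so SRV's supercluster logic has a true positive — on a positive
baseline with half-normal noise, all scaled by the dilution factor.

KO tables nest ortholog presence along the richness gradient; the
bundled modules' orthologs sit at the head of the nesting order (so
uncoupled modules are clean nulls for association testing), the
designated rare module's orthologs near the 90th richness percentile
(prevalence ≈ 10 %), and only the designated coupled modules (MC0004,
MC0005) have abundances multiplied by `exp(hip_z)`. Genus counts are
Dirichlet-multinomial draws from `n_communities` archetypes
(Bacteroides-diverse, Prevotella, Ruminococcus, Bacteroides-low-diversity,
concentration 50) at negative-binomial depth around 10⁴. Community
assignment tilts along the richness factor (logistic weights, coupling
0.8) and per-subject Dirichlet precision scales as `exp(0.35 z)`, so
Shannon diversity and enterotype membership carry hippurate-correlated
signal. The evenness coupling was deliberately kept weak: at 0.8 it
reproduces the emulated cohort's hippurate–Shannon ρ² ≈ 0.1 but the
precision heterogeneity leaves the Dirichlet-multinomial family and
breaks DMM model selection; at 0.35 the DMM recovers the planted k and
labels essentially perfectly while Shannon carries a correct-direction
but weaker association (ρ² ≈ 0.02–0.05).

The clinical layer draws age, sex, BMI, fasting glucose; log HOMA-IR is
linear in standardised BMI/age/sex and the hippurate factor with
coefficient `−0.05 − 0.35·[diet_axis > 0]` — a negative association
concentrated almost entirely in the meat/fat diet stratum — plus N(0,0.9)
noise; insulin is back-computed from HOMA-IR and glucose. TNFα follows
the same pattern more weakly. The diet block has 24 food items built
from two planted axes (meat/fat vs plants = the true diet axis; an
independent beverage axis) plus item noise.

What the generator does **not** emulate: chemical-shift drift, baseline
distortions or peak overlap beyond the planted library; sequencing reads
or mapping noise (KO tables are abundances, not read counts); taxon
co-occurrence beyond the mixture structure; longitudinal or batch
effects; realistic missingness in clinical tables. Passing tests
therefore demonstrate correctness of the statistical machinery on data
satisfying each method's assumptions, not robustness to every artefact
of real cohorts.

## Problem sizes

Test and acceptance runs use cohorts of 60–200 subjects (2000 for the
attribution and stratified analyses, where the spec-level effect sizes
need the precision), 999 or 99 permutations instead of 10 000, 50-run
Monte-Carlo repetitions, and DMM candidates k = 1…4 on 150 subjects ×
20 genera. These sizes give each check comfortable statistical margins
while keeping the full suite around two minutes.
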