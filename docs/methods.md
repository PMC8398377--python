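# Methods

This note documents the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic cohorts do and do not
emulate, and the numerical conventions that make runs reproducible.

## Study design and contrasts

The sampling frame is a partial-body irradiation study in nonhuman
primates: doses 0/8/11/12.5/14 Gy; study days −5, −1 (pre-exposure), 9, 10,
28, 29, 59, 60 pooled into timepoint groups TP1–TP4; males and females;
two collection cohorts (2016: days −5/9/29/59, males only; 2017: the
remaining days, both sexes). The default `DesignConfig` reproduces the
published per-cell sample counts exactly — 200 plasma samples. Because the
female arms are small, every statistic defaults to males only
(`sex_filter=("M",)`).

Two contrast families cover what the design can power: TP1 versus each
post-exposure group within a dose (the time axis), and sham (0 Gy) versus
each dose within a timepoint group (the dose axis). Contrasts with fewer
than 3 usable samples in either group are skipped and listed in the run
manifest rather than fitted badly.

## Preprocessing

Order is fixed and enforced through a stage tag on the matrix:
volume normalization → missingness filter → log transform → minimum
imputation.

* Volume normalization divides each sample's intensities by its plasma
  volume; units are treated as relative (only ratios matter).
* The missingness filter drops metabolites *strictly* above 20 % missing
  ("more than 20 %" read as >0.20, so exactly 20 % is retained). The
  denominator is all samples in the loaded matrix: the filter runs once,
  before any subsetting.
* Natural log is the default; the base only rescales log-space statistics
  and changes no p-value or VIP rank, so it is configurable but not
  interesting.
* Imputation replaces each missing entry with that metabolite's minimum
  observed value over all samples — the appropriate choice when missingness
  is detection-limit censoring, which is also how the generator produces it.
  No grouping is used, because none is implied by a per-compound minimum.

## Univariate statistics

Fold change is the ratio of arithmetic group means on the volume-normalized,
unlogged scale (the geometric-mean variant is available via
`fc_scale="logged"`; both agree in sign, and the unlogged form is the
default because a ratio of means is most naturally read on the measurement
scale). Imputed values participate in both the fold change and the test,
since imputation precedes analysis. The t-test is Welch's two-sample test
on logged values with Satterthwaite degrees of freedom; BH adjustment runs
across metabolites within one contrast. Degenerate zero-variance cases are
resolved exactly: equal constants give t = 0, p = 1; unequal constants give
p = 0 with a `degenerate` flag rather than an arbitrary jitter.

The FC threshold is symmetric (|log2 FC| > 1), which makes significance
counts invariant to swapping the group labels. A one-way ANOVA across
timepoint groups per dose exists as a secondary screen; the pairwise Welch
contrasts are the primary path because they are the ones with stated
operating parameters.

## OPLS-DA

The discriminant model is the standard NIPALS orthogonal-projections
construction for a single response. With X autoscaled (centre, unit
variance with ddof = 1 — the metabolomics norm; centre-only by flag) and y
the centred 0/1 class vector:

1. w ∝ Xᵀy (unit norm), t = Xw, p = Xᵀt/(tᵀt);
2. w_orth = p − (wᵀp)w, normalised; t_orth = X w_orth;
   p_orth = Xᵀt_orth/(t_orthᵀt_orth); deflate X ← X − t_orth p_orthᵀ;
3. repeat 1–2 per orthogonal component, then fit the single predictive
   component on the deflated X.

Because w is recomputed from the deflated matrix, each orthogonal score has
exactly zero covariance with y at fit time (checked to 1e-8), and with zero
orthogonal components the predictions coincide with one-component PLS1 to
machine precision — both properties are regression-tested against
scikit-learn's PLS as the independent reference.

* **Class coding**: y ∈ {0, 1}, centred; class calls threshold predictions
  at 0.5.
* **VIP** uses the predictive component only: VIP_j = √M·|w_j|/‖w‖, so mean
  squared VIP is identically 1 and VIP > 1 flags above-average contribution.
  (A total-VIP variant over orthogonal components was deliberately not made
  the default: the score is used to rank class-discriminating metabolites.)
* **Cross-validation**: stratified k-fold with k = 10 when the smaller class
  has ≥10 members, else 5, else leave-one-out; Q² = 1 − PRESS/TSS on the
  0/1 scale. Fold assignment keys on sample ids, not row order, so Q² is
  invariant to permuting the input rows at a fixed fold seed.
* **CV-ANOVA**: F = ((TSS − PRESS)/d₁)/(PRESS/d₂) with d₁ = number of model
  components (1 + n_orthogonal) and d₂ = N − 1 − d₁, p from the upper F
  tail — the SIMCA-style construction on cross-validated residuals. A model
  no better than the class-mean predictor reports F = 0, p = 1; a perfect
  model caps F at 1/ε and is flagged degenerate. The CV residuals are not
  strictly independent, so the null p is approximately, not exactly,
  uniform; the test suite checks it is not anticonservative.
* **Permutation test**: labels permuted, model and Q² recomputed under the
  same fold scheme, add-one rule p = (1 + #{perm ≥ obs})/(1 + n). With the
  default 100 permutations the smallest attainable p is 1/101 ≈ 0.0099.
  The Q²-based p is the headline statistic; R²Y-based p is also reported.
* **Orthogonal component count**: chosen greedily from 0 up to k_max = 3,
  accepting a component only if cross-validated Q² improves by more than
  0.01. On data whose only structure is class-correlated this returns 0,
  which is also why the well-powered synthetic contrasts are fit with
  n_orthogonal = 0 in the examples and acceptance runs.
* A model is **validated** when permutation p < 0.05 and Q² > 0 (both
  configurable); an unvalidated model blocks its contrast's selections
  unless `require_validated_model` is switched off.

Component signs are fixed (largest-magnitude loading positive) so score
tables are bit-reproducible.

## Enrichment

For each subpathway with K ≥ 5 members among the N background metabolites
(background = everything surviving preprocessing: only tested metabolites
can be significant), with n significant metabolites overlapping in k, the
exact inclusive tails are p_over = P(X ≥ k) and p_under = P(X ≤ k) for
X ~ Hypergeom(N, K, n). Both tails are always reported; a subpathway is
significant when min(p_over, p_under) < 0.05 with no doubling correction,
and no BH across subpathways by default (a raw 0.05 subpathway threshold;
BH available by flag). An exhaustive enumeration oracle (explicit point-mass
summation, N ≤ 30) cross-checks the implementation over the full small-N
grid. Metabolites absent from the annotation are excluded with a counted
"unannotated" bucket and can never be selected.

## Composite selection and the confounder filter

Selection is the intersection of all criteria — FC, p, VIP, validated
model, enriched subpathway of sufficient size — and every rejected
metabolite records the first criterion it failed, making selection tables
auditable. The significant set fed to enrichment is the univariate one
(|log2 FC| > 1 and p < 0.05): enrichment then refines it to
pathway-coherent signal rather than being gated by it.

The time-varying-confounder filter subtracts, from each irradiated arm's
TP1-vs-TPk selection, the metabolites and subpathways selected in the sham
arm's same time contrast. It applies at every dose with a supportable sham
contrast (the dose list is configurable), is idempotent, and records each
removal as "sham time drift". Dose-versus-sham contrasts at fixed timepoint
do not receive it — sham is already the comparator there. Venn partitions
are reported separately per axis (time contrasts within dose; doses after
unioning over time contrasts), since combining the two families into one
intersection would blur what each axis controls for.

## Synthetic cohorts

Log-intensities are built additively: per-metabolite baseline
~ N(14, 1.5²) (natural-log scale, i.e. median intensity ≈ e¹⁴ with a
realistic dynamic range), subject random intercepts ~ N(0, 0.2²) (the
design is repeated-measures; downstream tests nevertheless treat samples
as independent, exactly as the analysis under study does), i.i.d. noise
~ N(0, 0.4²), and a log(volume) term so that measured signal scales with
the plasma volume loaded — which is precisely what volume normalization
removes. Exponentiating gives strictly positive log-normal intensities.

Planted structure:

* **Radiation effects** (default 15 % of metabolites): signed log2 effects
  drawn uniformly from 1.0–2.5, scaled by a dose–response curve
  (0 Gy: 0, 8 Gy: 0.4, 11 Gy: 0.85, 12.5 Gy: 1.0, 14 Gy: 1.1 — 8 Gy
  weakest, saturating at high dose) and a time profile peaking at TP2
  (TP1: 0, TP2: 1.0, TP3: 0.5, TP4: 0.35 — partial restoration).
* **Sham drift** (default 3 %, disjoint subpathways): dose-independent
  log2 shift of 2.0 scaled by a profile growing over the study
  (TP2: 0.8, TP3: 0.9, TP4: 1.0). The magnitude is set so drift clears the
  pipeline's own FC > 2 detection threshold in both sham and irradiated
  arms with margin — a confounder the filter cannot see in the sham arm
  would be a vacuous test of the filter.
* Effects are planted as whole subpathway blocks by default (coordinated
  pathway dysregulation), giving hypergeometric enrichment real signal;
  drift occupies entirely different subpathways so the pathway-level filter
  also has a clean truth.
* **Censoring**: each metabolite loses the entries below its own
  detection-limit quantile (default 8 %; a disjoint ~17 % of null
  metabolites sit at 30 % censoring and are meant to fall to the
  missingness filter). An MCAR mechanism exists behind a flag for
  sensitivity work.

What the generator does **not** emulate: instrument or batch drift beyond
the cohort label, correlated metabolite modules within subpathways
(covariance is diagonal given the design factors), non-Gaussian tails,
missingness that depends on the planted effects, or any raw-spectra
features. Passing tests therefore demonstrate correctness of the
statistical machinery under a faithful but idealised data model — not
performance on real LC-MS data.

## Problem sizes and calibration checks

The test and acceptance runs use deliberately scaled problem sizes chosen
to keep the full suite fast while leaving every property measurable:
null-calibration cohorts of 2,000 metabolites for the Welch uniformity
check (on a dose-axis contrast, where groups share no animals — time-axis
contrasts reuse subjects, making unpaired Welch conservative by
construction); 200 replicate permutation tests at 50 permutations for the
permutation-p calibration; 300-metabolite cohorts with 50 planted effects
(|log2 FC| ≥ 1.3, n = 12/group, noise SD 0.4) and 20 drift metabolites for
end-to-end recovery. Under those conditions the pipeline reaches recall
≈ 0.9–0.96 with false-discovery proportion ≤ 0.02, and the confounder
filter removes ≥ 94 % of drift metabolites that were selected pre-filter.

## Reproducibility

Every run descends from one master seed through `numpy.random.SeedSequence`
spawning: design, abundances, censoring, fold assignment, permutations and
per-contrast model seeds (hashed from the contrast label with CRC-32, not
Python's randomised `hash`). Manifests and tables are written with sorted
keys and no timestamps, so identical seeds give byte-identical output
files.

## Known limitations

* No mixed-effects modelling of the repeated-measures structure; the
  analysis intentionally mirrors an unpaired design.
* No batch correction across cohorts; the real workflow merged cohorts
  after a visual ordination check, reproduced here only as the cohort label.
* CV-ANOVA degrees of freedom follow one defensible bookkeeping among
  several in circulation; its p-values are approximate under the null.
* The hypergeometric enumeration oracle is O(N) per tuple and restricted
  to N ≤ 30 by design; it exists to verify, not to run.
* Single-response OPLS-DA only (two classes); no multi-class extension.
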