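# Methods

This note documents the statistical models implemented in `crcmeta`, the
choices made where the design was genuinely open, what the synthetic-data
generator does and does not emulate, and the numerical conventions used
throughout. Problem sizes quoted for tests are the package's own validation
scale.

## Effect-size meta-analysis

Abundances are fractions in [0, 1]; analyses operate on the
arcsine-square-root transform `y = asin(sqrt(p))`, the classical
variance-stabilizing transform for proportions. Inputs within 1e-12 of the
bounds are clipped; anything further out is a hard error rather than a
silent fix.

Per cohort and feature, the standardized mean difference is Hedges' g: the
pooled-SD Cohen's d times the small-sample correction `J = 1 - 3/(4 df - 1)`
with `df = n1 + n2 - 2`, and sampling variance
`Var(g) = J^2 ((n1+n2)/(n1 n2) + d^2/(2 df))`. The approximate J is used
rather than the exact gamma-ratio form; they differ by < 0.1% for n ≥ 10,
and the exact form would change no decision the package makes. When both
groups are constant (`s_pooled = 0`) the effect is reported as 0 with the
mean-term variance only and flagged degenerate; degenerate effects are not
pooled. The direction convention is fixed: positive g means higher in
group 1 (the case / late-stage / right-sided arm of a contrast).

Pooling uses inverse-variance random-effects weights `w_i = 1/(v_i + τ²)`.
τ² is estimated by REML via the standard fixed-point iteration (to |Δτ²| <
1e-10 or 100 iterations) or by Paule–Mandel. Paule–Mandel is defined as the
root of `Q(τ²) = k - 1`; since Q is monotone decreasing in τ², the root is
found by bisection to the same tolerance — the same solution the usual
iterative scheme converges to, without its step-size pathologies. Both
estimators were cross-checked against R's `metafor::rma` and agree to ≥ 5
decimals on fixed fixtures (frozen in the test suite).

Confidence intervals and p-values use the Hartung–Knapp adjustment:
variance `Σ w_i (g_i - ĝ)² / ((k-1) Σ w_i)` with a t(k−1) reference
distribution. Simulation at the package's validation scale (k = 5 studies,
τ² = 0.04, 10,000 replicates) puts empirical 95% CI coverage at ~94.8%.
Heterogeneity is reported as the Q-based `I² = max(0, 100 (Q - (k-1))/Q)`
with fixed-effect weights — note this deliberately differs from metafor's
τ²-based I² definition. Single-study features are reported with their own
normal-theory CI and flagged `pooled=False` rather than dropped.

Eligibility before testing mirrors multi-cohort practice: a feature must
reach ≥ 10% prevalence with ≥ 5 detected samples in at least one class-set,
and ≥ 3 cohorts must have ≥ 10 samples in each class. Benjamini–Hochberg
q-values are computed across the tested features only.

Covariate-adjusted effects replace the two-group g with the class
coefficient of an ordinary least-squares fit of the transformed abundance
on [intercept, class, covariates], with variance its squared standard
error; rows with any missing covariate are dropped (logged), cohorts with
fewer than 10 complete rows or a rank-deficient design are skipped. OLS is
solved by `lstsq` directly — the design matrices are tiny and no inference
beyond the coefficient SE is needed.

## Oral signature and enrichment

The oral-typical panel uses three prevalence criteria over participants
sampled at both body sites, with one shared denominator (participants with
both samples): exclusively-oral fraction ≥ 0.20 (boundary inclusive, "at
least"), both-sites fraction strictly below the exclusively-oral fraction,
exclusively-stool fraction strictly below 0.05 ("fewer than"). "Present"
means detected at any nonzero abundance. The pooled-participant computation
is used (criteria are not required per cohort). An SGB absent from one
body-site table is treated as absent at that site.

Fisher's exact test is implemented as two-sided hypergeometric tail
summation (probabilities ≤ the observed table's, with a 1e-9 relative
tolerance guarding floating-point ties); it matches both exhaustive
enumeration over fixed margins and `scipy.stats.fisher_exact` in the test
suite. The odds ratio is the sample (a·d)/(b·c) with ∞ when b·c = 0 and a
NaN flag when a margin is empty (p = 1 in that case).

## PERMANOVA with blocked permutations

One-factor PERMANOVA on a distance matrix: `SS_total = Σ_{i<j} d²_ij / N`,
within-group sums analogously per group, pseudo-F from the usual mean
squares. The permutation null shuffles labels independently within each
block (cohort), so cohort-level batch structure can never masquerade as a
group effect; a label structure perfectly aligned with blocks is by
construction unrejectable (p = 1). The permutation p uses the +1
correction, `p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm)`, guaranteeing
p ≥ 1/(n_perm+1). The pseudo-F agrees with scikit-bio's `permanova` to
machine precision on unblocked fixtures; the blocked p agrees with
exhaustive within-block enumeration on 8-sample fixtures. Bray–Curtis runs
on raw relative abundances (standard practice); Jaccard on presence sets is
used for binary strain features.

## Classifier-evaluation harness

The harness is the contribution; the learner is injected. Any object with
`fit(X, y)` / `predict_proba(X)` works. The default configuration is a
1,000-tree random forest, minimum 5 samples per leaf, per-split feature
count grid-searched over {sqrt(p), 0.1p, 0.2p, 0.3p} in an inner stratified
5-fold CV on training data only; a 200-tree no-grid `LIGHT_CONFIG` is
provided for rapid runs and is what the bundled validation uses. Eligibility
is 15 samples per class for a CV cohort and for both sides of
cross-dataset/LODO splits; a validation-ineligible cohort can still serve in
LODO training pools. Per-dataset CV re-randomizes stratified folds each
repeat and pools out-of-fold scores per repeat before computing AUC (the
repeat mean and SD are reported); pooled-then-AUC was chosen over per-fold
averaging because it is well-defined for small test folds. AUC is the
rank-based Mann–Whitney statistic with ties counted 0.5. Feature subsetting
(oral / non-oral) renormalizes each sample's retained abundances by their
sum before the arcsine-sqrt transform; a sample with nothing retained
becomes an all-zero row and stays in the design (logged), so cohort sizes
and eligibility are unaffected.

## Strain-level SNV features

Alignment columns are scored by the binary entropy of the major-allele
frequency computed over non-N residues, with the gap counted as an ordinary
symbol (gap preference is itself a strain feature); columns with entropy
< 0.5 bits — major-allele frequency outside roughly (0.11, 0.89) — are
dropped, as are all-N columns. Each kept column expands to five binary
features (A, C, G, T, gap); an N residue leaves all five at zero, so per
(sample, position) the one-hot block sums to 1 unless the residue is
missing. Prevalence filtering keeps features with pooled control+case
prevalence in [0.20, 0.80], both boundaries inclusive (the removal rule is
stated as strict "< 20%" / "> 80%"). Collinearity pruning is greedy in
construction order — (SGB, position, symbol) — keeping a feature only if
|Pearson φ| ≤ 0.5 against every previously kept feature; zero-variance
features are dropped first with a warning. Pearson on 0/1 vectors is the φ
coefficient and is computed exactly.

The redundancy-collapse step before encoding is the one genuinely ambiguous
part of this pipeline's description in the literature it follows, and the
implemented interpretation is explicit and switchable (`ani_dedup=False`
for pass-through): samples are single-linkage clustered at SNP distance
(1 − identity over shared non-N columns) ≤ 0.05; within each cluster of ≥ 2
samples, positions inducing the same *sample partition* (canonical residue
relabeling, so A/A/C/C duplicates G/G/−/−) are collapsed to the one with
the fewest gaps, earliest position on ties; the union of per-cluster
keepers survives. Clusters of size 1 carry no pattern information and are
ignored; if only singletons exist the step is a no-op. This reading should
be treated as a plausible reconstruction, not settled intent.

A note on degeneracy: a two-clade alignment is a single sample split, so
every discriminating position is perfectly collinear and pruning correctly
collapses the set to one feature; validation scenarios therefore use ≥ 4
clades, where complementary clade indicators (pairwise φ = −1/3 at equal
sizes) survive. Samples whose surviving feature row is all zeros are
excluded from the Jaccard PERMANOVA with a warning (Jaccard is undefined on
empty sets).

## Synthetic multi-cohort generator

The generator exists so every downstream stage is testable with known
ground truth. Per cohort, feature log-abundances are
`mu_f + batch_{c,f} + sigma_f z` with `mu_f ~ N(0, 1.5²)` (heavy-tailed
marginals after closure), `sigma_f ~ U(0.6, 1.4)` (within-cohort log-SD of
roughly 1, typical of species-level microbiome data), and per-cohort,
per-feature batch offsets `N(0, 0.5²)`. Samples are closed to sum 1 by
exponentiation and normalization. Zero-inflation afterwards zeroes each
feature's smallest values to hit a per-feature prevalence target
(U(0.6, 1.0) for gut features; U(0.25, 0.6) for oral features, whose latent
mean is also shifted down 2 log units — oral species are rare and sparse in
stool). Defaults: 5 cohorts × (100 control + 100 CRC) × 300 features, 50 of
them oral-typical with a 3-fold latent boost in cases.

Planted effects are targets on the Hedges'-g scale of the transformed
abundances. Calibration is closed-form under the generator's own model: for
a low-abundance feature, `asin(sqrt(p)) ≈ exp(log p / 2)` is lognormal with
log-SD `sigma/2`, giving

    g(delta) = (e^{delta/2} - 1) / ( sqrt(e^{sigma²/4} - 1) · sqrt((1+e^{delta})/2) )

for a case log-shift delta; the generator inverts this monotone mapping by
bisection per feature. The mapping saturates at `sqrt(2)/sqrt(e^{sigma²/4}-1)`;
targets above 98% of that are capped (separation keeps increasing, the
realized g plateaus). Because closure forces each sample to sum to 1,
planting mass in cases would otherwise depress every feature and attenuate
the planted effects; a short fixed-point iteration inflates the shifted
features by the expected log-total inflation (lognormal means as weights)
so planted features hit their targets. The compositional counterpart cannot
be removed entirely: unshifted features drift slightly negative in cases
(≈ −0.05 g at the defaults), which is faithful to how real compositional
data behaves and is why the null-calibration scenarios turn the
introgression boost off. Realized pooled estimates recover targets to
roughly ±0.1 at default sizes.

Stage trends add a per-sample shift proportional to stage (0 → IV mapped to
0 → 1) on the same calibrated scale. Stage and location frequencies for CRC
samples, and the paired body-site design (495 participants), mirror the
multi-cohort corpus this framework targets; age ~ N(60, 10²), sex
Bernoulli(0.5), BMI ~ N(26, 4²) are generic adult-cohort choices since no
within-cohort covariate distributions are specified anywhere authoritative.

What the generator does *not* emulate: read-level noise and profiler error,
taxonomic misassignment, within-cohort batch structure, covariate–disease
confounding (age/sex/BMI are independent of condition, so adjusted and
unadjusted effects coincide in expectation), realistic phylogenetic
correlation between features, and recombination or homoplasy in MSAs
(clades are star-like around consensus sequences). Passing the bundled
calibration therefore demonstrates correctness of the statistical
machinery under the stated model, not robustness to real-data artifacts.

The paired body-site truth mixes four non-member archetypes (rarely-oral,
shared-carriage-dominant, stool-spillover, gut-only) with true members
drawn away from the decision boundaries by sampling-noise margins at
n = 495 — species genuinely colonizing both sites are modeled as found in
both far more often than exclusively orally (1.5–3×), which is what keeps
criterion (2) discriminative.

## Numerical conventions and degenerate inputs

All randomness flows through `numpy.random.default_rng` seeded explicitly;
fixed seed means bit-identical tables and byte-identical written TSVs.
Writers emit `%.17g` floats, round-trips are lossless to 1e-12. Percentage
tables are auto-detected (column sum > 1.5) and rescaled once at read time.
Ambiguous IUPAC bases map to N (missing), never to gap. Missing covariates
stay missing at the IO layer. Empty or single-group inputs to diversity and
PERMANOVA raise rather than return conventions; empty-set Jaccard is
defined 0 and empty-signature overlap NaN, both flagged. BH q-values are
capped at 1 and restored to input order.

## Known limitations

- The one-factor PERMANOVA has no covariate terms; contrasts needing
  age/sex/BMI adjustment must rely on the adjusted meta-analysis path.
- The Paule–Mandel/REML agreement is only guaranteed on well-conditioned
  inputs; with k = 2 and wildly unequal variances both are unstable, as in
  any meta-analysis package.
- The ANI-cluster dedup interpretation is a reconstruction (above) and off
  by a flag if its behavior is unwanted.
- `adjusted_effect` treats the class coefficient's scale as comparable
  across cohorts after SE standardization; it is not a Hedges' g and the
  two pipelines' pooled estimates are not numerically interchangeable.
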