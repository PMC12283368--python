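# crcmeta

A reusable Python toolkit for pooled cross-cohort analysis of stool
shotgun-metagenome profiles in colorectal cancer (CRC) research. It is aimed
at microbiome researchers who have per-cohort species-level relative-abundance
tables (MetaPhlAn-style merged TSVs), per-sample clinical metadata and,
optionally, marker-gene multiple sequence alignments (StrainPhlAn-style
aligned FASTA), and who want to ask: which microbial species reproducibly
change with disease, stage or tumor location across heterogeneous cohorts;
how well does the microbiome predict disease in *new* cohorts; and do
strain-level genomic features carry signal beyond species abundances?

## What it computes

**Oral-to-gut introgression.** From paired oral/stool presence tables of
healthy participants, the oral-typical species panel is the set of SGBs
(species-level genome bins) that are (1) exclusively oral in ≥ 20% of
participants, (2) in both sites in fewer participants than exclusively oral,
and (3) exclusively in stool in < 5%. Each stool sample then gets an
*oral-to-gut score* (summed relative abundance of panel members) and an
*oral-to-gut richness* (count of panel members detected).

**Per-feature random-effects meta-analysis.** For a binary contrast (e.g.
CRC vs control), each cohort contributes a Hedges' *g* standardized mean
difference of arcsine-square-root-transformed abundances:

    d = (m1 - m2) / s_pooled,   J = 1 - 3/(4 df - 1),   g = J d,
    Var(g) = J^2 ((n1+n2)/(n1 n2) + d^2 / (2 df)),  df = n1 + n2 - 2.

Cohort effects are pooled with inverse-variance random-effects weights
w_i = 1/(v_i + τ²), with τ² estimated by REML (or Paule–Mandel), confidence
intervals and p-values from the Hartung–Knapp adjustment (t distribution
with k−1 df and weighted residual variance), heterogeneity summarized as
I² = max(0, 100·(Q−(k−1))/Q), and multiplicity controlled by
Benjamini–Hochberg q-values. Eligibility mirrors multi-cohort practice:
a feature is tested when it reaches ≥ 10% prevalence with ≥ 5 positive
samples in some class-set and ≥ 3 cohorts have ≥ 10 samples per class.
Covariate-adjusted effects (age, sex, BMI) come from per-cohort OLS with the
standardized class coefficient pooled the same way.

**Community structure.** Shannon diversity, richness, Bray–Curtis and
Jaccard distances, and a one-factor PERMANOVA whose permutations are
restricted *within* cohorts (blocked), the correct null when cohorts carry
batch effects.

**Transfer-learning evaluation.** A classifier-agnostic harness for the
three standard designs: per-dataset cross-validation (10-fold × 20 repeats),
pairwise cross-dataset prediction, and leave-one-dataset-out (LODO), with
15-per-class eligibility rules, oral/non-oral feature subsetting (retained
abundances renormalized to [0, 1] before the arcsine-sqrt transform), and
rank-based AUC. The default learner is a 1,000-tree random forest with
min 5 samples per leaf and grid-searched per-split feature counts.

**Strain-level SNV features.** From a species MSA: keep columns whose
major-allele frequency has binary entropy ≥ 0.5, optionally collapse
positions that induce identical sample partitions within near-identical
sample clusters (keeping the least-gapped), one-hot encode each column into
five binary features (A/C/G/T/gap), drop features outside 20–80% pooled
prevalence, greedily prune features with |Pearson φ| > 0.5 against an
earlier-kept feature, and test the surviving binary matrix with a
Jaccard-distance blocked PERMANOVA.

**Signature analytics.** Jaccard similarity and overlap fractions between
biomarker signatures; Fisher-exact enrichment (hypergeometric tail
summation); a covariate-adjusted partial-Spearman rank score for
cardiometabolic risk (ranks averaged within and then across index
categories, selection above the third quartile); and a country-adjusted,
Paule–Mandel-pooled disease-signature recipe (q < 0.1 in ≥ 3 datasets).

**Synthetic cohorts.** A first-class generator producing multi-cohort
compositional tables with cohort batch effects, planted Hedges'-g effects
(calibrated by a closed-form lognormal mapping, see `docs/methods.md`),
elevated oral-species introgression in cases, monotone stage trends,
paired body-site presence data, and clade-structured MSAs — everything the
analyses assume, with ground truth returned for validation.

## Worked example

```bash
crcmeta run-all --seed 3 --out demo_run
```

simulates 5 cohorts × (100 control + 100 CRC) × 300 species with 10 planted
case effects (g = 0.8) and 50 oral-typical species boosted 3-fold in cases,
then chains every stage. The summary it printed:

```
"oral_signature":    {"n_members": 50, "recall": 1.0, "precision": 1.0}
"meta_analysis":     {"n_features_tested": 300, "n_significant_q10": 191}
"permanova":         {"r2": 0.0305, "pseudo_f": 31.39, "p": 0.005, "n_perm": 199}
"lodo":              {"cohort01": 0.9993, ..., "cohort05": 0.9995}
"strain_features":   {"funnel": [["one_hot", 75], ["prevalence[0.2,0.8]", 56],
                      ["collinearity<=|0.5|", 4]], "permanova_p": 0.005}
"signature_compare": {"n_crc_associated": 60, "overlap_with_oral": 0.833}
```

Reading this: the oral panel was recovered perfectly from 495 simulated
paired participants; 191 species pass q < 0.1 (the 50 introgressing oral
species, the 10 planted effects, plus their compositional counterparts —
closure makes unshifted features drift slightly negative in cases at this
sample size); community composition separates cases from controls
(R² ≈ 3%, blocked p = 0.005); LODO AUC ≈ 1.0 under this strong planted
signal; the strain funnel reduces 75 one-hot features to 4 clade indicators
whose Jaccard PERMANOVA rejects; and 50 of the 60 strongest positive
associations are oral-typical (overlap 0.83).

Individual stages are available as `crcmeta simulate | oral-signature |
meta | diversity | permanova | ml-eval | strain-features | signatures`, and
as plain library calls (`crcmeta.meta.pool_random_effects`, ...).

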