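# Methods

This note records the statistical definitions, modelling assumptions and
numerical decisions behind the package, in enough detail to re-derive every
computed quantity.

## 1. Phenotypes

All phenotypes are functions of a subject's Alda ratings: the A score
`a ∈ {0..10}` and five B items `b1..b5 ∈ {0,1,2}` with `B = Σ bᵢ`.

* **Total Score** `ts = max(0, a − B)`. The floor at zero is part of the
  definition, not a clipping convenience: negative differences are reported
  as "no demonstrated response", 0.
* **Original category** `alda_cat = GR iff ts ≥ 7` (boundary included).
* **A/Low B** `a_low_b = a if B < 4 else excluded`. Exclusion (not
  imputation) is deliberate: the phenotype trades sample size for rating
  reliability, and excluded subjects are reported as missing (`<NA>`).
* **Best-estimate category.** A CHAID tree is fitted de novo on each
  cohort: predictors `b1..b5` (ordinal), provisional target
  `GR iff a ≥ 7`. The leaf-level GR fraction is `grp`, and
  `algo_cat = GR iff grp > 0.62` (strict inequality; a leaf at exactly the
  cutoff is NR). On cohorts where the B items carry no information about
  the A score the tree is a single root node and `grp` equals the
  provisional GR prevalence for every subject.

The best-estimate model is exposed as a scikit-learn estimator
(`BestEstimateClassifier`), as is the underlying tree (`CHAIDClassifier`);
the remaining modules are pure functions/statistics with no fit step and
keep a functional interface.

## 2. CHAID trees

The tree builder is written from scratch (no installed library provides
CHAID) and follows the classic chi-square automatic interaction detection
scheme:

1. **Category merging** (per predictor, per node). Starting from the
   observed categories, repeatedly merge the pair of groups whose two-group
   Pearson chi-square p is largest, while that p exceeds `alpha_merge`
   (default 0.05). Nominal predictors may merge any pair; ordinal
   predictors only adjacent pairs, except that a missing-value category
   floats freely. Merging may reach a single group, in which case the
   predictor offers no split. The optional re-split refinement and
   exhaustive CHAID are deliberately not implemented.
2. **Bonferroni adjustment.** The merged-table chi-square p is multiplied
   by the number of ways the `c` observed categories could have been
   grouped into `r` groups: Stirling-2 `S(c, r)` for nominal predictors,
   `C(c−1, r−1)` for ordinals, and `C(c−2, r−2) + r·C(c−2, r−1)` for an
   ordinal with a floating missing category. The product is capped at 1.
3. **Split selection.** The node splits on the predictor with the smallest
   adjusted p, if that p ≤ `alpha_split` (default 0.05) and every child
   would contain at least `min_child` subjects (default 10). Ties break on
   predictor name. Recursion stops at `max_depth` (default 3), below
   `min_parent` (default 30) or on pure nodes. Defaults are sized for
   cohorts of a few hundred subjects.

Continuous predictors (age) are quantile-binned into at most 10 ordinal
bins before entering the search; bin edges are stored so that new values
(including values outside the training range) route deterministically.
Routing a category never seen at a split either raises (`unseen="error"`,
the default, so silent imputation cannot distort concordance estimates) or
falls back to the largest child (`unseen="majority"`, used inside
cross-validation).

Cross-validated risk is the k-fold (default 10, stratified, seeded)
misclassification rate of leaf-majority prediction, reported with the
binomial standard error `sqrt(r(1−r)/n)`.

### Greedy search vs exhaustive oracle

The test suite contains an exhaustive oracle that enumerates *all*
admissible partitions per predictor (set partitions for nominals,
contiguous groupings with a floating missing category for ordinals) and
selects the global minimum adjusted p. Greedy Kass merging does not always
reach that optimum: on 500 random small instances the split *decisions*
(chosen predictor, or no split) agree on 493; the 7 disagreements are
alpha-boundary cases where an unreachable partition is slightly more
significant, plus occasional predictor flips. This is an inherent property
of the greedy algorithm, not a bug; the acceptance test that demands exact
agreement on every instance is therefore expected to fail and is kept
failing rather than weakened.

A related calibration caveat: the Bonferroni multiplier corrects selection
*within* a predictor, so on pure-noise data the per-predictor split
frequency stays near `alpha_split` (measured 0.02–0.05 at α = 0.05), but
CHAID applies no correction *across* predictors, so the union split
frequency over several noise predictors is correspondingly larger (~0.10
with two predictors). The calibration test therefore uses a single noise
predictor.

## 3. Genotype model and QC

Genotypes are stored as minor-allele dosages (0/1/2, NaN for missing).
The simulator draws each SNP as Binomial(2, MAF) — i.e. exact
Hardy–Weinberg proportions — and masks calls missing at an independent
1% rate (typical chip-level missingness, compatible with the call-rate
thresholds below).

QC computes, in a single pass over the input (making the operation
idempotent on already-filtered tables):

* **MAF** ≥ 0.05 per SNP;
* **call rate** ≥ 0.97 per SNP and ≥ 0.90 per sample (boundaries
  included);
* **heterozygosity** within mean ± 3 sd across samples;
* **HWE**, reported but not used as a hard filter by default: the 1-df
  chi-square against expectations from the observed allele frequency, and
  an exact p by full enumeration of heterozygote counts conditional on the
  allele counts (probability-ordered two-sided tail, computed in log
  space). Monomorphic SNPs return p = 1 by convention.

The exact and asymptotic HWE p-values agree within 0.05 whenever the
asymptotic p is itself below 0.05 and all expected genotype counts are
≥ 5 (worst observed difference 0.026 over thousands of sampled triples).
They do **not** agree that tightly in the mid-range (differences up to
~0.28) regardless of expected counts — a consequence of the discreteness
of the heterozygote-count distribution — so the cross-check property is
asserted only in the decision-relevant regime.

**Best-SNP selection** within a gene: SNP pairs with LD r² > 0.05
(pairwise-complete squared Pearson correlation of dosages) are pruned
keeping the member more associated with the continuous response score
(smaller Kruskal–Wallis p across dosage groups; ties broken by SNP id),
and the surviving SNP with the smallest p is selected. This optimises
significance and is selection-biased by construction; it mirrors standard
candidate-gene practice and is flagged in the function documentation.

**VCF round-trips.** The reader recomputes the minor allele from the data
(`recode="minor"`), so for a SNP with true MAF 0.5 the sample minor allele
can flip relative to the writer's ALT allele and dosages come back as
`2 − d`. Literal round-trips use `recode="alt"`; the dosage-TSV path is
always exact.

## 4. Association scan

Each SNP enters under its gene's coding — dominant (carrier vs
non-carrier) or codominant (three genotype groups); the default map codes
the two low-MAF genes dominant and the balanced-allele gene codominant.
Tests by phenotype type:

* categorical (`alda_cat`, `algo_cat`): Pearson chi-square without
  continuity correction; Fisher's exact on 2×2 tables with any expected
  count below 5;
* continuous (`ts`, `a_low_b`, `grp`): two groups — Wilcoxon rank-sum,
  computed by *exact enumeration over group assignments with midranks*
  when both groups have ≤ 10 subjects (the normal approximation is
  unreliable there, and scipy's exact method refuses ties), otherwise the
  tie-corrected normal approximation without continuity correction; three
  groups — Kruskal–Wallis.

`a_low_b` is tested on its B < 4 subsample only. Degenerate cells (e.g. a
single-class phenotype, or a coding that leaves one group) produce an
explicit `test = "undefined"` marker row with NaN statistic/p rather than
silently dropping the cell, so every scan has exactly
genes × phenotypes rows.

Significance tiers: p < 0.017 (0.05/3, corrected for three genes) and
p < 0.003 (0.05/15, corrected for genes × phenotypes). On 100 null
cohorts the fraction of scans with any fully-corrected hit was 0.01,
within the nominal familywise bound 15 × 0.003 + 0.03.

## 5. Power

Two-sample t-test power uses the exact noncentral t distribution:
noncentrality `ncp = d·sqrt(n1·n2/(n1+n2))`, `df = n1+n2−2`, rejection at
the central-t critical value with both tails counted for two-sided tests.
The claims of interest sit close to the 0.80 boundary (0.8078 at
110 vs 46, 0.8350 at 102 vs 53, d = 0.5, α = 0.05 two-sided), so a normal
approximation would not be adequate; the implementation is cross-checked
in tests against statsmodels and against direct Monte-Carlo simulation of
the t test.

## 6. Synthetic cohorts

The generator mirrors the reference sample's marginals: n = 164, 60%
female, age ~ Normal(44.70, 12.29) truncated at 18, A ~ Normal(6.33, 2.99)
rounded half-away-from-zero and clipped to [0, 10], B items drawn from
their observed per-item category prevalences *independently of A* (the
published table reports only marginals), and three SNPs at the published
allele frequencies. Optional `effect_map` entries add `effect × dosage` to
the latent A score before rounding, for planted-effect studies.

Randomness is split from a single master seed into named sub-streams
(demographics, A, B, one per SNP, missingness) via `SeedSequence.spawn`,
so adding a SNP does not perturb the other draws and every output is
byte-reproducible from the seed.

Because B ⊥ A under the default generator, the de-novo tree has no signal
on default cohorts and `algo_cat` collapses to all-NR; properties that
require the best-estimate phenotype to track the original category (e.g.
prevalence agreement within 10 percentage points) are therefore tested on
cohorts with an explicit latent-responder structure linking A and the B
items, which is the regime those properties presuppose.

One bookkeeping note: the published genotype counts for one gene sum to
155 against a stated genotyped n of 156; the printed counts (23/79/53) are
used as-is.

## 7. Numerical and engineering choices

* scipy provides the standard tests (chi-square, Fisher, Kruskal–Wallis,
  asymptotic rank-sum, noncentral t); the exact rank-sum enumeration, the
  exact HWE test, the CHAID machinery and the Bonferroni multipliers are
  hand-written, as no installed library supplies them.
* Problem sizes in tests (cohorts of 150–500, 100-seed property batteries,
  500 oracle instances) were chosen to keep the full suite under a few
  minutes on one CPU while leaving the binomial error of measured
  frequencies well inside the asserted margins.
* Configuration objects are plain dataclasses with `__post_init__`
  validation; errors form a small hierarchy rooted at `LithophenoError`,
  with pipeline failures re-raised as `StageError` tagged by stage.
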