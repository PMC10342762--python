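# Methods

This note documents the modelling choices behind `fuzzybiopsy`: the cascade
and its assumptions, every tunable that matters, what the synthetic-cohort
generator does and does not emulate, and the numerical conventions.

## The cascade

The classifier answers one question — *will a targeted prostate biopsy find
cancer?* — from six prebiopsy variables: PSA density (ng/mL²), DRE
(negative/positive), prior biopsy (no/yes), number of suspicious mpMRI
lesions, lesion location (peripheral vs transitional/anterior) and PI-RADS
score (3–5). It is a cascade of a rule-based fuzzy inference system and a
linear support-vector machine. The FIS is preferred wherever its rules
reach because each verdict is a readable list of IF–THEN rules; the SVM
guarantees total coverage. The SVM is trained on the *entire* training
cohort, not just on rule-missed patients: the rule-missed region is not
known before the rules exist, and a separator fitted on all patients is the
maximum-margin summary of the same six variables.

Assumptions worth making explicit:

* the six variables carry the predictive signal (they were originally
  chosen by an exhaustive Gower-KNN subset search, reproduced in
  `feature_selection`);
* rule antecedents and fuzzy terms live on a shared discretization — the
  binarization intervals equal the membership-function supports, so a mined
  pattern translates one-to-one into a fuzzy rule;
* class structure is locally homogeneous: rules are frequent patterns of
  SOM subgroups, filtered by whole-cohort class predominance.

## Rule induction

Per outcome class: (1) a 4×4 SOM clusters the class's patients (encoded
one-hot for categoricals, min–max scaled numerics); (2) each cluster is
binarized into variable–interval items; (3) FP-growth mines the cluster's
frequent itemsets; (4) candidates are counted against the full training
cohort and kept iff one class predominates.

**Maximal itemsets.** Only *maximal* frequent itemsets of a cluster become
candidate antecedents (`candidate_itemsets="all"` restores every itemset).
A maximal itemset is the most specific frequent description of the
subgroup; its sub-itemsets match supersets of the same patients and, used
as rules, mostly add generic antecedents that fire for both classes at
once. Empirically the "all" variant produces hundreds of rules whose
conflicting activations drive most defuzzified scores to exactly 0.5,
while the maximal variant yields rule bases of a few dozen rules and
two-thirds to three-quarters cohort coverage — the regime the method is
designed for.

**Predominance.** `max(n₊, n₋) / max(1, min(n₊, n₋))`, computed on the full
training cohort; a rule is kept iff this ratio ≥ `predominance_threshold`
and at least one patient matches. A pure rule (one class count zero) gets
the finite value `max count`, so a pure rule matching a single patient does
*not* automatically survive — deliberate, to avoid one-off rules.

## Tunable parameters

| parameter | default | units | rationale |
| --- | --- | --- | --- |
| SOM grid | 4×4 | neurons | subgroup resolution used in the field for cohorts of ~10³ |
| learning rate η | 0.4 | – | winner-take-most update step |
| neighbourhood φ | 1 / 0.5 / 0 | – | winner / lattice distance 1 / beyond |
| lattice metric | Chebyshev | – | "distance 1" includes diagonals; Manhattan switchable |
| SOM epochs | 50 | passes | empirically past convergence for ≤ 2·10³ records |
| `min_support` | 0.25 | fraction of cluster | a rule must describe ≥ ¼ of a subgroup |
| `predominance_threshold` | 2.0 | ratio | "strongly one-class": 2:1 majority |
| FIS threshold | 0.5 | score | crossing point of the two output triangles |
| PSA-density breakpoints | 0.10, 0.15 | ng/mL² | clinical biopsy-decision cut-offs |
| SVM C | 1.0 | – | unweighted hinge loss; config-exposed |
| KNN k | 33 | neighbours | the value used in the original subset search |

Membership functions: PSA-density terms low/medium/high are trapezoids
crossing at degree 0.5 exactly at 0.10 and 0.15; lesion-count terms 1/2/3+
are triangles on the integer axis; PI-RADS and the three binary variables
are crisp categories. The exact shapes used in the original clinical study
are not published; these defaults are assumptions, overridable per variable.

## Synthetic cohorts

`generate_synthetic_cohort` emulates the published development-cohort
demographics: prevalence 0.569; PSA ~ lognormal(mean 8.4, SD 7.5) ng/mL;
prostate volume ~ lognormal(55.8, 27.8) cc; lesion volume ~ lognormal(0.98,
1.91) cc; age ~ normal(69, 8) years; DRE positive 12 %; PI-RADS 3/4/5 at
27.9/56.6/15.5 %; peripheral lesions 85.5 %. Lognormals are used where the
published SD is of the order of the mean (a normal would generate negative
values). PSA density is computed as psa / prostate_volume, so the
record-level consistency invariant holds by construction.

Class-conditional structure is a location/probability shift applied to
positives — higher PSA, smaller prostates (hence higher density), older
age, more positive DREs, right-shifted PI-RADS — with the whole sample
rescaled so the *marginal* moments still match the published values. The
per-class effect sizes are **assumptions** (the study reports which
variables differ significantly, not by how much); defaults were chosen so
the class-specific rates aggregate to the published marginals (e.g. DRE+
16 % in positives, 7 % in negatives → 12 % overall at prevalence 0.569).
`CohortSpec.strong_signal()` is a separate preset with large separations on
every informative variable, used for discrimination sanity checks.

What the generator does **not** emulate: correlations beyond those induced
by the density = PSA/volume construction (real PSA co-varies with age and
lesion burden), measurement error and inter-observer variability in DRE and
PI-RADS, temporal drift between development and validation periods, and
missing data. Tests passing on these cohorts therefore demonstrate the
*mechanics* of the method — determinism, coverage, oracle equivalence,
metric arithmetic, discrimination under known signal — not clinical
performance on real patients.

`generate_logistic_cohort` draws the same features without class
conditioning and assigns labels from an explicit logistic model — the
fixture for coefficient-recovery checks of the regression baseline.

## Numerical conventions

* **Defuzzification** integrates on a fixed 1001-point grid over [0, 1]
  with trapezoidal quadrature; the pure-class centroids are 1/3 and 2/3 to
  ≈10⁻⁷. Scores produced by centroid defuzzification of the two default
  output triangles always lie in [1/3, 2/3].
* **Cascade ranking score** (for ROC/DCA): the defuzzified score where the
  rules classified the patient; otherwise the SVM margin squashed
  monotonically into the same [1/3, 2/3] band with margin 0 ↦ 0.5. The
  cascade is not a probability model; this score is a ranking device on a
  single scale across stages, and is documented as such.
* **Tie-breaks.** SOM winner and cluster assignment: lowest neuron index.
  KNN: all records tied with the k-th distance are included; a vote tie
  returns negative (conservative toward the NPV goal). SVM margin exactly
  0: positive (missing a cancer is the costlier error). Subset-search
  ranking ties: smaller subset, then lexicographic. FP-growth output:
  support descending, then lexicographic.
* **Frequency threshold.** Support ≥ `min_support` is evaluated as count ≥
  ⌈min_support·n − 10⁻⁹⌉, robust to floating-point representation of the
  fraction.
* **Rounding** of reported percentages: half-up to one decimal (the
  convention of the published tables), via `decimal.Decimal`.
* **Determinism.** All stochastic stages (generator, SOM init and
  presentation order, CV folds) take explicit seeds; the per-class SOMs use
  `seed` and `seed + 1`. Training twice with one seed yields byte-identical
  model files.
* **Degenerate inputs.** A class with fewer records than neurons triggers a
  warning (clustering degenerates to fewer effective clusters); empty rule
  bases, single-class cohorts, zero Gower ranges and uncovered binarization
  values raise typed errors naming the offending variable.

## Evaluation choices

The ROC "optimal threshold" criterion is Youden's J (max sens + spec − 1),
switchable to closest-to-(0,1); thresholds follow the "score ≥ threshold is
positive" convention. AUC is trapezoidal and equals the Mann–Whitney
U-statistic form on tie-free scores. Decision curves use the standard net
benefit `TP/n − FP/n · p_t/(1−p_t)` with treat-all/treat-none references;
the logistic baseline is a maximum-likelihood fit (statsmodels) reporting
coefficient standard errors. The cascade itself is never evaluated through
a library re-implementation — sklearn supplies only the SVM fit and the ROC
sweep, and the FP-growth, SOM, Gower-KNN and FIS cores are tested against
independent brute-force oracles.

Problem sizes used in the shipped tests and the acceptance script — cohorts
of 400–2 000 records for pipeline checks, 5 000–10 000 for moment- and
coefficient-recovery, 100 random transaction sets for the FP-growth oracle
— were chosen as the smallest sizes at which the statistical assertions
(3-SE bands, binomial CIs, AUC bands) are stable across seeds.

## Known limitations

* Rule bases and coverage depend on the SOM seed; rule *counts* vary by
  ±20 % across seeds even at fixed data (the kept-rule criterion is
  whole-cohort predominance, which stabilises rule *quality* more than rule
  count).
* The FIS score takes few distinct values when antecedents are mostly
  crisp, so within-stage ranking is coarse; AUC is driven by the
  stage-pooled ordering.
* Class-conditional generator effects are assumptions; conclusions about
  real cohorts require real data.
* Net-benefit is reported as standard decision-curve analysis; no
  single-number "net benefit" column is claimed for model comparison.
* No probability calibration: the cascade's score is a ranking, not a risk
  estimate (a cascade of a rule base and a margin classifier does not emit
  probabilities).
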