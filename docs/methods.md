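# Methods

This note documents the models and procedures implemented in `essgene`,
the defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical conventions that make every run
deterministic.

## Problem setting

Binary supervised classification of mouse protein-coding genes into
*essential* (single-gene knockout lethal before postnatal day 3) and
*non-essential* (knockout viable). Inputs are a genes × features table
with numeric and integer-coded categorical columns and missing cells,
optionally an interaction edge list and a gene → chromosome map. The
classes are imbalanced: viable genes outnumber lethal ones roughly 3:1
in curated knockout catalogues.

## Class balancing and the representative subset

Each balanced training set contains all minority-class (essential)
genes plus an equal-sized without-replacement sample of the majority
class. The draw is repeated (default 10 times) and each subset is
scored by k-fold cross-validation; the subset whose accuracy is closest
to the mean over draws is used for all further modelling, with ties
going to the lowest index. Choosing the subset nearest the mean, rather
than the best one, avoids inflating reported performance through subset
selection.

A structural consequence worth knowing: because every essential gene is
in every balanced subset, the genes outside the chosen subset — the
natural held-out set — are all non-essential. Held-out accuracy there
measures viable-class specificity only. A stratified external test set
is needed for TPR estimates; the evaluation module supports any labelled
table for that purpose.

## Pre-processing

* **Sparse-feature drop.** Features missing in more than
  `max_missing_fraction` (default 0.30) of genes are removed. The 0.30
  default separates the two missingness regimes seen in real
  essentiality tables — a block of interaction-network features absent
  for ~40% of genes versus everything else below ~12% — and is
  configurable.
* **Imputation.** Numeric features are filled with the training mean.
  Integer-coded categorical features use the training mode (ties to the
  smallest code): a fractional mean is not a valid category code, so
  mode imputation preserves the integer-code contract. Fill values
  learned on training data are reused unchanged on held-out tables.
* **Categorical handling.** Categorical features are carried as integer
  codes throughout and are exempt from discretisation.

## ChiMerge discretisation

Numeric features are discretised bottom-up against the binary class.
Initial intervals are the distinct sorted values (one value per
interval). Repeatedly, the adjacent pair with the smallest Pearson χ²
on its 2 × C interval-by-class contingency table merges, while that
minimum does not exceed the critical value at the configured
significance (default 0.95 → χ²₁⁻¹(0.95) ≈ 3.841; degrees of freedom are
(intervals − 1)(classes − 1) = 1 for the binary case). Conventions:

* expected-count-0 cells contribute 0 to the statistic (avoids division
  by zero when a class is absent from both intervals);
* ties for the minimum merge the leftmost pair, making results
  deterministic;
* cutpoints are midpoints between the last value of one surviving
  interval and the first observed value above it;
* a value equal to a cutpoint codes into the upper interval; values
  outside the training range clamp to the first or last interval;
* no maximum-interval cap is imposed.

Because distinct-value initialisation is quadratic in the worst case, a
quantile pre-binning cap (default 256 initial bins) is applied to very
high-cardinality features; the exact algorithm runs below the cap, and
tests of the merge logic disable the cap.

A post-fit certificate holds by construction: recomputing χ² for every
surviving adjacent pair yields values above the threshold. Schemes are
fitted on training rows only and applied unchanged to held-out rows.

**Known behaviour on continuous noise.** On a feature whose values are
all distinct and unrelated to the class, the greedy merge first fuses
same-class neighbours into pure runs; adjacent pure runs of opposite
classes are strongly class-associated and never merge, so tens of
intervals can survive and the feature acquires a positive information
gain. This is a documented property of the classic algorithm at this
significance level, not a defect of the implementation (the replay
oracle in the tests confirms the greedy rule step by step). It means a
noise feature rarely collapses to a single interval; what holds, and
what the recovery tests assert, is that genuinely class-shifted features
score clearly higher than noise in the information-gain ranking.

## Feature selection

* **Information gain.** IG(f) = H(Y) − H(Y | f), entropies base 2 over
  empirical frequencies, 0·log 0 ≡ 0. Features with IG = 0 are excluded
  from the retained ranking (all scores are still reported). Ranking
  ties break by feature name, so the result is invariant to column
  order.
* **GA wrapper.** Binary chromosomes (bit = feature included), fitness
  = mean k-fold CV accuracy of the chosen classifier on the candidate
  subset (the empty subset scores the majority-class rate instead of
  crashing). Defaults follow the classic GeneticSearch configuration:
  population 20, single-point crossover at 0.6, per-bit mutation at
  0.033, roulette selection on shifted fitness, 1 elite, 20
  generations, 10 fitness folds (3 in fast test profiles). Fitness
  values are cached per chromosome. Ties resolve toward the smaller
  subset, then the lexicographically lowest chromosome. Elitism makes
  the best-so-far trace non-decreasing. The winning subset's fitness is
  optimistically biased because the subset was selected for it; honest
  estimates require a held-out set.

## Classifiers and confidence

The primary model is a random forest, default 230 trees, bootstrap
sampling on and √m features per split (conventional defaults; the
ensemble size is the deliberate choice). Baselines: RBF-kernel SVM
(C = 50, γ default 0.01 from the canonical grid {0.1 … 0.0001}),
polynomial-kernel SVM (C = 50, degree ∈ {1..4}), logistic regression
with ridge 10⁻⁸ on the squared weights (implemented as inverse
regularisation C = 1/ridge), Gaussian naive Bayes, and a pruned decision
tree whose C4.5-style confidence factor 0.25 is approximated by
cost-complexity pruning.

Prediction confidence is defined for the forest: the fraction of trees
voting for the predicted class, hence in [0.5, 1] for binary majority
voting. An exact tie is called non-essential at confidence 0.5 — the
conservative choice, minimising false essential calls. Non-forest
families expose a probability-like essential-class score for ROC use
(SVM margins pass through a logistic link); their "confidence" is the
same max(score, 1 − score) construction but lacks the vote-fraction
interpretation.

## Evaluation

* **Cross-validation.** Seeded unstratified random partition into k
  near-equal folds (remainder spread one per fold from fold 0),
  matching a plain random split; a stratified option is deliberately
  not the default. Imputation and discretisation are refit inside each
  training fold and applied to its test fold — stricter than fitting
  them once on the full table before CV (which leaks label information
  through the cutpoints); the looser order is available via
  `refit_per_fold=False` for comparison.
* **Metrics.** TPR, FPR and accuracy from the pooled confusion counts;
  pooled accuracy is total correct over total genes.
* **ROC/AUC.** Threshold sweep over distinct scores with simultaneous
  steps on ties; trapezoid AUC, equal to the Mann–Whitney concordance
  probability with ties counted ½ (asserted against a brute-force
  pair-count oracle in tests).
* **Confidence comparison.** Each group (correct vs incorrect
  predictions) is Shapiro–Wilk-tested at α = 0.05; if both pass, Welch's
  two-sided unequal-variance t-test, otherwise the two-sided Wilcoxon
  rank-sum (Mann–Whitney) test. A zero-variance group is treated as
  non-normal so the tie-tolerant rank test is used.

## Network statistics

Edges carry a confidence in [0, 1] and an experimental-evidence flag.
Filtering keeps confidence ≥ 0.4 (default) and, when required,
experimental evidence; self-loops and duplicates collapse and isolated
nodes are removed. Summary conventions follow the NetworkAnalyzer
definitions: mean local clustering over nodes of degree ≥ 2; density
2E/(N(N−1)); average neighbours 2E/N (an identity, tested exactly);
heterogeneity = population (not sample) coefficient of variation of
degree; degree centralisation N/(N−2)·(d_max/(N−1) − density). The
power-law fit is least squares on the log-log degree histogram over
non-zero counts (matching the convention of the network tools this
mirrors) rather than maximum likelihood; the fit reports slope and R².

## Synthetic data generator

The generator emulates the *structural roles* of a real essentiality
feature table, not its marginal distributions:

* default class sizes 1307 essential / 3459 non-essential (the curated
  knockout catalogue proportions) and 102 features in typed blocks:
  heavy-tailed positive interaction-degree-like features (log-normal
  with wide latent scale — positive, right-skewed, matching scale-free
  degree spread), log-normal expression-like features, logistic-normal
  composition fractions in [0, 1], and integer categories with
  class-tilted level probabilities;
* one 10-feature block at 40% missingness (the sparse
  interaction-network block) and low missingness (2–8%) elsewhere;
* a 24-feature block with zero effect size plays the role of sequence
  summaries that carry no essentiality signal;
* class shifts are applied on the latent (log/logit) scale — essential
  +d/2, viable −d/2 in latent standard deviations — so values stay in
  their natural ranges; default effect sizes (0.9 for degree-like, 0.5
  expression, 0.25 composition, 0.4 categories) were chosen once to
  give a clearly learnable but imperfect signal, in line with
  cross-validation accuracies around 90–95% rather than a separable
  toy;
* features are drawn independently; real feature tables are strongly
  correlated (e.g. gene length with protein length), and no
  correlation structure is modelled — a flagged assumption. Passing
  tests therefore demonstrate correctness of the machinery under the
  stated statistical structure, not performance on real data;
* a single top-level seed derives per-block sub-seeds keyed on the
  block index, so appending a block never perturbs earlier blocks;
  identical spec + seed gives byte-identical tables.

The interaction-graph generator is preferential attachment from a
complete seed core of m + 1 nodes; each new node attaches to m distinct
existing nodes with probability proportional to degree, giving exactly
C(m+1, 2) + m(n − m − 1) edges and a scale-free degree distribution.
Edge confidences are uniform on [0.4, 1] with an 80% experimental-
evidence rate, mimicking a filtered database export.

## Problem sizes in tests and the acceptance script

Test and demonstration runs use reduced problem sizes chosen as the
package's own fast profiles: pipeline smoke/determinism runs at a few
hundred genes with 2–3 subsets and 30–60 trees; the GA recovery check
uses 300 genes, 5 planted (d = 1) + 15 noise features, naive-Bayes
fitness with 3 folds; the well-separated benchmark uses 600 genes with
effect size 3. Determinism and correctness of each code path do not
depend on n, so the reduced profiles exercise the same logic as the
full-scale defaults. The acceptance script additionally runs the
complete default-scale study (10 subsets of 2 × 1307 genes, 10-fold CV,
230 trees) once.

## Known limitations

* The workflow's own performance numbers on synthetic data say nothing
  quantitative about real essentiality tables (no real marginals, no
  feature correlation, no label noise).
* ChiMerge at significance 0.95 with distinct-value initialisation
  over-segments continuous noise (see above); a max-interval cap is
  deliberately not imposed.
* The GA fitness is evaluated on the same table that selection
  optimises; reported fitness is optimistic by construction.
* Confidence semantics are forest-specific; calibrations of the
  baseline families' scores are not modelled beyond a logistic link for
  SVM margins.
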