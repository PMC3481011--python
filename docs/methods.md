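# Methods

This note documents the statistical model behind `implinet`, the choices
made where the design was genuinely open, and what the synthetic-data tests
do and do not demonstrate about real cohorts.

## Implication rules on dichotomized expression

Expression of each gene is dichotomized against its mean in the designated
training samples: state 1 ("up") strictly above the mean, state 0 ("down")
at or below it, ties included. Reference means are frozen at training time
and reused unchanged on test cohorts — the same frozen-parameter principle
applied to the Cox risk model below.

For an ordered gene pair (A, B) with 2×2 joint counts n_ij over N samples,
six rule types are evaluated, each defined by its error cells:

| rule | reading | error cells (A,B) |
|---|---|---|
| A⇔B  | concordant up/down | (1,0), (0,1) |
| A⇔¬B | discordant | (1,1), (0,0) |
| A⇒B  | up(A) forces up(B) | (1,0) |
| A⇒¬B | up(A) forces down(B) | (1,1) |
| ¬A⇒B | down(A) forces up(B) | (0,0) |
| ¬A⇒¬B| down(A) forces down(B) | (0,1) |

With V the observed error-cell mass and K the expected mass under marginal
independence (products of the row/column marginals summed over the error
cells), the rule's **precision** is the prediction-logic del statistic

    ∇ = 1 − V / K,

the proportionate reduction in rule error relative to chance. ∇ = 1 exactly
when the error cells are empty, 0 at independence. The **scope** U is the
fraction of samples the premise covers: the antecedent marginal for the
four directional rules, structurally 1 for the equivalences.

**Significance.** Precision is tested one-sided with

    z = (N·K − N·V) / sqrt(N·K·(1−K)),

i.e. the error count treated as Binomial(N, K) under independence. Scope is
tested against a configurable minimum coverage (default 0, which makes the
scope test structural: any non-empty premise passes). An edge requires both
tests at p < α (default 0.05) plus ∇ > 0. These estimator forms are a
reconstruction — the historical implication-induction software did not
publish its exact formulas — and they are deliberately pinned by exact
worked examples in the test suite (e.g. table (40,10,10,40) under A⇒B gives
V = 0.10, K = 0.25, ∇ = 0.6, z = 3.464).

**Calibration caveat.** Under a *label-permutation* null both marginals are
fixed, so the error count of a single-error-cell (directional) rule is
hypergeometric with variance roughly (N−n_A)(N−n_B̄)/N² times the binomial
variance used by z. The binomial z is therefore conservative for the
directional rules (measured per-rule type-I ≈ 0.002 at nominal 0.05, versus
≈ 0.047 for the two equivalence rules, whose permutation variance the
binomial matches when marginals are balanced). The package ships an exact
permutation oracle (`permutation_pvalue`) for users who want the
permutation-calibrated p; the analytic z is retained as the edge criterion
because the worked arithmetic above pins it.

**Rule selection.** All six rules are scored per pair; among significant
rules the maximum-∇ rule is stored, with exact ties resolved in favour of
the equivalences and then a fixed rule order. Degenerate all-up/all-down
state vectors produce no edge rather than an error. One rule at most is
stored per unordered pair, oriented from the lower-index gene.

## Screening and network construction

The candidate set for network analysis is built in a fixed order: a
univariate Cox proportional-hazards screen of every gene against overall
survival (Wald p < α, raw p-values, continuous expression as the single
covariate), then a two-sided Welch t-test screen of the survivors for
smoker-vs-non-smoker differential expression, then the union with the hub
(signaling-pathway anchor) genes, which enter regardless of screen results.
Welch rather than pooled-variance t was chosen because group variances are
not assumed equal; an optional Benjamini–Hochberg flag exists but is off by
default, matching the raw-threshold screening design. Samples with missing
smoking status are excluded from screening and network construction with a
logged count. Quantile normalization (columns forced onto the mean
order-statistic distribution, ties averaged) is applied before screening by
default and is idempotent.

## Differential networks, validation, signature selection

Implication networks are built separately for the smoker and non-smoker
groups of the training cohort. A pair is a **differential component** when
it carries an edge in one group and no edge of any type in the other; pairs
with different rule types in both groups are reported separately
("type-changed") and excluded from selection by default (a toggle treats
them as differential for both groups — the looser reading of "comparing the
coexpression types"). Differential edges are **validated** against an
independent test cohort dichotomized with the training means: an edge from
group G survives iff its training rule type is significant in the test
cohort's group G and no rule is significant for the pair in the other test
group. Validation never adds edges. **Signature genes** are then the
non-hub genes whose validated group-specific edges reach *every* hub.

A known statistical consequence of the strict presence/absence definition:
each planted pair must avoid a chance edge (any of six rules at α = 0.05,
union rate ≈ 0.09 per null pair) in the other group twice (training and
test). With 6 hubs this makes *perfect* recovery of a planted all-hub gene
an ≈ 0.55 event per gene per cohort pair, so a 7-gene planted signature is
typically recovered as a proper subset (measured: mean gene recall ≈ 0.6,
zero false-positive genes over 20 default cohort pairs). Relaxing α for the
"absence" check, or counting type changes as differential, trades this
false-negative rate against specificity; both knobs are exposed.

## Network evaluation

Edges are labeled against an annotation collection ingested uniformly from
GMT gene-set files plus two-column interaction lists: TP if the pair shares
any set or has an interaction, FP if both genes are annotated but share
nothing, ND if either gene is outside the annotated universe. Network
precision is TP/(TP+FP), the q-value FP/(TP+FP); ND edges are excluded from
both. Precision is reported for the validated signature subnetwork (the
hub edges of the selected genes), the network the analysis ultimately
reports.

**Permutation FDR.** The smoker labels of the *test* cohort are permuted;
for each permutation the fixed training differential edge set is
re-validated against the permuted groups and the q-value of the surviving
edges recorded; the FDR is the mean q over permutations (permutations with
no labeled edge are skipped and counted). The edge universe defaults to
the full expression matrix so the permuted null sets are non-degenerate.
On synthetic cohorts whose decoy annotations mark a random annotated pair
TP with probability ρ, the permuted survivors are essentially random
pairs, so the FDR concentrates at 1−ρ (measured 0.501 at ρ = 0.5 with 200
permutations on the default cohort).

**Stability.** The reference set is the validated differential relations
from the full training data; each of n_iter iterations subsamples the
training cohort without replacement within each smoking group (preserving
the group ratio, default fraction 0.8), re-runs dichotomization → networks
→ differential → validation, and records the fraction of reference
relations retrieved. Relations, not post-selection genes, are counted:
that is what the stability of a coexpression network measures, and it
avoids the all-hub selection step amplifying single-edge noise. Fraction
1.0 reproduces the reference exactly (stability ≡ 1).

## Prognostic and diagnostic models

The signature genes are fitted jointly in a Cox proportional-hazards model
(partial likelihood, lifelines); the linear predictor Σ βᵢxᵢ is the risk
score. The score threshold maximizes the Youden index (sensitivity +
specificity − 1) on the 3-year ROC curve, with death within 36 months as
the outcome and samples censored before 36 months excluded; ties resolve
to the lower threshold and a near-chance AUC is flagged as unstable. Both
the outcome definition and the Youden criterion are reconstructions of
"best prediction on the 3-year ROC curve" and are exposed in the API.
Coefficients and threshold are frozen and applied to test cohorts without
re-estimation (asserted by a serialization round trip). Stratified groups
are compared by Kaplan–Meier curves and the log-rank test; the dichotomized
risk group enters a multivariate Cox model next to gender (male = 1),
age > 60, tumor differentiation (well as reference) and stage (I as
reference), reported with and without the risk-group row. Association of
the risk group with smoking or cessation uses Pearson's χ² without
continuity correction (expected-count < 5 warnings are raised, not fatal).

Diagnosis uses a k-nearest-neighbour classifier (default k = 1, Euclidean)
on the signature genes, with per-gene standardization by frozen training
mean/SD (a documented addition; toggleable). Performance is summarized by
accuracy and the odds ratio ad/bc with the Woolf logit 95% CI, Haldane–
Anscombe +0.5 correction when a cell is zero, and a two-sided Wald p.

## Synthetic cohorts

The generator plants structure at the state level and maps states to
expression as μ_g + δ·state + ε, ε ~ N(0, σ²), with δ = 1.5 log2 units and
σ = 0.5 by default. A per-sample latent binary factor drives the hub genes
in all samples; smoker-planted signature genes follow the latent factor
(through their assigned rule type) in smoker samples only, the non-smoker
gene in non-smoker samples only; background genes are independent fair
coins. Planted violations flip states at rate 0.02. Three further choices
make the planted genes discoverable by the screening stages, sized by a
design-stage power analysis at the default 150/150 cohort:

- per-gene baseline means μ_g are a stable function of the gene name, not
  of the cohort seed, so independently generated train/test cohorts share
  expression levels the way two cohorts on one platform do;
- planted genes carry a ±1.5 log2 smoker/non-smoker mean shift (t-screen
  power ≈ 1);
- survival risk is Σ effect_g·(state_g − 0.5) with effects sign-aligned to
  each gene's latent orientation (±0.65; 2.0 for the lone non-smoker gene,
  which cannot borrow the shared latent signal), event times exponential
  with hazard 0.03·exp(risk) per month, administrative censoring at 60
  months plus 10% random dropout.

What the generator does **not** emulate: probe-level measurement, batch and
institution effects, correlated background co-expression modules, missing
values, or non-proportional hazards. Passing the synthetic tests therefore
demonstrates the machinery's correctness and calibration under its own
assumptions, not performance on real microarray cohorts.

## Numerical and engineering notes

- Network construction is vectorized over all pairs (counts via integer
  matrix products); a 213-gene, 300-sample cohort builds both group
  networks in well under a second.
- Default problem sizes in the test suite and acceptance script (e.g. 10–20
  cohort-pair seeds, 200 permutations, 20 stability iterations) are chosen
  to estimate each rate to within a few percent.
- All randomness flows from named substreams of one master seed; pipeline
  reruns are byte-identical (stage timings live in a separate file).
- k-NN tie-breaking for even k follows scikit-learn's convention; the
  default k = 1 never ties.
- Known limitations: the analytic z is conservative for directional rules
  (see above); the strict differential definition trades recall for
  specificity (see above); χ² association tests are asymptotic and warn on
  small expected counts.
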