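# Methods

## Problem setting

`qsarscreen` models binary inhibitor activity from precomputed molecular
descriptors and screens compound libraries through a consensus funnel. A
compound is *active* when its IC50 is at or below 1 μM (the boundary is
inclusive and configurable); everything above the boundary is kept as
inactive by default, with an optional exclude-range for the ambiguous
1–10 μM zone. Duplicate activity records sharing a canonical structure
key are collapsed to the median IC50 — robust against a single outlier
assay — with a keep-first alternative; the structure canonicalizer is a
pluggable hook (the identity key by default) so a chemistry backend can
supply validity/organic-element filtering when structures are real.

## Descriptor selection

Tier 1 removes redundancy: the upper triangle of the Pearson correlation
matrix is scanned in descriptor-name order and, for every pair with
|r| > 0.85 whose members are both still alive, a seeded RNG picks the
member to drop. Absolute correlation is used because redundancy is
sign-agnostic. The greedy scan is deterministic given the seed; constant
columns are removed first since their correlation is undefined.

Tier 2 is Boruta. Each iteration appends a shuffled shadow copy of every
candidate, fits a random forest (default 50 trees, depth 5 — depth-limited
forests give stable impurity importances at the problem sizes used
throughout, 400 × ~100 features; configurable, including permutation
importance), and records a hit for candidates whose importance exceeds the
maximum shadow importance. After n iterations (default 100) hit counts are
tested two-sided against Binomial(n, ½) at α = 0.05 with Bonferroni
correction across candidates: significantly above half → confirmed, below
→ rejected, otherwise tentative. Tentatives are excluded from the kept set
by default; a rough-fix option resolves them by comparing each tentative's
median importance to the median of the per-iteration shadow maxima.

## Models

Four classifiers are trained on identical descriptors and labels: SVM
(RBF kernel; margins are not probabilities, so a Platt-style sigmoid
calibration supplies them), random forest (500 trees), XGBoost (300
rounds, depth 6, learning rate 0.1) and kNN (k = 5,
inverse-distance-weighted vote fraction as the probability). SVM and kNN
standardize inputs with train-set mean/SD inside their pipelines; tree
ensembles consume raw values, since only the former are scale-sensitive.
Hard labels follow p ≥ 0.5 → active everywhere, including exactly 0.5
(this also settles kNN ties at even k). The consensus call is hard-label
unanimity across the four models, which makes the consensus-active set a
subset of every model's active set and monotone in any per-model
threshold. The default split for evaluation is stratified 80/20 under a
fixed seed.

## Evaluation statistics

precision = TP/(TP+FP), recall = TP/(TP+FN), accuracy = (TP+TN)/n,
F1 = 2PR/(P+R). (Printed variants that give precision the recall
denominator, or drop the factor 2 from F1, circulate in the applied
literature; they collapse precision onto recall and halve F1, so the
standard forms are implemented.) Zero-denominator ratios are reported as
undefined with a reason, never coerced to 0. AUC uses the midrank
(Mann–Whitney) formulation — the probability that a random active
outscores a random inactive with ties counted ½ — which the test suite
checks against a brute-force all-pairs count; ROC curve points come from
scikit-learn for plotting. Cumulative gain sorts by score descending with
a stable tie-break on input order; gain(d) is the fraction of all actives
in the top ⌈d·n⌉. Outcome-stratified probability summaries group scores
by TP/TN/FP/FN under the 0.5 rule.

## Applicability domain

Descriptors are standardized by training mean/SD and projected onto the
leading principal components (default 2). The domain is the axis-aligned
box spanned by the training scores per component, optionally expanded by
`margin × range` per side; a query is inside iff every component score is
within bounds. A box was chosen over density or leverage criteria because
it is deterministic, margin-controllable, and mirrors the usual PC1/PC2
scatter argument; a convex-hull criterion on the first two components is
available. Training scores are recomputed through the query-path
projection so every training compound is inside its own domain at margin
0 bit-for-bit.

## Y-randomization

Each of n runs (default 500) draws ⌈fraction·n_train⌉ training compounds
without replacement (default 50%), permutes their labels, retrains the
model with identical hyperparameters, and records accuracy and AUC on the
untouched held-out test set with true labels — the held-out variant was
chosen as the default evaluation set so the scrambled and reference
models are scored on the same data. Draws that come out single-class are
redrawn and counted. Per-run RNGs derive from `SeedSequence([seed, run])`,
so any run is independently reproducible; with fraction 1 and the
identity permutation the protocol reproduces the reference model exactly.
On balanced data scrambled models must hover at accuracy ≈ 0.5, and the
reference model must beat the maximum scrambled run.

## Fingerprints

166-bit structural keys are handled as plain bit tables.
Tc = C/(A+B−C); an all-zero pair is defined as 0 (the expression is 0/0)
with a warning, a conservative dissimilarity. Pairwise matrices use the
bit-count identity C = A·Bᵀ. Per-class bit frequency is
100 × on-count / class size; differential bits are those whose
active-minus-inactive frequency difference reaches a configurable
threshold, default 10 percentage points, ranked by difference with ties
broken by bit index. Mapping bit indices to substructure definitions is a
plugin concern, out of scope here.

## Screening funnel

Filter 1: unanimous active call. Filter 2: mean of the four probabilities
at or above a threshold; the mean treats the models symmetrically, and a
per-model-minimum rule is available for stricter presets (e.g. 0.6).
Filter 3: inside the applicability domain. The final pass is the strict
conjunction; passing compounds are ranked by mean probability, ties by
compound id. Each hit is annotated with its maximum Tanimoto similarity
to the training actives and flagged novel at Tc ≤ 0.5. Missing
fingerprints degrade the annotation, never the filters.

## Synthetic data: what it emulates and what it does not

The generator emulates the statistical structure of a curated two-class
inhibitor set: balanced classes (200 + 200 by default), 54 descriptors —
5 informative columns whose class-conditional means differ by Cohen's
d = 2, 45 N(0,1) noise columns, and 2 redundant pairs built as
x₂ = ρx₁ + √(1−ρ²)ε with ρ = 0.9 so the >0.85 filter always has work to
do — plus 166-bit fingerprints with 8 bits enriched in actives
(p = 0.8 vs 0.4) over a 0.3 baseline. IC50s are log-uniform within each
class's side of the boundary. All sampling uses NumPy's PCG64 generator
under one explicit seed, giving bit-identical output across platforms.

It does **not** produce chemically valid structures, realistic descriptor
marginals (real descriptors are skewed, discrete and block-correlated),
activity cliffs, or assay noise. Passing tests therefore demonstrate that
the algorithms behave as specified under their own assumptions — signal
recovery, chance-level scrambled performance, domain exclusion — not that
any particular real-world screen would reach the same operating
characteristics.

## Problem sizes and numerical choices

The reference study conditions used by the test suite and the acceptance
script are 400 compounds × 54 descriptors, an 80/20 stratified split, 100
Boruta iterations, 500 y-randomization runs, and screening libraries of
400–1000 compounds with 30% decoys shifted 10 SDs. Boruta recovery is
assessed over 20 seeds. Tolerances: exact equality is asserted wherever
the computation is deterministic (metrics, Tanimoto, AD membership);
Monte-Carlo assertions use 3-standard-error bands or the stated
success-fraction criteria. Degenerate inputs (all-zero fingerprints,
zero-variance descriptors, single-class draws, empty outcome groups) are
handled explicitly as described above rather than erroring deep in a
dependency.

## Known limitations

- The per-model probability calibration differs in character (Platt for
  SVM, vote fractions for kNN, raw ensemble frequencies for forests), so
  mean-probability ranking mixes differently calibrated scores.
- The box-shaped domain overcovers in directions where training scores
  are sparse and ignores correlations between components.
- Boruta's Bonferroni correction is conservative; with many hundreds of
  candidates the tentative set grows and a rough-fix pass may be needed.
- Duplicate resolution assumes IC50s on a common assay scale; no
  assay-quality weighting is attempted.
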