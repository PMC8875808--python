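# Methods

## The adaptive administration model

The package treats fall-risk assessment as sequential classification. A
subject's 14 BBS task scores (each 0–4) determine a total (0–56) and hence
a risk band: high (0–20), medium (21–40), low (41–56), ordinal-coded
high = 0, medium = 1, low = 2 so that an adjacent-band error contributes 1
to the ordinal MSE and a high↔low error contributes 4.

For every task subset `SS` a random forest predicts the band from the
subset's scores alone. An adaptive session administers tasks one at a
time: after each task the current subset's predictor emits a band and a
confidence, and the session stops when the confidence reaches the
threshold `CT`, otherwise a greedy selector (Methods 1–4, see README)
chooses the next task. The approach assumes (i) the training cohort is
exchangeable with the patient being tested, (ii) task scores are
informative about the band individually and jointly, and (iii) the
ensemble confidence is a usable proxy for the probability of a correct
prediction. None of these is checked at run time; the evaluation module
exists to measure them empirically.

## Key parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `ensemble_size` | 100 trees | subset-predictor forest size; standard small-cohort setting |
| `max_depth` | 10 | enough to memorise any pattern over ≤14 ordinal features; limits runtime |
| `CT` | 0.96 | stopping threshold on the ensemble confidence, grid 0.90–1.00 in evaluation |
| `sigma2` | `"auto"` | similarity bandwidth; auto = median pairwise squared distance of training restrictions to the current subset, recomputed each step, floored at 1e-6 |
| SVM `C`, `γ` | 3, 1/14 | full-battery RBF reference classifier |
| initial subset | best singleton | re-optimised per CV fold by training accuracy; sizes 1–3 supported |
| `missing_rate` | 0.05/task | generator's per-task missingness |

## Confidence

Confidence is the ensemble-averaged class probability of the predicted
class — the mean over trees of each tree's leaf class fractions, i.e.
`predict_proba` of a scikit-learn forest — with ties broken toward the
higher-risk band (the conservative clinical choice, applied wherever the
three class scores are compared). A hard modal *vote share* was evaluated
first and rejected: over a handful of 0–4 ordinal features bootstrapped
trees almost always agree, so the vote share sits at 1 even for score
patterns whose leaves are heavily class-mixed, and the stopping threshold
stops discriminating (every session ends at the initial subset). The
averaged posterior keeps the leaf mixing information, so `CT` trades tasks
for accuracy as intended. Probabilities are not otherwise calibrated.

## Selector details

- The per-subject weights of Methods 2–4 use the strict inequality
  `Conf(CSS, x_i) < CT`, exactly as the objective is defined; the *session*
  stopping rule is `confidence ≥ CT` (configurable to strict `>`), so the
  threshold itself is attainable.
- All sums run over training subjects complete on the augmented subset
  `CSS ∪ {T}` (subjects with a missing score in a subset are never imputed,
  mirroring per-task sample-size variation in real cohorts). Method 4's
  all-tasks predictions exist only for fully complete subjects; incomplete
  ones drop out of its sum.
- Ties in the argmax go to the lowest standard task number, for
  reproducibility.
- If the weights annihilate every candidate's objective (e.g. no training
  subject is below `CT`), the selector falls back to the Method-1 objective
  and logs a warning rather than picking arbitrarily.

## Predictor bank mechanics

Banks default to lazy training with caching: a greedy session touches
O(k²) subsets per path, so eagerly fitting all 2¹⁴ − 1 forests is wasteful
(eager enumeration remains available and is what the all-subsets
cardinality check exercises on a 4-task battery). Each subset's forest is
seeded by hashing (master seed, sorted subset), so lazy and eager training
produce bit-identical models. A subset whose complete-case training
restriction collapses to a single class yields a logged constant predictor
(that class, confidence 1) instead of a forest.

Ranking is by training accuracy, then mean training confidence, then
smaller subset, then lexicographic task ids. The initial subset of a
session is the top-ranked subset of the requested cardinality.

## Synthetic cohorts

No clinical score cohort is publicly deposited, so the generator emulates
one. Each subject draws a latent balance ability θ from a three-stratum
Gaussian mixture; task `t` scores are `Binomial(4, logistic(a_t(θ − b_t)))`
(difficulty `b_t`, discrimination `a_t > 0`), giving the closed-form task
mean `4·logistic(a_t(θ − b_t))` used by the generator's own tests. Labels
are computed from the *pre-masking* totals, then per-task missingness is
applied, so stored labels are always sum-consistent. The default profile
makes task 3 (sitting unsupported) near-universally top-scored and tasks
12–14 the hardest, weights the low-risk stratum heaviest, and places the
stratum means where the expected totals sit mid-band (≈11, 30, 49 of 56) —
distinct strata with only the binomial noise creating boundary-ambiguous
subjects. One seeded `numpy` generator drives everything; equal seeds give
bitwise-equal cohorts.

What the generator does **not** emulate: rater disagreement and scoring
error, within-subject task correlations beyond the single latent ability,
informative missingness (tasks skipped *because* a subject is frail), or
cohort-specific score distributions. Results on this profile therefore
demonstrate that the machinery behaves as designed under its assumptions —
not that any particular accuracy or session length will transfer to a
clinical population.

## Evaluation choices

- Cross-validation is stratified five-fold by risk band (leave-one-out is
  available for the SVM reference). Every trained artifact — bank, initial
  subset, selector statistics — is refit per fold on the training split
  only; fold hygiene is asserted via cohort fingerprints.
- Pooling: accuracy and mean-tasks are computed over the held-out
  predictions of all folds pooled, not averaged per fold.
- Sessions are evaluated on held-out subjects complete on the whole
  battery: at administration time a live subject can perform any task, so
  missingness is treated as a training-data artifact.
- The occurrence matrix places a session's initial tasks at the leading
  positions in ascending task order (positions are only meaningful for
  singleton initial subsets, the configuration used for sequence analysis).
- ICC is the consistency form ICC(3,1) — two-way mixed model, single
  measure, `(MSR − MSE)/(MSR + MSE)` for two raters — including the
  per-subject minimum of two raters as a derived conservative column.
  Absolute-agreement ICC is not implemented.
- Threshold adjustment for false negatives normalises the full-battery
  classifier's per-class scores and assigns the highest-risk class whose
  share reaches `τ`, falling back to the modal class; lowering `τ` can only
  add high-risk calls.

## Problem sizes

The shipped experiments use a 300-subject default cohort, five folds, and
the 0.90–1.00 threshold grid — large enough for stable band proportions
and repeatable accuracies at desk scale. Toy batteries of 4 tasks with
12–40 subjects back the exhaustive oracle checks (all 15 subsets, brute
force objective enumeration).

## Known limitations

- Greedy selection only; no lookahead or task-cost weighting.
- Forest confidences are uncalibrated; `CT` is a tuning dial, not a
  coverage guarantee.
- The short-form comparator's 7-task membership is configuration — the
  package enforces only its size and evaluates it on the 0–4 scores.
- With heavy missingness, per-subset training sets shrink and lazy banks
  can fall back to constant predictors; the logs flag this.
- Toy batteries with fewer than 14 tasks rescale the band cuts
  proportionally to the battery's maximum total when labeling synthetic
  cohorts.
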