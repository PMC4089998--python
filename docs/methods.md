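# Methods

## Data model

One record is one color choice: `(group, participant, odor, choice_type,
color_id)` with `choice_type ∈ {congruent, incongruent}` and
`color_id ∈ 1..36`. A trial (one participant × one odor) is exactly 3
congruent and 3 incongruent choices; the two sets are distinct within type
and disjoint across types within the same trial (the same color may of
course be chosen as congruent by one participant and incongruent by
another). Identifiers are trimmed and lower-cased; odor and group orderings
are taken from configuration when given, else lexicographic, so every
matrix output has a reproducible row/column order. The palette is the
Berkeley Color Project's 32 chromatic colors (8 hues × saturated/light/
muted/dark) plus white, light gray, dark gray, black; its RGB coordinates
are approximate sRGB renderings used only by figures — every statistic
depends on the integer id alone, so palette color fidelity cannot affect
results.

## Color patterns

The unit of analysis is the 72-feature pattern per (group, odor): positions
1–36 count congruent choices per color, 37–72 incongruent choices. Each
half sums to 3n for n contributing participants. For classification,
participants are partitioned into near-equal folds (e.g. 7/7/6 for n = 20)
and one pattern is compiled per (fold, odor); fold patterns sum elementwise
to the whole-group pattern. Because folds differ in size, patterns fed to
the classifier are normalized by the fold's participant count (counts / n),
removing a pure scale difference between folds. Correlation-based
dissimilarities are computed on raw pooled counts, since Pearson r is
location/scale invariant. Both choices are exposed as flags
(`normalize`, `feature_mask`); `feature_mask` also supports a
congruent-only variant of any analysis.

## Consistency tests

Per odor, the congruent and incongruent 36-cell vectors are each tested
against the uniform expectation E = 3n/36 per cell with the Pearson
statistic Σ(O−E)²/E, df = 35, p from the chi-square upper tail; the results
table reports both, plus a combined statistic (their sum, df = 70) as the
per-odor headline, labeling the convention explicitly. Bonferroni
correction uses m = |groups| × |odors| by default (84 in the 6 × 14
design; per-test threshold 0.05/84 ≈ 0.0006). Cells are never pooled; when
E < 5 (i.e. n < 60) a warning is logged rather than switching tests.

Two calibration caveats, both verified by simulation in the test suite:
(i) with E ≈ 1.7 the asymptotic approximation is rough; (ii) more
importantly, the three choices within a trial are *distinct* colors
(sampling without replacement), which underdisperses cell counts relative
to the multinomial the chi-square assumes (per-cell variance factor
≈ 0.94). The test is therefore conservative on truly association-free
data: Monte-Carlo puts the realized type-I error near 2–2.5% at nominal
5%, not at 5%. Rejections remain trustworthy; power is slightly
understated.

## Classification

`fld_fit` computes class means and the pooled within-class covariance with
the maximum-likelihood denominator n (so duplicating every training
pattern leaves the model unchanged), then shrinks it:
Σ = (1−s)·S + s·(tr S/72)·I. Shrinkage is mandatory — with 3 folds and 14
odors the training set has ~28 patterns in 72 dimensions, so S is singular
— and s defaults to the analytic variance-minimizing (Ledoit–Wolf)
estimate computed on the pooled within-class deviations; any fixed
s ∈ [0, 1] can be supplied. If the within-class scatter is exactly zero
(degenerate data) the identity metric is used, reducing the classifier to
nearest class mean — which is also its exact behavior at s = 1, a fact the
tests check against a brute-force oracle and against a reference
shrunken-covariance LDA implementation. Prediction maximizes the
equal-prior Gaussian discriminant; ties break to the first label in sorted
class order.

`cv_accuracy` runs one cross-validation pass per refolding: partition
participants into `n_folds` (default 3) seeded near-equal folds, rotate
each fold as test once, and score the fraction of held-out (fold, odor)
patterns classified correctly — accuracies are therefore multiples of
1/(n_folds × n_odors). The permutation null redraws, per repetition, an
independent random permutation of the 36 color ids for every
(participant, odor) trial, applies it to both halves of that trial's
counts, and runs one fresh cross-validation pass. Per-trial (rather than
one shared) permutation is the default because a single global relabeling
preserves cross-participant agreement — every analysis here is invariant
under it, a property the tests assert — and so cannot serve as a stability
null; the shared variant and a fully nested scheme (refold `n_shuffles`
times per permutation) are available as options. The p-value is
add-one-smoothed: (1 + #{null ≥ observed mean}) / (1 + n_permutations).

## Representational similarity

First-order RDMs use whole-group pooled patterns: cell (i, j) is
1 − Pearson r between odors i and j (range [0, 2]); the diagonal is set to
exactly 0 by construction rather than computed, avoiding ±1e−16 residue.
The RDM null reuses the per-trial color-shuffle scheme and collects
strict-upper-triangle values over repetitions; for association-free data
its mean sits at ≈ 1 (independent patterns, r ≈ 0). A participant
bootstrap (resampling participants with replacement) is provided
separately as an uncertainty — not null — estimator. The second-order RDM
correlates two groups' RDM upper triangles (1 − Pearson r by default;
Spearman behind a flag, since rank correlation is common for second-order
comparisons and the right choice is genuinely open).

## Synthetic data generator

The generator emulates the structure the analyses are designed to detect,
not any fitted estimate of real populations. Per odor, a global
congruent/incongruent profile pair is drawn from a symmetric
Dirichlet(κ) over the 36 colors; each group's profile is the ρ-weighted
mixture of that global pair with a group-specific Dirichlet(κ) draw, and
groups listed in `group_pairs_shared` receive identical profiles (planted
second-order structure). Trials sample 3 congruent colors by sequential
weighted sampling without replacement from p_cong, then 3 incongruent
colors from p_incong restricted to the 33 remaining colors — disjointness
holds by construction. Every trial has its own RNG stream keyed by
(seed, group, participant, odor), so datasets are bit-reproducible and
invariant to generation-loop order. The association-free null draws each
trial's 6 distinct colors uniformly.

Defaults mirror the emulated study design: six groups sized
20/20/20/20/20/22 (122 participants), 14 odors, 36 colors. κ = 0.5 and
ρ = 0.3 were fixed once as a clearly-detectable operating point: spiky
enough that consistency tests and the classifier should fire decisively on
structured data (classifier accuracy far above the ~7% chance level —
deliberately stronger than typical human consistency, so pipeline defects
are unmistakable), with partial cross-group sharing so second-order
structure is non-trivial. Profiles are shared by all participants within a
group; participant-level heterogeneity, odor intensity, and demographic
covariates are out of scope, which means passing tests demonstrate
correctness of the pipeline under the profile model, not effect sizes to
expect from human data.

## Problem sizes and numerical choices

The test suite and the acceptance script scale stochastic stages to
desk-size while keeping the study-shaped design: chance-level
classification uses the full 6 × 20 × 14 null study with 200 refoldings
and a 500-repetition permutation null per group; calibration and
planted-recovery properties use ~100 seeded replicates; unit tests use
2–20 participants and 3–8 odors. All randomness flows from explicit seeds
through `numpy.random.SeedSequence` streams. Symmetry is enforced to
1e−12, dissimilarities are clipped to [0, 2] only within 1e−9 of the
boundary (anything further violates validation), and matrix solves use a
Cholesky factorization of the shrunk covariance, whose positive
definiteness is checked at model construction.

## Known limitations

- The chi-square consistency test is conservative under the within-trial
  distinctness constraint (see above); an exact or permutation-calibrated
  alternative is not implemented.
- The generator's Dirichlet profile model has no participant-level
  heterogeneity and no response-order or device effects.
- Second-order comparisons on few odors (< 5) rest on short upper-triangle
  vectors and are accordingly noisy.
- Figures render approximate sRGB palette coordinates; they are faithful
  to color identity, not to colorimetric stimulus values.
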