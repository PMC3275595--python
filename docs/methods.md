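# Methods

## The problem

Linear B-cell epitopes are short contiguous antigen stretches recognised
by antibodies. A long-standing question is *which* physico-chemical
propensities of amino acids (hydrophilicity, surface accessibility,
turn preference, ...) actually determine whether a 20-mer peptide is an
epitope. A propensity scale contributes 20 positional values per peptide,
so the features it generates must be accepted or rejected *as a block*:
ordinary per-feature selection is the wrong tool. This package implements
group feature selection for that setting with a gated multilayer
perceptron, plus the evaluation protocols that make the selection
interpretable.

## The model

Peptides of length 20 are encoded under `k = 8` propensity scales, each
first normalised to [-1, 1] by the symmetric min-max map
`v' = 2(v - Rmin)/(Rmax - Rmin) - 1` (the unique affine map sending the
scale's extremes to ±1; it preserves residue rank order and is invariant
to positive affine transforms of the raw scale). The encoded vector has
160 entries laid out group-major — 20 contiguous positions per scale — so
one gate masks one contiguous slice.

The classifier is a three-layer perceptron (160 inputs, `n` sigmoid
hidden units, one sigmoid output, 0.5 decision threshold) in which every
feature of group *i* is multiplied by an attenuator gate
`G_i = sigmoid(lambda_i)` in [0, 1] before entering the network.
Training is gradient descent on squared classification error with
separate learning rates: `eta` for weights/biases and `mu` for the gate
parameters `lambda_i`, back-propagated through the multiplicative gates.
`G_i = 0` makes the output *exactly* invariant to group *i*; `G_i = 1`
passes the group through unaltered; `mu = 0` leaves every `lambda_i`
bit-identical. A group is counted as **selected** when its terminal gate
is at least 0.5 (the threshold is exposed as a parameter).

Design choices that were genuinely open, and what we chose:

* **Gate function** — any monotone map onto [0, 1] with a tunable
  parameter works; we use the logistic sigmoid. "Nearly closed"
  initialisation is `g0 = 0.05` (`lambda = logit(0.05) ≈ -2.94`).
  "Completely open" has two operational readings: a clamp at exactly
  `G = 1` with `lambda` frozen (used wherever gates are not trained), and
  a trainable open start at `lambda = logit(0.95)` (used in the
  pair-cooperation protocol, where the seeded gate must remain free to
  close if its group is useless). `lambda` is clipped to ±30 purely for
  floating-point hygiene; `sigmoid(±30)` is 0/1 to 1e-13.
* **Update mode** — per-pattern (online) descent with a seeded
  Fisher-Yates shuffle each sweep is the default; one "iteration" is a
  full sweep over the data. A full-batch mode is available via
  `TrainingConfig(mode="batch")`.
* **Initialisation** — weights and biases uniform in [-0.3, 0.3] from the
  run's seed; repeated-run experiments give run *r* the *r*-th word of a
  `SeedSequence` stream from the master seed, so an experiment of R runs
  is exactly the union of sub-experiments at offsets (tested).
* **Loss** — mean squared error per sweep is recorded as the loss trace;
  misclassification is evaluated on the final iteration's weights.

The inner training loop is JIT-compiled with numba; semantics are plain
numpy and every run is bit-reproducible from its seed within a process.

## Experiment protocols

* `rank_propensities` — all gates start nearly closed; gates and weights
  train jointly (defaults `eta=0.2, mu=0.1, n=15`); over repeated seeded
  runs the per-group selection counts rank the propensities.
* `evaluate_single_propensity` — one gate clamped at 1, the others at
  exactly 0, `mu` forced to 0: only the weights train, and the reported
  numbers are **training** errors (mean ± sample sd over runs). This
  measures a group's separating power, *not* generalisation: with 15
  hidden units and ~600 peptides the network partially memorises
  arbitrary labels (training error on label-shuffled data falls well
  below the 50% chance level as sweeps accumulate), so training error
  should never be read as a test-error estimate. Permutation nulls
  belong to the cross-validated protocol below, where held-out accuracy
  does sit at chance.
* `pair_cooperation` — one gate starts open (trainable), the rest nearly
  closed; counting which other gates training opens measures how groups
  collaborate rather than discriminate alone.

## Nested cross-validated SVM

Selected propensity subsets are evaluated with an RBF-kernel SVM under
two-level stratified 10-fold cross-validation: the inner level grid
searches `C in 2^-5..2^15` and `gamma in 2^-15..2^3` (steps of 2^2; ties
break toward smaller `C`, then smaller `gamma`) using only the outer
training folds; the winning setting is refit and scored on the held-out
fold. Overall accuracy is pooled over outer folds (per-fold mean is also
reported). Rows are canonicalised (sorted lexicographically by feature
vector, then label) before splitting, so the result is exactly invariant
to input record order; fold bookkeeping maps back to the caller's
indices and records which indices the inner search saw, making the
no-leakage property directly assertable. Permutation nulls are averaged
over several label permutations: one fixed permutation of a few hundred
labels both retains a hypergeometric fluctuation of agreement with the
true labels (sd ≈ 3.5% at n = 200) and offers fixed chance structure the
SVM can partly learn, so single-permutation accuracies scatter by
several points around chance.

## Dataset handling

Benchmark-style inputs are fixed-length 20-mers labelled epitope /
non-epitope, read from two-column TSV or FASTA (class token in the
header). Cleaning follows the conventional protocol: exact-duplicate
removal keeping the first occurrence (label-blind; conflicts are
warned), removal of sequences with non-standard symbols (B/J/O/U/X/Z) or
wrong length, seeded random down-sampling of the majority negative
class to balance, and dataset merging with cross-set deduplication. No
homology reduction is applied — only 100% identity is collapsed.

## Synthetic benchmark generator

Real benchmark collections for this problem are distributed ad hoc and
have no stable public accessions, so the package ships a generator that
plants a group-level signal of known location and strength. Positives
draw residues i.i.d. across positions from a categorical distribution
exponentially tilted toward high values of the informative scale(s),
`p±(r) ∝ exp(± effect * v(r))`, negatives toward low values, with a
`noise` fraction of residues drawn uniformly. The class-conditional
residue mean is then available in closed form (`tilted_mean`), which the
tests use as an analytic oracle. An `xor` mode makes two groups jointly
but not marginally informative (a hidden per-peptide sign couples them).

Defaults — the conditions every acceptance-scale check uses — are 300
peptides per class, signal in group 8 (beta-turn), `effect = 1.5`,
`noise = 0.1`. At these settings the planted group's class-mean gap in
normalised units is ≈ 0.9 and the peptide-level separation is large
(Cohen's d of the group average ≈ 6), i.e. a clean, strongly-informative
benchmark rather than a hard one.

What the generator does *not* emulate: positional structure (residues
are i.i.d. given the class), real epitope sequence statistics, and —
importantly — scale independence. Because a residue's identity fixes its
value under *every* scale simultaneously, tilting toward one real scale
also shifts correlated scales (the bundled turn scales correlate
strongly); only the planted group is guaranteed to carry the *largest*
gap. Tests that need signal confined to a single group use constructed
Walsh-pattern scales that are exactly orthogonal under the uniform
residue distribution. Passing recovery tests therefore show the
machinery recovers a planted compositional signal — not that any
particular real propensity determines real epitopes.

## Problem sizes and tolerances

The repeated-run experiments in the tests and the acceptance script use
50 ranking runs and 20 evaluation runs at 500 training sweeps — the
package's standard benchmark scale, at which the planted group is
recovered in essentially every run (larger run counts reproduce the same
ranking). The nested-CV checks use 100 peptides per class at
`effect = 3.0` with the full default grid. Exact-arithmetic claims
(closed-gate invariance, frozen lambdas, checkpoint round-trips,
correlation symmetry) are asserted bit-exactly; the hand-computed
correlation oracle to 1e-12; Monte-Carlo comparisons against the
analytic tilted mean at ~3 sigma of their sampling error.

## Known limitations

* Training error from the single-propensity protocol conflates
  separating power with memorisation (see above); compare groups with
  it, do not quote it as accuracy.
* The gate functional form from the original grouped-selection
  literature is not uniquely pinned down; any monotone [0, 1] map with
  the stated limits yields the same qualitative behaviour, but exact
  gate trajectories depend on the choice.
* The SVM grid is the conventional log grid; no probability calibration
  or ROC analysis is provided.
* Scales are bundled as literature tables; two of the eight use standard
  alternative tabulations of the named property (see the citation
  comments in `data/propensity_scales.tsv`). All results in this package
  depend only on scale *shape* through the [-1, 1] normalisation.
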