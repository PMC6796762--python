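# Methods

## Problem setting

The classifier decides whether the central adenine of a 41-nt DNA
window carries the N6-methyladenine (6mA) mark. Windows are fixed at
20 nt of context on each side of the adenine; positions are reported
1-based with the adenine at position 21. Only the forward strand is
considered: training data are supplied as strand-resolved windows, and
prediction-time scanning emits one window per eligible adenine on the
given sequence. Windows whose context crosses a contig edge or
contains an ambiguous base are dropped rather than padded.

## Feature encodings

Five encodings are used by the default predictor; a k-mer composition
encoding is included for comparison experiments.

* **NUM (40)** — each flanking base is mapped alphabetically to a
  scalar: A=0.25, C=0.50, G=0.75, T=1.0. The central adenine is
  constant by construction and is omitted.
* **MBE (164)** — per-position one-hot over (A, C, G, T) for all 41
  positions.
* **DBE_LPF (200)** — the 40 overlapping dinucleotides each encoded as
  the 4-bit binary form of an index under letter order A, T, C, G for
  both letters (AA=0000, AT=0001, AC=0010, …, GG=1111), concatenated
  with the local position-specific dinucleotide frequency: for
  j = 2..41, the count of the dinucleotide ending at position j among
  the dinucleotides of the length-j prefix, divided by j. The letter
  order is the unique one consistent with the three anchor codes AA,
  AT, AC; the frequency denominator is the prefix length, mirroring
  the density convention of RFHC, which makes the first value 1/2 and
  every value a positive fraction ≤ 1.
* **RFHC (164)** — per position, three chemical indicator bits — purine
  ring count {A,G}, hydrogen-bond class {A,T}, amino group {A,C},
  giving A=(1,1,1), C=(0,0,1), G=(1,0,0), T=(0,1,0) — plus the
  cumulative density of the position's base within the prefix ending
  there (d₁ is always 1; a homopolymer has all densities 1).
* **KNN (7)** — for n ∈ {2, 4, 8, 16, 32, 64, 128}, the fraction of
  methylated sequences among the n reference windows most similar to
  the query, with similarity +2 per matching position and −1 per
  mismatch (range −41…82 for 41-mers). Ties in similarity are broken
  by reference insertion order, which makes the encoding
  deterministic. The per-n feature is defined as the positive fraction
  of the neighbourhood — the standard convention for this family of
  encodings; a similarity-weighted variant would be a reasonable
  alternative and is the main degree of freedom in this definition.
* **KMER (1364)** — mono- to penta-nucleotide composition; each
  k-block is a frequency vector summing to one.

### KNN leakage control

The KNN encoding is the only one that depends on labels, so it is the
only place training information can leak into evaluation. Two rules
prevent that: (1) inside any cross-validation, the reference snapshot
is rebuilt from the training folds only; (2) a reference entry with
the same record id as the query is removed before ranking
(`exclude_self`), so a training record never counts its own label
among its neighbours — this applies to the final refit as well. The
test suite includes an injected-leak experiment showing that the
self-inclusive protocol inflates accuracy on label-free data from
chance (≈0.49) to ≈0.76, while the guarded protocol stays at chance.
Because the largest neighbourhood is 128, the encoding requires at
least 128 labeled reference records (129 when self-exclusion can
apply).

## Feature optimisation

Features of each encoding are ranked by the univariate F-score
(between-class squared mean deviations over the sum of within-class
sample variances, ddof=1). Columns constant in both classes score 0
with a warning; in the one-hot encodings this is expected (e.g. the
indicator of A at the central position). The score is invariant to
affine transformations of a feature.

A sequential forward search then evaluates prefixes of the ranking —
starting at the top-2 prefix and growing — by stratified k-fold CV
accuracy of the classifier with hyperparameters frozen at their
full-feature-set optimum, and keeps the smallest prefix attaining the
maximum accuracy. The same folds are used for every prefix so the
curve is comparable across sizes, and the full dimension is always
evaluated, so the selected subset can never score below the full set
on those folds. Hyperparameters are tuned once before the search
rather than per prefix; re-tuning at every prefix size could shift the
optimum slightly but multiplies cost by the grid size. The 7-dim KNN
encoding skips the search. A `step` parameter coarsens the prefix
stride for wide encodings; step 1 is the default, and scaled-down runs
(below) use step 16.

## Classifiers and tuning

* **SVM** — RBF kernel, grid C ∈ {2⁻⁵, 2⁻³, …, 2¹⁵} (11 values),
  γ ∈ {2⁻¹⁵, …, 2⁻⁵} (11 values). Inputs are min-max scaled with
  parameters learned on the data the model is fit on (the scaler is
  part of the estimator pipeline). Probabilities come from sigmoid
  (Platt) calibration fitted on cross-validated decision values during
  the final refit.
* **ERT** — extremely randomized trees, grid ntree ∈ {50, 75, …, 2000},
  mtry ∈ {1..15}, nsplit ∈ {1..12}. The tree implementation requires
  nsplit ≥ 2 and mtry ≤ n_features, so infeasible grid points are
  clamped to the nearest feasible value and duplicate effective
  settings are searched once. Tree inputs are unscaled.
* **RF / XGB** — optional plug-ins behind the same interface with small
  library-default grids; flagged experimental and excluded from the
  default architecture.

Grid search maximises mean accuracy over stratified k-fold CV (10
folds by default) and is exhaustive in a deterministic enumeration
order; ties go to the first grid point. The winner is refit on all
training data. All estimators are seeded, so training is reproducible
end to end.

## Two-layer ensemble

Within each classifier family, the five per-encoding probability
streams are combined as a weighted sum. Weights are non-negative
multiples of a grid step (default 0.1; 0.05 available) summing to
exactly one; all 1001 such 5-part simplex points (step 0.1) are
enumerated and the accuracy-maximising point at threshold 0.5 is kept,
ties resolved by lexicographic enumeration order. The search is fed
out-of-fold probabilities from the same stratified folds used for
tuning — resubstitution probabilities would systematically favour
overfit streams. Because the simplex corners are in the grid, the
fused stream is never less accurate than the best single stream on the
search data.

Layer 2 averages the SVM and ERT layer-1 scores with equal weights and
thresholds at 0.5. A score exactly equal to the threshold is called
positive; the boundary convention is documented and tested. Other
classifier-family subsets can be configured; {SVM, ERT} is the
default architecture.

## Evaluation

Stratified k-fold CV keeps per-fold class counts within one of the
per-class quota. `cross_validate` retrains the entire pipeline inside
each fold and pools out-of-fold predictions (micro averaging) for
SN/SP/ACC/MCC/AUC; macro (mean-of-folds) averaging is available behind
a flag. MCC with a zero denominator is defined as 0 with a warning.
AUC uses rank-averaged tie handling and equals the normalised
Mann-Whitney U statistic (verified against a pairwise-count oracle).
McNemar's test uses the discordant-pair chi-square without continuity
correction by default; an exact two-sided binomial variant is
available and is selected by `method="auto"` when b + c < 25. The
ΔACC robustness summary is the absolute difference between CV and
independent-set accuracy in percentage points.

## Synthetic data generator

`sixma.simdata.generate` draws windows i.i.d. from a background base
distribution (uniform by default), forces the central adenine, and
implants the motif (default GAGG) at a uniformly random offset that
never overlaps the centre, with a class-specific rate. Positives may
additionally receive a per-position base-frequency bias.

Default study conditions:

* **Strong-signal condition** (`strong_signal_config`): 400/400
  training and 200/200 independent windows; implant rate 0.9 for
  positives vs 0.1 for negatives; positives biased to
  (A, C, G, T) = (0.42, 0.08, 0.42, 0.08) at the 12 flank positions
  within ±6 of the centre. The bias strength was chosen by a
  likelihood-ratio analysis of the implied Bayes error (≈6–8%
  combining motif and compositional signal) so that a competent
  classifier clearly separates the classes without the task being
  trivial; with motif presence alone the best attainable accuracy is
  only ≈0.85 because GAGG also arises by chance in ≈13% of uniform
  windows.
* **Null condition** (`null_dataset`): both classes drawn from the
  identical process (implant rate 0.1, no bias). Any pipeline should
  sit at chance accuracy here; departures indicate leakage or an
  evaluation bug.

What the generator does *not* emulate: sequence redundancy and its
removal, genome-scale base composition, SMRT kinetic noise or ModQV
score filtering, chromosomal clustering of 6mA, or reverse-strand
context. Passing the synthetic tests therefore demonstrates that the
machinery (encodings, selection, tuning, fusion, evaluation) works and
is leakage-free — not that the predictor attains any particular
accuracy on real plant genomes, which depends on the benchmark data
used for training.

## Problem sizes and numerical choices

The test suite and `scripts/acceptance.py` run the full architecture
at reduced search scale, the package's standard configuration for
desk-scale experiments: a 5×5 SVM sub-grid drawn from the full grid, an
8-combination ERT sub-grid, and forward-search stride 16. At these
sizes the strong-signal pipeline trains in ≈4 minutes on one CPU and
reaches test ACC ≈ 0.90–0.92, MCC ≈ 0.80–0.85, AUC ≈ 0.96–0.98
depending on the seed; the null-condition CV accuracy stays within
0.5 ± 0.03. The full grids (11×11 SVM; 79×15×12 ERT) are the library
defaults and are recommended when reproducing benchmark-scale runs.

Other conventions: probabilities are positive-class probabilities in
[0, 1]; stable sorts fix all tie-breaks (feature ranking by column
index, KNN neighbours by reference order, grid search and weight
search by enumeration order); lowercase FASTA input is uppercased and
`U` is rejected; model archives are joblib files with a schema version
and provenance (class counts, seed, package version, timestamp).

## Known limitations

* Forward-strand windows only; no reverse-complement augmentation.
* The per-n KNN feature definition (positive fraction) and the exact
  probability calibration are conventional choices; alternatives could
  shift single-model probabilities without changing the architecture.
* SFS freezes hyperparameters during the search (see above).
* The weight search optimises accuracy only; optimising MCC or AUC
  would be a one-line change but alters the selected weights.
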