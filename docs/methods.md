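# Methods

## Search model

A putative i-motif needs four equal-length all-C cores of ≥ `min_tract_len`
(default 3) nt separated by three loops of `loop_min`–`loop_max` (default
1–12) nt. The searcher treats **maximal** C-runs as graph nodes rather than
all C-substrings; variation inside long runs is handled afterwards at the
core-placement stage. This two-stage reading reproduces both canonical
worked enumerations (five equal tracts → three full-span conformations;
tracts of lengths 4,3,5,3 → six conformations, i.e. 2×1×3×1 window
placements) without spurious extras.

Choices that the pattern alone does not fix:

- **Core length per path** is the minimum run length among the path's four
  runs; shorter cores are not enumerated. Leftover run cytosines are
  absorbed by the adjacent loops, which are then re-validated against
  `loop_max` (violating placements are dropped).
- **Greedy vs non-greedy** representatives: greedy keeps, per starting run,
  the formation with maximal region end; non-greedy the minimal end. Ties
  break by larger core length, then smaller total loop length, then
  lexicographic region. Non-overlapping mode is a left-to-right scan that
  skips formations intersecting an emitted region, so emitted regions are
  pairwise disjoint.
- **Conformation A** uses the *population* standard deviation of the three
  loop lengths (sample vs population does not change any argmin on ties we
  are aware of; population is fixed here). Conformation ties break by
  lexicographically smallest core starts.
- **Side-loop tie**: when the 5′ and 3′ side loops have equal length, the
  5′ loop is labelled the "longest". Any fixed rule works; this one is
  deterministic and documented.
- **N handling**: any candidate region containing a non-ACGT base is
  dropped (an N could be anything, so neither cores nor loops are
  trustworthy through it).
- Coordinates are 0-based half-open; minus-strand formations (found by
  scanning the reverse complement) report forward-strand coordinates with
  strand "−", and are *featurised* on their C-rich orientation.

## Feature encoding

33 features: C-tract (core) length, iM length, and seven loop-length
aggregates, followed by A/C/G/T densities in six regions (iM span, all
loops, middle loop, longest side loop, shortest side loop, both side
loops). The aggregate "loop length" is the arithmetic mean of the three
loops — the natural scalar once cores are equalised. Densities are counts
over region length, so each region's quadruple sums to 1 exactly; flanking
sequence is not used. The ordering is frozen and versioned
(`imfold-features-1`); model artifacts refuse to score feature matrices
of any other width.

## Datasets

*Classification.* High-confidence peaks are the exact n-way intersection
of replicate peak tracks (n = 3 in practice). A putative iM is **folded**
iff its region is fully contained in a peak and **unfolded** iff it is
fully outside all peaks; straddlers are discarded and counted, since a
half-covered region is evidence for neither class. Peaks are strandless
(tagmentation-based assays do not resolve strand), so minus-strand
formations are labelled against the same intervals. The non-overlapping
search strategy is enforced to avoid counting one locus twice.

*Regression.* Each input sequence is reduced to its putative-iM sequence
(greedy, non-overlapping, conformation A); exact duplicate (sequence,
pH_T) records collapse, and groups where one iM sequence carries several
distinct pH_T are removed entirely — the measurements are irreconcilable
and keeping any one would be arbitrary. Strength = pH_T standardised then
min-max scaled; the composition is numerically identical to plain min-max
(affine invariance), which a property test asserts to 1e−12. A
pre-assigned `high_confidence` flag column is honoured, not recomputed:
the underlying spectroscopic quality criteria are judgment calls that the
package does not model.

## Models

*Balanced random forest* (implemented in-package): each tree is a CART fit
on a bootstrap of the minority class plus an equal-size undersample of the
majority class, so every tree sees a 1:1 problem while the ensemble covers
most majority data. This targets the ~1:83 folded:unfolded imbalance of
genome-wide candidate sets, where an unweighted forest collapses onto the
majority class. `imbalanced-learn` is not a dependency of this package;
the estimator follows the scikit-learn API (`fit`/`predict_proba`/
`feature_importances_`) and a plain `RandomForestClassifier` is kept as
the baseline.

*Gradient-boosted strength regressor*: scikit-learn's
`GradientBoostingRegressor` (least-squares boosting on CARTs). Its
impurity-based `feature_importances_` are the per-feature loss-reduction
(gain) attributions used for the importance report.

Protocol, both tasks: seeded hold-out split (stratified 90/10 for
classification, plain 80/20 for regression — 120 rows leave a 24-row test
set), exhaustive grid search under seeded 5-fold CV on the training part,
selection by mean AUROC (classification) or mean R² (regression), refit on
the full training part. Default grids are deliberately small (trees ∈
{100, 300}, depth ∈ {4, 8, none}; learning rate ∈ {0.05, 0.1, 0.3} for
boosting) and user-replaceable; a single named selection criterion per
task keeps model choice reproducible. Degenerate CV folds with a
single-class training part are skipped with a warning. Seeds are mandatory
inputs, recorded in every artifact and manifest; there is no hidden global
state. AUROC is reported as missing on a single-class test set.

Importance report: features are ranked by gain and split into a
positive-PCC (stabilising) and negative-PCC (destabilising) group by the
sign of their marginal Pearson correlation with the target on the training
set; constant features get sign "positive" by the r := 0 convention and
zero importance.

## Synthetic data

The generators state one fixed world (everything is a function of the
seed):

- **Genome**: 50 kb of i.i.d. background at 40% GC with 20 planted motifs
  (tract lengths 3–6, loop lengths 1–8, random strand). Background C- and
  G-runs of length ≥ 3 are broken by single-base substitution, and guard
  bases flank every insert, so the planted motifs are provably the only
  putative iMs — exact ground truth, at the price of not modelling real
  genomic k-mer statistics or C-rich background competition.
- **Peak tracks**: three replicates covering 40% of planted motifs with
  25 nt margins jittered by up to 20 nt; margin > jitter guarantees the
  3-way intersection still contains every chosen motif.
- **Strength table**: pH_T = 6.0 + 0.15·core_len − 0.05·mean_loop +
  0.8·(C+T loop density) − 0.8·(G+A loop density) + N(0, 0.05), yielding
  values in a realistic ≈5.6–7.1 range. The coefficient signs encode the
  biophysical consensus (long tracts and C/T-rich loops stabilise; long
  loops and G/A-rich loops destabilise), so recovering them from the
  trained regressor is a meaningful end-to-end check. Classification
  fixtures default to heavy imbalance (up to 1:99) with the folded class
  drawn from a long-tract/short-loop regime.
- Planted-motif loops never place a C adjacent to a core and never contain
  three consecutive C, keeping the planted tract structure canonical.

A green test on this world shows the pipeline recovers what it planted; it
does not establish performance on real genomes, where background C-rich
sequence, chromatin context and measurement noise are all harder.

## Limitations

- The searcher is exhaustive, not heuristic: pathological all-C inputs
  have combinatorially many conformations (cost grows with run count and
  placement products), which is acceptable at genome scale only with the
  representative strategies.
- No RNA i-motifs, no G-quadruplex search (the complementary-strand C-rich
  scan covers the minus strand), no thermodynamic folding-energy model.
- Headline real-data accuracies depend on proprietary-scale training data
  and are not reproduced by the synthetic world; the test suite asserts
  the protocol and recovery properties instead.
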