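# imfold

Putative DNA i-motif discovery and folding prediction.

i-Motifs (iMs) are four-stranded secondary structures formed by cytosine-rich
DNA, held together by hemi-protonated C⁺:C base pairs. Their canonical
sequence pattern is (C≥3 N1–12)3 C≥3 — four tracts of at least three
cytosines joined by three loops of 1–12 nt — but regex matching alone cannot
say *which* four tracts pair when five or more are present, nor which of the
many core placements a sequence with unequal tract lengths adopts. `imfold`
is aimed at genomics researchers who want to enumerate those possibilities
exhaustively and score each candidate's probability of folding in vivo and
its structural stability.

## What it computes

**Search.** Maximal C-runs are nodes of a directed acyclic graph; an edge
i→j is added whenever the gap start_j − end_i lies in [1, 12]. Every 4-node
path yields conformations by sliding an equal-length core window (length =
the minimum run length on the path) inside each run, keeping placements
whose three loops stay within bounds. Conformations sharing (first run,
last run) endpoints form one *formation*; representatives are chosen under
greedy/non-greedy × overlapping/non-overlapping strategies, and within a
formation by conformation **A** (minimum standard deviation of the three
loop lengths) or **B** (minimum summed side-loop length). Both strands are
scanned; minus-strand hits are reported in forward BED coordinates.

**Features.** Each conformation is encoded as 33 real features: nine
lengths (C-tract length, iM length, mean/middle/side/extreme loop lengths)
and A/C/G/T densities over six regions (whole iM, all loops, middle loop,
longest and shortest side loop, both side loops).

**Models.** A balanced random forest (per-tree bootstrap that undersamples
the majority class to the minority count) predicts folding status from
peak-labelled genomic candidates; gradient-boosted regression trees predict
folding strength, defined as transitional pH (pH_T, the pH at the folding
midpoint) min-max scaled to [0, 1]. Both follow the same protocol: seeded
hold-out split (90/10 classification, 80/20 regression), exhaustive grid
search under 5-fold cross-validation selecting on mean AUROC / mean R²,
final refit, hold-out evaluation. Gain-based feature importances are
grouped by the sign of each feature's Pearson correlation with the target.

## Worked example

```bash
cat > examples.fa <<'FA'
>ex1
CCCACCCACCCACCCACCC
>ex2
CCCCACCCACCCCCACCC
FA
imfold search --fasta examples.fa --out-bed search.bed --out-tsv search.tsv
```

`search.tsv` (greedy, non-overlapping, conformation A defaults):

```
chrom  formation  start  end  strand  core_starts  core_len  loop_lengths  dash_notation
ex1    iM_0       0      19   +       0,4,8,16     3         1,1,5         CCC-A-CCC-A-CCC-ACCCA-CCC
ex2    iM_1       0      18   +       0,5,10,15    3         2,2,2         CCC-CA-CCC-AC-CCC-CA-CCC
```

`ex1` has five C-tracts; the greedy representative formation spans all of
them ([0,19)), and its conformation-A representative uses tracts 1-2-3-5,
leaving tract 4 inside the 5 nt third loop. `ex2` has four tracts of
lengths 4,3,5,3 admitting six core placements; conformation A is the one
with perfectly even loops (2,2,2). With `--representative all` the TSV
lists all six placements for `ex2`.

Training on synthetic fixtures and annotating the same file:

```bash
imfold predict --fasta examples.fa --classifier clf.joblib \
               --regressor reg.joblib --out-bed pred.bed --out-tsv pred.tsv
```

```
chrom  start  end  strand  folded_probability  predicted_strength
  ex1      0   19      +                0.86            0.564877
  ex2      0   18      +                0.90            0.676760
```

`folded_probability` is the balanced-forest vote fraction (the BED score
column holds `round(1000 × p)`); `predicted_strength` is the regressor's
scaled-pH_T estimate in [0, 1] — here both candidates are confidently
called folded, with `ex2` slightly more stable (shorter, more even loops).
Numbers above come from models trained on the package's synthetic
generators and will differ for models trained on real data.

Other subcommands: `featurize`, `build-datasets`, `train-classifier`,
`train-regressor` — see `imfold --help`.

## Library surface

```python
from imfold import SearchConfig, search_sequence, feature_table
from imfold.models import FoldingClassifier, StrengthRegressor

forms = search_sequence("CCCCACCCACCCCCACCC", SearchConfig())
X = feature_table(forms, "CCCCACCCACCCCCACCC")
res = StrengthRegressor(X_train, y_train, seed=0).fit()   # CV grid + refit
print(res.summary()); print(res.evaluate(X_test, y_test).summary())
```

## Acceptance script

`scripts/acceptance.py` re-runs the graph searcher from scratch on the
canonical five-tract example sequence and writes the recomputed target
quantities (the number of detected C-tracts and the number of
conformations of the full-span formation, with their tract subsets
verified) as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

See `docs/methods.md` for the model assumptions, synthetic-data design and
numerical choices.
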