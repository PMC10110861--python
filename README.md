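# mulcnn

Supervised cell-type annotation for single-cell RNA-seq count matrices,
with open-set rejection of cell types never seen in training.

Single-cell experiments produce a cells x genes matrix of UMI counts. Given
a labeled reference dataset, `mulcnn` trains a classifier that (a) filters
and depth-normalizes the counts (CPM x 10,000, natural log), (b) reshapes
each cell's expression vector into a square "gene image" read by two
parallel convolutional branches at different scales (256 filters of 2x2 and
128 of 5x5, each with ReLU, dropout 0.25, and max pooling), (c) concatenates
those features with a 50-component PCA projection of the same vector, and
(d) classifies through a 128-128-64 ReLU perceptron with a softmax output,
trained with plain SGD on categorical cross-entropy. At prediction time a
cell is only assigned a type if its maximum softmax probability reaches a
rejection threshold (0.97 by default); otherwise it is labeled `unknown`,
which is how cells of types absent from the reference are handled.

The convolution is valid cross-correlation,
`S[i,j] = sum_m sum_n I[i+m, j+n] W[m,n]`, on the gene image `I`; evaluation
uses accuracy, macro precision/recall/F1, one-vs-rest ROC/AUC (trapezoid
rule), precision-recall curves, and the adjusted Rand index computed from
the contingency table between reference and predicted labels.

The package is NumPy/Numba throughout (no deep-learning framework), ships a
negative-binomial + dropout simulator of labeled UMI matrices so everything
is trainable and testable at desk scale, and is deterministic under a fixed
seed down to the bit level.

## Worked example

Simulate a small labeled dataset, train, and annotate it:

```bash
mulcnn simulate --seed 3 --out-prefix sim/
mulcnn train --matrix sim/matrix.tsv --labels sim/labels.tsv \
    --outdir run/ --seed 3 --epochs 70 --learning-rate 3e-4
mulcnn predict --model run/model.mulcnn --query sim/matrix.tsv \
    --threshold 0.97 --out preds.tsv
mulcnn evaluate --truth sim/labels.tsv --pred preds.tsv --out metrics.json
mulcnn sweep --model run/model.mulcnn --matrix sim/matrix.tsv \
    --labels sim/labels.tsv --out sweep.tsv
```

The same pipeline from Python, on the package's default benchmark
(5 cell types x 300 cells, 1,024 genes):

```python
from mulcnn import ModelConfig, SimConfig, SplitSpec, generate_dataset, train_pipeline

counts, labels, markers = generate_dataset(SimConfig(seed=1))
result = train_pipeline(
    counts, labels,
    ModelConfig(seed=1, learning_rate=3e-4),
    SplitSpec(seed=1),
    epochs=70,
)
print({k: round(v, 4) for k, v in result.test_metrics.items()
       if isinstance(v, float)})
```

which prints

```
{'accuracy': 0.9644, 'macro_precision': 0.965, 'macro_recall': 0.9644,
 'macro_f1': 0.9642, 'ari': 0.9132, 'macro_auc': 0.9974}
```

on the 225 held-back test cells: 96.4% of test cells receive their true
type, macro F1 0.964 shows no type is sacrificed, and ARI 0.913 measures
chance-corrected agreement between the predicted and planted partitions.
Training takes about three minutes on one CPU. A model trained with one of
the five types withheld labels 100% of the withheld cells `unknown` at
threshold 0.97.

Input formats: dense TSV/CSV (header = gene ids, first column = cell ids)
or Matrix Market `.mtx` with `genes.tsv`/`barcodes.tsv` sidecars; labels as
two-column TSV; predictions as TSV with per-class probabilities. See
`docs/methods.md` for the model, its assumptions, and the design choices.

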