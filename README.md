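# mlppso

A multilayer perceptron (MLP) classifier whose weights and biases are
trained by **particle swarm optimization (PSO)** instead of
backpropagation, together with the full preprocessing, cross-validation
and metrics pipeline needed to apply it to clinical tabular data in the
UCI Cleveland heart-disease dialect (13 features + binary diagnosis,
comma-separated, `?` for missing values).

## Why train a network with a swarm?

Backpropagation needs a differentiable loss and can stall in poor local
minima; it is also sensitive to the learning rate and initialization. PSO
is a gradient-free population search: each *particle* carries a candidate
solution (here, the complete flat vector of network weights and biases),
a velocity, and a memory of its personal best position; the swarm also
tracks the best position any particle has found. Each iteration applies

```
v(t+1) = w·v(t) + c1·r1·(pbest − x(t)) + c2·r2·(gbest − x(t))
x(t+1) = x(t) + v(t+1)
```

with inertia weight `w = 0.9`, cognitive coefficient `c1 = 0.5`, social
coefficient `c2 = 0.3`, and `r1, r2` drawn uniformly from [0, 1) per
dimension (a fixed-`r` mode with `r1 = 0.4`, `r2 = 0.5` makes runs
bit-reproducible). The fitness minimized is the mean squared error
between the 0/1 labels and the network's output probabilities,

```
MSE = (1/n) Σ (yᵢ − ŷᵢ)²,
```

with the default network of 30 ReLU hidden units and one sigmoid output.
The default swarm has 100 particles and runs 50 iterations or until the
global best MSE drops below an error limit. One-hot encoding the five
multi-level Cleveland categoricals gives a 25-column design matrix and
hence 25·30 + 30 + 30·1 + 1 = **811** trainable parameters — the
dimension of each particle's position.

The package also contains:

* `data_io` — the Cleveland schema, a strict UCI-dialect reader/writer,
  and byte-stable JSON serialization of trained models and metric reports;
* `synthetic` — a class-conditional generator emulating the Cleveland
  schema with a single `effect_size` knob for class separation, so the
  whole pipeline is testable without any download;
* `preprocess` — mean imputation, one-hot/integer encoding,
  standardization and min–max scaling, stratified train/test splits, and
  Pearson correlation analysis, all fitted on training rows only;
* `evaluation` — confusion-matrix metrics (accuracy, precision, recall,
  F1, FPR), ROC/AUC computed from first principles, and a k-fold
  cross-validation harness (default k = 5);
* `cli` — `simulate`, `eda`, `train`, `evaluate`, `cv` and an optional
  `benchmark` command (requires scikit-learn).

## Worked example

Simulate a 303-row Cleveland-like dataset with moderate class separation
and cross-validate the swarm-trained network:

```
$ mlppso simulate -o heart.csv --n 303 --effect-size 1.0 --seed 42
wrote 303 rows to heart.csv

$ mlppso cv heart.csv --seed 42
fold 1  acc 0.8852  prec 0.8148  rec 0.9167  f1 0.8627  auc 0.9583
fold 2  acc 0.8852  prec 1.0000  rec 0.8056  f1 0.8923  auc 0.9667
fold 3  acc 0.9180  prec 0.8621  rec 0.9615  f1 0.9091  auc 0.9725
fold 4  acc 0.9167  prec 0.9000  rec 0.9310  f1 0.9153  auc 0.9533
fold 5  acc 0.8667  prec 0.8621  rec 0.8621  f1 0.8621  auc 0.9488
mean    acc 0.8944  prec 0.8878  rec 0.8954  f1 0.8883  auc 0.9599
```

Each fold row reports the held-out fold's accuracy, precision, recall,
F1 and area under the ROC curve; the final row is their unweighted mean.
At `effect_size 1.0` each continuous feature's class means differ by one
within-class standard deviation and the categorical level probabilities
are tilted by ±0.5 log-odds, which puts the task's difficulty in the same
range as the real Cleveland data. `mlppso train` fits and saves a model,
`mlppso evaluate` scores a saved model on a held-out file, and
`mlppso eda` writes the Pearson correlation matrix and per-feature
summaries. To work with the real data, download the processed Cleveland
file from the UCI Heart Disease repository
(<https://archive.ics.uci.edu/ml/datasets/heart+disease>) and pass it to
`train`/`cv` directly; raw severity grades 1–4 in the target are
collapsed to "disease present".

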