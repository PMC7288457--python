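# m6acnn

Prediction of N6-methyladenosine (m6A) sites in RNA from fixed-length 51-nt
sequence windows with a small 1-D convolutional neural network.

The package provides:

- **`m6acnn.io_encoding`** — FASTA/TSV readers, sequence validation
  (alphabet {A,C,G,U}, T normalized to U, fixed 51-nt length), and one-hot
  encoding of windows into 51×4 binary matrices (channel order A,C,G,U).
- **`m6acnn.architecture`** — a declarative model specification, a pure
  shape-inference calculus (valid convolutions, floor pooling arithmetic),
  exact parameter counting, and model construction. The default
  architecture is two blocks of Conv1D(16,5,1) → ELU → GroupNorm(4) →
  MaxPool1D(4,2), followed by Flatten → Dropout(0.35) → Dense(32, ELU) →
  Dense(1) → Sigmoid, with L2 of 0.001 on conv layers and 0.0001 on dense
  layers.
- **`m6acnn.nn`** — a self-contained NumPy training backend (manual
  backpropagation, SGD with momentum 0.95, learning rate 0.003, binary
  cross-entropy, batch size 32, up to 100 epochs with early stopping at
  patience 30 and best-validation-accuracy checkpointing). No deep-learning
  framework is required.
- **`m6acnn.train_eval`** — the 10-fold 8/1/1 cross-validation rotation
  (8 training folds, 1 validation fold, 1 test fold per repetition), the
  ACC / Sn / Sp / MCC metric suite, and ROC/AUC via threshold sweep +
  trapezoidal integration.
- **`m6acnn.gridsearch`** — enumeration of the 3,920-point hyperparameter
  grid (conv layers × filters × kernel × pool size × pool stride ×
  dropout) with feasibility filtering and minimum-validation-loss
  selection on a fixed split; budgeted random subsampling supported.
- **`m6acnn.fixtures`** — synthetic benchmark generation: balanced 51-nt
  windows with a configurable planted motif (default DRACH-like GGACU at
  offset 24) in positives, plus a permuted-label null control.

## Test

```bash
python -m pytest -q tests/
```

The suite includes `tests/test_acceptance.py`, one test (class) per
acceptance criterion; the learnability criterion runs two full 10-fold
cross-validations on synthetic data and takes a few minutes on one CPU.

## CLI

```bash
# generate a synthetic benchmark (two FASTA files + manifest)
m6acnn simulate --n-pos 1000 --n-neg 1000 --seed 0 --out-dir sim/

# 10-fold cross-validation with the default architecture
m6acnn cv --pos sim/dataset_pos.fasta --neg sim/dataset_neg.fasta \
    --k 10 --seed 0 --out-dir cv_run/

# train one model and score new sequences
m6acnn train --pos sim/dataset_pos.fasta --neg sim/dataset_neg.fasta \
    --out-dir train_run/
m6acnn predict --model train_run/model.npz --fasta sim/dataset_pos.fasta \
    --out predictions.tsv

# hyperparameter search (seeded 20-candidate subsample of the grid)
m6acnn gridsearch --pos sim/dataset_pos.fasta --neg sim/dataset_neg.fasta \
    --budget 20 --seed 0 --out leaderboard.tsv
```

`cv` writes per-fold + mean metrics (`metrics.tsv`), pooled ROC points
(`roc.tsv`), per-fold confusion matrices, and a JSON run record with the
full configuration and seeds. Any option can also come from a YAML config
file (`--config`); explicit flags win.

Non-default behaviors are opt-in flags: `--no-stratify` (plain shuffled
folds), `--permissive-n` (encode ambiguous residues as all-zero rows),
`--require-central-a`, `--monitor val_loss`, `--threshold`.

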