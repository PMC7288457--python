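"""Hyperparameter grid enumeration and validation-loss selection.

The default search space is the published grid: number of convolution
blocks {1,2,3,4}, filters {6,8,16,24,32,44,64}, kernel size
{2,4,5,7,8,10,13}, pool size {2,4}, pool stride {2,4}, dropout
{0.3,0.35,0.4,0.45,0.5} — 3,920 candidates before feasibility filtering.
One value per axis is shared across all convolution blocks of a candidate.
Candidates whose shape calculus fails (kernel or pool exceeding the
remaining length, or the fixed 4-way channel grouping not dividing the
filter count) are flagged infeasible and never trained.

Selection trains each candidate on one fixed stratified train/validation
split (not nested cross-validation) and ranks by ascending validation
loss, breaking ties by higher validation accuracy, then fewer parameters.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .architecture import (
    ConvLayerSpec,
    DenseSpec,
    DropoutSpec,
    EluSpec,
    FlattenSpec,
    GroupNormSpec,
    InfeasibleArchitectureError,
    MaxPoolSpec,
    ModelSpec,
    SigmoidSpec,
    TrainingConfig,
    count_parameters,
    infer_shapes,
)
from .io_encoding import LabeledDataset
from .train_eval import make_folds, train_fold

GROUPS = 4
CONV_L2 = 0.001
DENSE_L2 = 0.0001
DENSE_UNITS = 32


@dataclass(frozen=True)
class SearchSpace:
    conv_layers: tuple[int, ...] = (1, 2, 3, 4)
    filters: tuple[int, ...] = (6, 8, 16, 24, 32, 44, 64)
    kernel_sizes: tuple[int, ...] = (2, 4, 5, 7, 8, 10, 13)
    pool_sizes: tuple[int, ...] = (2, 4)
    pool_strides: tuple[int, ...] = (2, 4)
    dropouts: tuple[float, ...] = (0.3, 0.35, 0.4, 0.45, 0.5)

    def __post_init__(self) -> None:
        for name in ("conv_layers", "filters", "kernel_sizes", "pool_sizes", "pool_strides", "dropouts"):
            if not getattr(self, name):
                raise ValueError(f"search-space axis {name!r} is empty")

    @property
    def size(self) -> int:
        return (
            len(self.conv_layers)
            * len(self.filters)
            * len(self.kernel_sizes)
            * len(self.pool_sizes)
            * len(self.pool_strides)
            * len(self.dropouts)
        )


@dataclass
class Candidate:
    conv_layers: int
    filters: int
    kernel_size: int
    pool_size: int
    pool_stride: int
    dropout: float
    feasible: bool = True
    spec: ModelSpec | None = None
    n_params: int | None = None
    val_loss: float | None = None
    val_accuracy: float | None = None
    extra: dict = field(default_factory=dict)


def candidate_spec(
    cand: Candidate, input_shape: tuple[int, int] = (51, 4)
) -> ModelSpec:
    """Model spec for a candidate: ``conv_layers`` identical conv blocks
    followed by the fixed flatten/dropout/dense head.

    Raises :class:`InfeasibleArchitectureError` if shape inference fails.
    """
    block = (
        ConvLayerSpec(cand.filters, cand.kernel_size, 1, weight_l2=CONV_L2, bias_l2=CONV_L2),
        EluSpec(),
        GroupNormSpec(GROUPS),
        MaxPoolSpec(cand.pool_size, cand.pool_stride),
    )
    layers = block * cand.conv_layers + (
        FlattenSpec(),
        DropoutSpec(cand.dropout),
        DenseSpec(DENSE_UNITS, activation="elu", weight_l2=DENSE_L2, bias_l2=DENSE_L2),
        DenseSpec(1, activation=None, weight_l2=DENSE_L2, bias_l2=DENSE_L2),
        SigmoidSpec(),
    )
    spec = ModelSpec(layers=layers, input_shape=input_shape)
    infer_shapes(spec)  # raises if infeasible
    return spec


def enumerate_grid(
    space: SearchSpace | None = None,
    input_shape: tuple[int, int] = (51, 4),
) -> list[Candidate]:
    """Cartesian product of the axes in documented order
    (conv_layers, filters, kernel_size, pool_size, pool_stride, dropout);
    deterministic ordering, infeasible candidates flagged."""
    space = space or SearchSpace()
    candidates = []
    for layers, f, k, l, r, d in itertools.product(
        space.conv_layers,
        space.filters,
        space.kernel_sizes,
        space.pool_sizes,
        space.pool_strides,
        space.dropouts,
    ):
        cand = Candidate(
            conv_layers=layers, filters=f, kernel_size=k, pool_size=l, pool_stride=r, dropout=d
        )
        try:
            cand.spec = candidate_spec(cand, input_shape)
            cand.n_params = count_parameters(cand.spec)
        except InfeasibleArchitectureError:
            cand.feasible = False
        candidates.append(cand)
    return candidates


def run_search(
    space: SearchSpace | None,
    dataset: LabeledDataset,
    config: TrainingConfig,
    budget: int | None = None,
    seed: int = 0,
    val_folds: int = 10,
) -> tuple[list[Candidate], ModelSpec]:
    """Evaluate (a budgeted subsample of) the grid; return candidates
    ranked by ascending validation loss, plus the best candidate's spec.

    Every evaluated candidate is trained on the same stratified split
    (one fold of ``val_folds`` held out for validation, the rest training).
    """
    space = space or SearchSpace()
    candidates = enumerate_grid(space, input_shape=(dataset.sequence_length, 4))
    feasible = [c for c in candidates if c.feasible]
    if not feasible:
        raise InfeasibleArchitectureError("no feasible candidate in the search space")
    rng = np.random.default_rng(seed)
    if budget is not None:
        if budget > len(feasible):
            import warnings

            warnings.warn(
                f"budget {budget} exceeds the {len(feasible)} feasible candidates; clamping"
            )
            budget = len(feasible)
        chosen = rng.choice(len(feasible), size=budget, replace=False)
        evaluated = [feasible[i] for i in sorted(chosen)]
    else:
        evaluated = feasible

    X, y = dataset.encode()
    folds = make_folds(y, k=val_folds, seed=seed, stratified=True)
    val_idx = folds.fold_indices(0)
    train_idx = np.flatnonzero(folds.fold_of != 0)

    for cand in evaluated:
        cand_config = replace(config, seed=seed)
        model, history = train_fold(
            cand.spec, cand_config, X[train_idx], y[train_idx], X[val_idx], y[val_idx]
        )
        best = int(history["best_epoch"]) - 1
        cand.val_loss = history["val_loss"][best]
        cand.val_accuracy = history["val_accuracy"][best]
        cand.extra["stopped_epoch"] = history["stopped_epoch"]

    ranked = sorted(
        evaluated,
        key=lambda c: (c.val_loss, -c.val_accuracy, c.n_params),
    )
    return ranked, ranked[0].spec
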