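"""Model evaluation: leakage-safe jackknife, independent tests, grid search.

The jackknife (leave-one-out) here has one non-obvious requirement: PSNP and
PSDP encodings are *trained* features — their propensity matrices summarize
class-conditional frequencies — so inside every fold the matrices must be
refit from the n−1 training samples only, and both the training samples and
the single held-out sample are encoded with those fold-local matrices.
Fitting the matrices once on all n samples would leak the held-out sample's
own nucleotides (and label) into its encoding and inflate every metric.

Per-fold refitting is implemented by count decrement: the class-conditional
occurrence counts are accumulated once over the full dataset, and each fold
subtracts the held-out sample's contribution, which is numerically identical
to recounting the n−1 training samples.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.svm import SVC

from pseui.errors import ValidationError
from pseui.encoders import (
    FeatureRecipe,
    PhysicochemicalTable,
    PropensityMatrix,
    _dinucleotide_codes,
    encode_dataset,
    encode_nc,
    encode_dc,
    encode_psednc,
    fit_recipe_matrices,
)
from pseui.metrics import ConfusionCounts, MetricSet, chou_metrics, roc_auc
from pseui.segments_io import LabeledDataset


@dataclass(frozen=True)
class SVMConfig:
    """RBF-SVM hyperparameters in box-constraint / kernel-scale form.

    The kernel is K(x,y) = exp(−‖x−y‖² / s²) with kernel scale ``s`` and
    box constraint (regularization) ``c``. Libraries parameterized by γ use
    γ = 1/s²; the conversion is applied internally.
    """

    c: float = 1.0
    s: float = 1.0

    def __post_init__(self) -> None:
        if self.c <= 0 or self.s <= 0:
            raise ValidationError(
                f"box constraint and kernel scale must be positive (c={self.c}, s={self.s})"
            )

    @property
    def gamma(self) -> float:
        return 1.0 / self.s**2

    def make_svc(self) -> SVC:
        return SVC(kernel="rbf", C=self.c, gamma=self.gamma, tol=1e-3,
                   cache_size=256, max_iter=-1)


@dataclass(frozen=True)
class GridSpec:
    """Candidate (c, s) values for grid search.

    Defaults are powers of two: s ∈ {2⁻³..2¹⁰}, c ∈ {2⁻⁵..2¹⁰}, wide enough
    to contain every optimum the benchmark models use (0.03125 up to 1024).
    """

    c_values: tuple[float, ...] = tuple(2.0**k for k in range(-5, 11))
    s_values: tuple[float, ...] = tuple(2.0**k for k in range(-3, 11))

    def __post_init__(self) -> None:
        if not self.c_values or not self.s_values:
            raise ValidationError("grid must be nonempty")
        if any(v <= 0 for v in self.c_values) or any(v <= 0 for v in self.s_values):
            raise ValidationError("grid values must be positive")

    def cells(self) -> list["SVMConfig"]:
        return [SVMConfig(c=c, s=s) for c in self.c_values for s in self.s_values]


@dataclass
class EvaluationResult:
    """Aggregated evaluation: confusion counts, metrics, per-sample scores."""

    counts: ConfusionCounts
    metrics: MetricSet
    scores: np.ndarray
    predictions: np.ndarray
    labels: np.ndarray
    roc: np.ndarray | None = None


class _JackknifeEncoder:
    """Precomputed state for fast leave-one-out encoding.

    Static feature blocks (NC/DC/pseDNC) are segment-only and computed once;
    propensity blocks are recomputed per fold from decremented counts.
    """

    def __init__(
        self,
        dataset: LabeledDataset,
        recipe: FeatureRecipe,
        table: PhysicochemicalTable | None,
    ):
        self.recipe = recipe
        self.labels = dataset.labels
        self.codes = dataset.code_matrix()
        self.di_codes = _dinucleotide_codes(self.codes)
        self.n = len(dataset)
        self.xi = dataset.xi
        L = self.codes.shape[1]

        self.static_blocks: dict[str, np.ndarray] = {}
        for name in recipe.names:
            if name == "NC":
                self.static_blocks[name] = np.stack(
                    [encode_nc(s) for s in dataset.segments]
                )
            elif name == "DC":
                self.static_blocks[name] = np.stack(
                    [encode_dc(s) for s in dataset.segments]
                )
            elif name == "pseDNC":
                self.static_blocks[name] = np.stack(
                    [encode_psednc(s, recipe.psednc, table) for s in dataset.segments]
                )

        # class-conditional occurrence counts over the FULL dataset;
        # per-fold matrices subtract the held-out sample's contribution
        self.counts: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for kind in recipe.required_matrices():
            sym_codes = self.codes if kind == "PSNP" else self.di_codes
            n_sym = 4 if kind == "PSNP" else 16
            width = sym_codes.shape[1]
            pos = np.zeros((n_sym, width))
            neg = np.zeros((n_sym, width))
            for s in range(n_sym):
                pos[s] = (sym_codes[self.labels] == s).sum(axis=0)
                neg[s] = (sym_codes[~self.labels] == s).sum(axis=0)
            self.counts[kind] = (pos, neg)

        self.n_pos = int(self.labels.sum())
        self.n_neg = self.n - self.n_pos

    def fold_matrices(self, k: int) -> dict[str, PropensityMatrix]:
        """Propensity matrices refit on the dataset minus sample k."""
        out = {}
        held_pos = bool(self.labels[k])
        for kind, (pos, neg) in self.counts.items():
            sym_codes = self.codes if kind == "PSNP" else self.di_codes
            width = sym_codes.shape[1]
            pos = pos.copy()
            neg = neg.copy()
            target = pos if held_pos else neg
            target[sym_codes[k], np.arange(width)] -= 1
            n_pos = self.n_pos - (1 if held_pos else 0)
            n_neg = self.n_neg - (0 if held_pos else 1)
            if n_pos < 1 or n_neg < 1:
                raise ValidationError(
                    f"fold {k}: training part lost class "
                    f"{'positive' if held_pos else 'negative'} entirely"
                )
            out[kind] = PropensityMatrix(
                kind=kind, Z_plus=pos / n_pos, Z_minus=neg / n_neg, xi=self.xi
            )
        return out

    def encode_all(self, matrices: Mapping[str, PropensityMatrix]) -> np.ndarray:
        """Feature matrix for all n samples under the given matrices."""
        blocks = []
        for name in self.recipe.names:
            if name in self.static_blocks:
                blocks.append(self.static_blocks[name])
            else:
                Z = matrices[name].Z
                sym_codes = self.codes if name == "PSNP" else self.di_codes
                blocks.append(Z[sym_codes, np.arange(sym_codes.shape[1])])
        return np.hstack(blocks)


def jackknife(
    dataset: LabeledDataset,
    recipe: FeatureRecipe,
    svm: SVMConfig,
    table: PhysicochemicalTable | None = None,
) -> EvaluationResult:
    """Leave-one-out evaluation with per-fold propensity-matrix refitting.

    For each of the n folds, the propensity matrices (when the recipe uses
    PSNP/PSDP) are refit on the n−1 training samples, every segment is
    encoded under those matrices, an RBF-SVM is trained on the n−1 samples
    and the held-out sample is scored. Confusion counts aggregate the n
    verdicts; AUC is computed from the n held-out decision scores.
    Deterministic for fixed inputs and independent of sample order.
    """
    dataset.require_both_classes()
    n = len(dataset)
    if n < 4:
        raise ValidationError(f"jackknife needs at least 4 samples, got {n}")
    enc = _JackknifeEncoder(dataset, recipe, table)
    y = dataset.labels
    scores = np.empty(n)

    needs_fit = recipe.needs_fitting
    if not needs_fit:
        X_all = enc.encode_all({})

    for k in range(n):
        train_mask = np.ones(n, dtype=bool)
        train_mask[k] = False
        if needs_fit:
            matrices = enc.fold_matrices(k)
            X = enc.encode_all(matrices)
        else:
            if y[train_mask].all() or not y[train_mask].any():
                raise ValidationError(
                    f"fold {k}: training part contains a single class"
                )
            X = X_all
        clf = svm.make_svc().fit(X[train_mask], y[train_mask])
        scores[k] = clf.decision_function(X[k : k + 1])[0]

    predictions = scores > 0.0
    counts = ConfusionCounts.from_predictions(y, predictions)
    auc, curve = roc_auc(y, scores)
    return EvaluationResult(
        counts=counts,
        metrics=chou_metrics(counts, auc=auc),
        scores=scores,
        predictions=predictions,
        labels=y.copy(),
        roc=curve,
    )


def evaluate_independent(
    train: LabeledDataset,
    test: LabeledDataset,
    recipe: FeatureRecipe,
    svm: SVMConfig,
    table: PhysicochemicalTable | None = None,
) -> EvaluationResult:
    """Fit matrices and SVM on the full training set once; score the test set.

    Training and test sets must share the half-window size. Overlap between
    them is not rejected (resubstitution is a legitimate diagnostic) but a
    warning is printed when segments coincide.
    """
    if train.xi != test.xi:
        raise ValidationError(
            f"train xi={train.xi} != test xi={test.xi}"
        )
    if len(test) == 0:
        raise ValidationError("test set is empty")
    train.require_both_classes()
    test.require_both_classes()
    overlap = {s.sequence for s in train.segments} & {
        s.sequence for s in test.segments
    }
    if overlap:
        print(
            f"warning: {len(overlap)} segment sequence(s) shared between "
            f"train and test sets",
            file=sys.stderr,
        )
    matrices = fit_recipe_matrices(train, recipe)
    X_train = encode_dataset(train.segments, recipe, matrices, table)
    X_test = encode_dataset(test.segments, recipe, matrices, table)
    clf = svm.make_svc().fit(X_train, train.labels)
    scores = clf.decision_function(X_test)
    predictions = scores > 0.0
    counts = ConfusionCounts.from_predictions(test.labels, predictions)
    auc, curve = roc_auc(test.labels, scores)
    return EvaluationResult(
        counts=counts,
        metrics=chou_metrics(counts, auc=auc),
        scores=scores,
        predictions=predictions,
        labels=test.labels.copy(),
        roc=curve,
    )


def grid_search(
    dataset: LabeledDataset,
    recipe: FeatureRecipe,
    grid: GridSpec,
    criterion: str = "MCC",
    table: PhysicochemicalTable | None = None,
) -> tuple[SVMConfig, list[dict]]:
    """Jackknife every (c, s) cell; return the best config and the full table.

    ``criterion`` is ``"MCC"`` or ``"Acc"``. Ties are broken by higher Acc,
    then smaller box constraint c, then larger kernel scale s (preferring
    the smoother, more regularized model).
    """
    if criterion not in ("MCC", "Acc"):
        raise ValidationError(f"criterion must be MCC or Acc, got {criterion!r}")
    rows = []
    for cfg in grid.cells():
        result = jackknife(dataset, recipe, cfg, table)
        row = {"c": cfg.c, "s": cfg.s, **result.metrics.as_dict()}
        rows.append(row)

    def sort_key(row: dict):
        return (-row[criterion], -row["Acc"], row["c"], -row["s"])

    best = min(rows, key=sort_key)
    return SVMConfig(c=best["c"], s=best["s"]), rows
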