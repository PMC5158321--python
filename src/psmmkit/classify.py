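"""Repeated random-split classification of two promoter sets.

The evaluation harness mirrors the study design the feature matrix was
built for: a stratified random train/test split at one of five learn:test
ratios (50:50 ... 90:10), repeated 25 times, with the mean test accuracy
reported.  Feature reduction (selection or transform) is, by default,
fitted on the training split only and applied to the test split, so no
test information leaks into the selected features; fitting the reduction
on the full matrix before splitting is available behind a flag.

KNN is implemented natively (Euclidean distance, majority vote, ties broken
by the nearest neighbour's class then by training order); SVM kernels and
decision trees are standard learners behind the same contract — the
historical kernel menu maps "quadratic" and "polynomial" to polynomial
kernels of degree 2 and 3 and "mlp" to the sigmoid kernel.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .psmm import FeatureMatrix
from . import selection as sel

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "GridSpec",
    "split_samples",
    "knn_classify",
    "fit_eval_classifier",
    "enumerate_grid",
    "RATIOS",
    "SVM_KERNELS",
    "REDUCTION_METHODS",
    "DEFAULT_LEVELS",
]

RATIOS: tuple[tuple[int, int], ...] = ((50, 50), (60, 40), (70, 30), (80, 20), (90, 10))
SVM_KERNELS = ("linear", "quadratic", "polynomial", "rbf", "mlp")
REDUCTION_METHODS = ("variance", "pvalue", "mrmr", "pca", "svd")
DEFAULT_LEVELS: tuple[float, ...] = (50, 40, 30, 20, 10)

_SVC_KERNELS = {
    "linear": dict(kernel="linear"),
    "quadratic": dict(kernel="poly", degree=2),
    "polynomial": dict(kernel="poly", degree=3),
    "rbf": dict(kernel="rbf"),
    "mlp": dict(kernel="sigmoid"),
}


@dataclass(frozen=True)
class ExperimentConfig:
    """One cell of the experiment grid.

    ``reduction`` is None for the complete feature set, otherwise a
    (method, level) pair where level is a percent for variance/pvalue and a
    component/feature count for mrmr/pca/svd.
    """

    classifier: Literal["knn", "svm", "decision_tree"]
    knn_k: int | None = None
    svm_kernel: str | None = None
    learn_test_ratio: tuple[int, int] = (50, 50)
    reduction: tuple[str, float] | None = None
    repetitions: int = 25
    seed: int = 0
    presplit_reduction: bool = False
    pair: int | None = None

    def __post_init__(self) -> None:
        if sum(self.learn_test_ratio) != 100:
            raise ValueError("learn:test ratio parts must sum to 100")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.classifier == "knn" and not 1 <= (self.knn_k or 0):
            raise ValueError("knn requires knn_k >= 1")
        if self.classifier == "svm" and self.svm_kernel not in _SVC_KERNELS:
            raise ValueError(f"svm_kernel must be one of {SVM_KERNELS}")
        if self.reduction is not None:
            method, level = self.reduction
            if method not in REDUCTION_METHODS:
                raise ValueError(f"unknown reduction method {method!r}")
            if level <= 0:
                raise ValueError("reduction level must be positive")


@dataclass(frozen=True)
class ExperimentResult:
    """Per-repetition and mean test accuracies for one grid cell."""

    per_rep_accuracy: tuple[float, ...]
    mean_accuracy: float
    per_class_recall: tuple[dict[str, float], ...] = ()

    def __post_init__(self) -> None:
        accs = np.asarray(self.per_rep_accuracy)
        if ((accs < 0) | (accs > 1)).any():
            raise ValueError("accuracies must lie in [0, 1]")
        if abs(self.mean_accuracy - accs.mean()) > 1e-12:
            raise ValueError("mean_accuracy must equal the mean of per-rep values")


def split_samples(
    labels: Sequence[str], ratio: tuple[int, int], seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified random split: floor(train% x class size) per class to train.

    Same seed gives the same split; train and test partition the samples.
    """
    if sum(ratio) != 100:
        raise ValueError("ratio parts must sum to 100")
    rng = np.random.default_rng(seed)
    labels = list(labels)
    train_idx: list[int] = []
    test_idx: list[int] = []
    seen: list[str] = []
    for lab in labels:
        if lab not in seen:
            seen.append(lab)
    for lab in seen:
        members = np.array([i for i, l in enumerate(labels) if l == lab])
        if members.size < 2:
            raise ValueError(f"class {lab!r} needs >= 2 samples to split")
        n_train = math.floor(ratio[0] / 100.0 * members.size)
        if n_train == 0 or n_train == members.size:
            raise ValueError(
                f"ratio {ratio} leaves class {lab!r} with an empty split side"
            )
        shuffled = rng.permutation(members)
        train_idx.extend(shuffled[:n_train].tolist())
        test_idx.extend(shuffled[n_train:].tolist())
    return np.array(sorted(train_idx)), np.array(sorted(test_idx))


def knn_classify(
    train_x: np.ndarray,
    train_y: Sequence[str],
    test_x: np.ndarray,
    k: int,
) -> list[str]:
    """k-nearest-neighbour vote under Euclidean distance.

    Vote ties are broken by the class of the single nearest neighbour;
    equal distances rank by ascending training index (stable sort).
    """
    train_x = np.asarray(train_x, dtype=float)
    test_x = np.asarray(test_x, dtype=float)
    n_train = train_x.shape[0]
    if not 1 <= k <= n_train:
        raise ValueError(f"k must be in 1..{n_train}, got {k}")
    train_y = list(train_y)
    diffs = test_x[:, None, :] - train_x[None, :, :]
    dists = np.sqrt((diffs**2).sum(axis=2))
    predictions: list[str] = []
    for row in dists:
        order = np.argsort(row, kind="stable")[:k]
        votes = Counter(train_y[i] for i in order)
        top = max(votes.values())
        winners = {lab for lab, c in votes.items() if c == top}
        if len(winners) == 1:
            predictions.append(next(iter(winners)))
        else:
            # tie: first neighbour in distance-then-index order whose class ties
            for i in order:
                if train_y[i] in winners:
                    predictions.append(train_y[i])
                    break
    return predictions


def _fit_reduction(
    train_values: np.ndarray,
    train_labels: list[str],
    space,
    method: str,
    level: float,
):
    """Fit a reduction on training rows; return a transform for any rows."""
    train_fm = FeatureMatrix(
        sample_ids=[f"s{i}" for i in range(train_values.shape[0])],
        labels=train_labels,
        space=space,
        values=train_values,
    )
    if method == "variance":
        result = sel.variance_select(sel.compute_variances(train_fm), level)
        idx = np.array(result.selected)
        return lambda x: x[:, idx]
    if method == "pvalue":
        result = sel.pvalue_select(sel.ttest_pvalues(train_fm), level)
        idx = np.array(result.selected)
        return lambda x: x[:, idx]
    if method == "mrmr":
        result = sel.mrmr_miq_select(train_fm, int(level))
        idx = np.array(result.selected)
        return lambda x: x[:, idx]
    if method == "pca":
        from sklearn.decomposition import PCA

        pca = PCA(n_components=int(level), svd_solver="full").fit(
            train_values.astype(float)
        )
        return lambda x: pca.transform(x.astype(float))
    if method == "svd":
        _, s, vt = np.linalg.svd(train_values.astype(float), full_matrices=False)
        v_k = vt[: int(level)].T
        return lambda x: x.astype(float) @ v_k
    raise ValueError(f"unknown reduction method {method!r}")


def _train_predict(config: ExperimentConfig, train_x, train_y, test_x, rep_seed):
    if config.classifier == "knn":
        k = min(config.knn_k, train_x.shape[0])
        return knn_classify(train_x, train_y, test_x, k)
    if config.classifier == "svm":
        model = SVC(**_SVC_KERNELS[config.svm_kernel], gamma="scale")
    else:
        model = DecisionTreeClassifier(random_state=rep_seed)
    model.fit(np.asarray(train_x, dtype=float), train_y)
    return list(model.predict(np.asarray(test_x, dtype=float)))


def fit_eval_classifier(
    config: ExperimentConfig, matrix: FeatureMatrix
) -> ExperimentResult:
    """Run the repeated random-split evaluation for one grid cell.

    Per repetition: split, fit any reduction on the training rows, train,
    and score accuracy = correct / test size on the held-out rows.
    """
    if len(matrix.classes) != 2:
        raise ValueError("two classes required")
    rng = np.random.default_rng(config.seed)
    values = matrix.values
    labels = list(matrix.labels)

    presplit_transform = None
    if config.reduction is not None and config.presplit_reduction:
        method, level = config.reduction
        presplit_transform = _fit_reduction(
            values, labels, matrix.space, method, level
        )

    accuracies: list[float] = []
    recalls: list[dict[str, float]] = []
    for _ in range(config.repetitions):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        train_idx, test_idx = split_samples(labels, config.learn_test_ratio, rep_seed)
        train_x, test_x = values[train_idx], values[test_idx]
        train_y = [labels[i] for i in train_idx]
        test_y = [labels[i] for i in test_idx]
        if presplit_transform is not None:
            transform = presplit_transform
        elif config.reduction is not None:
            method, level = config.reduction
            transform = _fit_reduction(train_x, train_y, matrix.space, method, level)
        else:
            transform = lambda x: x
        train_r, test_r = transform(train_x), transform(test_x)
        if train_r.shape[1] == 0:
            raise ValueError("reduction emptied the feature set")
        predicted = _train_predict(config, train_r, train_y, test_r, rep_seed)
        correct = sum(p == t for p, t in zip(predicted, test_y))
        accuracies.append(correct / len(test_y))
        recalls.append(
            {
                lab: sum(
                    p == t for p, t in zip(predicted, test_y) if t == lab
                )
                / max(1, sum(t == lab for t in test_y))
                for lab in matrix.classes
            }
        )
    return ExperimentResult(
        per_rep_accuracy=tuple(accuracies),
        mean_accuracy=float(np.mean(accuracies)),
        per_class_recall=tuple(recalls),
    )


@dataclass(frozen=True)
class GridSpec:
    """The experiment-grid layout: per promoter-set pair, every classifier
    setting x ratio cell is run once with the complete feature set and once
    per (reduction method, level)."""

    classifier: Literal["knn", "svm", "decision_tree"]
    pairs: int = 8
    knn_ks: tuple[int, ...] = (1, 2, 3, 4, 5)
    svm_kernels: tuple[str, ...] = SVM_KERNELS
    ratios: tuple[tuple[int, int], ...] = RATIOS
    methods: tuple[str, ...] = REDUCTION_METHODS
    levels: tuple[float, ...] = DEFAULT_LEVELS


def enumerate_grid(grid: GridSpec) -> list[ExperimentConfig]:
    """Enumerate every experiment configuration of the grid."""
    if grid.classifier == "knn":
        settings: list[dict] = [{"knn_k": k} for k in grid.knn_ks]
    elif grid.classifier == "svm":
        settings = [{"svm_kernel": kern} for kern in grid.svm_kernels]
    else:
        settings = [{}]
    configs: list[ExperimentConfig] = []
    for pair in range(grid.pairs):
        for setting in settings:
            for ratio in grid.ratios:
                configs.append(
                    ExperimentConfig(
                        classifier=grid.classifier,
                        learn_test_ratio=ratio,
                        reduction=None,
                        pair=pair,
                        **setting,
                    )
                )
                for method in grid.methods:
                    for level in grid.levels:
                        configs.append(
                            ExperimentConfig(
                                classifier=grid.classifier,
                                learn_test_ratio=ratio,
                                reduction=(method, level),
                                pair=pair,
                                **setting,
                            )
                        )
    return configs
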