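"""Filter feature selection for motif-band feature matrices.

Two selectors rank the original (motif, band) count features without
transforming them, so the retained features remain directly interpretable
as "this motif in this promoter region":

* cumulative-variance selection — rank features by decreasing variance and
  keep the shortest prefix whose summed variance reaches P% of the total
  variance T_V; the realized cutoff is (P * T_V) / 100;
* t-test P-value selection — rank features by increasing two-sample t-test
  P value between the two promoter classes and keep k = floor(n * T / 100)
  features (at least one).

Three conventional reducers are provided for comparison: greedy mRMR-MIQ
(mutual-information quotient), PCA on the column-centered matrix, and SVD
on the raw matrix.  All tie-breaks are by ascending feature index so
selections are deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA

from .psmm import FeatureMatrix

__all__ = [
    "VarianceProfile",
    "PValueProfile",
    "SelectionResult",
    "compute_variances",
    "variance_select",
    "ttest_pvalues",
    "pvalue_select",
    "mrmr_miq_select",
    "pca_reduce",
    "svd_reduce",
]

Method = Literal["variance", "pvalue", "mrmr", "pca", "svd"]


@dataclass(frozen=True)
class VarianceProfile:
    """Per-feature variances and their total T_V."""

    variances: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.variances, dtype=float)
        if (v < 0).any():
            raise ValueError("variances must be non-negative")
        object.__setattr__(self, "variances", v)

    @property
    def total(self) -> float:
        return float(self.variances.sum())


@dataclass(frozen=True)
class PValueProfile:
    """Per-feature two-sample t-test P values."""

    pvalues: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.pvalues, dtype=float)
        if ((p < 0) | (p > 1)).any():
            raise ValueError("P values must lie in [0, 1]")
        object.__setattr__(self, "pvalues", p)


@dataclass(frozen=True)
class SelectionResult:
    """Ordered retained feature indices with their criterion values."""

    method: Method
    selected: tuple[int, ...]
    criterion: tuple[float, ...]
    threshold_parameter: float
    realized_cutoff: float

    def __post_init__(self) -> None:
        if len(self.selected) != len(set(self.selected)):
            raise ValueError("selected indices must be distinct")
        crit = np.asarray(self.criterion)
        if self.method == "variance" and (np.diff(crit) > 1e-12).any():
            raise ValueError("variance criterion must be non-increasing")
        if self.method == "pvalue" and (np.diff(crit) < -1e-12).any():
            raise ValueError("P-value criterion must be non-decreasing")

    def __len__(self) -> int:
        return len(self.selected)


def compute_variances(matrix: FeatureMatrix, ddof: int = 1) -> VarianceProfile:
    """Per-column variance over all samples, regardless of class.

    Uses the sample variance (denominator n-1) by default.
    """
    if matrix.n_samples < 2:
        raise ValueError("at least 2 samples required to compute variances")
    return VarianceProfile(np.var(matrix.values.astype(float), axis=0, ddof=ddof))


def variance_select(profile: VarianceProfile, P: float) -> SelectionResult:
    """Keep the top-variance prefix covering P% of the total variance.

    Features are ranked by decreasing variance (ties by ascending index);
    the selected set is the shortest rank-prefix whose cumulative variance
    is at least (P * T_V) / 100, so the prefix without its last feature
    falls strictly below the cutoff.
    """
    if not 0 < P <= 100:
        raise ValueError(f"P must be in (0, 100], got {P}")
    total = profile.total
    if total <= 0:
        raise ValueError("no variation; nothing selectable")
    cutoff = (P * total) / 100.0
    v = profile.variances
    # stable sort on negated values: decreasing variance, ascending index ties
    order = np.argsort(-v, kind="stable")
    cumulative = np.cumsum(v[order])
    k = int(np.searchsorted(cumulative, cutoff * (1 - 1e-12)) + 1)
    k = min(k, len(order))
    selected = tuple(int(i) for i in order[:k])
    return SelectionResult(
        method="variance",
        selected=selected,
        criterion=tuple(float(v[i]) for i in selected),
        threshold_parameter=float(P),
        realized_cutoff=cutoff,
    )


def ttest_pvalues(
    matrix: FeatureMatrix, equal_var: bool = False
) -> PValueProfile:
    """Two-sided two-sample t-test P value per feature between the classes.

    Welch's unequal-variance test by default; ``equal_var=True`` pools.
    Features degenerate for the t statistic (both class variances zero) get
    P = 1 when the class means agree and P = 0 when they differ, the limits
    of the statistic.
    """
    classes = matrix.classes
    if len(classes) != 2:
        raise ValueError("exactly two classes required")
    a = matrix.values[matrix.class_rows(classes[0])].astype(float)
    b = matrix.values[matrix.class_rows(classes[1])].astype(float)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each class needs >= 2 samples for a t-test")
    with np.errstate(divide="ignore", invalid="ignore"):
        result = stats.ttest_ind(a, b, axis=0, equal_var=equal_var)
        p = np.asarray(result.pvalue, dtype=float)
    degenerate = (a.var(axis=0) == 0) & (b.var(axis=0) == 0)
    means_equal = a.mean(axis=0) == b.mean(axis=0)
    p = np.where(degenerate & means_equal, 1.0, p)
    p = np.where(degenerate & ~means_equal, 0.0, p)
    p = np.nan_to_num(p, nan=1.0)
    return PValueProfile(p)


def pvalue_select(profile: PValueProfile, T: float) -> SelectionResult:
    """Keep the k = floor(n*T/100) features of smallest P value (min 1).

    Selected features are ordered by increasing P value, ties by ascending
    feature index.
    """
    if not 0 < T <= 100:
        raise ValueError(f"T must be in (0, 100], got {T}")
    p = profile.pvalues
    n = p.size
    if n < 1:
        raise ValueError("empty P-value profile")
    k = max(1, math.floor(n * T / 100.0))
    order = np.argsort(p, kind="stable")
    selected = tuple(int(i) for i in order[:k])
    return SelectionResult(
        method="pvalue",
        selected=selected,
        criterion=tuple(float(p[i]) for i in selected),
        threshold_parameter=float(T),
        realized_cutoff=float(k),
    )


def _discretize(values: np.ndarray) -> np.ndarray:
    """Z-score each feature and cut at +/-0.5 into 3 states (0, 1, 2)."""
    x = values.astype(float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    z = (x - mu) / sd
    return (np.digitize(z, [-0.5, 0.5])).astype(np.int64)


def _mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information of two discrete vectors, in nats."""
    n = x.size
    joint: dict[tuple[int, int], int] = {}
    for xi, yi in zip(x.tolist(), y.tolist()):
        joint[(xi, yi)] = joint.get((xi, yi), 0) + 1
    px: dict[int, int] = {}
    py: dict[int, int] = {}
    for (xi, yi), c in joint.items():
        px[xi] = px.get(xi, 0) + c
        py[yi] = py.get(yi, 0) + c
    mi = 0.0
    for (xi, yi), c in joint.items():
        pxy = c / n
        mi += pxy * math.log(pxy * n * n / (px[xi] * py[yi]))
    return max(mi, 0.0)


def mrmr_miq_select(matrix: FeatureMatrix, k: int) -> SelectionResult:
    """Greedy mRMR feature selection with the MIQ (quotient) criterion.

    Features are discretized to 3 states (z-score cut at +/-0.5); the first
    pick maximizes mutual information with the class label and each later
    pick maximizes MI(f; class) / mean MI(f; already-selected).  Ties break
    by ascending feature index.
    """
    n = matrix.n_features
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}, got {k}")
    disc = _discretize(matrix.values)
    label_codes = np.array(
        [matrix.classes.index(lab) for lab in matrix.labels], dtype=np.int64
    )
    relevance = np.array(
        [_mutual_information(disc[:, j], label_codes) for j in range(n)]
    )
    selected: list[int] = [int(np.argmax(relevance))]
    scores: list[float] = [float(relevance[selected[0]])]
    pair_mi: dict[tuple[int, int], float] = {}

    def mi_between(i: int, j: int) -> float:
        key = (min(i, j), max(i, j))
        if key not in pair_mi:
            pair_mi[key] = _mutual_information(disc[:, key[0]], disc[:, key[1]])
        return pair_mi[key]

    while len(selected) < k:
        best_j, best_q = -1, -math.inf
        for j in range(n):
            if j in selected:
                continue
            redundancy = sum(mi_between(j, s) for s in selected) / len(selected)
            q = relevance[j] / redundancy if redundancy > 0 else math.inf
            if q > best_q:
                best_j, best_q = j, q
        selected.append(best_j)
        scores.append(float(best_q) if math.isfinite(best_q) else float("inf"))
    return SelectionResult(
        method="mrmr",
        selected=tuple(selected),
        criterion=tuple(scores),
        threshold_parameter=float(k),
        realized_cutoff=float(k),
    )


def pca_reduce(matrix: FeatureMatrix, k: int) -> np.ndarray:
    """Top-k principal-component scores of the column-centered matrix."""
    max_k = min(matrix.n_samples - 1, matrix.n_features)
    if not 1 <= k <= max_k:
        raise ValueError(f"k must be in 1..{max_k}, got {k}")
    return PCA(n_components=k, svd_solver="full").fit_transform(
        matrix.values.astype(float)
    )


def svd_reduce(matrix: FeatureMatrix, k: int) -> np.ndarray:
    """U_k * S_k of the uncentered matrix, in decreasing singular-value order."""
    max_k = min(matrix.n_samples, matrix.n_features)
    if not 1 <= k <= max_k:
        raise ValueError(f"k must be in 1..{max_k}, got {k}")
    u, s, _ = np.linalg.svd(matrix.values.astype(float), full_matrices=False)
    return u[:, :k] * s[:k]
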