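"""Group classification from NII features with CART under LOOCV.

A Gini-impurity decision tree (axis-aligned binary splits with
cost-complexity pruning) is evaluated with leave-one-out cross-validation
on the two-column (nii_mean, nii_sd) feature table, and its accuracy is
tested against the no-information rate with a one-sided exact binomial
test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.tree import DecisionTreeClassifier

FEATURE_COLUMNS = ("nii_mean", "nii_sd")


@dataclass(frozen=True)
class CartParams:
    """CART complexity controls; ``None`` fields resolve per sample size.

    Defaults mirror common recursive-partitioning practice: minimum split
    size min(20, n // 3), minimum leaf size min(7, max(1, n // 10)),
    cost-complexity pruning at alpha = 0.01.
    """

    min_samples_split: int | None = None
    min_samples_leaf: int | None = None
    ccp_alpha: float = 0.01

    def resolve(self, n: int) -> tuple[int, int]:
        split = self.min_samples_split or max(2, min(20, n // 3))
        leaf = self.min_samples_leaf or max(1, min(7, n // 10))
        return split, leaf


@dataclass
class ClassificationResult:
    name: str
    accuracy: float
    nir: float
    p_vs_nir: float
    n: int
    predictions: np.ndarray  # per-fold held-out predictions
    truth: np.ndarray


def _build_tree(
    features: np.ndarray, labels: np.ndarray, params: CartParams
) -> DecisionTreeClassifier:
    n = features.shape[0]
    split, leaf = params.resolve(n)
    tree = DecisionTreeClassifier(
        criterion="gini",
        min_samples_split=split,
        min_samples_leaf=leaf,
        ccp_alpha=params.ccp_alpha,
        random_state=0,
    )
    tree.fit(features, labels)
    return tree


def cart_fit(
    features: np.ndarray, labels: np.ndarray, params: CartParams | None = None
) -> DecisionTreeClassifier:
    """Fit a CART tree; deterministic given the data.

    Class ties at a leaf resolve toward the alphabetically first label
    (sklearn predicts the first class in sorted order on count ties).
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if features.ndim != 2:
        raise ValueError("features must be a 2-D array")
    n = features.shape[0]
    if n < 6:
        raise ValueError(f"need at least 6 samples, got {n}")
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two classes")
    return _build_tree(features, labels, params or CartParams())


def nir_test(accuracy: float, n: int, nir: float) -> float:
    """One-sided exact binomial test of accuracy against the NIR.

    P(X >= round(accuracy * n)) with X ~ Binomial(n, nir).
    """
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError("accuracy must be in [0, 1]")
    if not 0.0 < nir < 1.0:
        raise ValueError("nir must be in (0, 1)")
    k = int(round(accuracy * n))
    return float(stats.binom.sf(k - 1, n, nir))


def loocv_accuracy(
    features: np.ndarray,
    labels: np.ndarray,
    params: CartParams | None = None,
    name: str = "",
) -> ClassificationResult:
    """Leave-one-out CART accuracy with the no-information-rate test.

    Each of the n folds trains on n-1 rows and predicts the held-out row;
    row order does not affect the predictions.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    n = features.shape[0]
    if labels.shape[0] != n:
        raise ValueError("features and labels must align")
    if n < 6:
        raise ValueError(f"need at least 6 samples, got {n}")
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two classes")
    params = params or CartParams()
    preds = np.empty(n, dtype=labels.dtype)
    idx = np.arange(n)
    for i in range(n):
        mask = idx != i
        # training folds have n-1 rows; bypass the full-set size check
        tree = _build_tree(features[mask], labels[mask], params)
        preds[i] = tree.predict(features[i : i + 1])[0]
    accuracy = float(np.mean(preds == labels))
    _, counts = np.unique(labels, return_counts=True)
    nir = float(counts.max() / n)
    return ClassificationResult(
        name=name,
        accuracy=accuracy,
        nir=nir,
        p_vs_nir=nir_test(accuracy, n, nir),
        n=n,
        predictions=preds,
        truth=labels.copy(),
    )
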