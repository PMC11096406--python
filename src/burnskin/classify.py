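"""LOOCV multiclass logistic-regression classification of loading rate.

A multinomial (softmax) logistic model is asked to predict, from the five
material parameters alone, which loading rate a specimen was tested at.
Leave-one-out cross-validation gives an unbiased confusion matrix; four
chance-aware agreement metrics summarize it.  Near-chance accuracy and
near-zero MCC/ARI constitute multivariate evidence that the feature
distributions do not separate the rates.

The model carries a small L2 ridge (strength 1e-6 on per-fold standardized
features): it guarantees a unique optimum under separation or collinearity
without materially changing dense-data fits.  Features are standardized
inside each training fold, so the held-out sample never leaks into the
scaling.

"Feature contribution" is operationalized as the normalized mean absolute
standardized coefficient per feature (a permutation-importance alternative
is available behind a flag); it is a coefficient-magnitude summary, not a
classical latent-factor model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .univariate import FEATURES

__all__ = [
    "ConfusionMatrix",
    "ClassificationReport",
    "loocv_classify",
    "metrics",
    "feature_contributions",
    "classify_cohort",
]

# ridge strength 1e-6 on standardized features; sklearn's objective scales
# the penalty as 1/C
_RIDGE_C = 1e6
_MAX_ITER = 2000


@dataclass(frozen=True)
class ConfusionMatrix:
    """3x3 counts, rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_labels: tuple[float, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", c)
        if c.ndim != 2 or c.shape[0] != c.shape[1] or (c < 0).any():
            raise ValueError("counts must be a square nonnegative matrix")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class ClassificationReport:
    confusion: ConfusionMatrix
    accuracy: float
    mcc: float
    fmi: float
    ari: float
    contributions: pd.Series  # per-feature nonnegative fractions summing to 1


def _standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    return (train - mean) / sd, (test - mean) / sd


def _model() -> LogisticRegression:
    return LogisticRegression(C=_RIDGE_C, max_iter=_MAX_ITER, solver="lbfgs")


def loocv_classify(X, y, class_labels: Sequence[float] | None = None) -> ConfusionMatrix:
    """Leave-one-out confusion matrix of the multinomial logistic model.

    For every sample, the model is refit on all other samples (features
    standardized with that training fold's mean/SD) and predicts the
    held-out one.  Deterministic given the data.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    labels = tuple(class_labels) if class_labels is not None else tuple(np.unique(y))
    index = {lab: i for i, lab in enumerate(labels)}
    # integer class codes: rate labels are floats, which classifiers reject
    codes = np.array([index[lab] for lab in y])
    for lab in labels:
        if (codes == index[lab]).sum() < 2:
            raise ValueError(f"class {lab} needs at least 2 samples for LOOCV")

    counts = np.zeros((len(labels), len(labels)), dtype=int)
    n = len(y)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if len(np.unique(codes[mask])) < len(labels):
            raise ValueError("degenerate LOOCV fold: a class vanished from the training set")
        Xtr, Xte = _standardize(X[mask], X[i : i + 1])
        clf = _model().fit(Xtr, codes[mask])
        pred = int(clf.predict(Xte)[0])
        counts[codes[i], pred] += 1
    return ConfusionMatrix(counts=counts, class_labels=labels)


def _pair_counts(counts: np.ndarray) -> tuple[float, float, float, float]:
    """Pair-counting sums over the true/predicted contingency table.

    Returns (sum_ij C(n_ij,2), sum_i C(row_i,2), sum_j C(col_j,2), C(n,2)).
    """
    def comb2(a):
        return (a * (a - 1) / 2.0)

    n = counts.sum()
    return (
        float(comb2(counts).sum()),
        float(comb2(counts.sum(axis=1)).sum()),
        float(comb2(counts.sum(axis=0)).sum()),
        float(comb2(n)),
    )


def metrics(confusion: ConfusionMatrix) -> dict[str, float]:
    """Accuracy, multiclass MCC (R_k), Fowlkes-Mallows and Adjusted Rand.

    MCC uses the R_k generalization computed directly from the matrix; a
    zero factor in its denominator yields MCC = 0 by convention.  FMI and
    ARI use pair counting over the true-label partition vs. the predicted
    partition (FMI's zero denominator also yields 0; a degenerate ARI
    denominator yields 1 when the partitions agree exactly, else 0).
    """
    c = confusion.counts.astype(float)
    n = c.sum()
    if n < 2:
        raise ValueError("confusion matrix must contain at least 2 samples")
    accuracy = float(np.trace(c) / n)

    t = c.sum(axis=1)  # true-class sizes
    p = c.sum(axis=0)  # predicted-class sizes
    cov = np.trace(c) * n - float(t @ p)
    denom = (n**2 - float(p @ p)) * (n**2 - float(t @ t))
    mcc = float(cov / np.sqrt(denom)) if denom > 0 else 0.0

    same_same, same_true, same_pred, all_pairs = _pair_counts(c)
    fmi = float(same_same / np.sqrt(same_true * same_pred)) if same_true * same_pred > 0 else 0.0

    expected = same_true * same_pred / all_pairs
    max_index = 0.5 * (same_true + same_pred)
    if max_index == expected:
        ari = 1.0 if same_same == expected else 0.0
    else:
        ari = float((same_same - expected) / (max_index - expected))
    return {"accuracy": accuracy, "mcc": mcc, "fmi": fmi, "ari": ari}


def feature_contributions(
    X,
    y,
    feature_names: Sequence[str] = FEATURES,
    method: str = "coefficients",
    n_permutations: int = 20,
    seed: int = 0,
) -> pd.Series:
    """Per-feature contribution fractions of the full-data classifier.

    ``coefficients`` (default): fit the multinomial model on the fully
    standardized data and report mean |coefficient| over classes per
    feature, normalized to sum to 1.  ``permutation``: mean accuracy drop
    when each feature column is shuffled, clipped at 0 and normalized.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    labels = list(np.unique(y))
    codes = np.array([labels.index(lab) for lab in y])
    Xs, _ = _standardize(X, X[:1])
    clf = _model().fit(Xs, codes)
    if method == "coefficients":
        raw = np.abs(clf.coef_).mean(axis=0)
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        base = clf.score(Xs, codes)
        raw = np.zeros(X.shape[1])
        for j in range(X.shape[1]):
            drops = []
            for _ in range(n_permutations):
                Xp = Xs.copy()
                Xp[:, j] = rng.permutation(Xp[:, j])
                drops.append(base - clf.score(Xp, codes))
            raw[j] = max(float(np.mean(drops)), 0.0)
    else:
        raise ValueError("method must be 'coefficients' or 'permutation'")
    total = raw.sum()
    frac = raw / total if total > 0 else np.full_like(raw, 1.0 / len(raw))
    return pd.Series(frac, index=list(feature_names), name="contribution")


def classify_cohort(
    cohort: pd.DataFrame,
    features: Sequence[str] = FEATURES,
    label_col: str = "rate_mm_per_s",
) -> ClassificationReport:
    """End-to-end multivariate stage on a screened feature table."""
    X = cohort[list(features)].to_numpy(dtype=float)
    y = cohort[label_col].to_numpy()
    labels = tuple(sorted(np.unique(y)))
    confusion = loocv_classify(X, y, class_labels=labels)
    m = metrics(confusion)
    contrib = feature_contributions(X, y, feature_names=features)
    return ClassificationReport(confusion=confusion, contributions=contrib, **m)
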