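"""Group statistics and the liver-vs-tumor decision rules.

Differences between liver and tumor feature distributions are assessed with
the Mann-Whitney U test (exact by enumeration for small samples, normal
approximation with tie correction otherwise; significance read at p < 0.01
for the small cohorts this targets).  Classification uses a soft-margin
linear SVM on z-scored features, evaluated by leave-one-out
cross-validation with the tumor class positive; the four classifier
variants pair the three diagnostic features (λ365, λ450, StO₂) as the full
3-D rule plus the three 2-D rules.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, erf, sqrt

import numpy as np
from sklearn.svm import SVC

__all__ = [
    "FEATURE_NAMES",
    "CLASSIFIER_SUBSETS",
    "ClassifierModel",
    "DiagnosticMetrics",
    "mann_whitney",
    "fit_linear_svm",
    "loocv_metrics",
    "classifier_suite",
]

FEATURE_NAMES = ("lambda365", "lambda450", "sto2")
# Table-2 order: 3-D rule, then the three 2-D pairings
CLASSIFIER_SUBSETS = (
    ("lambda365", "lambda450", "sto2"),
    ("lambda365", "lambda450"),
    ("lambda365", "sto2"),
    ("lambda450", "sto2"),
)
EXACT_LIMIT = 12


@dataclass
class DiagnosticMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    skipped_folds: int = 0

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")


@dataclass
class ClassifierModel:
    subset: tuple
    means: np.ndarray
    scales: np.ndarray
    weights: np.ndarray
    bias: float
    C: float

    def decision(self, X) -> np.ndarray:
        Xs = (np.asarray(X, float) - self.means) / self.scales
        return Xs @ self.weights + self.bias

    def predict(self, X) -> np.ndarray:
        """1 = tumor, 0 = liver."""
        return (self.decision(X) > 0).astype(int)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U of sample x: pairs with x > y, ties counted half."""
    xx = x[:, None]
    return float(np.sum(xx > y[None, :]) + 0.5 * np.sum(xx == y[None, :]))


def mann_whitney(x, y):
    """Mann-Whitney U (of the first sample) and two-sided p value.

    Exact null distribution by enumeration of all C(n, nx) rank
    assignments when nx + ny <= 12; otherwise the normal approximation
    with tie correction and 0.5 continuity correction.  The two-sided p is
    P(|U - n1 n2 / 2| >= |U_obs - n1 n2 / 2|) under the null.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = x.size, y.size
    u_obs = _u_statistic(x, y)
    mu = n1 * n2 / 2.0
    if n1 + n2 <= EXACT_LIMIT:
        pooled = np.concatenate([x, y])
        dev = abs(u_obs - mu)
        hits = 0
        total = comb(n1 + n2, n1)
        for idx in combinations(range(n1 + n2), n1):
            mask = np.zeros(n1 + n2, bool)
            mask[list(idx)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            if abs(u - mu) >= dev - 1e-12:
                hits += 1
        p = hits / total
    else:
        pooled = np.concatenate([x, y])
        n = n1 + n2
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(counts ** 3 - counts) / (n * (n - 1))
        var = n1 * n2 / 12.0 * (n + 1 - tie_term)
        if var <= 0:
            return u_obs, 1.0
        z = (abs(u_obs - mu) - 0.5) / sqrt(var)
        z = max(z, 0.0)
        p = 2.0 * (1.0 - 0.5 * (1.0 + erf(z / sqrt(2.0))))
    return u_obs, min(1.0, float(p))


def _feature_matrix(features, subset):
    X = np.array([[getattr(f, name) for name in subset] for f in features],
                 float)
    y = np.array([1 if f.label == "tumor" else 0 for f in features], int)
    return X, y


def fit_linear_svm(features, subset=FEATURE_NAMES,
                   C: float = 1.0) -> ClassifierModel:
    """Soft-margin linear SVM on z-scored features (tumor = positive)."""
    subset = tuple(subset)
    unknown = set(subset) - set(FEATURE_NAMES)
    if unknown:
        raise ValueError(f"unknown features: {sorted(unknown)}")
    X, y = _feature_matrix(features, subset)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    means = X.mean(axis=0)
    scales = X.std(axis=0)
    scales = np.where(scales > 0, scales, 1.0)
    svc = SVC(kernel="linear", C=C)
    svc.fit((X - means) / scales, y)
    return ClassifierModel(subset=subset, means=means, scales=scales,
                           weights=svc.coef_.ravel().copy(),
                           bias=float(svc.intercept_[0]), C=C)


def loocv_metrics(features, subset=FEATURE_NAMES,
                  C: float = 1.0) -> DiagnosticMetrics:
    """Leave-one-site-out confusion counts (tumor = positive class)."""
    features = list(features)
    labels = [f.label for f in features]
    if min(labels.count("tumor"), labels.count("liver")) < 2:
        raise ValueError("need at least two samples per class")
    tp = fp = tn = fn = skipped = 0
    for i, held in enumerate(features):
        rest = features[:i] + features[i + 1:]
        rest_labels = {f.label for f in rest}
        if len(rest_labels) < 2:
            skipped += 1
            continue
        model = fit_linear_svm(rest, subset=subset, C=C)
        x = [[getattr(held, name) for name in subset]]
        pred = int(model.predict(x)[0])
        truth = 1 if held.label == "tumor" else 0
        if truth == 1:
            tp += pred
            fn += 1 - pred
        else:
            fp += pred
            tn += 1 - pred
    return DiagnosticMetrics(tp=tp, fp=fp, tn=tn, fn=fn,
                             skipped_folds=skipped)


def classifier_suite(features, C: float = 1.0):
    """LOOCV metrics for the four feature subsets, in the fixed
    (3-D; λ365+λ450; λ365+StO₂; λ450+StO₂) order."""
    return {subset: loocv_metrics(features, subset=subset, C=C)
            for subset in CLASSIFIER_SUBSETS}


def suite_report(metrics_by_subset) -> dict:
    """JSON-ready report mirroring the four-classifier summary table."""
    out = {}
    for i, subset in enumerate(CLASSIFIER_SUBSETS, start=1):
        m = metrics_by_subset[subset]
        out[f"classifier_{i}"] = {
            "features": list(subset),
            "sensitivity": round(m.sensitivity, 4),
            "specificity": round(m.specificity, 4),
            "tp": m.tp, "fp": m.fp, "tn": m.tn, "fn": m.fn,
        }
    return out
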