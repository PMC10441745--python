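"""Empirical ROC/AUC diagnostics for single markers and combined axes.

AUC is the Mann-Whitney pair-winning probability with ties credited 1/2,
oriented so that higher scores indicate the case class; values below 0.5
are reported as-is.  A lncRNA-miRNA-mRNA axis is combined into one score
by an in-sample logistic model on standardized log2 expression, its linear
predictor serving as the composite marker (the protocol a multi-marker
ROC web tool applies); leave-one-out scoring is available as the
out-of-sample alternative.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .synthetic_data import CASE, ExpressionBundle

logger = logging.getLogger(__name__)


@dataclass
class ROCResult:
    markers: tuple[str, ...]
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_case: int
    n_control: int


def _as_binary(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "USO":
        y = (labels == CASE).astype(int)
    else:
        y = labels.astype(int)
    if y.min() == y.max():
        raise ValueError("labels must contain both case and control samples")
    return y


def auc_score(scores, labels) -> float:
    """Mann-Whitney AUC: P[case > control] + P[tie]/2 over all pairs."""
    y = _as_binary(labels)
    scores = np.asarray(scores, dtype=float)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    ranks = stats.rankdata(scores)  # midranks credit ties 1/2
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_points(scores, labels) -> ROCResult:
    """Empirical ROC curve swept over the unique score values.

    Points run from (0, 0) to (1, 1) with both coordinates non-decreasing;
    their trapezoidal area equals the Mann-Whitney AUC.
    """
    y = _as_binary(labels)
    scores = np.asarray(scores, dtype=float)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    order = np.argsort(-scores, kind="stable")
    y_sorted = y[order]
    s_sorted = scores[order]
    # cut after each distinct score value
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], len(s_sorted) - 1]
    tp = np.cumsum(y_sorted)[distinct]
    fp = np.cumsum(1 - y_sorted)[distinct]
    fpr = np.r_[0.0, fp / n0]
    tpr = np.r_[0.0, tp / n1]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(markers=(), fpr=fpr, tpr=tpr, auc=auc,
                     n_case=n1, n_control=n0)


def combine_triplet(features: np.ndarray, labels, loo: bool = False) -> np.ndarray:
    """Composite score for a marker axis via logistic regression.

    ``features`` is (n_samples, n_features); features are standardized and
    the fitted linear predictor is returned.  Perfect separation falls back
    to a ridge-stabilized fit with a logged notice.  ``loo=True`` scores
    each sample from a model fitted without it.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = _as_binary(labels)
    if X.shape[0] != y.size:
        raise ValueError("features and labels disagree on sample count")
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = (X - X.mean(axis=0)) / sd
    if not loo:
        return _linear_predictor(X, y)
    out = np.empty(y.size)
    for i in range(y.size):
        mask = np.ones(y.size, bool)
        mask[i] = False
        coef, intercept = _fit(X[mask], y[mask])
        out[i] = X[i] @ coef + intercept
    return out


def _fit(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            model = LogisticRegression(C=np.inf, max_iter=1000, tol=1e-8)
            model.fit(X, y)
        except ConvergenceWarning:
            logger.info("separable data: ridge-stabilized logistic fit used")
            model = LogisticRegression(C=1.0, max_iter=1000)
            model.fit(X, y)
    return model.coef_.ravel(), float(model.intercept_[0])


def _linear_predictor(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    coef, intercept = _fit(X, y)
    return X @ coef + intercept


def compare_markers(
    bundle: ExpressionBundle,
    triplets: list[tuple[str, str, str]],
    loo: bool = False,
) -> tuple[pd.DataFrame, dict[str, ROCResult]]:
    """AUC report for every single marker and every combined axis.

    Single markers are the union of features over the given axes, scored
    on log2(value + 1) directly; each axis additionally gets a combined
    logistic score.  Returns the report table and the ROC curves keyed by
    marker name.
    """
    labels = bundle.groups.values
    expr = pd.concat([bundle.lncrna, bundle.mirna, bundle.mrna])
    singles: list[str] = []
    for trip in triplets:
        for f in trip:
            if f not in expr.index:
                raise KeyError(f"marker {f!r} missing from expression tables")
            if f not in singles:
                singles.append(f)
    rows, curves = [], {}
    for f in singles:
        s = np.log2(expr.loc[f].to_numpy(dtype=float) + 1.0)
        res = roc_points(s, labels)
        res.markers = (f,)
        rows.append((f, "single", res.auc, res.n_case, res.n_control))
        curves[f] = res
    for trip in triplets:
        X = np.log2(expr.loc[list(trip)].to_numpy(dtype=float).T + 1.0)
        s = combine_triplet(X, labels, loo=loo)
        name = "—".join(trip)
        res = roc_points(s, labels)
        res.markers = tuple(trip)
        rows.append((name, "combined", res.auc, res.n_case, res.n_control))
        curves[name] = res
    report = pd.DataFrame(
        rows, columns=["marker", "kind", "auc", "n_case", "n_control"]
    )
    return report, curves
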