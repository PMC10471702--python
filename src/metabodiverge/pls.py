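"""Partial least squares regression and discriminant analysis, from scratch.

Implements single-response (PLS1) NIPALS with X-deflation, variable
importance in projection (VIP) scores, Martens-jackknife confidence
intervals for the regression coefficients, and the cross-validated Q^2
statistic. PLS-DA is PLS1 on a 0/1 class coding with a 0.5 decision
threshold. This module is the model core driven by the cross-model
validation layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

_EPS = 1e-12


@dataclass
class PlsModel:
    """A fitted NIPALS PLS1 (or PLS-DA) model.

    ``coef_path[:, a-1]`` holds the collapsed coefficient vector of the
    model truncated to its first ``a`` components, so predictions at any
    smaller component count come free from a single fit. ``classes`` is
    set only for discriminant fits and maps code 0/1 to labels.
    """

    n_components: int
    x_weights: np.ndarray  # (p, A), unit-norm columns
    x_loadings: np.ndarray  # (p, A)
    y_loadings: np.ndarray  # (A,)
    scores: np.ndarray  # (n, A), mutually orthogonal
    coef_path: np.ndarray  # (p, A)
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    ssy_per_component: np.ndarray  # (A,) y-variance captured by each component
    classes: tuple | None = None  # (label coded 0, label coded 1) for PLS-DA
    vip: np.ndarray | None = None
    coef_ci: np.ndarray | None = None  # (p, 2) low/high

    @property
    def coefficients(self) -> np.ndarray:
        return self.coef_path[:, self.n_components - 1]

    def predict(self, X, n_components: int | None = None) -> np.ndarray:
        a = self.n_components if n_components is None else n_components
        X0 = (np.asarray(X, dtype=float) - self.x_mean) / self.x_scale
        return self.y_mean + X0 @ self.coef_path[:, a - 1]

    def predict_class(self, X, n_components: int | None = None) -> np.ndarray:
        """Decision rule: predicted score >= 0.5 maps to the class coded 1."""
        if self.classes is None:
            raise ValueError("not a discriminant model")
        yhat = self.predict(X, n_components)
        codes = (yhat >= 0.5).astype(int)
        return np.asarray(self.classes)[codes]


def fit_pls(
    X,
    y,
    n_components: int,
    center: bool = True,
    scale: bool = False,
) -> PlsModel:
    """Fit PLS1 by NIPALS with X-deflation per component.

    ``X`` is expected column-standardized by the caller (the pipeline
    standardizes the joined dataset once); centering is still applied
    internally so the fit is well-defined on raw inputs too.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("X and y disagree on sample count")
    if np.var(y) < _EPS:
        raise ValueError("response has zero variance")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    max_rank = min(n - (1 if center else 0), p)
    if n_components > max_rank:
        raise ValueError(f"n_components={n_components} exceeds rank bound {max_rank}")

    x_mean = X.mean(axis=0) if center else np.zeros(p)
    x_scale = X.std(axis=0, ddof=1) if scale else np.ones(p)
    x_scale = np.where(x_scale < _EPS, 1.0, x_scale)
    y_mean = float(y.mean()) if center else 0.0

    Xd = (X - x_mean) / x_scale
    yd = y - y_mean

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    T = np.zeros((n, n_components))
    ssy = np.zeros(n_components)

    a_used = n_components
    for a in range(n_components):
        w = Xd.T @ yd
        norm_w = np.linalg.norm(w)
        if norm_w < _EPS:
            a_used = a  # X residual orthogonal to y: no further components
            break
        w /= norm_w
        t = Xd @ w
        tt = t @ t
        if tt < _EPS:
            a_used = a
            break
        pvec = Xd.T @ t / tt
        qa = yd @ t / tt
        Xd = Xd - np.outer(t, pvec)
        yd = yd - qa * t
        W[:, a], P[:, a], q[a], T[:, a] = w, pvec, qa, t
        ssy[a] = qa**2 * tt

    if a_used == 0:
        raise ValueError("no predictive component could be extracted")
    W, P, q, T, ssy = W[:, :a_used], P[:, :a_used], q[:a_used], T[:, :a_used], ssy[:a_used]

    # collapsed coefficients for every truncation of the component sequence
    R = W @ np.linalg.inv(P.T @ W)  # p x A; columns map X to scores directly
    coef_path = np.cumsum(R * q[None, :], axis=1)

    model = PlsModel(
        n_components=a_used,
        x_weights=W,
        x_loadings=P,
        y_loadings=q,
        scores=T,
        coef_path=coef_path,
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        ssy_per_component=ssy,
    )
    model.vip = vip_scores(model)
    return model


def fit_plsda(X, class_labels, n_components: int, **kwargs) -> PlsModel:
    """PLS-DA: PLS1 on a 0/1 coding of a two-class label vector.

    Classes are coded in sorted label order (first label -> 0, second -> 1).
    The decision rule and all selection statistics are invariant to which
    class carries code 1.
    """
    labels = np.asarray(class_labels)
    uniq = sorted(pd.unique(labels))
    if len(uniq) != 2:
        raise ValueError(f"need exactly two classes, got {uniq}")
    y = (labels == uniq[1]).astype(float)
    model = fit_pls(X, y, n_components, **kwargs)
    model.classes = (uniq[0], uniq[1])
    return model


def vip_scores(model: PlsModel) -> np.ndarray:
    """Variable importance in projection.

    VIP_j = sqrt( p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a ),
    where SSY_a is the y-variance explained by component a. The mean of
    the squared VIPs is exactly 1, so VIP >= 0.8 flags predictors pulling
    roughly their average weight or more.
    """
    W = model.x_weights
    if W.size == 0:
        raise ValueError("model is not fitted")
    p = W.shape[0]
    wnorm2 = (W**2) / np.maximum((W**2).sum(axis=0, keepdims=True), _EPS)
    ssy = model.ssy_per_component
    return np.sqrt(p * (wnorm2 @ ssy) / ssy.sum())


def _segment_folds(n: int, n_folds: int, rng: np.random.Generator | None) -> list[np.ndarray]:
    idx = np.arange(n)
    if rng is not None:
        idx = rng.permutation(n)
    return [idx[k::n_folds] for k in range(n_folds)]


def coefficient_ci(
    X,
    y,
    n_components: int,
    inner_folds: int = 7,
    level: float = 0.95,
    rng: np.random.Generator | None = None,
    discriminant: bool = False,
    segments: list[np.ndarray] | None = None,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Martens-jackknife confidence intervals for PLS coefficients.

    The model is refit leaving out each of ``inner_folds`` segments in
    turn; the spread of the segment coefficients around the full-data
    coefficients gives the jackknife variance
    ``SE_j^2 = (m-1)/m * sum_i (b_(i)j - b_j)^2`` and a symmetric
    t-interval with m-1 degrees of freedom. Returns the (p, 2) interval
    array and the segment coefficient vectors (reusable by callers).
    """
    if inner_folds < 2:
        raise ValueError("need at least 2 jackknife segments")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = X.shape[0]
    fit = fit_plsda if discriminant else fit_pls
    full = fit(X, y, n_components)
    a = min(n_components, full.n_components)
    b_full = full.coef_path[:, a - 1]

    if segments is None:
        segments = _segment_folds(n, inner_folds, rng)
    b_seg = []
    for seg in segments:
        keep = np.setdiff1d(np.arange(n), seg)
        sub = fit(X[keep], y[keep], n_components)
        b_seg.append(sub.coef_path[:, min(a, sub.n_components) - 1])
    B = np.asarray(b_seg)  # (m, p)
    m = B.shape[0]
    se = np.sqrt((m - 1) / m * ((B - b_full[None, :]) ** 2).sum(axis=0))
    tq = stats.t.ppf(0.5 + level / 2.0, df=m - 1)
    ci = np.column_stack([b_full - tq * se, b_full + tq * se])
    return ci, b_seg


def q2_statistic(y_true, y_pred, y_train_mean: float) -> float:
    """Cross-validated predictive R^2: 1 - PRESS / TSS.

    TSS is taken around the *training* mean, so predicting that mean for
    every sample scores exactly 0 and values above 0 indicate genuine
    predictive ability.
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must be nonempty and equal-length")
    tss = ((y_true - y_train_mean) ** 2).sum()
    if tss < _EPS:
        raise ValueError("zero total sum of squares around the training mean")
    return float(1.0 - ((y_true - y_pred) ** 2).sum() / tss)
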