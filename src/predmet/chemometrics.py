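"""Latent-variable pattern recognition: PCA screening and OPLS-DA.

Orthogonal projections to latent structures (OPLS) separates predictor
variation into a single predictive component — correlated with the class
response — and a configurable number of orthogonal components that are
systematically structured but unrelated to class.  For a two-class problem
this yields one predictive score axis ``t_pred`` per sample and one
predictive weight ``w*`` per feature.

Model quality is summarized the way the field reports it:

* ``R2X`` — fraction of (scaled) predictor variance captured by the model,
* ``R2Y`` — fraction of class-response variance described,
* ``Q2``  — fraction of class-response variance *predicted* under k-fold
  cross-validation, ``1 - PRESS/SS``,

and the cross-validated model is tested for significance with CV-ANOVA: an
F-test comparing the cross-validated residuals against the total response
variation.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .tables import FeatureTable

__all__ = [
    "OPLSModel",
    "CVResult",
    "scale",
    "apply_scaling",
    "pca_overview",
    "fit_opls",
    "predict_scores",
    "cross_validate",
    "cv_anova",
    "select_orthogonal",
]


@dataclasses.dataclass
class OPLSModel:
    """A fitted OPLS-DA model with one predictive component.

    ``w_star`` has unit norm and is oriented so the class coded 1 has
    positive mean predictive score.  Orthogonal weights/loadings/scores are
    stored column-wise (one column per orthogonal component).
    """

    A_pred: int
    A_orth: int
    w_star: np.ndarray
    t_pred: np.ndarray
    p_pred: np.ndarray
    c_pred: float
    w_orth: np.ndarray  # features x A_orth
    p_orth: np.ndarray
    t_orth: np.ndarray  # samples x A_orth
    R2X: float
    R2Y: float
    center_: np.ndarray
    scale_: np.ndarray
    scaling_mode: str
    y_mean_: float
    feature_ids: list = dataclasses.field(default_factory=list)
    sample_ids: list = dataclasses.field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "A_pred": self.A_pred,
            "A_orth": self.A_orth,
            "R2X": self.R2X,
            "R2Y": self.R2Y,
            "w_star": self.w_star.tolist(),
            "t_pred": self.t_pred.tolist(),
            "p_pred": self.p_pred.tolist(),
            "c_pred": self.c_pred,
            "feature_ids": list(self.feature_ids),
            "sample_ids": list(self.sample_ids),
        }


@dataclasses.dataclass
class CVResult:
    """Cross-validation output: per-sample held-out predictive scores.

    ``tcv`` is the cross-validated predictive score of each sample — its
    position on the predictive axis under a model that never saw it.  Every
    sample is predicted exactly once.
    """

    tcv: np.ndarray
    y_pred: np.ndarray
    Q2: float
    press: float
    ss: float
    fold_assignment: np.ndarray
    A_orth: int
    k: int
    p_cvanova: float | None = None
    sample_ids: list = dataclasses.field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "Q2": self.Q2,
            "press": self.press,
            "ss": self.ss,
            "k": self.k,
            "A_orth": self.A_orth,
            "p_cvanova": self.p_cvanova,
            "tcv": self.tcv.tolist(),
            "fold_assignment": self.fold_assignment.tolist(),
            "sample_ids": list(self.sample_ids),
        }


# ---------------------------------------------------------------------------
# scaling

def _scaling_vectors(X: np.ndarray, mode: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (center, scale, keep_mask) for a raw matrix."""
    center = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    keep = np.ones(X.shape[1], dtype=bool)
    if mode == "center":
        scale_vec = np.ones_like(sd)
    elif mode == "uv":
        keep = sd > 0
        scale_vec = np.where(keep, sd, 1.0)
    elif mode == "pareto":
        keep = sd > 0
        scale_vec = np.where(keep, np.sqrt(sd), 1.0)
    else:
        raise ValueError(f"unknown scaling mode {mode!r}")
    return center, scale_vec, keep


def scale(table: FeatureTable, mode: str = "uv") -> FeatureTable:
    """Column-wise centering plus the requested variance scaling.

    ``uv`` divides each centered column by its SD (unit variance), ``pareto``
    by the square root of the SD, ``center`` only centers.  Zero-variance
    columns cannot be unit-variance scaled; they are dropped with a warning.
    The centering/scaling vectors are stored on the result so the identical
    transform can be applied to held-out samples.
    """
    if table.scaling_state != "raw":
        raise ValueError("table is already scaled")
    X = table.values()
    center, scale_vec, keep = _scaling_vectors(X, mode)
    if not keep.all():
        dropped = list(table.X.columns[~keep])
        warnings.warn(f"dropping {len(dropped)} zero-variance feature(s): {dropped}")
    Xs = (X - center) / scale_vec
    out = FeatureTable(
        X=pd.DataFrame(Xs[:, keep], index=table.X.index, columns=table.X.columns[keep]),
        sample_meta=table.sample_meta.copy(),
        feature_meta=table.feature_meta.loc[table.X.columns[keep]].copy(),
        scaling_state=mode if mode != "center" else "centered",
        center_=center[keep],
        scale_=scale_vec[keep],
    )
    return out


def apply_scaling(table_scaled: FeatureTable, new: FeatureTable) -> FeatureTable:
    """Apply a fitted table's stored scaling to new raw data."""
    if table_scaled.center_ is None:
        raise ValueError("source table carries no scaling vectors")
    cols = table_scaled.X.columns
    Xn = new.X[cols].to_numpy(dtype=float)
    Xs = (Xn - table_scaled.center_) / table_scaled.scale_
    return FeatureTable(
        X=pd.DataFrame(Xs, index=new.X.index, columns=cols),
        sample_meta=new.sample_meta.copy(),
        feature_meta=table_scaled.feature_meta.copy(),
        scaling_state=table_scaled.scaling_state,
        center_=table_scaled.center_.copy(),
        scale_=table_scaled.scale_.copy(),
    )


# ---------------------------------------------------------------------------
# PCA overview

def hotelling_t2_limit(n: int, a: int = 2, alpha: float = 0.05) -> float:
    """Critical value of Hotelling's T² for ``a`` PCA score dimensions."""
    if n <= a:
        return np.inf
    f = stats.f.ppf(1.0 - alpha, a, n - a)
    return a * (n**2 - 1) / (n * (n - a)) * f


def pca_overview(
    table: FeatureTable,
    n_components: int = 2,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray, pd.Series]:
    """Unsupervised overview of the table plus score-space outlier flags.

    Returns ``(scores, loadings, r2x_per_component, outlier_flags)`` where
    scores/loadings come from the SVD of the column-centered matrix (in the
    table's current scaling) and ``outlier_flags`` marks samples whose
    Hotelling-T² on the first two components exceeds the ``1 - alpha``
    ellipse.
    """
    n, p = table.X.shape
    if n_components > min(n - 1, p):
        raise ValueError("n_components too large for the table")
    X = table.values()
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-magnitude loading positive
    for a in range(len(s)):
        j = np.argmax(np.abs(Vt[a]))
        if Vt[a, j] < 0:
            Vt[a] *= -1
            U[:, a] *= -1
    T = U[:, :n_components] * s[:n_components]
    total = (s**2).sum()
    r2x = (s[:n_components] ** 2) / total if total > 0 else np.zeros(n_components)
    a_out = min(2, n_components)
    lam = (s[:a_out] ** 2) / (n - 1)
    t2 = np.sum(T[:, :a_out] ** 2 / np.where(lam > 0, lam, np.inf), axis=1)
    limit = hotelling_t2_limit(n, a_out, alpha)
    flags = pd.Series(t2 > limit, index=table.X.index, name="outlier")
    scores = pd.DataFrame(
        T, index=table.X.index, columns=[f"t{a+1}" for a in range(n_components)]
    )
    loadings = pd.DataFrame(
        Vt[:n_components].T,
        index=table.X.columns,
        columns=[f"p{a+1}" for a in range(n_components)],
    )
    return scores, loadings, r2x, flags


# ---------------------------------------------------------------------------
# OPLS core

def _opls_arrays(Xs: np.ndarray, y01: np.ndarray, a_orth: int):
    """Fit 1-predictive-component OPLS on an already scaled matrix.

    Returns a dict of arrays; no sign convention applied here.
    """
    y = np.asarray(y01, dtype=float)
    yc = y - y.mean()
    if np.allclose(yc, 0):
        raise ValueError("class response is constant")
    X = Xs.copy()
    n, p = X.shape
    if a_orth >= min(n, p):
        raise ValueError("A_orth must be smaller than the rank of X")
    W_o, P_o, T_o = [], [], []
    for _ in range(a_orth):
        w = X.T @ yc
        nw = np.linalg.norm(w)
        if nw < 1e-300:
            raise ValueError("degenerate predictive direction")
        w = w / nw
        t = X @ w
        p_load = X.T @ t / (t @ t)
        w_o = p_load - (w @ p_load) * w
        n_o = np.linalg.norm(w_o)
        if n_o < 1e-12:
            break  # no orthogonal structure left
        w_o = w_o / n_o
        t_o = X @ w_o
        p_o = X.T @ t_o / (t_o @ t_o)
        X = X - np.outer(t_o, p_o)
        W_o.append(w_o)
        P_o.append(p_o)
        T_o.append(t_o)
    w = X.T @ yc
    w = w / np.linalg.norm(w)
    t = X @ w
    p_load = X.T @ t / (t @ t)
    c = float(yc @ t / (t @ t))
    E = X - np.outer(t, p_load)
    ss_x = (Xs**2).sum()
    r2x = 1.0 - (E**2).sum() / ss_x if ss_x > 0 else 0.0
    r2y = 1.0 - ((yc - c * t) ** 2).sum() / (yc**2).sum()
    return {
        "w": w,
        "t": t,
        "p": p_load,
        "c": c,
        "W_o": np.array(W_o).T if W_o else np.zeros((p, 0)),
        "P_o": np.array(P_o).T if P_o else np.zeros((p, 0)),
        "T_o": np.array(T_o).T if T_o else np.zeros((n, 0)),
        "R2X": float(r2x),
        "R2Y": float(r2y),
        "y_mean": float(y.mean()),
    }


def _orient(fit: dict, y01: np.ndarray) -> dict:
    """Flip the predictive axis so class 1 has positive mean score."""
    t = fit["t"]
    if t[y01 == 1].mean() < t[y01 == 0].mean():
        fit["w"] = -fit["w"]
        fit["t"] = -fit["t"]
        fit["p"] = -fit["p"]
        fit["c"] = -fit["c"]
    return fit


def _encode_y(y, index=None) -> np.ndarray:
    y = np.asarray(y)
    levels = pd.unique(y)
    if len(levels) != 2:
        raise ValueError("y must have exactly two classes")
    if set(levels.tolist()) == {0, 1}:
        return y.astype(int)
    order = sorted(levels.tolist(), key=str)
    return np.asarray([order.index(v) for v in y], dtype=int)


def fit_opls(table: FeatureTable, y, A_orth: int = 0) -> OPLSModel:
    """Fit OPLS-DA with one predictive and ``A_orth`` orthogonal components.

    ``table`` must be scaled (see :func:`scale`); ``y`` is a binary class
    indicator (0/1 or two labels, sorted lexically to 0/1).  Each class needs
    at least 3 samples.
    """
    if table.scaling_state == "raw":
        raise ValueError("table must be scaled before fitting")
    y01 = _encode_y(y)
    if min((y01 == 0).sum(), (y01 == 1).sum()) < 3:
        raise ValueError("each class needs at least 3 samples")
    fit = _orient(_opls_arrays(table.values(), y01, A_orth), y01)
    return OPLSModel(
        A_pred=1,
        A_orth=fit["T_o"].shape[1],
        w_star=fit["w"],
        t_pred=fit["t"],
        p_pred=fit["p"],
        c_pred=fit["c"],
        w_orth=fit["W_o"],
        p_orth=fit["P_o"],
        t_orth=fit["T_o"],
        R2X=fit["R2X"],
        R2Y=fit["R2Y"],
        center_=table.center_ if table.center_ is not None else np.zeros(table.n_features),
        scale_=table.scale_ if table.scale_ is not None else np.ones(table.n_features),
        scaling_mode=table.scaling_state,
        y_mean_=fit["y_mean"],
        feature_ids=list(table.X.columns),
        sample_ids=list(table.X.index),
    )


def predict_scores(model: OPLSModel, X_raw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predictive scores and predicted responses for new raw-scale rows."""
    X = (np.asarray(X_raw, dtype=float) - model.center_) / model.scale_
    for a in range(model.t_orth.shape[1]):
        t_o = X @ model.w_orth[:, a]
        X = X - np.outer(t_o, model.p_orth[:, a])
    t = X @ model.w_star
    y_hat = model.y_mean_ + model.c_pred * t
    return t, y_hat


# ---------------------------------------------------------------------------
# cross-validation

def _fold_assignment(y01: np.ndarray, k: int, seed: int | None = None) -> np.ndarray:
    """Deterministic stratified round-robin folds (class-sorted, dealt in turn)."""
    n = len(y01)
    order = np.lexsort((np.arange(n), y01))  # class first, original order second
    if seed is not None:
        rng = np.random.default_rng(seed)
        parts = []
        for cls in (0, 1):
            idx = order[y01[order] == cls]
            rng.shuffle(idx)
            parts.append(idx)
        order = np.concatenate(parts)
    folds = np.empty(n, dtype=int)
    folds[order] = np.arange(n) % k
    return folds


def cross_validate(
    table: FeatureTable,
    y,
    A_orth: int = 0,
    k: int = 7,
    mode: str = "uv",
    seed: int | None = None,
) -> CVResult:
    """Seven-fold (by default) cross-validation of the OPLS-DA model.

    One seventh of the samples is held out while the remaining six sevenths
    are scaled and modeled; the held-out samples are then projected, and this
    rotates until every sample has been predicted exactly once.  ``table``
    must be raw — scaling is refit inside each training split.  ``Q2 = 1 -
    PRESS/SS`` with PRESS the squared held-out response error and SS the
    total centered response sum of squares.

    Fold assignment is deterministic (samples sorted by class then original
    order, dealt round-robin); pass ``seed`` for randomized stratified folds.
    """
    if table.scaling_state != "raw":
        raise ValueError("cross_validate expects a raw table; scaling is refit per fold")
    y01 = _encode_y(y)
    n = len(y01)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError("k may not exceed the number of samples")
    folds = _fold_assignment(y01, k, seed=seed)
    X = table.values()
    tcv = np.empty(n)
    y_pred = np.empty(n)
    for f in range(k):
        test = folds == f
        train = ~test
        center, scale_vec, keep = _scaling_vectors(X[train], mode)
        Xtr = (X[train][:, keep] - center[keep]) / scale_vec[keep]
        fit = _orient(_opls_arrays(Xtr, y01[train], A_orth), y01[train])
        Xte = (X[test][:, keep] - center[keep]) / scale_vec[keep]
        for a in range(fit["T_o"].shape[1]):
            t_o = Xte @ fit["W_o"][:, a]
            Xte = Xte - np.outer(t_o, fit["P_o"][:, a])
        t = Xte @ fit["w"]
        tcv[test] = t
        y_pred[test] = fit["y_mean"] + fit["c"] * t
    ss = float(((y01 - y01.mean()) ** 2).sum())
    press = float(((y01 - y_pred) ** 2).sum())
    q2 = 1.0 - press / ss
    return CVResult(
        tcv=tcv,
        y_pred=y_pred,
        Q2=q2,
        press=press,
        ss=ss,
        fold_assignment=folds,
        A_orth=A_orth,
        k=k,
        sample_ids=list(table.X.index),
    )


def cv_anova(cv: CVResult, y) -> float:
    """CV-ANOVA significance of a cross-validated model.

    The F statistic compares the variance explained under cross-validation,
    ``(SS - PRESS)``, against the cross-validated residual ``PRESS``:

        F = ((SS - PRESS) / d1) / (PRESS / d2)

    with ``d1`` the number of model components (1 predictive + A_orth) and
    ``d2 = n - 1 - d1``; the p-value is the upper tail of ``F(d1, d2)``.  A
    model with no predictive power (PRESS >= SS) returns p = 1; a zero
    cross-validated residual returns the smallest positive float rather
    than 0.
    """
    y01 = _encode_y(y)
    n = len(y01)
    d1 = 1 + cv.A_orth
    d2 = n - 1 - d1
    if d2 <= 0:
        raise ValueError("too few samples for CV-ANOVA")
    if cv.press <= 0:
        p = float(np.finfo(float).tiny)
    else:
        f_stat = ((cv.ss - cv.press) / d1) / (cv.press / d2)
        p = 1.0 if f_stat <= 0 else float(stats.f.sf(f_stat, d1, d2))
        if p == 0.0:
            p = float(np.finfo(float).tiny)
    cv.p_cvanova = p
    return p


def select_orthogonal(
    table: FeatureTable,
    y,
    max_orth: int = 2,
    k: int = 7,
    mode: str = "uv",
    improvement: float = 0.01,
) -> int:
    """Smallest orthogonal-component count beyond which Q2 stops improving.

    Starting at 0, one more orthogonal component is accepted only while it
    raises cross-validated Q2 by more than ``improvement`` (absolute).
    """
    if max_orth < 0:
        raise ValueError("max_orth must be >= 0")
    best = 0
    q2 = cross_validate(table, y, A_orth=0, k=k, mode=mode).Q2
    for a in range(1, max_orth + 1):
        try:
            q2_next = cross_validate(table, y, A_orth=a, k=k, mode=mode).Q2
        except ValueError:
            break
        if q2_next - q2 > improvement:
            best, q2 = a, q2_next
        else:
            break
    return best
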