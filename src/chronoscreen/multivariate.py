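"""OPLS time-of-day regression with cross-validated significance testing.

Regresses a unit-variance-scaled, mean-centered omics matrix on collection
time (ZT) with orthogonal projections to latent structures: X-variation is
split into a single Y-predictive component (LV1) and a sequence of
Y-orthogonal components (LVo1, ...).  Model robustness is judged by Q2(cum)
from 7-fold venetian-blind cross-validation and by a CV-ANOVA F-test on the
cross-validated residuals.

Degrees-of-freedom convention for CV-ANOVA (conventions differ across
software; this one is pinned and tested against an independent F-distribution
oracle): with N samples and k fitted components (1 predictive + n_ortho),
F = ((SS_y - PRESS)/k) / (PRESS/(N - 1 - k)) on (k, N - 1 - k) dof, where
SS_y is the total corrected sum of squares of y and PRESS the final model's
cross-validated prediction error.  PRESS >= SS_y yields p = 1 (no model).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .synth import TimeCourseMatrix

__all__ = [
    "ScaledMatrix",
    "OPLSModel",
    "CVReport",
    "preprocess",
    "fit_opls",
    "opls_predict",
    "cross_validate",
    "cv_anova",
    "model_significance",
    "fit_pca",
]


# --------------------------------------------------------------------------
# Preprocessing
# --------------------------------------------------------------------------

@dataclass
class ScaledMatrix:
    X: np.ndarray                 # samples x features, column mean 0, SD 1
    feature_ids: list[str]
    sample_ids: list[str]
    means: np.ndarray
    sds: np.ndarray
    dropped: list[str] = field(default_factory=list)  # zero-variance features
    log_transformed: bool = False


def _uv_scale(X: np.ndarray):
    """Unit-variance scaling and mean centering (sample SD, ddof=1)."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    return (X[:, keep] - mu[keep]) / sd[keep], mu, sd, keep


def preprocess(matrix: TimeCourseMatrix, group: str, y_encoding: str = "numeric",
               log_transform: bool = False):
    """Select one group's samples and scale; returns (ScaledMatrix, y).

    ``y`` is the ZT hour as a single numeric response by default; the
    ``"circular"`` encoding returns the (sin, cos) pair of the 24-h phase
    angle, which maps ZT 0 and 24 to the same point.
    """
    meta = matrix.group_samples(group)
    if len(meta) < 8:
        raise ValueError("need at least 8 samples for 7-fold cross-validation")
    X = matrix.values[meta["sample_id"]].to_numpy(float).T
    if log_transform:
        X = np.log1p(X)
    Xs, mu, sd, keep = _uv_scale(X)
    dropped = [f for f, k in zip(matrix.feature_ids, keep) if not k]
    if dropped:
        warnings.warn(f"dropped {len(dropped)} zero-variance features")
    sm = ScaledMatrix(
        X=Xs,
        feature_ids=[f for f, k in zip(matrix.feature_ids, keep) if k],
        sample_ids=list(meta["sample_id"]),
        means=mu[keep],
        sds=sd[keep],
        dropped=dropped,
        log_transformed=log_transform,
    )
    zt = meta["zt"].to_numpy(float)
    if y_encoding == "numeric":
        y = zt
    elif y_encoding == "circular":
        ang = 2 * np.pi * zt / 24.0
        y = np.column_stack([np.sin(ang), np.cos(ang)])
    else:
        raise ValueError("y_encoding must be 'numeric' or 'circular'")
    return sm, y


# --------------------------------------------------------------------------
# OPLS core (single numeric response)
# --------------------------------------------------------------------------

@dataclass
class OPLSModel:
    w: np.ndarray                 # predictive weights (unit norm)
    t: np.ndarray                 # predictive scores (LV1)
    p: np.ndarray                 # predictive loadings
    q: float                      # y-loading
    W_o: np.ndarray               # orthogonal weights, columns LVo1..
    T_o: np.ndarray               # orthogonal scores
    P_o: np.ndarray               # orthogonal loadings
    n_ortho: int
    y_mean: float
    R2X: float
    R2X_pred: float
    R2X_ortho: float
    R2Y: float


def fit_opls(X: np.ndarray, y: np.ndarray, n_ortho: int = 0) -> OPLSModel:
    """Single-response OPLS (orthogonal projections to latent structures).

    ``X`` must already be column-centered/scaled; ``y`` is centered
    internally.  The predictive weight is w = X'y/||X'y|| (invariant under
    the orthogonal deflations); each orthogonal component removes the part
    of the current X-loading orthogonal to w.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X and y disagree on sample count")
    if np.ptp(y) == 0:
        raise ValueError("y is constant")
    if n_ortho < 0:
        raise ValueError("n_ortho must be >= 0")
    if n_ortho > min(X.shape) - 1:
        raise ValueError("n_ortho exceeds the rank budget of X")

    y_mean = float(y.mean())
    yc = y - y_mean
    ssx = float((X ** 2).sum())
    Xd = X.copy()

    w = Xd.T @ yc
    w = w / np.linalg.norm(w)

    W_o, T_o, P_o = [], [], []
    for _ in range(n_ortho):
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        nw = np.linalg.norm(w_o)
        if nw < 1e-12:
            raise ValueError("no orthogonal variation left (rank exhausted)")
        w_o = w_o / nw
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Xd = Xd - np.outer(t_o, p_o)
        W_o.append(w_o)
        T_o.append(t_o)
        P_o.append(p_o)

    t = Xd @ w
    p = Xd.T @ t / (t @ t)
    q = float((yc @ t) / (t @ t))

    ss_pred = float((np.outer(t, p) ** 2).sum())
    ss_ortho = sum(float((np.outer(to, po) ** 2).sum()) for to, po in zip(T_o, P_o))
    ssy = float((yc ** 2).sum())
    r2y = 1.0 - float(((yc - q * t) ** 2).sum()) / ssy

    return OPLSModel(
        w=w, t=t, p=p, q=q,
        W_o=np.column_stack(W_o) if W_o else np.zeros((X.shape[1], 0)),
        T_o=np.column_stack(T_o) if T_o else np.zeros((X.shape[0], 0)),
        P_o=np.column_stack(P_o) if P_o else np.zeros((X.shape[1], 0)),
        n_ortho=n_ortho, y_mean=y_mean,
        R2X=(ss_pred + ss_ortho) / ssx,
        R2X_pred=ss_pred / ssx,
        R2X_ortho=ss_ortho / ssx,
        R2Y=r2y,
    )


def opls_predict(model: OPLSModel, X_new: np.ndarray) -> np.ndarray:
    """Predict y for new (already scaled) samples: strip the orthogonal
    components, project on the predictive weight, apply the y-loading."""
    Xd = np.asarray(X_new, float).copy()
    for a in range(model.n_ortho):
        t_o = Xd @ model.W_o[:, a]
        Xd = Xd - np.outer(t_o, model.P_o[:, a])
    return model.y_mean + model.q * (Xd @ model.w)


# --------------------------------------------------------------------------
# Cross-validation and CV-ANOVA
# --------------------------------------------------------------------------

@dataclass
class CVReport:
    folds: int
    press: list[float]       # per component count 0..n_ortho
    q2: list[float]
    q2cum: float
    n_ortho: int
    n_samples: int
    ss_y: float
    cv_anova_F: float = float("nan")
    cv_anova_dof: tuple[int, int] = (0, 0)
    cv_anova_p: float = float("nan")


def _venetian_folds(n: int, folds: int) -> np.ndarray:
    return np.arange(n) % folds


def cross_validate(X_raw: np.ndarray, y: np.ndarray, n_ortho: int = 0,
                   folds: int = 7) -> CVReport:
    """Deterministic venetian-blind CV with in-fold re-scaling (no leakage).

    ``X_raw`` is the unscaled samples x features matrix in metadata order
    (group/ZT/replicate); sample i goes to fold i mod ``folds``.  For each
    component count a = 0..n_ortho the held-out prediction error PRESS_a and
    Q2_a = 1 - PRESS_a/SS_a are computed, with SS_a = sum over samples of
    (y_i - mean of y over the training part of i's fold split)^2;
    Q2cum = 1 - prod_a(PRESS_a/SS_a).
    """
    X_raw = np.asarray(X_raw, float)
    y = np.asarray(y, float).ravel()
    n = y.size
    if n < folds:
        raise ValueError("need at least `folds` samples")
    assign = _venetian_folds(n, folds)
    if min(np.bincount(assign, minlength=folds)) < 2:
        raise ValueError("a fold has fewer than 2 samples")

    press = []
    ss = []
    for a in range(n_ortho + 1):
        pr = 0.0
        s = 0.0
        for f in range(folds):
            test = assign == f
            train = ~test
            Xs, mu, sd, keep = _uv_scale(X_raw[train])
            model = fit_opls(Xs, y[train], n_ortho=a)
            Xt = (X_raw[test][:, keep] - mu[keep]) / sd[keep]
            yhat = opls_predict(model, Xt)
            pr += float(((y[test] - yhat) ** 2).sum())
            s += float(((y[test] - y[train].mean()) ** 2).sum())
        press.append(pr)
        ss.append(s)

    q2 = [1.0 - p / s for p, s in zip(press, ss)]
    ratio = 1.0
    for p, s in zip(press, ss):
        ratio *= p / s
    return CVReport(
        folds=folds, press=press, q2=q2, q2cum=1.0 - ratio,
        n_ortho=n_ortho, n_samples=n,
        ss_y=float(((y - y.mean()) ** 2).sum()),
    )


def cv_anova(report: CVReport, y: np.ndarray | None = None):
    """CV-ANOVA F-test on cross-validated residuals; returns (F, p).

    Uses the final model's PRESS against the total corrected SS of y with
    the dof convention documented in the module docstring.
    """
    ss_y = report.ss_y if y is None else float(
        ((np.asarray(y, float) - np.mean(y)) ** 2).sum()
    )
    press = report.press[-1]
    k = 1 + report.n_ortho
    d2 = report.n_samples - 1 - k
    if d2 <= 0:
        raise ValueError("not enough samples for the dof convention")
    if press >= ss_y:
        report.cv_anova_F, report.cv_anova_dof, report.cv_anova_p = 0.0, (k, d2), 1.0
        return 0.0, 1.0
    F = ((ss_y - press) / k) / (press / d2)
    p = float(scipy.stats.f.sf(F, k, d2))
    report.cv_anova_F, report.cv_anova_dof, report.cv_anova_p = float(F), (k, d2), p
    return float(F), p


# --------------------------------------------------------------------------
# Model-significance verdict
# --------------------------------------------------------------------------

def model_significance(matrix: TimeCourseMatrix, group: str, alpha: float = 0.05,
                       max_ortho: int = 3, folds: int = 7,
                       y_encoding: str = "numeric"):
    """Grow orthogonal components while Q2cum improves by > 0.01, then test.

    Returns (verdict, OPLSModel, CVReport) with verdict "significant" iff
    the CV-ANOVA p of the selected model is below ``alpha``.
    """
    meta = matrix.group_samples(group)
    X_raw = matrix.values[meta["sample_id"]].to_numpy(float).T
    sm, y = preprocess(matrix, group, y_encoding=y_encoding)
    if y_encoding != "numeric":
        raise NotImplementedError("model_significance supports the numeric encoding")

    best = cross_validate(X_raw, y, n_ortho=0, folds=folds)
    for a in range(1, max_ortho + 1):
        try:
            cand = cross_validate(X_raw, y, n_ortho=a, folds=folds)
        except ValueError:
            break
        if cand.q2cum - best.q2cum > 0.01:
            best = cand
        else:
            break
    _, p = cv_anova(best, y)
    model = fit_opls(sm.X, y, n_ortho=best.n_ortho)
    verdict = "significant" if p < alpha else "not_significant"
    return verdict, model, best


# --------------------------------------------------------------------------
# PCA (outlier QC)
# --------------------------------------------------------------------------

def fit_pca(X: np.ndarray, k: int):
    """Principal components of a scaled matrix via SVD (QC use only).

    Returns (scores, loadings, explained_variance_ratio).
    """
    X = np.asarray(X, float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > min(X.shape):
        raise ValueError("k exceeds the rank budget of X")
    U, s, Vt = np.linalg.svd(X - X.mean(axis=0), full_matrices=False)
    scores = U[:, :k] * s[:k]
    evr = (s ** 2) / float((s ** 2).sum()) if s.any() else np.zeros_like(s)
    return scores, Vt[:k], evr[:k]
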