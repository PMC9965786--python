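"""Latent-variable models: NIPALS partial least squares (PLS) regression
and orthogonal PLS discriminant analysis (OPLS-DA).

Both estimators follow the scikit-learn protocol (``fit`` / ``predict`` /
``get_params``; fitted attributes carry a trailing underscore) so they
compose with pipelines and :func:`sklearn.base.clone`-based resampling.

PLS extracts components t = Xw maximizing covariance with the response;
X and Y are deflated by rank-one updates after each component (classic
NIPALS). OPLS-DA first strips "orthogonal" structured variation — X
components constrained to zero covariance with the class indicator matrix
— and then fits the predictive PLS on the filtered X, which concentrates
class separation in the predictive scores. With zero orthogonal
components the predictive part reduces exactly to PLS-DA.

Scaling conventions: ``scale="uv"`` (unit variance autoscaling, the common
chemometrics default), ``"pareto"`` (divide by √sd) or ``"center"``.
Weight-vector sign is pinned (first non-negligible element ≥ 0) so refits
are bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

_TINY = 1e-12


def _scale_vectors(X: np.ndarray, scale: str) -> tuple[np.ndarray, np.ndarray]:
    """Return (center, divisor) for a scaling convention; errors on a
    constant feature when a variance-based divisor is requested."""
    mean = X.mean(axis=0)
    if scale == "center":
        return mean, np.ones(X.shape[1])
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = list(np.flatnonzero(sd == 0))
        raise ValueError(f"constant feature(s) at column index {bad}: "
                         f"cannot apply '{scale}' scaling")
    if scale == "uv":
        return mean, sd
    if scale == "pareto":
        return mean, np.sqrt(sd)
    raise ValueError(f"unknown scaling {scale!r}; use 'uv', 'pareto' or 'center'")


def _fix_sign(w: np.ndarray) -> float:
    """Sign making the first non-negligible element of w non-negative."""
    nz = np.flatnonzero(np.abs(w) > _TINY)
    if nz.size and w[nz[0]] < 0:
        return -1.0
    return 1.0


def _nipals(X: np.ndarray, Y: np.ndarray, n_components: int,
            max_iter: int = 500, tol: float = 1e-10):
    """Core NIPALS PLS2 extraction on already centered/scaled matrices.

    Returns (W, T, P, C, ssy, X_res, Y_res); ``ssy[a]`` is the Y sum of
    squares captured by component a, the weight used by VIP. Extraction
    stops early if X is rank-exhausted.
    """
    Xa = X.copy()
    Ya = Y.copy()
    n, p = Xa.shape
    m = Ya.shape[1]
    W = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    C = np.zeros((m, n_components))
    ssy = np.zeros(n_components)
    a = 0
    for a in range(n_components):
        if np.linalg.norm(Xa) < _TINY or np.linalg.norm(Ya) < _TINY:
            break
        u = Ya[:, int(np.argmax(Ya.var(axis=0)))].copy()
        if np.linalg.norm(u) < _TINY:
            break
        t = np.zeros(n)
        for _ in range(max_iter):
            w = Xa.T @ u
            nw = np.linalg.norm(w)
            if nw < _TINY:
                break
            w /= nw
            t_new = Xa @ w
            c = Ya.T @ t_new / (t_new @ t_new)
            u = Ya @ c / (c @ c)
            if np.linalg.norm(t_new - t) < tol * max(np.linalg.norm(t_new), _TINY):
                t = t_new
                break
            t = t_new
        tt = t @ t
        if tt < _TINY:
            break
        s = _fix_sign(w)
        w, t = s * w, s * t
        c = Ya.T @ t / tt
        pvec = Xa.T @ t / tt
        Xa -= np.outer(t, pvec)
        Ya -= np.outer(t, c)
        W[:, a], T[:, a], P[:, a], C[:, a] = w, t, pvec, c
        ssy[a] = tt * (c @ c)
        a += 1
    k = a
    return W[:, :k], T[:, :k], P[:, :k], C[:, :k], ssy[:k], Xa, Ya


def _regression_coef(W: np.ndarray, P: np.ndarray, C: np.ndarray) -> np.ndarray:
    """B such that Ŷ = X_scaled @ B, via R = W (PᵀW)⁻¹."""
    if W.shape[1] == 0:
        return np.zeros((W.shape[0], C.shape[0]))
    R = W @ np.linalg.inv(P.T @ W)
    return R @ C.T


class NIPALSPLS(RegressorMixin, BaseEstimator):
    """NIPALS partial least squares regression (PLS1/PLS2).

    Parameters
    ----------
    n_components : int
        Number of latent components to extract.
    scale : {"uv", "pareto", "center"}
        Column scaling applied to X (Y is centered only).
    max_iter, tol : NIPALS inner-loop controls (score-change convergence).

    Attributes (after fit)
    ----------------------
    x_weights_ ``W``, x_scores_ ``T``, x_loadings_ ``P``, y_loadings_ ``C``;
    ``coef_`` on the scaled axes; ``r2x_``/``r2y_`` cumulative explained
    variance; ``ssy_`` per-component explained Y sum of squares.
    """

    def __init__(self, n_components: int = 2, scale: str = "uv",
                 max_iter: int = 500, tol: float = 1e-10):
        self.n_components = n_components
        self.scale = scale
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, Y):
        X = check_array(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        self._y_1d = Y.ndim == 1
        if self._y_1d:
            Y = Y[:, None]
        if Y.shape[0] != X.shape[0]:
            raise ValueError("X and Y sample counts differ")
        n, p = X.shape
        cap = min(n - 1, p)
        if not 1 <= self.n_components <= cap:
            raise ValueError(
                f"n_components={self.n_components} outside 1..min(n_samples-1,"
                f" n_features)={cap}")
        self.x_mean_, self.x_scale_ = _scale_vectors(X, self.scale)
        Xs = (X - self.x_mean_) / self.x_scale_
        self.y_mean_ = Y.mean(axis=0)
        Yc = Y - self.y_mean_
        (self.x_weights_, self.x_scores_, self.x_loadings_, self.y_loadings_,
         self.ssy_, X_res, Y_res) = _nipals(Xs, Yc, self.n_components,
                                            self.max_iter, self.tol)
        self.n_components_ = self.x_weights_.shape[1]
        self.coef_ = _regression_coef(self.x_weights_, self.x_loadings_,
                                      self.y_loadings_)
        ssx_tot = (Xs ** 2).sum()
        ssy_tot = (Yc ** 2).sum()
        self.r2x_ = 1.0 - (X_res ** 2).sum() / ssx_tot if ssx_tot > 0 else 0.0
        self.r2y_ = 1.0 - (Y_res ** 2).sum() / ssy_tot if ssy_tot > 0 else 0.0
        self.n_features_in_ = p
        return self

    def _scaled(self, X) -> np.ndarray:
        X = check_array(X, dtype=float)
        return (X - self.x_mean_) / self.x_scale_

    def transform(self, X) -> np.ndarray:
        """Project new samples onto the latent scores."""
        check_is_fitted(self)
        W, P = self.x_weights_, self.x_loadings_
        R = W @ np.linalg.inv(P.T @ W)
        return self._scaled(X) @ R

    def predict_response(self, X) -> np.ndarray:
        """Continuous Ŷ (always 2-D), used by cross-validation."""
        check_is_fitted(self)
        return self._scaled(X) @ self.coef_ + self.y_mean_

    def predict(self, X):
        Yhat = self.predict_response(X)
        return Yhat[:, 0] if self._y_1d else Yhat

    @property
    def predictive_weights_(self) -> np.ndarray:
        return self.x_weights_

    @property
    def predictive_ssy_(self) -> np.ndarray:
        return self.ssy_


class OPLSDA(ClassifierMixin, BaseEstimator):
    """Orthogonal PLS discriminant analysis against a one-hot class matrix.

    ``n_orth`` X-components with exactly zero covariance to every class
    indicator column are extracted and removed before the ``n_pred``
    predictive components are fitted (default: n_classes − 1). Orthogonal
    weights are obtained by projecting the X-loading of a provisional PLS
    component off the column space of XᵀY, which guarantees
    cov(t_orth, Y) = 0 to machine precision.
    """

    def __init__(self, n_orth: int = 1, n_pred: int | None = None,
                 scale: str = "uv", max_iter: int = 500, tol: float = 1e-10):
        self.n_orth = n_orth
        self.n_pred = n_pred
        self.scale = scale
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y):
        X = check_array(X, dtype=float)
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y sample counts differ")
        if self.n_orth < 0:
            raise ValueError("n_orth must be >= 0")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if self.classes_.size < 2:
            raise ValueError("need at least 2 classes")
        counts = np.bincount(y_idx)
        small = [str(self.classes_[i]) for i in np.flatnonzero(counts < 2)]
        if small:
            raise ValueError(f"class(es) with fewer than 2 samples: {small}")
        Y = np.zeros((X.shape[0], self.classes_.size))
        Y[np.arange(X.shape[0]), y_idx] = 1.0

        self.x_mean_, self.x_scale_ = _scale_vectors(X, self.scale)
        Xs = (X - self.x_mean_) / self.x_scale_
        self.y_mean_ = Y.mean(axis=0)
        Yc = Y - self.y_mean_
        ssx_tot = (Xs ** 2).sum()
        ssy_tot = (Yc ** 2).sum()

        # Y-predictive weight space: orthonormal basis of Xs'Y (invariant
        # under orthogonal deflation, since cov(t_orth, Y) = 0).
        cov = Xs.T @ Yc
        u_svd, s_svd, _ = np.linalg.svd(cov, full_matrices=False)
        basis = u_svd[:, s_svd > max(s_svd.max(), _TINY) * 1e-10] if s_svd.size else cov[:, :0]

        n, p = Xs.shape
        Xcur = Xs.copy()
        W_o, T_o, P_o = [], [], []
        for _ in range(self.n_orth):
            W1, T1, P1, _, _, _, _ = _nipals(Xcur, Yc, 1, self.max_iter, self.tol)
            if W1.shape[1] == 0:
                break
            pvec = P1[:, 0]
            w_o = pvec - basis @ (basis.T @ pvec)
            nrm = np.linalg.norm(w_o)
            if nrm < 1e-10 * max(np.linalg.norm(pvec), _TINY):
                break  # no orthogonal variation left
            w_o /= nrm
            w_o *= _fix_sign(w_o)
            t_o = Xcur @ w_o
            tt = t_o @ t_o
            if tt < _TINY:
                break
            p_o = Xcur.T @ t_o / tt
            Xcur -= np.outer(t_o, p_o)
            W_o.append(w_o)
            T_o.append(t_o)
            P_o.append(p_o)
        self.orth_weights_ = np.column_stack(W_o) if W_o else np.zeros((p, 0))
        self.orth_scores_ = np.column_stack(T_o) if T_o else np.zeros((n, 0))
        self.orth_loadings_ = np.column_stack(P_o) if P_o else np.zeros((p, 0))
        self.n_orth_ = self.orth_weights_.shape[1]

        n_pred = self.n_pred if self.n_pred is not None else self.classes_.size - 1
        n_pred = max(1, min(n_pred, n - 1, p))
        (self.x_weights_, self.x_scores_, self.x_loadings_, self.y_loadings_,
         self.ssy_, X_res, Y_res) = _nipals(Xcur, Yc, n_pred,
                                            self.max_iter, self.tol)
        self.n_pred_ = self.x_weights_.shape[1]
        self.coef_ = _regression_coef(self.x_weights_, self.x_loadings_,
                                      self.y_loadings_)
        self.r2x_ = 1.0 - (X_res ** 2).sum() / ssx_tot if ssx_tot > 0 else 0.0
        self.r2y_ = 1.0 - (Y_res ** 2).sum() / ssy_tot if ssy_tot > 0 else 0.0
        self.n_features_in_ = p
        return self

    def _filter(self, X) -> np.ndarray:
        """Scale and remove the fitted orthogonal components from new data."""
        X = check_array(X, dtype=float)
        Xs = (X - self.x_mean_) / self.x_scale_
        for k in range(self.n_orth_):
            t_o = Xs @ self.orth_weights_[:, k]
            Xs = Xs - np.outer(t_o, self.orth_loadings_[:, k])
        return Xs

    def transform(self, X) -> np.ndarray:
        """Predictive scores of new samples (orthogonal part removed)."""
        check_is_fitted(self)
        W, P = self.x_weights_, self.x_loadings_
        R = W @ np.linalg.inv(P.T @ W)
        return self._filter(X) @ R

    def orthogonal_scores(self, X) -> np.ndarray:
        check_is_fitted(self)
        X = check_array(X, dtype=float)
        Xs = (X - self.x_mean_) / self.x_scale_
        scores = []
        for k in range(self.n_orth_):
            t_o = Xs @ self.orth_weights_[:, k]
            scores.append(t_o)
            Xs = Xs - np.outer(t_o, self.orth_loadings_[:, k])
        return np.column_stack(scores) if scores else np.zeros((X.shape[0], 0))

    def predict_response(self, X) -> np.ndarray:
        """Continuous one-hot-scale Ŷ (columns follow ``classes_``)."""
        check_is_fitted(self)
        return self._filter(X) @ self.coef_ + self.y_mean_

    def predict(self, X):
        Yhat = self.predict_response(X)
        return self.classes_[np.argmax(Yhat, axis=1)]

    @property
    def predictive_weights_(self) -> np.ndarray:
        return self.x_weights_

    @property
    def predictive_ssy_(self) -> np.ndarray:
        return self.ssy_


def vip_scores(model) -> np.ndarray:
    """Variable importance in projection for a fitted PLS or OPLS-DA model.

    VIP_j = sqrt( p · Σ_a SSY_a (w_aj / ‖w_a‖)² / Σ_a SSY_a ), summed over
    predictive components only; satisfies Σ_j VIP_j² = p exactly.
    """
    check_is_fitted(model)
    W = model.predictive_weights_
    ssy = model.predictive_ssy_
    if W.shape[1] == 0 or ssy.sum() <= _TINY:
        raise ValueError("model explains no response variance: VIP undefined")
    p = W.shape[0]
    wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    return np.sqrt(p * (wn ** 2 @ ssy) / ssy.sum())
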