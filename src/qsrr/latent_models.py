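"""NIPALS partial least squares and RBF kernel PLS for a single response.

PLS extracts latent variables maximizing predictor-response covariance and
regresses RT on them; kernel PLS performs the same extraction on a
double-centered Gram matrix, letting a Gaussian kernel k(x_i, x_j) =
exp(-||x_i - x_j||^2 / (2 sigma^2)) carry the nonlinearity.  Both models
store their training scaler and response mean so prediction accepts raw
descriptor values and returns minutes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .pretreatment import Scaler, fit_scaler

__all__ = [
    "PLSModel",
    "KPLSModel",
    "ModelError",
    "rbf_kernel",
    "fit_pls",
    "fit_kpls",
    "choose_sigma",
    "predict",
]

_ITER_CAP = 500
_TOL = 1e-10


class ModelError(ValueError):
    pass


def rbf_kernel(x_i: np.ndarray, x_j: np.ndarray, sigma: float) -> float:
    """Gaussian similarity exp(-||x_i - x_j||^2 / (2 sigma^2)), in (0, 1]."""
    if sigma <= 0:
        raise ModelError("sigma must be > 0")
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    if x_i.shape != x_j.shape:
        raise ModelError("rbf_kernel requires equal-length vectors")
    d2 = float(np.sum((x_i - x_j) ** 2))
    return float(np.exp(-d2 / (2.0 * sigma**2)))


def _rbf_gram(A: np.ndarray, B: np.ndarray, sigma: float) -> np.ndarray:
    d2 = cdist(A, B, metric="sqeuclidean")
    return np.exp(-d2 / (2.0 * sigma**2))


def _pls_nipals(Xs: np.ndarray, yc: np.ndarray, n_lv: int):
    """Univariate-response NIPALS with deflation.

    Returns weights W, loadings P, response loadings q and coefficients in
    scaled-X units.  Raises if the X residual collapses before n_lv
    components (reporting the achievable rank).
    """
    n, k = Xs.shape
    W = np.zeros((k, n_lv))
    P = np.zeros((k, n_lv))
    q = np.zeros(n_lv)
    T = np.zeros((n, n_lv))
    Xd = Xs.copy()
    yd = yc.copy()
    for a in range(n_lv):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw < _TOL:
            raise ModelError(
                f"X residual collapsed at component {a + 1}; achievable rank is {a}"
            )
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt < _TOL:
            raise ModelError(
                f"score norm collapsed at component {a + 1}; achievable rank is {a}"
            )
        p = Xd.T @ t / tt
        qa = float(yd @ t) / tt
        Xd -= np.outer(t, p)
        yd = yd - qa * t
        W[:, a], P[:, a], q[a], T[:, a] = w, p, qa, t
    coef = W @ np.linalg.solve(P.T @ W, q) if n_lv else np.zeros(k)
    return W, P, q, T, coef


@dataclass
class PLSModel:
    """Fitted NIPALS PLS regression (single RT response)."""

    n_lv: int
    x_weights: np.ndarray      # K x n_lv
    x_loadings: np.ndarray     # K x n_lv
    y_loadings: np.ndarray     # n_lv
    scores: np.ndarray         # n x n_lv
    coef_scaled: np.ndarray    # in autoscaled-X units
    coefficients: np.ndarray   # in original descriptor units
    intercept: float           # minutes
    scaler: Scaler
    y_mean: float
    training_rows: np.ndarray
    fitted: np.ndarray         # training predictions, minutes
    descriptor_names: list[str] | None = None

    @property
    def n_inputs(self) -> int:
        return self.coefficients.size

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_inputs:
            raise ModelError(
                f"expected {self.n_inputs} descriptor columns, got {X.shape[1]}"
            )
        Xs = self.scaler.transform(X)
        return self.y_mean + Xs @ self.coef_scaled


def fit_pls(X: np.ndarray, y: np.ndarray, n_lv: int,
            descriptor_names: list[str] | None = None) -> PLSModel:
    """Fit PLS with n_lv latent variables on raw descriptors.

    Autoscaling (training-row z-score) and response centering happen
    internally and are stored on the model.  n_lv = 0 yields the constant
    mean-RT model.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if not (0 <= n_lv <= min(n - 1, k)):
        raise ModelError(f"require 0 <= n_lv <= min(n-1, K) = {min(n - 1, k)}")
    scaler = fit_scaler(X)
    Xs = scaler.transform(X)
    y_mean = float(y.mean())
    yc = y - y_mean
    W, P, q, T, coef = _pls_nipals(Xs, yc, n_lv)
    fitted = y_mean + Xs @ coef
    coef_orig = coef / scaler.sds
    intercept = y_mean - float(coef_orig @ scaler.means)
    return PLSModel(
        n_lv=n_lv,
        x_weights=W,
        x_loadings=P,
        y_loadings=q,
        scores=T,
        coef_scaled=coef,
        coefficients=coef_orig,
        intercept=intercept,
        scaler=scaler,
        y_mean=y_mean,
        training_rows=np.arange(n),
        fitted=fitted,
        descriptor_names=descriptor_names,
    )


@dataclass
class KPLSModel:
    """Fitted kernel PLS regression with a retained training matrix."""

    sigma: float | None        # None for the linear kernel
    kernel: str                # "rbf" or "linear"
    n_lv: int
    training_matrix: np.ndarray    # scaled n x K
    dual_scores: np.ndarray        # U, n x n_lv
    score_matrix: np.ndarray       # T, n x n_lv
    alpha: np.ndarray              # dual regression vector, length n
    k_row_means: np.ndarray        # training-kernel column means
    k_grand_mean: float
    scaler: Scaler
    y_mean: float
    fitted: np.ndarray             # training predictions, minutes
    descriptor_names: list[str] | None = None

    @property
    def n_inputs(self) -> int:
        return self.training_matrix.shape[1]

    def _gram(self, Xs: np.ndarray) -> np.ndarray:
        if self.kernel == "linear":
            return Xs @ self.training_matrix.T
        return _rbf_gram(Xs, self.training_matrix, self.sigma)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_inputs:
            raise ModelError(
                f"expected {self.n_inputs} descriptor columns, got {X.shape[1]}"
            )
        Xs = self.scaler.transform(X)
        Kt = self._gram(Xs)
        # feature-space centering with training statistics
        Ktc = (
            Kt
            - Kt.mean(axis=1, keepdims=True)
            - self.k_row_means[None, :]
            + self.k_grand_mean
        )
        return self.y_mean + Ktc @ self.alpha


def fit_kpls(
    X: np.ndarray,
    y: np.ndarray,
    sigma: float | None,
    n_lv: int,
    kernel: str = "rbf",
    descriptor_names: list[str] | None = None,
) -> KPLSModel:
    """Fit kernel PLS: double-center the Gram matrix, extract n_lv scores.

    Component extraction is the iterative dual algorithm (power iteration
    with deflation K <- (I - t t')K(I - t t')); for a single response it
    converges immediately but the loop and cap are kept for generality.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if not (1 <= n_lv <= n - 1):
        raise ModelError(f"require 1 <= n_lv <= n-1 = {n - 1}")
    if kernel == "rbf":
        if sigma is None or sigma <= 0:
            raise ModelError("rbf kernel requires sigma > 0")
    elif kernel != "linear":
        raise ModelError(f"unknown kernel: {kernel!r}")
    scaler = fit_scaler(X)
    Xs = scaler.transform(X)
    y_mean = float(y.mean())
    yc = y - y_mean

    K0 = Xs @ Xs.T if kernel == "linear" else _rbf_gram(Xs, Xs, sigma)
    row_means = K0.mean(axis=0)
    grand = float(K0.mean())
    Kc = K0 - row_means[None, :] - row_means[:, None] + grand

    T = np.zeros((n, n_lv))
    U = np.zeros((n, n_lv))
    Kd = Kc.copy()
    yd = yc.copy().astype(float)
    for a in range(n_lv):
        ny = np.linalg.norm(yd)
        if ny < _TOL:
            raise ModelError(
                f"response residual collapsed at component {a + 1}; "
                f"achievable rank is {a}"
            )
        u = yd / ny
        t_old = np.zeros(n)
        for it in range(_ITER_CAP):
            t = Kd @ u
            nt = np.linalg.norm(t)
            if nt < _TOL:
                raise ModelError(
                    f"kernel score collapsed at component {a + 1}; "
                    f"achievable rank is {a}"
                )
            t = t / nt
            c = float(yd @ t)
            u_new = yd * c
            u_new = u_new / np.linalg.norm(u_new)
            if np.linalg.norm(t - t_old) < _TOL:
                break
            t_old = t
            u = u_new
        else:
            raise ModelError(f"kernel-PLS component {a + 1} did not converge")
        T[:, a] = t
        U[:, a] = u
        proj = np.eye(n) - np.outer(t, t)
        Kd = proj @ Kd @ proj
        yd = yd - t * float(t @ yd)

    # dual regression vector: alpha = U (T' Kc U)^{-1} T' yc
    M = T.T @ Kc @ U
    alpha = U @ np.linalg.solve(M, T.T @ yc)
    fitted = y_mean + Kc @ alpha
    return KPLSModel(
        sigma=sigma if kernel == "rbf" else None,
        kernel=kernel,
        n_lv=n_lv,
        training_matrix=Xs,
        dual_scores=U,
        score_matrix=T,
        alpha=alpha,
        k_row_means=row_means,
        k_grand_mean=grand,
        scaler=scaler,
        y_mean=y_mean,
        fitted=fitted,
        descriptor_names=descriptor_names,
    )


def choose_sigma(
    X: np.ndarray,
    y: np.ndarray,
    grid: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0),
    n_lv: int = 3,
    n_folds: int = 5,
    seed: int = 0,
) -> float:
    """Pick the RBF width minimizing cross-validated RMSE.

    Grid entries are multipliers of the median pairwise Euclidean distance
    of the autoscaled descriptors; ties break toward the smaller sigma.
    """
    if len(grid) == 0:
        raise ModelError("sigma grid is empty")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if not np.any(pdist(X) > 0):
        raise ModelError("degenerate distances: all points identical")
    scaler = fit_scaler(X)
    d = pdist(scaler.transform(X))
    med = float(np.median(d))
    if med <= 0:
        raise ModelError("degenerate distances: all points identical")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, n_folds)
    best_sigma, best_rmse = None, np.inf
    for mult in sorted(grid):
        sigma = mult * med
        press = 0.0
        for fold in folds:
            mask = np.ones(n, dtype=bool)
            mask[fold] = False
            lv = min(n_lv, int(mask.sum()) - 1)
            model = fit_kpls(X[mask], y[mask], sigma, lv)
            press += float(np.sum((y[fold] - model.predict(X[fold])) ** 2))
        rmse = np.sqrt(press / n)
        if rmse < best_rmse - 1e-15:
            best_rmse, best_sigma = rmse, sigma
    return float(best_sigma)


def predict(model, X: np.ndarray) -> np.ndarray:
    """Predict RT (minutes) from raw descriptor values with a fitted model."""
    return model.predict(X)
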