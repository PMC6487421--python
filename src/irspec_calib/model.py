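"""The hybrid regressor: NIPALS-PLS latent variables feeding an RBF LS-SVM.

Stage 1 extracts ``A`` covariance-maximizing latent variables from the
(centered) spectra with single-response NIPALS PLS, denoising and reducing
dimension. Stage 2 fits a least-squares support vector machine with a
Gaussian RBF kernel, ``K(u, v) = exp(-||u - v||^2 / (2 sigma2))``, on the
score vectors. Training reduces to one symmetric linear system

    [[0, 1^T], [1, Omega + I/gamma]] @ [b; alpha] = [0; y]

whose solution satisfies the KKT identities ``sum(alpha) = 0`` and
``alpha_i = gamma * (y_i - yhat_i)`` on the training data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import get_lapack_funcs, lu_factor, lu_solve
from scipy.spatial.distance import cdist, pdist

from .exceptions import (
    ConfigError,
    IllConditionedError,
    RankError,
    ShapeError,
    TuningError,
)

__all__ = [
    "PLSModel",
    "LSSVMModel",
    "HybridModel",
    "nipals_pls_fit",
    "pls_transform",
    "rbf_kernel",
    "lssvm_fit",
    "lssvm_predict",
    "hybrid_fit",
    "tune_hyperparameters",
    "median_sq_distance",
]

_RCOND_LIMIT = 1e-12  # reciprocal condition number below this -> singular


@dataclass
class PLSModel:
    """Fitted PLS1 latent-variable model.

    ``rotation`` is ``R = W (P^T W)^-1`` so that scores of new data are
    ``T = (X - x_mean) R``; ``y_loadings`` regress (centered) y on scores.
    """

    x_mean: np.ndarray     # (p,)
    y_mean: float
    weights: np.ndarray    # (p, A)
    loadings: np.ndarray   # (p, A)
    y_loadings: np.ndarray  # (A,)
    rotation: np.ndarray   # (p, A)
    n_lv: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Linear PLS regression prediction (without the LS-SVM stage)."""
        return self.y_mean + pls_transform(self, X) @ self.y_loadings


@dataclass
class LSSVMModel:
    """LS-SVM dual solution over PLS score space."""

    support_scores: np.ndarray  # (n, A) training scores
    alpha: np.ndarray           # (n,) dual coefficients
    b: float
    gamma: float
    sigma2: float

    def predict(self, T: np.ndarray) -> np.ndarray:
        return lssvm_predict(self, T)


@dataclass
class HybridModel:
    """SNV -> PLS -> LS-SVM chain (preprocessing applied upstream)."""

    pls: PLSModel
    lssvm: LSSVMModel
    preprocessing_tag: str = "snv"

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict responses for spectra rows (already preprocessed)."""
        return lssvm_predict(self.lssvm, pls_transform(self.pls, X))

    @property
    def n_lv(self) -> int:
        return self.pls.n_lv


def nipals_pls_fit(X: np.ndarray, y: np.ndarray, A: int) -> PLSModel:
    """Single-response NIPALS PLS with ``A`` latent variables.

    Per component: ``w = X^T y / ||X^T y||``, ``t = X w``,
    ``p = X^T t / (t^T t)``, ``q = y^T t / (t^T t)``; then X and y are
    deflated by the extracted component. Each weight vector is sign-fixed so
    its largest-magnitude element is positive.

    Raises
    ------
    RankError
        If no covariance remains at some component; ``.achievable`` reports
        how many components could be extracted.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ShapeError("X must be 2-D")
    n, p = X.shape
    if y.size != n:
        raise ShapeError(f"y has {y.size} entries for {n} rows of X")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ShapeError("non-finite values in PLS input")
    if A < 1 or A > min(n - 1, p):
        raise ConfigError(f"A must be in [1, {min(n - 1, p)}], got {A}")
    if np.ptp(y) == 0:
        raise ConfigError("y is constant; PLS undefined")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean

    W = np.empty((p, A))
    P = np.empty((p, A))
    q = np.empty(A)
    scale = np.sqrt(np.sum(Xc * Xc)) * np.sqrt(np.sum(yc * yc)) + 1e-300
    for a in range(A):
        w = Xc.T @ yc
        nw = np.linalg.norm(w)
        if nw <= 1e-14 * scale:
            raise RankError(
                f"no remaining X/y covariance at component {a + 1}; "
                f"only {a} latent variables achievable",
                achievable=a,
            )
        w /= nw
        # sign convention: largest-magnitude weight element positive
        if w[np.argmax(np.abs(w))] < 0:
            w = -w
        t = Xc @ w
        tt = float(t @ t)
        p_load = Xc.T @ t / tt
        q_a = float(yc @ t) / tt
        Xc = Xc - np.outer(t, p_load)
        yc = yc - q_a * t
        W[:, a], P[:, a], q[a] = w, p_load, q_a

    rotation = W @ np.linalg.inv(P.T @ W)
    return PLSModel(
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        loadings=P,
        y_loadings=q,
        rotation=rotation,
        n_lv=A,
    )


def pls_transform(m: PLSModel, X: np.ndarray) -> np.ndarray:
    """Project spectra rows onto the latent variables: T = (X - x_mean) R."""
    X = np.asarray(X, dtype=float)
    one_row = X.ndim == 1
    if one_row:
        X = X[None, :]
    if X.shape[1] != m.x_mean.size:
        raise ShapeError(
            f"X has {X.shape[1]} columns, model expects {m.x_mean.size}"
        )
    T = (X - m.x_mean) @ m.rotation
    return T[0] if one_row else T


def rbf_kernel(t1: np.ndarray, t2: np.ndarray, sigma2: float) -> float:
    """Gaussian RBF kernel value exp(-||t1 - t2||^2 / (2 sigma2))."""
    if sigma2 <= 0:
        raise ConfigError("sigma2 must be > 0")
    d = np.asarray(t1, dtype=float).ravel() - np.asarray(t2, dtype=float).ravel()
    return float(np.exp(-(d @ d) / (2.0 * sigma2)))


def _kernel_matrix(T1: np.ndarray, T2: np.ndarray, sigma2: float) -> np.ndarray:
    d2 = cdist(np.atleast_2d(T1), np.atleast_2d(T2), metric="sqeuclidean")
    return np.exp(-d2 / (2.0 * sigma2))


def lssvm_fit(
    T: np.ndarray, y: np.ndarray, gamma: float, sigma2: float
) -> LSSVMModel:
    """Solve the LS-SVM dual system on score vectors ``T``.

    The reciprocal condition of the saddle-point matrix is estimated from its
    LU factorization; below 1e-12 an :class:`IllConditionedError` is raised
    (a larger ``1/gamma`` regularizes the system).
    """
    if gamma <= 0:
        raise ConfigError("gamma must be > 0")
    if sigma2 <= 0:
        raise ConfigError("sigma2 must be > 0")
    T = np.atleast_2d(np.asarray(T, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = T.shape[0]
    if y.size != n:
        raise ShapeError(f"y has {y.size} entries for {n} score rows")
    if n < 2:
        raise ShapeError("LS-SVM needs at least 2 training points")
    if not (np.all(np.isfinite(T)) and np.all(np.isfinite(y))):
        raise ShapeError("non-finite values in LS-SVM input")

    omega = _kernel_matrix(T, T, sigma2)
    M = np.zeros((n + 1, n + 1))
    M[0, 1:] = 1.0
    M[1:, 0] = 1.0
    M[1:, 1:] = omega + np.eye(n) / gamma
    rhs = np.concatenate(([0.0], y))

    lu, piv = lu_factor(M)
    gecon = get_lapack_funcs("gecon", (M,))
    rcond, _ = gecon(lu, np.linalg.norm(M, 1))
    if rcond < _RCOND_LIMIT:
        raise IllConditionedError(
            f"LS-SVM system numerically singular (rcond={rcond:.2e}); "
            f"try a smaller gamma (larger ridge 1/gamma)"
        )
    sol = lu_solve((lu, piv), rhs)
    return LSSVMModel(
        support_scores=T.copy(),
        alpha=sol[1:],
        b=float(sol[0]),
        gamma=float(gamma),
        sigma2=float(sigma2),
    )


def lssvm_predict(m: LSSVMModel, T: np.ndarray) -> np.ndarray:
    """Predict with the dual expansion yhat(t) = sum_i alpha_i K(t, t_i) + b."""
    T = np.asarray(T, dtype=float)
    one_row = T.ndim == 1
    T2 = np.atleast_2d(T)
    if T2.shape[1] != m.support_scores.shape[1]:
        raise ShapeError(
            f"scores have {T2.shape[1]} dims, model expects "
            f"{m.support_scores.shape[1]}"
        )
    K = _kernel_matrix(T2, m.support_scores, m.sigma2)
    out = K @ m.alpha + m.b
    return float(out[0]) if one_row else out


def hybrid_fit(
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    A: int,
    gamma: float,
    sigma2: float,
) -> HybridModel:
    """Fit PLS on spectra, then the LS-SVM on the training scores."""
    pls = nipals_pls_fit(X_cal, y_cal, A)
    T = pls_transform(pls, X_cal)
    lssvm = lssvm_fit(T, np.asarray(y_cal, dtype=float).ravel(), gamma, sigma2)
    return HybridModel(pls=pls, lssvm=lssvm)


def median_sq_distance(T: np.ndarray) -> float:
    """Median squared pairwise Euclidean distance; RBF bandwidth scale."""
    T = np.atleast_2d(np.asarray(T, dtype=float))
    d2 = pdist(T, metric="sqeuclidean")
    med = float(np.median(d2)) if d2.size else 1.0
    return med if med > 0 else 1.0


def _loo_fold_scores(
    X: np.ndarray, y: np.ndarray, A: int
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray, float]]:
    """Per-LOO-fold (train scores, train y, held-out score, held-out y)."""
    n = X.shape[0]
    folds = []
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        pls = nipals_pls_fit(X[keep], y[keep], A)
        folds.append(
            (
                pls_transform(pls, X[keep]),
                y[keep],
                pls_transform(pls, X[i]),
                float(y[i]),
            )
        )
    return folds


def tune_hyperparameters(
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    A: int,
    gamma_grid: Sequence[float],
    sigma2_grid: Sequence[float],
) -> tuple[float, float]:
    """Grid search (gamma, sigma2) minimizing leave-one-out PRESS.

    The PLS stage is refit for every fold (so the search scores the full
    hybrid), but fold scores are shared across grid points since they do not
    depend on the kernel parameters. Ties prefer the smallest gamma, then the
    largest sigma2 (strongest regularization / smoothest kernel).
    """
    gamma_grid = sorted(set(float(g) for g in gamma_grid))
    sigma2_grid = sorted(set(float(s) for s in sigma2_grid), reverse=True)
    if not gamma_grid or not sigma2_grid:
        raise ConfigError("hyperparameter grids must be non-empty")
    X = np.asarray(X_cal, dtype=float)
    y = np.asarray(y_cal, dtype=float).ravel()
    folds = _loo_fold_scores(X, y, A)

    best: tuple[float, float] | None = None
    best_press = np.inf
    any_ok = False
    for gamma in gamma_grid:
        for sigma2 in sigma2_grid:
            press = 0.0
            try:
                for T_tr, y_tr, t_h, y_h in folds:
                    sub = lssvm_fit(T_tr, y_tr, gamma, sigma2)
                    press += (lssvm_predict(sub, t_h) - y_h) ** 2
            except IllConditionedError:
                continue
            any_ok = True
            if press < best_press:
                best_press = press
                best = (gamma, sigma2)
    if not any_ok or best is None:
        raise TuningError("every (gamma, sigma2) grid point was ill-conditioned")
    return best
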