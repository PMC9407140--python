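"""Partial least squares regression (single response, NIPALS).

PLS is the workhorse of the pipeline: it is both a model family in its
own right and the engine inside the CARS and UVE band selectors.  The
implementation is the classical single-``y`` NIPALS sequence -- weights
``w_a`` maximise covariance with the response, scores ``t_a = X w_a``,
deflation of ``X`` (and ``y``) after each component -- with ``X`` and
``y`` mean-centered internally.  For a single response each component is
obtained in closed form, so no within-component iteration is needed.

At ``n_components = rank(X)`` the fitted coefficients coincide with
ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PLSModel", "fit_pls", "coefficient_path", "pls_rmsecv",
           "select_components", "kfold_indices"]


@dataclass
class PLSModel:
    """Fitted PLS model; prediction is ``y_mean + (X - x_mean) @ coef``."""

    x_mean: np.ndarray
    y_mean: float
    x_weights: np.ndarray    # (p, a)
    x_loadings: np.ndarray   # (p, a)
    y_loadings: np.ndarray   # (a,)
    coef: np.ndarray         # (p,)
    n_components: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.x_mean.size:
            raise ValueError(
                f"expected {self.x_mean.size} predictors, got "
                f"{X.shape[1] if X.ndim == 2 else X.shape}")
        return self.y_mean + (X - self.x_mean) @ self.coef


def fit_pls(X: np.ndarray, y: np.ndarray, n_components: int,
            tol: float = 1e-12) -> PLSModel:
    """Fit single-response PLS with ``n_components`` latent variables.

    Component extraction stops early (with fewer components than
    requested) if the deflated ``X`` carries no covariance with the
    residual response; the achieved count is recorded on the model.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be (n, p) with matching y")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("X and y must be finite")
    n, p = X.shape
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(
            f"n_components must lie in [1, min(n-1, p)] = [1, {min(n - 1, p)}]")
    if np.ptp(y) == 0:
        raise ValueError("response has zero variance")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    scale = np.linalg.norm(Xc) * max(np.abs(yc).max(), 1.0)
    a = 0
    for a in range(n_components):
        w = Xc.T @ yc
        norm_w = np.linalg.norm(w)
        if norm_w <= tol * max(scale, 1.0):
            break  # nothing left that covaries with the residual response
        w /= norm_w
        t = Xc @ w
        tt = float(t @ t)
        if tt <= tol:
            break
        pa = Xc.T @ t / tt
        qa = float(yc @ t / tt)
        W[:, a], P[:, a], q[a] = w, pa, qa
        Xc = Xc - np.outer(t, pa)
        yc = yc - qa * t
        a += 1
    if a == 0:
        raise ValueError("no PLS component could be extracted "
                         "(X carries no covariance with y)")
    W, P, q = W[:, :a], P[:, :a], q[:a]
    coef = W @ np.linalg.solve(P.T @ W, q)
    return PLSModel(x_mean=x_mean, y_mean=y_mean, x_weights=W, x_loadings=P,
                    y_loadings=q, coef=coef, n_components=a)


def coefficient_path(model: PLSModel) -> np.ndarray:
    """Coefficient vectors for every truncation 1..A of a fitted model.

    Returns a ``(p, A)`` array whose column ``a-1`` is the coefficient
    vector of the a-component model; used to score all component counts
    from a single fit.
    """
    W, P, q = model.x_weights, model.x_loadings, model.y_loadings
    A = model.n_components
    out = np.zeros((W.shape[0], A))
    for a in range(1, A + 1):
        out[:, a - 1] = W[:, :a] @ np.linalg.solve(P[:, :a].T @ W[:, :a], q[:a])
    return out


def kfold_indices(n: int, folds: int, seed: int = 0) -> list[np.ndarray]:
    """Seeded shuffled K-fold partition of ``range(n)``."""
    if not 2 <= folds <= n:
        raise ValueError(f"folds must lie in [2, {n}]")
    rng = np.random.default_rng(seed)
    return [np.sort(f) for f in np.array_split(rng.permutation(n), folds)]


def pls_rmsecv(X: np.ndarray, y: np.ndarray, n_components: int,
               folds: int = 5, seed: int = 0) -> float:
    """Pooled out-of-fold RMSE of a PLS model with fixed component count."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    sq = 0.0
    for test_idx in kfold_indices(y.size, folds, seed):
        train = np.setdiff1d(np.arange(y.size), test_idx)
        a = min(n_components, train.size - 1, X.shape[1])
        model = fit_pls(X[train], y[train], a)
        err = model.predict(X[test_idx]) - y[test_idx]
        sq += float(err @ err)
    return float(np.sqrt(sq / y.size))


def select_components(X: np.ndarray, y: np.ndarray, max_components: int,
                      folds: int = 5, seed: int = 0,
                      one_se_rule: bool = True) -> int:
    """Pick the component count by K-fold CV.

    One model is fitted per fold at the maximum count and all truncations
    are scored from its coefficient path.  By default the one-standard-
    error rule applies: the smallest count whose RMSECV is within one
    standard error (over folds) of the minimum wins -- later components
    buy little accuracy but destabilise the coefficient vector.  With
    ``one_se_rule=False`` the plain minimum is returned (ties go to fewer
    components).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    a_max = min(max_components, n - 1 - int(np.ceil(n / folds)), p)
    a_max = max(a_max, 1)
    fold_idx = kfold_indices(n, folds, seed)
    fold_mse = np.zeros((len(fold_idx), a_max))
    for fi, test_idx in enumerate(fold_idx):
        train = np.setdiff1d(np.arange(n), test_idx)
        a_fold = min(a_max, train.size - 1, p)
        model = fit_pls(X[train], y[train], a_fold)
        path = coefficient_path(model)          # (p, achieved)
        Xt = X[test_idx] - model.x_mean
        preds = model.y_mean + Xt @ path        # (n_test, achieved)
        err = preds - y[test_idx][:, None]
        achieved = path.shape[1]
        fold_mse[fi, :achieved] = np.mean(err ** 2, axis=0)
        if achieved < a_max:                    # extrapolate flat
            fold_mse[fi, achieved:] = fold_mse[fi, achieved - 1]
    rmsecv = np.sqrt(fold_mse.mean(axis=0))
    best = int(np.argmin(rmsecv))
    if not one_se_rule or len(fold_idx) < 2:
        return best + 1
    se = np.sqrt(fold_mse[:, best].std(ddof=1) ** 2 / len(fold_idx))
    # SE of the MSE, propagated to the RMSE scale
    se_rmse = se / max(2 * rmsecv[best], 1e-12)
    threshold = rmsecv[best] + se_rmse
    return int(np.argmax(rmsecv <= threshold)) + 1
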