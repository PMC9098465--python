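"""Univariate partial least squares regression (PLS1) by NIPALS.

The feature matrix is decomposed into orthogonal scores T and loadings P,
and the response is regressed on the first t score columns; the fitted
model is folded into an ordinary (coefficients, intercept) pair. Centering
happens on training means inside the fit — features are already scaled
globally by preprocessing, so no per-fit re-scaling — which keeps
validation rows out of every training statistic.

Component choice mirrors chemometrics practice: a leave-one-sample-out
cross-validation inside the training set over a component grid, selecting
the count with the highest LOO correlation (ties toward fewer components).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PLSModel", "pls1_fit", "pls1_predict", "loo_tune", "DEFAULT_COMPONENT_GRID"]

#: Component grid used throughout the analyses: 5, 10, 20, 50.
DEFAULT_COMPONENT_GRID: tuple[int, ...] = (5, 10, 20, 50)


@dataclass
class PLSModel:
    """Fitted PLS1 state.

    ``coefficients_path[:, k-1]`` holds the regression vector of the nested
    k-component model, so one fit serves every smaller component count.
    """

    n_components: int
    W: np.ndarray  # m x t weights
    P: np.ndarray  # m x t x-loadings
    q: np.ndarray  # t y-loadings
    T: np.ndarray  # n x t training scores
    x_center: np.ndarray
    y_center: float
    coefficients: np.ndarray
    intercept: float
    coefficients_path: np.ndarray = field(repr=False, default=None)

    def coef_at(self, k: int) -> tuple[np.ndarray, float]:
        """(coefficients, intercept) of the nested k-component model."""
        if not 1 <= k <= self.n_components:
            raise ValueError(f"k={k} outside 1..{self.n_components}")
        b = self.coefficients_path[:, k - 1]
        return b, self.y_center - float(self.x_center @ b)


def pls1_fit(Q_train: np.ndarray, y_train: np.ndarray, n_components: int) -> PLSModel:
    """NIPALS PLS1 with explicit deflation.

    Iterates w = X'y (normalized), t = Xw, p = X't/(t't), q = y't/(t't),
    deflating X <- X - t p' and y <- y - t q. Stops early (with a warning)
    if a weight vector vanishes before ``n_components`` is reached.
    """
    X = np.asarray(Q_train, dtype=float)
    y = np.asarray(y_train, dtype=float).ravel()
    n, m = X.shape
    if y.size != n:
        raise ValueError("y length does not match Q rows")
    if not np.all(np.isfinite(X)):
        raise ValueError("Q_train contains non-finite values")
    if not 1 <= n_components <= min(n - 1, m):
        raise ValueError(
            f"n_components={n_components} must be in 1..min(n-1, m)={min(n - 1, m)}"
        )

    x_center = X.mean(axis=0)
    y_center = float(y.mean())
    Xd = X - x_center
    yd = y - y_center
    scale = float(np.linalg.norm(Xd)) * float(np.linalg.norm(yd)) + 1e-300

    W = np.zeros((m, n_components))
    P = np.zeros((m, n_components))
    q = np.zeros(n_components)
    T = np.zeros((n, n_components))
    attained = 0
    for a in range(n_components):
        w = Xd.T @ yd
        wn = np.linalg.norm(w)
        if wn <= 1e-12 * np.sqrt(scale) or wn == 0.0:
            warnings.warn(
                f"weight vector vanished at component {a + 1}; "
                f"stopping with {attained} component(s)",
                stacklevel=2,
            )
            break
        w /= wn
        t = Xd @ w
        tt = float(t @ t)
        if tt <= 0:
            warnings.warn(
                f"degenerate score at component {a + 1}; stopping early",
                stacklevel=2,
            )
            break
        p = Xd.T @ t / tt
        ql = float(yd @ t / tt)
        Xd = Xd - np.outer(t, p)
        yd = yd - t * ql
        W[:, a], P[:, a], q[a], T[:, a] = w, p, ql, t
        attained = a + 1

    W, P, q, T = W[:, :attained], P[:, :attained], q[:attained], T[:, :attained]
    # nested-model coefficients: b_k = W_k (P_k' W_k)^-1 q_k; P'W is unit
    # upper-triangular in exact arithmetic, solved per truncation level
    path = np.zeros((m, attained))
    for k in range(1, attained + 1):
        R = P[:, :k].T @ W[:, :k]
        path[:, k - 1] = W[:, :k] @ np.linalg.solve(R, q[:k])
    b = path[:, attained - 1] if attained else np.zeros(m)
    return PLSModel(
        n_components=attained,
        W=W,
        P=P,
        q=q,
        T=T,
        x_center=x_center,
        y_center=y_center,
        coefficients=b,
        intercept=y_center - float(x_center @ b),
        coefficients_path=path,
    )


def pls1_predict(model: PLSModel, Q_new: np.ndarray, n_components: int | None = None) -> np.ndarray:
    """Predict via intercept + Q_new @ coefficients (optionally at a nested
    component count)."""
    Q_new = np.atleast_2d(np.asarray(Q_new, dtype=float))
    if Q_new.shape[1] != model.x_center.size:
        raise ValueError(
            f"Q_new has {Q_new.shape[1]} columns, model expects {model.x_center.size}"
        )
    if n_components is None:
        b, b0 = model.coefficients, model.intercept
    else:
        b, b0 = model.coef_at(n_components)
    return b0 + Q_new @ b


def loo_tune(
    Q_train: np.ndarray,
    y_train: np.ndarray,
    component_grid=DEFAULT_COMPONENT_GRID,
) -> tuple[pd.DataFrame, int]:
    """Leave-one-sample-out tuning of the component count.

    For each grid value, each training sample is left out, the model refit,
    and the sample predicted; reports LOO Pearson correlation and RMSE per
    count and selects the count maximizing correlation (ties toward fewer
    components). Grid values exceeding n-2 are skipped with a warning.
    """
    X = np.asarray(Q_train, dtype=float)
    y = np.asarray(y_train, dtype=float).ravel()
    n = X.shape[0]
    if n < 5:
        raise ValueError("leave-one-out tuning requires at least 5 samples")
    grid = sorted(set(int(g) for g in component_grid))
    if any(g < 1 for g in grid):
        raise ValueError("component grid values must be >= 1")
    usable = [g for g in grid if g <= n - 2 and g <= X.shape[1]]
    skipped = [g for g in grid if g not in usable]
    if skipped:
        warnings.warn(
            f"skipping component count(s) {skipped}: too large for "
            f"n={n}, m={X.shape[1]}",
            stacklevel=2,
        )
    if not usable:
        raise ValueError("no usable component counts in grid")

    kmax = max(usable)
    preds = np.zeros((n, len(usable)))
    idx = np.arange(n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # early stops inside LOO refits
        for i in range(n):
            mask = idx != i
            model = pls1_fit(X[mask], y[mask], kmax)
            for j, g in enumerate(usable):
                k = min(g, model.n_components)
                preds[i, j] = pls1_predict(model, X[i : i + 1], k)[0]

    rows = []
    for j, g in enumerate(usable):
        r = np.corrcoef(y, preds[:, j])[0, 1] if np.std(preds[:, j]) > 0 else np.nan
        rmse = float(np.sqrt(np.mean((y - preds[:, j]) ** 2)))
        rows.append({"n_components": g, "loo_correlation": r, "loo_rmse": rmse})
    table = pd.DataFrame(rows)
    # argmax with ties toward the smaller count (grid is ascending)
    corr = table["loo_correlation"].to_numpy()
    corr = np.where(np.isnan(corr), -np.inf, corr)
    selected = int(table["n_components"].iloc[int(np.argmax(corr))])
    return table, selected
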