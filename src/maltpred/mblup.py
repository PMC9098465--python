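"""Metabolomic BLUP: REML variance components and kernel predictions.

The model is the single-kernel mixed model

    y = 1*mu + m + e,    m ~ N(0, M sigma2_m),    e ~ N(0, I sigma2_e),

with the intercept as the only fixed effect: because the metabolome is
measured on the harvested material it already absorbs location/year
effects, so no further fixed effects are fitted. Total phenotypic variance
is sigma2_P = Mbar*sigma2_m + sigma2_e where Mbar is the mean diagonal of
M, and the relative variance component RVCm = Mbar*sigma2_m / sigma2_P is
the fraction of phenotypic variance carried by the metabolomic features.

REML is implemented directly (no mixed-model library): M is
eigendecomposed once, the criterion is profiled down to the single
variance fraction h = RVCm with the total variance solved in closed form
at each h, and h is found by a guarded grid scan plus bounded 1-D
minimization. Predictions for held-out samples use the standard BLUP
kernel form, which is algebraically identical to ridge regression on the
columns of Q with penalty m*lambda — that identity is the primary
correctness oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, eigh
from scipy.optimize import minimize_scalar

from .kernel import KernelMatrix

__all__ = ["VarianceComponents", "reml_fit", "relative_variance", "blup_predict"]

#: Bounds for the profiled variance fraction h = RVCm. Estimates landing at
#: a bound are flagged (``at_bound``) rather than treated as errors.
H_BOUNDS = (1e-6, 1.0 - 1e-6)


@dataclass
class VarianceComponents:
    """Fitted state of the single-kernel REML model."""

    sigma2_m: float
    sigma2_e: float
    mean_diag: float
    rvc_m: float
    mu_hat: float
    reml_loglik: float
    converged: bool
    n_used: int
    at_bound: bool = False
    se_rvc: float = float("nan")


def _reml_parts(h: float, d: np.ndarray, mbar: float, yt: np.ndarray, xt: np.ndarray):
    """Profiled REML pieces at variance fraction h.

    V = sigma2_P * V0 with V0 diagonalized as (h/Mbar)*d + (1-h); returns
    (restricted log-likelihood, profiled sigma2_P, GLS intercept).
    """
    n = yt.size
    d0 = (h / mbar) * d + (1.0 - h)
    w = 1.0 / d0
    xtvx = float(np.sum(xt * xt * w))
    beta = float(np.sum(xt * yt * w) / xtvx)
    r = yt - beta * xt
    quad = float(np.sum(r * r * w))  # y' P0 y
    s2 = quad / (n - 1)
    ll = -0.5 * (
        (n - 1) * np.log(2.0 * np.pi)
        + (n - 1) * np.log(s2)
        + float(np.sum(np.log(d0)))
        + np.log(xtvx)
        + (n - 1)
    )
    return ll, s2, beta


def reml_fit(
    y: np.ndarray,
    kernel: KernelMatrix,
    bounds: tuple[float, float] = H_BOUNDS,
    tol: float = 1e-8,
    n_grid: int = 65,
) -> VarianceComponents:
    """Estimate (sigma2_m, sigma2_e, mu) by REML for y = 1*mu + m + e.

    The kernel is eigendecomposed once; the criterion is profiled over the
    variance fraction h on ``bounds``. A coarse grid locates the basin and
    a bounded scalar minimization refines h to relative tolerance ``tol``.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n != kernel.n_samples:
        raise ValueError("y length does not match kernel")
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.var(y) == 0:
        raise ValueError("y has zero variance")

    d, U = eigh(kernel.M)
    lam_max = float(d[-1]) if d[-1] > 0 else 0.0
    if d[0] < -1e-8 * max(lam_max, 1.0):
        raise ValueError(
            f"kernel is not positive semidefinite (min eigenvalue {d[0]:.3e})"
        )
    d = np.clip(d, 0.0, None)
    mbar = kernel.mean_diag
    yt = U.T @ y
    xt = U.T @ np.ones(n)

    lo, hi = bounds
    grid = np.linspace(lo, hi, n_grid)
    lls = np.array([_reml_parts(h, d, mbar, yt, xt)[0] for h in grid])
    i = int(np.argmax(lls))
    bracket = (grid[max(i - 1, 0)], grid[min(i + 1, n_grid - 1)])

    res = minimize_scalar(
        lambda h: -_reml_parts(h, d, mbar, yt, xt)[0],
        bounds=bracket,
        method="bounded",
        options={"xatol": tol, "maxiter": 500},
    )
    h_hat = float(res.x)
    ll_hat = -float(res.fun)
    if lls[i] > ll_hat:  # grid point beat the local refinement
        h_hat, ll_hat = float(grid[i]), float(lls[i])
    ll_hat, s2p, mu = _reml_parts(h_hat, d, mbar, yt, xt)

    # curvature-based approximate standard error of the variance fraction
    eps = 1e-5
    h_lo, h_hi = max(lo, h_hat - eps), min(hi, h_hat + eps)
    ll_lo = _reml_parts(h_lo, d, mbar, yt, xt)[0]
    ll_hi = _reml_parts(h_hi, d, mbar, yt, xt)[0]
    d2 = (ll_hi - 2 * ll_hat + ll_lo) / ((h_hi - h_hat) * (h_hat - h_lo) + 1e-300)
    se = float(np.sqrt(-1.0 / d2)) if d2 < 0 else float("nan")

    at_bound = (h_hat <= lo + 10 * tol) or (h_hat >= hi - 10 * tol)
    return VarianceComponents(
        sigma2_m=h_hat * s2p / mbar,
        sigma2_e=(1.0 - h_hat) * s2p,
        mean_diag=mbar,
        rvc_m=h_hat,
        mu_hat=mu,
        reml_loglik=ll_hat,
        converged=bool(res.success),
        n_used=n,
        at_bound=at_bound,
        se_rvc=se,
    )


def relative_variance(vc: VarianceComponents) -> float:
    """RVCm = Mbar*sigma2_m / (Mbar*sigma2_m + sigma2_e)."""
    num = vc.mean_diag * vc.sigma2_m
    den = num + vc.sigma2_e
    if den == 0:
        raise ValueError("both variance components are zero")
    return num / den


def blup_predict(
    vc: VarianceComponents,
    y_train: np.ndarray,
    kernel: KernelMatrix,
    train_ids,
    target_ids,
) -> np.ndarray:
    """BLUP of held-out phenotypes from the training block of the kernel.

    yhat_target = mu + M[target, train] (M[train, train] + lambda*I)^-1
    (y_train - mu) with lambda = sigma2_e / sigma2_m and mu the GLS
    intercept computed on the training block. With sigma2_m = 0 the model
    carries no metabolomic signal and every prediction is the intercept.
    """
    y_train = np.asarray(y_train, dtype=float).ravel()
    tr = kernel.index_of(train_ids)
    tg = kernel.index_of(target_ids)
    if np.intersect1d(tr, tg).size:
        raise ValueError("train_ids and target_ids overlap")
    if y_train.size != tr.size:
        raise ValueError("y_train length does not match train_ids")

    if vc.sigma2_m == 0:
        return np.full(tg.size, vc.mu_hat)

    lam = vc.sigma2_e / vc.sigma2_m
    A = kernel.M[np.ix_(tr, tr)] + lam * np.eye(tr.size)
    A[np.diag_indices_from(A)] += 1e-10  # ridge jitter against exact singularity
    try:
        c, low = cho_factor(A)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "training kernel block is singular beyond jitter"
        ) from exc
    ones = np.ones(tr.size)
    Ai1 = cho_solve((c, low), ones)
    Aiy = cho_solve((c, low), y_train)
    mu = float(ones @ Aiy) / float(ones @ Ai1)
    alpha = Aiy - mu * Ai1  # = A^-1 (y - 1*mu)
    return mu + kernel.M[np.ix_(tg, tr)] @ alpha
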