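"""Logistic random-intercept mixed model via Gauss-Hermite quadrature.

Marginal likelihood for binary outcomes with one grouping factor (maternal
line): the group-level random intercept is integrated out with ordinary
Gauss-Hermite quadrature, and the resulting log-likelihood is maximized
with scipy's L-BFGS-B using an analytic gradient.  This supports the
likelihood-ratio tests on fixed effects; only a single variance component
is needed, so no general-purpose mixed-model machinery is involved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

__all__ = ["GlmmFit", "fit_logistic_glmm"]

_SEP_BOUND = 15.0  # |coef| beyond this on the logit scale suggests separation


@dataclass
class GlmmFit:
    beta: np.ndarray
    sigma: float
    loglik: float
    converged: bool
    separation: bool
    n_groups: int
    n_obs: int


def _prepare_groups(groups: np.ndarray):
    order = np.argsort(groups, kind="stable")
    g_sorted = np.asarray(groups)[order]
    starts = np.flatnonzero(np.r_[True, g_sorted[1:] != g_sorted[:-1]])
    return order, starts


def _nll_and_grad(theta, y, X, starts, z, logw):
    p_dim = X.shape[1]
    beta, log_sigma = theta[:p_dim], theta[p_dim]
    sigma = np.exp(log_sigma)
    eta0 = X @ beta  # (n,)
    # (n, K) linear predictor with quadrature offsets sqrt(2)*sigma*z_k
    offs = np.sqrt(2.0) * sigma * z
    eta = eta0[:, None] + offs[None, :]
    # per-observation Bernoulli log-lik and mean at each node
    ll_obs = y[:, None] * eta - np.logaddexp(0.0, eta)
    p = special.expit(eta)
    # per-group sums at each node
    ll_grp = np.add.reduceat(ll_obs, starts, axis=0)  # (G, K)
    resid_grp = np.add.reduceat(y[:, None] - p, starts, axis=0)
    log_int = ll_grp + logw[None, :]  # includes GH weights / sqrt(pi)
    m = log_int.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.exp(log_int - m).sum(axis=1))
    nll = -float(lse.sum())
    # node posterior weights a_gk
    a = np.exp(log_int - lse[:, None])  # (G, K), rows sum to 1
    # gradient wrt beta: sum_g sum_k a_gk X_g'(y_g - p_gk)
    w_obs = np.repeat(a, np.diff(np.r_[starts, len(y)]), axis=0)  # (n, K)
    resid_w = ((y[:, None] - p) * w_obs).sum(axis=1)  # (n,)
    grad_beta = X.T @ resid_w
    # gradient wrt log sigma: d eta/d log sigma = offs
    grad_ls = float((a * resid_grp * offs[None, :]).sum())
    return nll, -np.r_[grad_beta, grad_ls]


def fit_logistic_glmm(
    y,
    X,
    groups,
    n_quad: int = 25,
    start: np.ndarray | None = None,
) -> GlmmFit:
    """Maximum-likelihood logistic regression with a group random intercept."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    if y.ndim != 1 or X.shape[0] != len(y) or len(groups) != len(y):
        raise ValueError("y, X rows and groups must align")
    order, _ = _prepare_groups(groups)
    y_s, X_s, g_s = y[order], X[order], groups[order]
    starts = np.flatnonzero(np.r_[True, g_s[1:] != g_s[:-1]])
    z, w = np.polynomial.hermite.hermgauss(n_quad)
    logw = np.log(w) - 0.5 * np.log(np.pi)
    p_dim = X.shape[1]
    if start is None:
        # warm start from the unmixed logistic fit (ridge-stabilized IRLS)
        beta0 = _plain_logistic(y_s, X_s)
        start = np.r_[beta0, np.log(0.5)]
    res = optimize.minimize(
        _nll_and_grad,
        start,
        args=(y_s, X_s, starts, z, logw),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )
    beta = res.x[:p_dim]
    sigma = float(np.exp(res.x[p_dim]))
    separation = bool(np.any(np.abs(beta) > _SEP_BOUND))
    return GlmmFit(
        beta=beta,
        sigma=sigma,
        loglik=-float(res.fun),
        converged=bool(res.success),
        separation=separation,
        n_groups=len(starts),
        n_obs=len(y),
    )


def _plain_logistic(y, X, n_iter: int = 25, ridge: float = 1e-8) -> np.ndarray:
    beta = np.zeros(X.shape[1])
    for _ in range(n_iter):
        eta = X @ beta
        p = special.expit(eta)
        w = np.clip(p * (1 - p), 1e-10, None)
        H = X.T @ (X * w[:, None]) + ridge * np.eye(X.shape[1])
        g = X.T @ (y - p)
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
        beta = np.clip(beta, -2 * _SEP_BOUND, 2 * _SEP_BOUND)
    return beta
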