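"""Independent brute-force oracles used only by the test suite.

Each oracle is coded directly from first principles (closed forms, full
enumeration, leave-one-out refits) and never calls the package's own
implementation of the operation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

_MID_DOY = {1: 15, 2: 46, 3: 74, 4: 105, 5: 135, 6: 166, 7: 196, 8: 227, 9: 258,
            10: 288, 11: 319, 12: 349}
_DAYS = {1: 31, 2: 28, 3: 31, 4: 30, 5: 31, 6: 30, 7: 31, 8: 31, 9: 30, 10: 31,
         11: 30, 12: 31}


def oracle_thornthwaite(temps, lat):
    """Scalar-loop Thornthwaite PET, coded independently from the 1948 scheme."""
    i_heat = sum((t / 5.0) ** 1.514 for t in temps if t > 0)
    if i_heat <= 0:
        return [0.0] * 12
    a = 6.75e-7 * i_heat**3 - 7.71e-5 * i_heat**2 + 1.792e-2 * i_heat + 0.49239
    out = []
    for m, t in enumerate(temps, start=1):
        if t <= 0:
            out.append(0.0)
            continue
        doy = _MID_DOY[m]
        delta = 0.409 * math.sin(2 * math.pi * doy / 365.0 - 1.39)
        phi = math.radians(lat)
        cos_ws = max(-1.0, min(1.0, -math.tan(phi) * math.tan(delta)))
        n_hours = 24.0 / math.pi * math.acos(cos_ws)
        n_days = _DAYS[m]
        out.append(16.0 * (n_hours / 12.0) * (n_days / 30.0) * (10.0 * t / i_heat) ** a)
    return out


def oracle_ols(x, y):
    """Simple-regression F test from explicit sums of squares."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    b = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
    a = y.mean() - b * x.mean()
    yhat = a + b * x
    ss_reg = np.sum((yhat - y.mean()) ** 2)
    ss_res = np.sum((y - yhat) ** 2)
    f = ss_reg / (ss_res / (n - 2))
    from scipy.stats import f as fdist

    return {"slope": b, "intercept": a, "F": f, "p": fdist.sf(f, 1, n - 2),
            "r2": ss_reg / (ss_reg + ss_res)}


def oracle_cooks(X, y):
    """Cook's distance via literal leave-one-out refits."""
    X, y = np.asarray(X, float), np.asarray(y, float)
    n, p = X.shape
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    yhat = X @ beta
    s2 = np.sum((y - yhat) ** 2) / (n - p)
    d = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        beta_i = np.linalg.lstsq(X[keep], y[keep], rcond=None)[0]
        d[i] = np.sum((yhat - X @ beta_i) ** 2) / (p * s2)
    return d


def oracle_two_stage_slope(pf, mass, y):
    """Residualize y on mass, then regress residuals on pf (normal equations)."""
    mass, y, pf = np.asarray(mass, float), np.asarray(y, float), np.asarray(pf, float)
    X1 = np.column_stack([np.ones_like(mass), mass])
    resid = y - X1 @ np.linalg.solve(X1.T @ X1, X1.T @ y)
    X2 = np.column_stack([np.ones_like(pf), pf])
    return np.linalg.solve(X2.T @ X2, X2.T @ resid)[1]


def oracle_perm_p(on, off, tail):
    """Exact permutation p by enumerating all n! orderings of the pooled
    values (proportions coincide with the combinations enumeration)."""
    pooled = list(on) + list(off)
    k = len(on)
    obs = np.mean(on) - np.mean(off)
    eps = 1e-12 * max(1.0, max(abs(v) for v in pooled))
    hits = total = 0
    for perm in itertools.permutations(pooled):
        stat = np.mean(perm[:k]) - np.mean(perm[k:])
        total += 1
        if tail == "lower":
            hits += stat <= obs + eps
        elif tail == "upper":
            hits += stat >= obs - eps
        else:
            hits += abs(stat) >= abs(obs) - eps
    return hits / total


def oracle_glmm_loglik(y, X, groups, beta, sigma):
    """Marginal log-likelihood by adaptive numerical integration per group."""
    from scipy import integrate
    from scipy.special import expit

    y, X = np.asarray(y, float), np.asarray(X, float)
    eta0 = X @ beta
    total = 0.0
    for g in np.unique(groups):
        m = groups == g
        def integrand(u, m=m):
            p = expit(eta0[m] + u)
            lik = np.prod(np.where(y[m] > 0.5, p, 1 - p))
            return lik * math.exp(-0.5 * (u / sigma) ** 2) / (sigma * math.sqrt(2 * math.pi))
        val, _err = integrate.quad(integrand, -10 * sigma, 10 * sigma, limit=200)
        total += math.log(val)
    return total
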