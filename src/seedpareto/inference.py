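"""Gradient inference: permutation tests on front membership and
trait-climate regressions.

Whether populations on the Pareto front differ in aridity from populations
off it is tested with a two-sample permutation test on the difference in
group means of the covariate.  The historical aridity index uses a
one-tailed test in the *lower* tail ("more arid" = AI closer to zero); the
deviation index, for which no directional hypothesis exists, uses a
two-tailed test.  Group labels are permuted preserving group sizes; when
the number of distinct arrangements C(n, k) is small the test enumerates
them all (exact p = proportion of arrangements at least as extreme,
observed included), otherwise it samples B arrangements and reports the
add-one Monte-Carlo estimate p = (b + 1) / (B + 1).

Population trait means are also regressed on each aridity index with
ordinary least squares (F test on 1 and n - 2 degrees of freedom).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .pareto import ParetoResult

__all__ = [
    "PermutationResult",
    "RegressionResult",
    "permutation_test",
    "front_covariate_test",
    "trait_climate_regression",
    "DEFAULT_TAILS",
]

#: default tail per aridity covariate: on-front hypothesized more arid
#: (lower AI) for the historical index; no a-priori direction for deviation
DEFAULT_TAILS = {"historical_ai": "lower", "deviation_ai": "two_sided"}

EXACT_LIMIT = 20_000  # enumerate all arrangements when C(n, k) is at most this
_TIE_EPS = 1e-12


@dataclass(frozen=True)
class PermutationResult:
    statistic_observed: float  # mean(on-front) - mean(off-front)
    tail: str
    method: str  # "exact" | "monte_carlo"
    n_resamples: int  # arrangements enumerated, or B
    p_value: float
    rng_seed: int | None
    statistic: str = "mean_diff"
    n_on: int = 0
    n_off: int = 0
    covariate: str | None = None


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    F_statistic: float
    df: tuple
    p_value: float
    r_squared: float
    covariate: str | None = None
    trait: str | None = None


def _stat(values: np.ndarray, on_mask: np.ndarray, kind: str) -> float:
    a, b = values[on_mask], values[~on_mask]
    if kind == "mean_diff":
        return a.mean() - b.mean()
    # Welch t statistic alternative
    va, vb = a.var(ddof=1) if len(a) > 1 else 0.0, b.var(ddof=1) if len(b) > 1 else 0.0
    se = np.sqrt(va / len(a) + vb / len(b))
    return (a.mean() - b.mean()) / se if se > 0 else 0.0


def _count_extreme(sims: np.ndarray, observed: float, tail: str, scale: float) -> int:
    eps = _TIE_EPS * max(scale, 1.0)
    if tail == "lower":
        return int(np.sum(sims <= observed + eps))
    if tail == "upper":
        return int(np.sum(sims >= observed - eps))
    return int(np.sum(np.abs(sims) >= abs(observed) - eps))


def permutation_test(
    values_on,
    values_off,
    tail: str = "two_sided",
    B: int = 10_000,
    seed: int | None = None,
    method: str = "auto",
    statistic: str = "mean_diff",
) -> PermutationResult:
    """Two-sample permutation test on the difference in group means.

    ``tail`` is one of "lower", "upper", "two_sided".  ``method`` "auto"
    enumerates all C(n, k) equal-size arrangements when that count is at
    most 20,000 and falls back to B Monte-Carlo permutations otherwise.
    """
    if tail not in ("lower", "upper", "two_sided"):
        raise ValueError(f"unknown tail {tail!r}")
    if method not in ("auto", "exact", "monte_carlo"):
        raise ValueError(f"unknown method {method!r}")
    on = np.asarray(values_on, dtype=float)
    off = np.asarray(values_off, dtype=float)
    if len(on) == 0 or len(off) == 0:
        raise ValueError("both groups must be non-empty")
    if B < 1:
        raise ValueError("B must be >= 1")
    pooled = np.concatenate([on, off])
    n, k = len(pooled), len(on)
    scale = float(np.max(np.abs(pooled - pooled.mean()), initial=0.0))
    base_mask = np.zeros(n, dtype=bool)
    base_mask[:k] = True
    observed = _stat(pooled, base_mask, statistic)

    import warnings

    if np.allclose(pooled, pooled[0]):
        warnings.warn("covariate constant across groups; permutation p = 1")

    use_exact = method == "exact" or (method == "auto" and comb(n, k) <= EXACT_LIMIT)
    if use_exact:
        sims = np.empty(comb(n, k))
        mask = np.zeros(n, dtype=bool)
        for i, idx in enumerate(itertools.combinations(range(n), k)):
            mask[:] = False
            mask[list(idx)] = True
            sims[i] = _stat(pooled, mask, statistic)
        b = _count_extreme(sims, observed, tail, scale)
        p = b / len(sims)
        return PermutationResult(
            statistic_observed=float(observed),
            tail=tail,
            method="exact",
            n_resamples=len(sims),
            p_value=float(p),
            rng_seed=seed,
            statistic=statistic,
            n_on=k,
            n_off=n - k,
        )
    rng = np.random.default_rng(seed)
    sims = np.empty(B)
    for i in range(B):
        idx = rng.permutation(n)[:k]
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        sims[i] = _stat(pooled, mask, statistic)
    b = _count_extreme(sims, observed, tail, scale)
    p = (b + 1) / (B + 1)
    return PermutationResult(
        statistic_observed=float(observed),
        tail=tail,
        method="monte_carlo",
        n_resamples=B,
        p_value=float(p),
        rng_seed=seed,
        statistic=statistic,
        n_on=k,
        n_off=n - k,
    )


def front_covariate_test(
    populations: pd.DataFrame,
    front: ParetoResult,
    covariate: str = "historical_ai",
    tail: str | None = None,
    B: int = 10_000,
    seed: int | None = None,
    method: str = "auto",
) -> PermutationResult:
    """Permutation test of a climate covariate, on-front vs off-front.

    ``populations`` must carry ``population_id`` and the covariate column.
    The default tail follows the covariate (lower for historical AI,
    two-sided for deviation AI).
    """
    if covariate not in populations.columns:
        raise ValueError(f"covariate {covariate!r} not in population table")
    if tail is None:
        tail = DEFAULT_TAILS.get(covariate, "two_sided")
    on_ids = set(front.front_ids)
    mask = populations["population_id"].isin(on_ids).to_numpy()
    if mask.all():
        raise ValueError("degenerate front: every population on the front, test undefined")
    if not mask.any():
        raise ValueError("empty front")
    vals = populations[covariate].to_numpy(dtype=float)
    res = permutation_test(vals[mask], vals[~mask], tail=tail, B=B, seed=seed, method=method)
    return PermutationResult(**{**res.__dict__, "covariate": covariate})


def trait_climate_regression(
    populations: pd.DataFrame,
    covariate: str = "historical_ai",
    trait: str = "mean_sqrt_emergence",
) -> RegressionResult:
    """OLS of a population trait mean on a climate covariate.

    F statistic on (1, n - 2) degrees of freedom; two-sided p from the F
    distribution.  Requires at least 3 populations and a varying covariate.
    """
    d = populations[[covariate, trait]].dropna()
    x = d[covariate].to_numpy(dtype=float)
    y = d[trait].to_numpy(dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 populations with data, got {n}")
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0:
        raise ValueError("covariate has zero variance")
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    fitted = intercept + slope * x
    ss_reg = np.sum((fitted - y.mean()) ** 2)
    ss_res = np.sum((y - fitted) ** 2)
    df = (1, n - 2)
    ms_res = ss_res / df[1]
    if ms_res == 0.0:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = ss_reg / ms_res
        p = float(stats.f.sf(f_stat, *df))
    ss_tot = ss_reg + ss_res
    r2 = 1.0 if ss_tot == 0 else ss_reg / ss_tot
    return RegressionResult(
        slope=float(slope),
        intercept=float(intercept),
        F_statistic=float(f_stat),
        df=df,
        p_value=p,
        r_squared=float(r2),
        covariate=covariate,
        trait=trait,
    )
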