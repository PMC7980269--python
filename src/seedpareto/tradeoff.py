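"""Trade-off detection between within-year emergence speed and among-year
seed persistence, plus the seed-level model screens.

The central model regresses a maternal line's mean transformed emergence
time (sqrt days) on its seed persistence fraction, with source population
as a random intercept (REML).  The slope's Type II Wald chi-square on 1 df
is the trade-off test: a positive slope means lines with larger persistent
fractions emerge later.  Three variants are fitted:

* ``raw`` — line trait values as observed;
* ``deviation`` — both traits centered on their population means, isolating
  the within-population association from covariation of population means;
* ``mass_residualized`` — the response replaced by residuals from a first
  OLS of mean emergence time on mean seed mass, removing variation
  mediated by maternal provisioning.

Influence is screened with Cook's distance on the fixed-effects
representation of the line-level fit (population intercepts + persistence
slope); flagged lines trigger a with/without refit.

Seed-level screens fit the four response models (Gaussian on sqrt days for
emerged seeds; binomial-logit for persistence, emergence, mortality) with
maternal-line random intercepts, testing population, watering treatment,
their interaction, and seed mass (Type II Wald chi-square for the Gaussian
model, likelihood-ratio chi-square for the binomial models).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.outliers_influence import OLSInfluence
import statsmodels.api as sm

from ._glmm import fit_logistic_glmm

__all__ = [
    "TradeoffFit",
    "ScreenResult",
    "fit_tradeoff",
    "deviation_decomposition",
    "residualize_on_mass",
    "cooks_influence",
    "screen_seed_outcomes",
    "usable_lines",
]

DEFAULT_COOKS_THRESHOLD = 7.0


@dataclass
class TradeoffFit:
    variant: str  # raw | deviation | mass_residualized
    slope: float
    intercept: float
    wald_chisq: float
    df: int
    p_value: float
    n_lines: int
    method: str  # "mixed" or "fixed" (fallback)
    influential_lines: list = field(default_factory=list)
    cooks_threshold: float = DEFAULT_COOKS_THRESHOLD
    n_dropped_undefined: int = 0


@dataclass(frozen=True)
class ScreenResult:
    response: str  # emergence_time | persistence | emergence | mortality
    model_family: str  # gaussian | binomial-logit
    term: str  # population | treatment | population:treatment | seed_mass
    statistic: float
    df: int
    p_value: float
    direction_note: str
    unstable: bool = False


def usable_lines(lines: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Lines with both traits defined (lines where every living seed
    persisted have no emergence time and cannot enter the trade-off fits)."""
    ok = lines["mean_sqrt_emergence"].notna() & lines["persistence_fraction"].notna()
    return lines[ok].reset_index(drop=True), int((~ok).sum())


def _fit_grouped(y, x, groups, variant: str, n_dropped: int) -> TradeoffFit:
    """Random-intercept fit of y on x with fixed-intercept fallback."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    groups = np.asarray(groups)
    if np.ptp(x) == 0:
        raise ValueError("no variance in the persistence-fraction predictor")
    if len(y) < 3:
        raise ValueError(f"need >= 3 lines, got {len(y)}")
    if len(np.unique(groups)) < 2:
        # a single population: grouped fit degenerates to plain OLS
        return _fit_fixed(y, x, groups, variant, n_dropped)
    exog = np.column_stack([np.ones_like(x), x])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = MixedLM(y, exog, groups=groups)
            res = model.fit(reml=True, method="lbfgs")
        slope, se = res.params[1], res.bse[1]
        if not (np.isfinite(slope) and np.isfinite(se) and se > 0):
            raise ValueError("degenerate mixed fit")
    except Exception:
        warnings.warn(
            f"mixed fit failed for variant {variant!r}; "
            "falling back to population fixed intercepts"
        )
        return _fit_fixed(y, x, groups, variant, n_dropped)
    w = (slope / se) ** 2
    return TradeoffFit(
        variant=variant,
        slope=float(slope),
        intercept=float(res.params[0]),
        wald_chisq=float(w),
        df=1,
        p_value=float(stats.chi2.sf(w, 1)),
        n_lines=len(y),
        method="mixed",
        n_dropped_undefined=n_dropped,
    )


def _fixed_design(x, groups) -> np.ndarray:
    dummies = pd.get_dummies(pd.Series(groups), drop_first=False, dtype=float)
    return np.column_stack([dummies.to_numpy(), x])


def _fit_fixed(y, x, groups, variant: str, n_dropped: int) -> TradeoffFit:
    X = _fixed_design(x, groups)
    res = sm.OLS(y, X).fit()
    slope, se = res.params[-1], res.bse[-1]
    if np.isfinite(se) and se > 0:
        w = (slope / se) ** 2
        p = float(stats.chi2.sf(w, 1))
    else:  # perfect fit: zero residual variance
        w, p = float("inf"), 0.0
    return TradeoffFit(
        variant=variant,
        slope=float(slope),
        intercept=float(np.mean(res.params[:-1])),
        wald_chisq=float(w),
        df=1,
        p_value=p,
        n_lines=len(y),
        method="fixed",
        n_dropped_undefined=n_dropped,
    )


def fit_tradeoff(lines: pd.DataFrame, variant: str = "raw") -> TradeoffFit:
    """Trade-off fit: line mean sqrt emergence on persistence fraction,
    population random intercepts."""
    use, n_drop = usable_lines(lines)
    if use["population_id"].nunique() < 2 and variant == "raw":
        warnings.warn("fewer than 2 populations; fitting without grouping structure")
    return _fit_grouped(
        use["mean_sqrt_emergence"],
        use["persistence_fraction"],
        use["population_id"],
        variant,
        n_drop,
    )


def deviation_decomposition(lines: pd.DataFrame) -> tuple[pd.DataFrame, TradeoffFit]:
    """Center both traits on population means; refit the trade-off.

    A positive deviation slope indicates that the persistence/emergence
    association holds within populations, independently of differences in
    population means.  Populations contributing a single usable line are
    excluded (their deviations are identically zero).
    """
    use, n_drop = usable_lines(lines)
    counts = use.groupby("population_id")["maternal_line_id"].count()
    singles = counts[counts < 2].index
    if len(singles):
        warnings.warn(
            f"excluding single-line populations from deviation fit: {list(singles)}"
        )
        use = use[~use["population_id"].isin(singles)].reset_index(drop=True)
    cent = use.copy()
    for col in ("mean_sqrt_emergence", "persistence_fraction"):
        cent["dev_" + col] = cent[col] - cent.groupby("population_id")[col].transform("mean")
    fit = _fit_grouped(
        cent["dev_mean_sqrt_emergence"],
        cent["dev_persistence_fraction"],
        cent["population_id"],
        "deviation",
        n_drop,
    )
    return cent, fit


def residualize_on_mass(lines: pd.DataFrame) -> TradeoffFit:
    """Two-stage fit: residualize mean sqrt emergence on mean seed mass
    (OLS across all usable lines), then refit the trade-off on residuals."""
    use, n_drop = usable_lines(lines)
    mass = use["mean_seed_mass"].to_numpy(dtype=float)
    if np.ptp(mass) == 0:
        raise ValueError("seed mass constant across lines; residualization undefined")
    y = use["mean_sqrt_emergence"].to_numpy(dtype=float)
    X1 = np.column_stack([np.ones_like(mass), mass])
    coef, *_ = np.linalg.lstsq(X1, y, rcond=None)
    resid = y - X1 @ coef
    return _fit_grouped(
        resid, use["persistence_fraction"], use["population_id"], "mass_residualized", n_drop
    )


def cooks_influence(
    lines: pd.DataFrame,
    response: str = "mean_sqrt_emergence",
    predictor: str = "persistence_fraction",
    threshold: float = DEFAULT_COOKS_THRESHOLD,
) -> pd.DataFrame:
    """Cook's distance per line from the fixed-effects representation.

    The line-level model is refit as OLS with population intercepts plus the
    persistence slope (the mixed model has no standard Cook's distance);
    lines with D above ``threshold`` are flagged for a with/without refit.
    """
    use, _ = usable_lines(lines)
    y = use[response].to_numpy(dtype=float)
    x = use[predictor].to_numpy(dtype=float)
    X = _fixed_design(x, use["population_id"])
    n, p = X.shape
    if n <= p or np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient design for Cook's distance")
    res = sm.OLS(y, X).fit()
    d = OLSInfluence(res).cooks_distance[0]
    out = use[["population_id", "maternal_line_id"]].copy()
    out["cooks_d"] = d
    out["influential"] = d > threshold
    return out


def _wald_block(res, design_info, term_name: str) -> tuple[float, int, float]:
    sl = design_info.term_name_slices[term_name]
    b = np.asarray(res.params)[sl]
    V = np.asarray(res.cov_params())[sl, sl]
    chi2 = float(b @ np.linalg.solve(V, b))
    df = len(b)
    return chi2, df, float(stats.chi2.sf(chi2, df))


_FULL = "C(population_id) * C(treatment) + mass_c"
_NOINT = "C(population_id) + C(treatment) + mass_c"
_TERMS = {
    # term -> (formula providing the Type II frame, reduced formula for LRT)
    "population": (_NOINT, "C(treatment) + mass_c"),
    "treatment": (_NOINT, "C(population_id) + mass_c"),
    "population:treatment": (_FULL, _NOINT),
    "seed_mass": (_FULL, "C(population_id) * C(treatment)"),
}
_TERM_NAMES = {
    "population": "C(population_id)",
    "treatment": "C(treatment)",
    "population:treatment": "C(population_id):C(treatment)",
    "seed_mass": "mass_c",
}


def _direction(res_params: np.ndarray, design_info, term: str) -> str:
    if term == "population":
        return "varies among populations"
    name = (
        "C(treatment)[T.low]" if term == "treatment" else "mass_c" if term == "seed_mass" else None
    )
    if name is None:
        return "population-specific"
    try:
        i = design_info.column_names.index(name)
    except ValueError:
        return "n/a"
    return "increase" if res_params[i] > 0 else "decrease"


def _fit_lmm_formula(data: pd.DataFrame, formula: str):
    ymat, X = patsy.dmatrices("sqrt_day ~ " + formula, data, return_type="dataframe")
    model = MixedLM(ymat.to_numpy()[:, 0], X.to_numpy(), groups=data["maternal_line_id"])
    last_err = None
    for method in ("lbfgs", "bfgs", "cg"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(reml=True, method=method)
            if np.all(np.isfinite(np.asarray(res.fe_params))):
                return res, X.design_info
        except np.linalg.LinAlgError as exc:
            last_err = exc
    raise RuntimeError(f"mixed-model fit failed for formula {formula!r}: {last_err}")


def _glmm_ll(data: pd.DataFrame, yname: str, formula: str):
    X = patsy.dmatrix(formula, data, return_type="dataframe")
    fit = fit_logistic_glmm(
        data[yname].to_numpy(dtype=float), X.to_numpy(), data["maternal_line_id"].to_numpy()
    )
    return fit, X.design_info


def screen_seed_outcomes(records: pd.DataFrame) -> pd.DataFrame:
    """Seed-level screens of population, treatment, interaction and mass.

    Gaussian mixed model (maternal-line random intercept) on sqrt emergence
    day for emerged seeds with Type II Wald chi-square tests; binomial-logit
    mixed models for persistence, emergence and mortality with Type II
    likelihood-ratio chi-squares (2 x the log-likelihood difference of
    nested fits).  Returns one ScreenResult row per response x term.
    """
    from .records import validate_records

    df = validate_records(records).copy()
    if df["population_id"].nunique() < 2 or df["treatment"].nunique() < 2:
        raise ValueError("screens require >= 2 populations and both treatments")
    df["mass_c"] = df["seed_mass_mg"] - df["seed_mass_mg"].mean()
    rows: list[ScreenResult] = []

    # --- Gaussian model on emerged seeds
    em = df[df["fate"] == "emerged"].copy()
    em["sqrt_day"] = np.sqrt(em["emergence_day"].astype(float))
    lmm_cache: dict[str, tuple] = {}
    for term, (frame_formula, _) in _TERMS.items():
        if frame_formula not in lmm_cache:
            lmm_cache[frame_formula] = _fit_lmm_formula(em, frame_formula)
        res, dinfo = lmm_cache[frame_formula]
        chi2, dfree, p = _wald_block(res, dinfo, _TERM_NAMES[term])
        rows.append(
            ScreenResult(
                response="emergence_time",
                model_family="gaussian",
                term=term,
                statistic=chi2,
                df=dfree,
                p_value=p,
                direction_note=_direction(np.asarray(res.params), dinfo, term),
            )
        )

    # --- binomial models on all planted seeds
    df["y_persistence"] = (df["fate"] == "persistent").astype(float)
    df["y_emergence"] = (df["fate"] == "emerged").astype(float)
    df["y_mortality"] = (df["fate"] == "dead").astype(float)
    for response in ("persistence", "emergence", "mortality"):
        yname = "y_" + response
        cache: dict[str, tuple] = {}

        def fit(formula):
            if formula not in cache:
                cache[formula] = _glmm_ll(df, yname, formula)
            return cache[formula]

        for term, (full_formula, reduced_formula) in _TERMS.items():
            full, dinfo = fit(full_formula)
            red, _ = fit(reduced_formula)
            lrt = max(0.0, 2.0 * (full.loglik - red.loglik))
            dfree = dinfo.term_name_slices[_TERM_NAMES[term]].stop - \
                dinfo.term_name_slices[_TERM_NAMES[term]].start
            unstable = full.separation or red.separation or not (
                full.converged and red.converged
            )
            rows.append(
                ScreenResult(
                    response=response,
                    model_family="binomial-logit",
                    term=term,
                    statistic=lrt,
                    df=dfree,
                    p_value=float(stats.chi2.sf(lrt, dfree)),
                    direction_note=_direction(full.beta, dinfo, term),
                    unstable=unstable,
                )
            )
    return pd.DataFrame([r.__dict__ for r in rows])
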