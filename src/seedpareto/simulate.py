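"""Synthetic seed-trial and climate generator with recorded ground truth.

The generator emulates the structure the analysis assumes: populations
arrayed along an aridity gradient, maternal lines within populations, and
seed-level binomial fates under two watering treatments.  A single latent
*dormancy liability* per line simultaneously delays emergence (on the
sqrt-day scale) and lowers the probability of germinating — the pleiotropy
that produces a within-population trade-off between emergence speed and
seed persistence.  Emergence days are squared Gaussians (floored at one
day), so the sqrt-scale analysis model is exactly the generative model.

Scenarios
---------
* ``null`` — liability affects nothing (b_time = b_persist = 0): no
  trade-off, no aridity structure; the type-I-error scenario.
* ``tradeoff_only`` — liability drives both traits but is unrelated to
  aridity.
* ``constrained_adaptation`` — additionally, (a) population mean liability
  increases with site aridity (``dormancy_aridity_slope`` per unit -AI),
  and (b) mesic populations carry an *adaptation lag*: a displacement into
  the Pareto-dominated region (later emergence and higher seed mortality),
  so arid populations sit on or near the front.  The lag is scaled by
  ``adaptation_lag_slope`` times the site's relative wetness; the liability
  cline alone moves populations *along* the trade-off curve and therefore
  carries no front-membership signal.

Monthly climate series are constructed so that ``aridity_summaries``
recovers each site's assigned aridity index essentially exactly: monthly
precipitation is a fixed winter-weighted profile scaled to AI x annual PET,
with the collection water-year's final months adjusted to hit the assigned
collection-year index.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from . import climate as climate_mod
from .inference import front_covariate_test
from .pareto import identify_front
from .records import apply_viability_filters, population_summaries, summarize_lines
from .tradeoff import fit_tradeoff

__all__ = [
    "ScenarioTruth",
    "TreatmentEffects",
    "TREATMENT_PRESETS",
    "CONSTRAINED_SLOPE_PRESETS",
    "scenario_preset",
    "generate_study",
    "implied_line_slope",
    "simulate_operating_characteristics",
]


@dataclass(frozen=True)
class TreatmentEffects:
    """Logit shifts applied to seeds in the low watering treatment."""

    emergence_logit_low: float
    mortality_logit_low: float


#: species-style sign presets: a Stipa-like response (low water -> less
#: emergence, hence more persistence) and a Bromus-like response (low water
#: -> more mortality, hence less persistence)
TREATMENT_PRESETS = {
    "stipa_like": TreatmentEffects(emergence_logit_low=-0.5, mortality_logit_low=-0.2),
    "bromus_like": TreatmentEffects(emergence_logit_low=-0.2, mortality_logit_low=0.5),
    "none": TreatmentEffects(emergence_logit_low=0.0, mortality_logit_low=0.0),
}

#: constraint-strength presets for the constrained_adaptation scenario
CONSTRAINED_SLOPE_PRESETS = {"none": 0.0, "medium": 0.3, "large": 1.0}


@dataclass(frozen=True)
class ScenarioTruth:
    """Generator parameters; the ground truth echoed with every dataset."""

    scenario: str = "tradeoff_only"
    n_pops: int = 8
    n_lines_per_pop: int = 20
    n_seeds_per_line_per_treatment: int = 11  # 22 seeds per line
    aridity_range: tuple = (0.35, 1.6)
    dormancy_aridity_slope: float = 0.0  # liability per unit -AI (constrained only)
    adaptation_lag_slope: float = 0.0  # lag units per unit relative wetness
    lag_time_per_unit: float = 0.6  # sqrt-day delay per lag unit
    lag_mortality_per_unit: float = 1.5  # mortality logit per lag unit
    b_time: float = 0.5  # sqrt-days per unit liability
    b_persist: float = 1.2  # emergence logit decrease per unit liability
    mass_effect_time: float = -0.05  # sqrt-days per mg (larger seeds earlier)
    mass_effect_emergeprob: float = 0.2  # emergence logit per mg
    treatment_preset: str = "bromus_like"
    sigma_pop: float = 0.25
    sigma_line: float = 0.8
    sigma_seed: float = 0.35
    base_sqrt_day: float = 3.2  # ~10 days to emergence at liability 0
    emergence_logit0: float = 1.0
    mortality_logit0: float = -1.0
    mass_log_mean: float = math.log(5.0)  # mg, log-normal
    mass_log_sd: float = 0.3
    species_id: str = "synthetic_sp"
    rng_seed: int = 0

    def treatment_effects(self) -> TreatmentEffects:
        return TREATMENT_PRESETS[self.treatment_preset]

    def replace(self, **kw) -> "ScenarioTruth":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def scenario_preset(name: str, rng_seed: int = 0, **overrides) -> ScenarioTruth:
    """Named scenarios: 'null', 'tradeoff_only',
    'constrained_{none,medium,large}' (or 'constrained_adaptation' = large)."""
    if name == "null":
        truth = ScenarioTruth(scenario="null", b_time=0.0, b_persist=0.0)
    elif name == "tradeoff_only":
        truth = ScenarioTruth(scenario="tradeoff_only")
    elif name.startswith("constrained"):
        level = name.split("_", 1)[1] if "_" in name else "large"
        if level == "adaptation":
            level = "large"
        slope = CONSTRAINED_SLOPE_PRESETS[level]
        truth = ScenarioTruth(
            scenario="constrained_adaptation",
            dormancy_aridity_slope=slope,
            adaptation_lag_slope=slope,
        )
    else:
        raise ValueError(f"unknown scenario preset {name!r}")
    return truth.replace(rng_seed=rng_seed, **overrides)


# ---------------------------------------------------------------------------
# site placement and climate construction

#: Mediterranean-style monthly precipitation weights (January first); most
#: rain falls November-March, summers nearly dry
_PRECIP_WEIGHTS = np.array(
    [0.18, 0.16, 0.13, 0.06, 0.02, 0.005, 0.002, 0.003, 0.01, 0.04, 0.12, 0.25]
)
_PRECIP_WEIGHTS = _PRECIP_WEIGHTS / _PRECIP_WEIGHTS.sum()

_HIST_WINDOW = (1985, 2014)
_COLLECTION_START = (2014, 5)


def site_table(truth: ScenarioTruth) -> pd.DataFrame:
    """Assigned aridity index and latitude per site (deterministic)."""
    lo, hi = truth.aridity_range
    ai = np.linspace(lo, hi, truth.n_pops)
    lat = np.linspace(34.0, 41.0, truth.n_pops)  # wetter sites further north
    ids = [f"P{i + 1:02d}" for i in range(truth.n_pops)]
    return pd.DataFrame({"site_id": ids, "assigned_ai": ai, "latitude": lat})


def _seasonal_temps(n_pops_idx: int) -> np.ndarray:
    months = np.arange(1, 13)
    # warm-summer coastal profile; slightly cooler at higher (wetter) sites
    return 15.0 + 8.0 * np.cos(2.0 * np.pi * (months - 7.5) / 12.0) - 0.3 * n_pops_idx


def generate_climate(
    truth: ScenarioTruth, deviation_ai: np.ndarray | None = None
) -> pd.DataFrame:
    """Monthly climate series (1985-2015) reproducing each site's AI.

    Precipitation in each calendar year is the winter-weighted profile
    scaled so that annual P = AI x that year's annual PET, making the
    historical index exact by construction.  The collection water-year's
    four final months (outside the historical window) are then adjusted so
    the collection index equals AI + deviation (deviation defaults to 0).
    """
    sites = site_table(truth)
    if deviation_ai is None:
        deviation_ai = np.zeros(len(sites))
    deviation_ai = np.asarray(deviation_ai, dtype=float)
    rows = []
    years = range(_HIST_WINDOW[0], 2016)
    coll_months = climate_mod._window_months(*_COLLECTION_START)
    for k, site in sites.iterrows():
        temps = _seasonal_temps(k)
        per_year = {}
        for year in years:
            pet = climate_mod.monthly_pet(temps, site["latitude"])
            prcp = site["assigned_ai"] * pet.sum() * _PRECIP_WEIGHTS
            per_year[year] = {"pet": pet, "prcp": prcp.copy()}
        # hit the collection-year index exactly by adjusting Jan-Apr 2015
        pet_window = sum(per_year[y]["pet"][m - 1] for (y, m) in coll_months)
        p_window = sum(per_year[y]["prcp"][m - 1] for (y, m) in coll_months)
        target = (site["assigned_ai"] + deviation_ai[k]) * pet_window
        delta = target - p_window
        adj_months = [(y, m) for (y, m) in coll_months if y == 2015]
        w = _PRECIP_WEIGHTS[[m - 1 for (_y, m) in adj_months]]
        w = w / w.sum()
        for (y, m), wi in zip(adj_months, w):
            new = per_year[y]["prcp"][m - 1] + wi * delta
            if new < 0:
                raise ValueError(
                    f"deviation {deviation_ai[k]} for site {site['site_id']} "
                    "requires negative precipitation"
                )
            per_year[y]["prcp"][m - 1] = new
        for year in years:
            for m in range(12):
                rows.append(
                    {
                        "site_id": site["site_id"],
                        "year": int(year),
                        "month": m + 1,
                        "tmean_c": float(temps[m]),
                        "prcp_mm": float(per_year[year]["prcp"][m]),
                        "latitude": float(site["latitude"]),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# seed-level core

def _simulate_seeds(truth: ScenarioTruth, d_line: np.ndarray, lag_line: np.ndarray, rng):
    """Vectorized seed fates for one batch of lines.

    Returns flat per-seed arrays (line index, treatment-is-low, mass, fate
    code 0=emerged/1=persistent/2=dead, emergence day) in line-major order.
    """
    n_lines = len(d_line)
    s_per_tr = truth.n_seeds_per_line_per_treatment
    n_seeds = 2 * s_per_tr
    line_ix = np.repeat(np.arange(n_lines), n_seeds)
    is_low = np.tile(np.r_[np.zeros(s_per_tr), np.ones(s_per_tr)], n_lines)
    d = d_line[line_ix]
    lag = lag_line[line_ix]
    tr = truth.treatment_effects()

    mass = rng.lognormal(truth.mass_log_mean, truth.mass_log_sd, size=len(d))
    mass_c = mass - math.exp(truth.mass_log_mean + 0.5 * truth.mass_log_sd**2)

    eta_em = (
        truth.emergence_logit0
        - truth.b_persist * d
        + truth.mass_effect_emergeprob * mass_c
        + tr.emergence_logit_low * is_low
    )
    p_em = expit(eta_em)
    eta_mort = (
        truth.mortality_logit0
        + truth.lag_mortality_per_unit * lag
        + tr.mortality_logit_low * is_low
    )
    p_mort = expit(eta_mort)
    for name, p in (("emergence", p_em), ("mortality", p_mort)):
        if not 0.001 < float(p.mean()) < 0.999:
            raise ValueError(
                f"degenerate {name} probabilities (mean {p.mean():.4f}); "
                "check scenario parameters"
            )

    emerged = rng.random(len(d)) < p_em
    dead = (~emerged) & (rng.random(len(d)) < p_mort)
    fate = np.where(emerged, 0, np.where(dead, 2, 1))
    s = (
        truth.base_sqrt_day
        + truth.b_time * d
        + truth.lag_time_per_unit * lag
        + truth.mass_effect_time * mass_c
        + rng.normal(0.0, truth.sigma_seed, size=len(d))
    )
    day = np.maximum(s**2, 1.0)
    day[fate != 0] = np.nan
    return line_ix, is_low.astype(bool), mass, fate, day


def _population_liability(truth: ScenarioTruth, ai: np.ndarray, rng) -> tuple:
    """Population mean liabilities and adaptation lags along the gradient."""
    lo, hi = truth.aridity_range
    mu = -truth.dormancy_aridity_slope * (ai - ai.mean()) + rng.normal(
        0.0, truth.sigma_pop, size=len(ai)
    )
    wetness = (ai - lo) / (hi - lo)
    lag = truth.adaptation_lag_slope * wetness
    return mu, lag


def generate_study(
    truth: ScenarioTruth, make_climate: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame | None, ScenarioTruth]:
    """Generate one full study: seed records, climate series, truth echo.

    With a fixed ``truth.rng_seed`` the output is reproducible
    byte-for-byte.  ``make_climate=False`` skips the (deterministic)
    climate series, returning None in its place.
    """
    rng = np.random.default_rng(truth.rng_seed)
    sites = site_table(truth)
    ai = sites["assigned_ai"].to_numpy()
    mu_pop, lag_pop = _population_liability(truth, ai, rng)
    n_l = truth.n_lines_per_pop
    d_line = rng.normal(np.repeat(mu_pop, n_l), truth.sigma_line)
    lag_line = np.repeat(lag_pop, n_l)
    line_ix, is_low, mass, fate, day = _simulate_seeds(truth, d_line, lag_line, rng)

    pop_of_line = np.repeat(np.arange(truth.n_pops), n_l)
    pop_ids = sites["site_id"].to_numpy()
    line_labels = np.array(
        [f"{pop_ids[pop_of_line[i]]}_L{(i % n_l) + 1:02d}" for i in range(len(d_line))]
    )
    fate_names = np.array(["emerged", "persistent", "dead"])
    records = pd.DataFrame(
        {
            "species_id": truth.species_id,
            "population_id": pop_ids[pop_of_line[line_ix]],
            "maternal_line_id": line_labels[line_ix],
            "treatment": np.where(is_low, "low", "high"),
            "seed_mass_mg": mass,
            "fate": fate_names[fate],
            "emergence_day": day,
            "late_retrieval_emerger": False,
        }
    )
    climate = generate_climate(truth) if make_climate else None
    return records, climate, truth


# ---------------------------------------------------------------------------
# recovery target

def implied_line_slope(
    truth: ScenarioTruth,
    n_lines: int = 1_000_000,
    seed: int | None = None,
    chunk: int = 50_000,
) -> float:
    """Within-population line-level trade-off slope implied by the liability.

    Simulates ``n_lines`` maternal lines at the study design's seed counts
    (grouped into pseudo-populations of the design's size), computes each
    line's realized mean sqrt emergence day and persistence fraction, and
    returns the within-population-centered least-squares slope of the
    former on the latter.  This is the estimand the trade-off fit targets,
    including the attenuation from finite per-line seed counts and the
    exclusion of lines with no emerged or no viable seeds.
    """
    rng = np.random.default_rng(truth.rng_seed if seed is None else seed)
    n_per_pop = truth.n_lines_per_pop
    sxx = sxy = 0.0
    done = 0
    s_per_line = 2 * truth.n_seeds_per_line_per_treatment
    while done < n_lines:
        m = min(chunk, n_lines - done)
        n_pops = max(1, m // n_per_pop)
        m = n_pops * n_per_pop
        mu = rng.normal(0.0, truth.sigma_pop, size=n_pops)
        d_line = rng.normal(np.repeat(mu, n_per_pop), truth.sigma_line)
        lag_line = np.zeros(m)
        line_ix, _low, _mass, fate, day = _simulate_seeds(truth, d_line, lag_line, rng)
        fate2 = fate.reshape(m, s_per_line)
        day2 = day.reshape(m, s_per_line)
        n_em = (fate2 == 0).sum(axis=1)
        n_pe = (fate2 == 1).sum(axis=1)
        with np.errstate(invalid="ignore"):
            mean_sqrt = np.nansum(np.sqrt(day2), axis=1) / np.where(n_em > 0, n_em, np.nan)
            pfrac = n_pe / np.where(n_em + n_pe > 0, n_em + n_pe, np.nan)
        ok = np.isfinite(mean_sqrt) & np.isfinite(pfrac)
        pop_ix = np.repeat(np.arange(n_pops), n_per_pop)
        cnt_ok = np.bincount(pop_ix[ok], minlength=n_pops).astype(float)
        sel = ok & (cnt_ok >= 2)[pop_ix]
        px = np.bincount(pop_ix[sel], weights=pfrac[sel], minlength=n_pops)
        py = np.bincount(pop_ix[sel], weights=mean_sqrt[sel], minlength=n_pops)
        cnt = np.bincount(pop_ix[sel], minlength=n_pops).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            xc = pfrac[sel] - (px / cnt)[pop_ix[sel]]
            yc = mean_sqrt[sel] - (py / cnt)[pop_ix[sel]]
        sxx += float(np.sum(xc * xc))
        sxy += float(np.sum(xc * yc))
        done += m
    if sxx == 0:
        raise ValueError("no variance in simulated persistence fractions")
    return sxy / sxx


# ---------------------------------------------------------------------------
# operating characteristics

def _one_replicate(truth: ScenarioTruth, child_seed: int, tests, B: int):
    from .tradeoff import usable_lines  # local to avoid cycle at import time

    t = truth.replace(rng_seed=int(child_seed))
    records, _clim, _ = generate_study(t, make_climate=False)
    lines = summarize_lines(records, pool_treatments=True)
    retained, _log = apply_viability_filters(lines)
    out = {}
    if "tradeoff" in tests:
        fit = fit_tradeoff(retained)
        out["tradeoff_p"] = fit.p_value
        out["tradeoff_slope"] = fit.slope
    if "front" in tests:
        sites = site_table(t).rename(columns={"assigned_ai": "historical_ai"})
        pops = population_summaries(retained, aridity=sites)
        front = identify_front(pops)
        try:
            res = front_covariate_test(
                pops, front, covariate="historical_ai", tail="lower", B=B,
                seed=int(child_seed),
            )
            out["front_p"] = res.p_value
        except ValueError:
            out["front_p"] = np.nan  # degenerate front
        out["front_size"] = len(front.front_ids)
    return out


def simulate_operating_characteristics(
    scenarios: dict,
    n_replicates: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
    tests: tuple = ("tradeoff", "front"),
    B: int = 10_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rejection rates of the trade-off and front-covariate tests.

    ``scenarios`` maps name -> ScenarioTruth.  Each replicate redraws the
    data with a child seed, runs the standard pipeline (summaries, filters,
    fits, front, permutation), and records p-values.  Returns (summary,
    per-replicate results); replicates where a test is undefined (e.g., a
    degenerate front) are excluded from that test's denominator and
    counted.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    reps = []
    ss = np.random.SeedSequence(seed)
    for name, truth in scenarios.items():
        children = ss.spawn(n_replicates)
        for r, child in enumerate(children):
            child_seed = int(child.generate_state(1)[0] % (2**31 - 1))
            try:
                row = _one_replicate(truth, child_seed, tests, B)
            except Exception as exc:  # pipeline failure: record and move on
                warnings.warn(f"replicate {r} of scenario {name!r} failed: {exc}")
                row = {}
                row["error"] = str(exc)
            row.update({"scenario": name, "replicate": r, "seed": child_seed})
            reps.append(row)
    per_rep = pd.DataFrame(reps)
    summaries = []
    for name in scenarios:
        d = per_rep[per_rep["scenario"] == name]
        row = {"scenario": name, "n_replicates": len(d)}
        for test in tests:
            col = f"{test}_p"
            if col not in d:
                continue
            p = d[col].dropna()
            rate = float((p <= alpha).mean()) if len(p) else float("nan")
            row[f"{test}_rejection_rate"] = rate
            row[f"{test}_n_valid"] = int(len(p))
            row[f"{test}_se"] = (
                float(np.sqrt(rate * (1 - rate) / len(p))) if len(p) else float("nan")
            )
        summaries.append(row)
    return pd.DataFrame(summaries), per_rep
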