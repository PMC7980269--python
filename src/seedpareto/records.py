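"""Seed-level records: fate classification, emergence-time handling,
maternal-line summaries, and viability filters.

Each planted seed ends in exactly one of three fates: it *emerged* (on a
recorded day), it *persisted* (retrieved from the soil and assayed viable, or
emerged only during the high-frequency watering of the retrieval period), or
it suffered *mortality* (retrieved non-viable).  Persistence is the proxy for
spreading emergence among years (bet-hedging); emergence day, analyzed on the
square-root scale, measures within-year emergence speed.

Line-level summaries feed every downstream analysis.  Two data-quality
filters precede them all: maternal lines in which fewer than 50% of planted
seeds were viable (emerged or persisted, across both watering treatments) are
dropped, and then populations with fewer than 10 retained lines are dropped
whole.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AnchorRule",
    "IDENTITY_ANCHOR",
    "BROMUS_STYLE_ANCHOR",
    "classify_seed_outcome",
    "anchor_emergence_time",
    "transform_emergence",
    "summarize_lines",
    "apply_viability_filters",
    "population_summaries",
    "validate_records",
]

RECORD_COLUMNS = [
    "species_id",
    "population_id",
    "maternal_line_id",
    "treatment",
    "seed_mass_mg",
    "fate",
    "emergence_day",
    "late_retrieval_emerger",
]

FATES = ("emerged", "persistent", "dead")
TREATMENTS = ("high", "low")


@dataclass(frozen=True)
class AnchorRule:
    """Species rule mapping calendar emergence day to analysis days.

    The identity rule keeps the calendar day.  A re-anchoring rule subtracts
    ``offset`` days (the start of the effective watering cue), except that
    seeds emerging before ``floor`` are assigned the fixed value
    ``assigned`` — they are taken to have initiated germination before the
    later cue began.
    """

    offset: int = 0
    floor: int | None = None
    assigned: int | None = None


IDENTITY_ANCHOR = AnchorRule()
#: re-anchor to a watering pulse starting day 10; early emergers (< day 14)
#: are assigned the earliest time observed in the initial cohort, 4 days
BROMUS_STYLE_ANCHOR = AnchorRule(offset=10, floor=14, assigned=4)


def classify_seed_outcome(
    emerged_day: int | None = None,
    retrieved_viable: bool | None = None,
    emerged_during_retrieval: bool = False,
) -> tuple[str, int | None, bool]:
    """Classify one seed's terminal observation.

    Returns ``(fate, emergence_day, late_retrieval_emerger)``.  Exactly one
    terminal observation must be supplied: an emergence day, a retrieval
    viability verdict, or emergence during the retrieval watering period
    (scored persistent, flagged).
    """
    n_obs = sum(
        [emerged_day is not None, retrieved_viable is not None, emerged_during_retrieval]
    )
    if n_obs != 1:
        raise ValueError(
            "exactly one terminal observation required "
            f"(got emerged_day={emerged_day!r}, retrieved_viable={retrieved_viable!r}, "
            f"emerged_during_retrieval={emerged_during_retrieval!r})"
        )
    if emerged_day is not None:
        if emerged_day < 0:
            raise ValueError(f"negative emergence day {emerged_day}")
        return "emerged", int(emerged_day), False
    if emerged_during_retrieval:
        return "persistent", None, True
    if retrieved_viable:
        return "persistent", None, False
    return "dead", None, False


def anchor_emergence_time(calendar_day: int, rule: AnchorRule = IDENTITY_ANCHOR) -> int:
    """Apply a species anchoring rule to a calendar emergence day."""
    if calendar_day < 0:
        raise ValueError(f"negative calendar day {calendar_day}")
    if rule.floor is not None and calendar_day < rule.floor:
        return int(rule.assigned)
    return int(calendar_day - rule.offset)


def transform_emergence(days):
    """Square-root transform of emergence time (improves residual normality)."""
    arr = np.asarray(days, dtype=float)
    if np.any(arr < 0):
        raise ValueError("negative emergence time")
    out = np.sqrt(arr)
    return float(out) if np.isscalar(days) or arr.ndim == 0 else out


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Validate the seed-record table schema and invariants."""
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"seed records missing required columns: {missing}")
    df = records.copy()
    bad_fate = set(df["fate"]) - set(FATES)
    if bad_fate:
        raise ValueError(f"unknown fate values: {sorted(bad_fate)}")
    bad_tr = set(df["treatment"]) - set(TREATMENTS)
    if bad_tr:
        raise ValueError(f"unknown treatment values: {sorted(bad_tr)}")
    if (df["seed_mass_mg"] <= 0).any():
        raise ValueError("non-positive seed mass")
    emerged = df["fate"] == "emerged"
    if df.loc[emerged, "emergence_day"].isna().any():
        raise ValueError("emerged seed without emergence_day")
    if df.loc[~emerged, "emergence_day"].notna().any():
        raise ValueError("emergence_day present on a non-emerged seed")
    late = df["late_retrieval_emerger"].fillna(False).astype(bool)
    if (late & (df["fate"] != "persistent")).any():
        raise ValueError("late_retrieval_emerger set on a non-persistent seed")
    return df


def summarize_lines(
    records: pd.DataFrame,
    pool_treatments: bool = True,
    persistence_denominator: str = "viable",
) -> pd.DataFrame:
    """Per-maternal-line trait summaries.

    Fractions follow the definitions: viable = emerged + persistent;
    persistence fraction = persistent / viable (seeds that stayed alive but
    did not emerge, among living seeds) with ``persistence_denominator=
    "viable"``, or persistent / planted with ``"planted"``.  The mean
    transformed emergence time averages sqrt(day) over the line's emerged
    seeds and is NaN where no seed emerged.  With ``pool_treatments`` both
    watering treatments are combined before summarizing (maximizes line
    sample sizes and keeps observations independent); otherwise one row per
    line x treatment is returned.
    """
    if persistence_denominator not in ("viable", "planted"):
        raise ValueError(f"unknown persistence denominator {persistence_denominator!r}")
    df = validate_records(records)
    keys = ["species_id", "population_id", "maternal_line_id"]
    if not pool_treatments:
        keys = keys + ["treatment"]
    df = df.assign(
        _em=(df["fate"] == "emerged").astype(int),
        _pe=(df["fate"] == "persistent").astype(int),
        _de=(df["fate"] == "dead").astype(int),
        _sqrt_day=np.where(
            df["fate"] == "emerged", np.sqrt(df["emergence_day"].astype(float)), np.nan
        ),
    )
    g = df.groupby(keys, sort=True)
    out = g.agg(
        n_planted=("fate", "size"),
        n_emerged=("_em", "sum"),
        n_persistent=("_pe", "sum"),
        n_dead=("_de", "sum"),
        mean_sqrt_emergence=("_sqrt_day", "mean"),
        mean_seed_mass=("seed_mass_mg", "mean"),
    ).reset_index()
    viable = out["n_emerged"] + out["n_persistent"]
    out["viable_fraction"] = viable / out["n_planted"]
    denom = viable if persistence_denominator == "viable" else out["n_planted"]
    out["persistence_fraction"] = np.where(
        denom > 0, out["n_persistent"] / denom.replace(0, np.nan), np.nan
    )
    return out


def apply_viability_filters(
    lines: pd.DataFrame,
    line_threshold: float = 0.5,
    min_lines: int = 10,
) -> tuple[pd.DataFrame, list[dict]]:
    """Drop low-viability lines, then under-sampled populations.

    A line is excluded iff its viable fraction is strictly below
    ``line_threshold`` ("fewer than 50% of planted seeds either emerged or
    persisted"); a population is then excluded whole iff it retains strictly
    fewer than ``min_lines`` lines.  Returns the retained lines and an
    exclusion log (one dict per exclusion with a reason).
    """
    if not 0.0 < line_threshold <= 1.0:
        raise ValueError("line_threshold must be in (0, 1]")
    if min_lines < 1:
        raise ValueError("min_lines must be >= 1")
    log: list[dict] = []
    low = lines["viable_fraction"] < line_threshold
    for _, row in lines[low].iterrows():
        log.append(
            {
                "level": "line",
                "population_id": row["population_id"],
                "maternal_line_id": row["maternal_line_id"],
                "reason": f"viable_fraction {row['viable_fraction']:.3f} < {line_threshold}",
            }
        )
    kept = lines[~low]
    counts = kept.groupby("population_id")["maternal_line_id"].nunique()
    small_pops = set(counts[counts < min_lines].index)
    # populations that vanished entirely at the line stage also fail min_lines
    all_pops = set(lines["population_id"].unique())
    small_pops |= all_pops - set(counts.index)
    for pop in sorted(small_pops):
        log.append(
            {
                "level": "population",
                "population_id": pop,
                "maternal_line_id": None,
                "reason": f"{int(counts.get(pop, 0))} retained lines < {min_lines}",
            }
        )
    retained = kept[~kept["population_id"].isin(small_pops)].reset_index(drop=True)
    return retained, log


def _sem(x: pd.Series) -> float:
    x = x.dropna()
    n = len(x)
    if n < 2:
        return float("nan")
    return float(x.std(ddof=1) / math.sqrt(n))


def population_summaries(
    lines: pd.DataFrame, aridity: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Population trait means and standard errors across retained lines.

    Standard errors use n = number of maternal lines contributing to the
    trait (lines without any emerged seed do not contribute an emergence
    time).  If an aridity table is given (``site_id`` matching
    ``population_id``) its indices are merged in.
    """
    g = lines.groupby(["species_id", "population_id"], sort=True)
    out = g.apply(
        lambda d: pd.Series(
            {
                "n_lines_retained": d["maternal_line_id"].nunique(),
                "mean_sqrt_emergence": d["mean_sqrt_emergence"].mean(),
                "se_sqrt_emergence": _sem(d["mean_sqrt_emergence"]),
                "n_lines_emergence": int(d["mean_sqrt_emergence"].notna().sum()),
                "persistence_fraction": d["persistence_fraction"].mean(),
                "se_persistence": _sem(d["persistence_fraction"]),
                "n_lines_persistence": int(d["persistence_fraction"].notna().sum()),
                "mean_seed_mass": d["mean_seed_mass"].mean(),
            }
        ),
        include_groups=False,
    ).reset_index()
    if aridity is not None:
        out = out.merge(
            aridity.rename(columns={"site_id": "population_id"}),
            on="population_id",
            how="left",
        )
    return out
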