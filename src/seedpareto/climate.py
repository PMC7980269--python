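"""Thornthwaite potential evapotranspiration and aridity indices.

Sites along a climatic gradient are characterized by the unitless aridity
index AI = P / PET, the ratio of annual precipitation to annual potential
evapotranspiration; values closer to zero are more arid.  Two summaries are
computed per site:

* **historical AI** — the ratio of the mean annual precipitation to the mean
  annual PET over a multi-year reference window (default 1985–2014);
* **collection AI** — P/PET over the 12-month water-year in which seeds were
  collected (default May 2014 – April 2015);

and their difference, the **deviation AI** (collection − historical);
negative values mean the collection year was drier than the historical
average.

PET follows the classical Thornthwaite temperature-based formulation: a
yearly heat index accumulated from the monthly means, a cubic exponent in
that index, and a per-month correction for daylength (mid-month solar
declination and sunset hour angle) and month length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AriditySummary",
    "heat_index",
    "thornthwaite_exponent",
    "day_length_hours",
    "day_correction",
    "monthly_pet",
    "annual_ai",
    "aridity_summaries",
    "validate_climate",
]

CLIMATE_COLUMNS = ["site_id", "year", "month", "tmean_c", "prcp_mm", "latitude"]

# day of year of the 15th of each month and month lengths; a fixed 365-day
# calendar is used throughout (leap days would otherwise leak a spurious
# ~0.1% year-to-year PET difference into the deviation index)
_MID_MONTH_DOY = np.array([15, 46, 74, 105, 135, 166, 196, 227, 258, 288, 319, 349])
_MONTH_DAYS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])


@dataclass(frozen=True)
class AriditySummary:
    """Per-site aridity summary (all indices unitless P/PET ratios)."""

    site_id: str
    historical_ai: float
    collection_ai: float
    deviation_ai: float
    latitude: float


def heat_index(tmean_c: np.ndarray) -> float:
    """Annual heat index I = sum over months with T > 0 of (T/5)^1.514."""
    t = np.asarray(tmean_c, dtype=float)
    pos = t[t > 0.0]
    return float(np.sum((pos / 5.0) ** 1.514))


def thornthwaite_exponent(i: float) -> float:
    """Cubic exponent a(I) of the Thornthwaite formula."""
    return 6.75e-7 * i**3 - 7.71e-5 * i**2 + 1.792e-2 * i + 0.49239


def day_length_hours(latitude: float, month: int) -> float:
    """Mid-month daylength in hours from solar declination and sunset hour angle."""
    if not 1 <= month <= 12:
        raise ValueError(f"month must be in 1..12, got {month}")
    doy = _MID_MONTH_DOY[month - 1]
    decl = 0.409 * np.sin(2.0 * np.pi * doy / 365.0 - 1.39)
    phi = np.deg2rad(latitude)
    # clamp for polar day / night
    cos_ws = np.clip(-np.tan(phi) * np.tan(decl), -1.0, 1.0)
    ws = np.arccos(cos_ws)
    return float(24.0 / np.pi * ws)


def day_correction(latitude: float, month: int) -> float:
    """Combined daylength (hours/12) and month-length (days/30) correction."""
    return day_length_hours(latitude, month) / 12.0 * _MONTH_DAYS[month - 1] / 30.0


def monthly_pet(
    tmean_c,
    latitude: float,
    high_temp_correction: bool = False,
):
    """Monthly Thornthwaite PET (mm/month) for one site-year.

    Parameters
    ----------
    tmean_c : array-like of 12 monthly mean temperatures (°C), January first.
    latitude : decimal degrees.
    high_temp_correction : if True, months above 26.5 °C use the quadratic
        high-temperature formula instead of the standard power law.

    Returns
    -------
    ndarray of 12 non-negative PET values.  The heat index is computed from
    this same year's 12 monthly means; months at or below 0 °C contribute
    nothing and receive PET = 0.
    """
    t = np.asarray(tmean_c, dtype=float)
    if t.shape != (12,):
        raise ValueError(f"expected 12 monthly temperatures, got shape {t.shape}")
    if np.any(~np.isfinite(t)):
        raise ValueError("non-finite temperature in monthly series")
    i = heat_index(t)
    pet = np.zeros(12)
    if i <= 0.0:
        return pet  # no month above freezing
    a = thornthwaite_exponent(i)
    corr = np.array([day_correction(latitude, m) for m in range(1, 13)])
    warm = t > 0.0
    pet[warm] = 16.0 * corr[warm] * (10.0 * t[warm] / i) ** a
    if high_temp_correction:
        hot = t > 26.5
        pet[hot] = corr[hot] * (-415.85 + 32.24 * t[hot] - 0.43 * t[hot] ** 2)
    return pet


def annual_ai(precip_total: float, pet_total: float) -> float:
    """Aridity index = total precipitation / total PET (both mm)."""
    if pet_total <= 0.0:
        raise ValueError(f"aridity index undefined for PET total {pet_total} <= 0")
    return float(precip_total) / float(pet_total)


def validate_climate(climate: pd.DataFrame) -> pd.DataFrame:
    """Validate the monthly climate table schema and invariants."""
    missing = [c for c in CLIMATE_COLUMNS if c not in climate.columns]
    if missing:
        raise ValueError(f"climate table missing required columns: {missing}")
    df = climate.copy()
    if ((df["month"] < 1) | (df["month"] > 12)).any():
        raise ValueError("month outside 1..12 in climate table")
    if (df["prcp_mm"] < 0).any():
        raise ValueError("negative precipitation in climate table")
    dup = df.duplicated(subset=["site_id", "year", "month"])
    if dup.any():
        rows = df.loc[dup, ["site_id", "year", "month"]].head(5).to_dict("records")
        raise ValueError(f"duplicate (site, year, month) rows in climate table: {rows}")
    return df


def _site_monthly_pet(site: pd.DataFrame, high_temp_correction: bool) -> pd.DataFrame:
    """Attach a pet_mm column to one site's complete-year months."""
    lat = float(site["latitude"].iloc[0])
    out = []
    for year, grp in site.groupby("year"):
        grp = grp.sort_values("month")
        if len(grp) != 12 or list(grp["month"]) != list(range(1, 13)):
            present = set(grp["month"])
            gaps = sorted(set(range(1, 13)) - present)
            raise ValueError(
                f"site {site['site_id'].iloc[0]!r} year {year}: "
                f"incomplete monthly series, missing months {gaps}"
            )
        pet = monthly_pet(grp["tmean_c"].to_numpy(), lat, high_temp_correction)
        grp = grp.assign(pet_mm=pet)
        out.append(grp)
    return pd.concat(out, ignore_index=True)


def _window_months(start_year: int, start_month: int, n_months: int = 12):
    """(year, month) pairs of a water-year starting at start_year/start_month."""
    y, m = start_year, start_month
    out = []
    for _ in range(n_months):
        out.append((y, m))
        m += 1
        if m > 12:
            m, y = 1, y + 1
    return out


def aridity_summaries(
    climate: pd.DataFrame,
    historical_window: tuple[int, int] = (1985, 2014),
    collection_start: tuple[int, int] = (2014, 5),
    high_temp_correction: bool = False,
) -> pd.DataFrame:
    """Historical, collection-year and deviation aridity indices per site.

    historical AI uses the ratio of window means: (mean annual P) / (mean
    annual PET) over calendar years ``historical_window`` (inclusive).  The
    collection AI covers the 12 months beginning at ``collection_start``
    (year, month), a May–April water-year by default.  deviation AI is
    collection − historical.

    Raises if any site-month needed by either window is absent.
    """
    df = validate_climate(climate)
    y0, y1 = historical_window
    if y1 < y0:
        raise ValueError("historical_window must be (first_year, last_year)")
    coll = _window_months(*collection_start)
    rows = []
    for site_id, site in df.groupby("site_id", sort=True):
        needed = {(y, m) for y in range(y0, y1 + 1) for m in range(1, 13)} | set(coll)
        have = set(zip(site["year"], site["month"]))
        gaps = sorted(needed - have)
        if gaps:
            raise ValueError(
                f"site {site_id!r}: climate series missing site-months {gaps[:12]}"
                + ("..." if len(gaps) > 12 else "")
            )
        keep_years = sorted({y for (y, _m) in needed})
        site = site[site["year"].isin(keep_years)]
        site = _site_monthly_pet(site, high_temp_correction)
        hist = site[(site["year"] >= y0) & (site["year"] <= y1)]
        n_years = y1 - y0 + 1
        historical = annual_ai(
            hist["prcp_mm"].sum() / n_years, hist["pet_mm"].sum() / n_years
        )
        key = pd.MultiIndex.from_frame(site[["year", "month"]])
        in_coll = key.isin(coll)
        collection = annual_ai(
            site.loc[in_coll, "prcp_mm"].sum(), site.loc[in_coll, "pet_mm"].sum()
        )
        rows.append(
            {
                "site_id": site_id,
                "historical_ai": historical,
                "collection_ai": collection,
                "deviation_ai": collection - historical,
                "latitude": float(site["latitude"].iloc[0]),
            }
        )
    return pd.DataFrame(rows)
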