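"""Diet exposure construction: meal-level food records are summed to
patient-day sugar totals, and each microbiome sample is paired with the
mean sugar intake of the two days before collection (a sample taken on
day 3 gets the mean of day 1 and day 2).

Food items carry 8-digit food codes resolved against a nutrient lookup
(sugar grams per 100 g of food), emulating the highest-resolution food
coding of the USDA FNDDS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import pandas as pd

logger = logging.getLogger(__name__)

MEAL_COLUMNS = ["patient_id", "day", "food_code", "grams"]


def _validate_meals(meals: pd.DataFrame) -> pd.DataFrame:
    if missing := set(MEAL_COLUMNS) - set(meals.columns):
        raise ValueError(f"meal log missing columns {sorted(missing)}")
    if (meals["grams"] < 0).any():
        raise ValueError("negative grams in meal log")
    bad = meals["food_code"].astype(str).str.len() != 8
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} meal rows have food codes that are not 8 digits"
        )
    return meals


def daily_sugar_totals(
    meals: pd.DataFrame, nutrients: pd.DataFrame
) -> pd.DataFrame:
    """Per (patient, day) total sugar intake in grams.

    ``nutrients`` maps ``food_code`` to ``sugar_g_per_100g``.  Meals
    whose code is absent from the table are skipped (logged with a
    count).  Days with no resolvable meals are absent from the output.
    """
    meals = _validate_meals(meals)
    if missing := {"food_code", "sugar_g_per_100g"} - set(nutrients.columns):
        raise ValueError(f"nutrient table missing columns {sorted(missing)}")
    if (nutrients["sugar_g_per_100g"] < 0).any():
        raise ValueError("negative sugar density in nutrient table")
    m = meals.copy()
    m["food_code"] = m["food_code"].astype(str)
    nut = nutrients.copy()
    nut["food_code"] = nut["food_code"].astype(str)
    merged = m.merge(nut[["food_code", "sugar_g_per_100g"]], on="food_code", how="left")
    unresolved = merged["sugar_g_per_100g"].isna()
    if unresolved.any():
        logger.warning(
            "skipping %d meal rows with unresolvable food codes", int(unresolved.sum())
        )
        merged = merged[~unresolved]
    merged["sugar_g"] = merged["grams"] * merged["sugar_g_per_100g"] / 100.0
    out = (
        merged.groupby(["patient_id", "day"], sort=True)["sugar_g"]
        .sum()
        .reset_index()
    )
    return out


@dataclass(frozen=True)
class SampleExposure:
    patient_id: str
    sample_day: int
    sugar_exposure: Optional[float]  # grams/day; None when no prior-day data
    n_days_available: int


def lagged_exposure(
    day_totals: pd.DataFrame,
    patient_id: str,
    sample_day: int,
    lag_days: int = 2,
    require_all_days: bool = False,
) -> SampleExposure:
    """Sugar exposure for one microbiome sample: mean of the day totals
    over the ``lag_days`` days before ``sample_day``.

    Missing prior days are dropped from the mean (a day without records
    is non-recording, not fasting); ``require_all_days`` switches to a
    strict mode where any missing prior day makes the exposure
    undefined.  Exposure is None when no prior day has records, and
    such samples are excluded downstream.
    """
    sub = day_totals[day_totals["patient_id"] == patient_id]
    wanted = [sample_day - k for k in range(lag_days, 0, -1)]
    avail = sub[sub["day"].isin(wanted)]
    n = len(avail)
    if n == 0 or (require_all_days and n < lag_days):
        return SampleExposure(patient_id, sample_day, None, n)
    return SampleExposure(
        patient_id, sample_day, float(avail["sugar_g"].mean()), n
    )


def exposures_for_samples(
    day_totals: pd.DataFrame,
    samples: pd.DataFrame,
    lag_days: int = 2,
    require_all_days: bool = False,
) -> pd.DataFrame:
    """Vectorized :func:`lagged_exposure` over a sample table with
    columns ``patient_id`` and ``sample_day`` (and optionally
    ``sample_id``)."""
    rows = []
    for _, r in samples.iterrows():
        e = lagged_exposure(
            day_totals,
            r["patient_id"],
            int(r["sample_day"]),
            lag_days=lag_days,
            require_all_days=require_all_days,
        )
        rows.append(
            {
                "sample_id": r.get("sample_id", f"{e.patient_id}_d{e.sample_day}"),
                "patient_id": e.patient_id,
                "sample_day": e.sample_day,
                "sugar_exposure": e.sugar_exposure,
                "n_days_available": e.n_days_available,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "patient_id",
            "sample_day",
            "sugar_exposure",
            "n_days_available",
        ],
    )
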