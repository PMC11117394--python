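"""Hour-indexed lambda-cyhalothrin dose schedules from daily exposure estimates.

A 24-h dietary recall reports *when* meals were eaten but exposure models
report only a *total daily* dose, so the daily dose is split equally across
the reported meal hours.  Urine is collected the following day; no foods are
recorded for that day, so collection-day meals are assumed to repeat the
recall-day mealtimes and per-meal doses, minus any meals excluded by the
reported pre-collection fasting window.  A stochastic food-washing behavior
(washer / non-washer, Beta-distributed residue reduction) scales the dose,
and the mean of the two recall days' doses provides the constant intake rate
used to initialize serum 3PBA at steady state.

Hour indexing: hour 0 is midnight starting recall day 1; the schedule runs
through hour T = 24 + collection_hour (the collection hour on day 2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .config import BehaviorParams, ConfigError

__all__ = [
    "BehaviorDraw",
    "DoseSchedule",
    "split_daily_dose",
    "build_collection_day_meals",
    "sample_behavior",
    "sample_behavior_arrays",
    "apply_washing",
    "steady_state_initial_rate",
    "build_schedule",
    "build_schedule_matrix",
]


@dataclass(frozen=True)
class BehaviorDraw:
    """One participant-iterate's food-washing behavior."""

    is_washer: bool
    washing_factor: float  # fraction of residue removed, in [0, 1]

    def __post_init__(self) -> None:
        if not 0.0 <= self.washing_factor <= 1.0:
            raise ValueError(
                f"washing_factor must lie in [0, 1], got {self.washing_factor}"
            )


@dataclass(frozen=True)
class DoseSchedule:
    """Hour-indexed ingestion schedule for one participant-iterate.

    ``doses[t]`` is the mass (mg) ingested during hour ``[t, t+1)``; the array
    covers t = 0 … T with T = 24 + collection_hour.  ``initial_mean_hourly_rate``
    is the constant intake rate (mg/h) used for the steady-state initial serum
    concentration.
    """

    participant_id: object
    iterate: int
    doses: np.ndarray
    day1_daily_dose_mg: float  # washing-adjusted
    initial_mean_hourly_rate: float
    collection_index: int  # = 24 + collection_hour

    def __post_init__(self) -> None:
        doses = np.asarray(self.doses, dtype=float)
        if np.any(doses < 0):
            raise ValueError("doses must be non-negative")
        object.__setattr__(self, "doses", doses)


def split_daily_dose(
    daily_dose_mg: float, meal_hours: Iterable[int]
) -> dict[int, float]:
    """Divide a daily dose equally among the reported meal hours.

    Returns a map hour → mg covering all 24 hours, zero away from meals.
    """
    hours = sorted(set(int(h) for h in meal_hours))
    if not hours:
        raise ValueError("meal_hours must be non-empty: participant must report >= 1 meal")
    if any(h < 0 or h > 23 for h in hours):
        raise ValueError(f"meal hours must lie in 0..23, got {hours}")
    if daily_dose_mg < 0:
        raise ValueError("daily_dose_mg must be non-negative")
    per_meal = daily_dose_mg / len(hours)
    out = {h: 0.0 for h in range(24)}
    for h in hours:
        out[h] = per_meal
    return out

def build_collection_day_meals(
    meal_hours_day1: Iterable[int], collection_hour: int, fasting_hours: float
) -> set[int]:
    """Meal hours retained on the urine-collection day.

    A meal at hour h is kept iff h < collection_hour − fasting_hours: any meal
    inside the reported fasting window, or at/after collection, is excluded.
    An empty result (a full fast) is valid.
    """
    if fasting_hours < 0:
        raise ValueError("fasting_hours must be non-negative")
    cutoff = collection_hour - fasting_hours
    return {int(h) for h in meal_hours_day1 if h < cutoff}


def sample_behavior(
    rng: np.random.Generator,
    washer_prob: float = 0.5,
    washing_alpha: float = 3.0,
    washing_beta: float = 7.0,
) -> BehaviorDraw:
    """Draw one washing-behavior realization.

    is_washer ~ Bernoulli(washer_prob); washing_factor ~ Beta(alpha, beta)
    (mean 0.30 under the defaults).  The factor is drawn regardless of washer
    status but only applied to washers.
    """
    BehaviorParams(washer_prob, washing_alpha, washing_beta).validate()
    is_washer = bool(rng.random() < washer_prob)
    factor = float(rng.beta(washing_alpha, washing_beta))
    return BehaviorDraw(is_washer=is_washer, washing_factor=factor)


def sample_behavior_arrays(
    rng: np.random.Generator, n: int, params: BehaviorParams
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized behavior draws: (is_washer bool[n], washing_factor float[n])."""
    params.validate()
    is_washer = rng.random(n) < params.washer_prob
    factor = rng.beta(params.washing_alpha, params.washing_beta, size=n)
    return is_washer, factor


def apply_washing(daily_dose_mg, behavior: BehaviorDraw):
    """Washing-adjusted dose: washers lose a ``washing_factor`` fraction."""
    dose = np.asarray(daily_dose_mg, dtype=float)
    if np.any(dose < 0):
        raise ValueError("daily_dose_mg must be non-negative")
    if behavior.is_washer:
        adjusted = dose * (1.0 - behavior.washing_factor)
    else:
        adjusted = dose
    return float(adjusted) if np.ndim(daily_dose_mg) == 0 else adjusted


def steady_state_initial_rate(
    day1_dose_mgkg: float,
    day2_dose_mgkg: float,
    body_weight_kg: float,
    behavior: BehaviorDraw,
) -> float:
    """Mean hourly intake rate (mg/h) from the two recall days' doses.

    Both daily doses are washing-adjusted under the same behavior draw,
    averaged, converted to absolute mass, and spread over 24 h.  Feeds the
    steady-state serum initial condition.
    """
    if day1_dose_mgkg < 0 or day2_dose_mgkg < 0:
        raise ValueError("daily doses must be non-negative")
    if body_weight_kg <= 0:
        raise ValueError("body_weight_kg must be positive")
    adj1 = apply_washing(day1_dose_mgkg * body_weight_kg, behavior)
    adj2 = apply_washing(day2_dose_mgkg * body_weight_kg, behavior)
    return (adj1 + adj2) / 2.0 / 24.0


def build_schedule(
    individual: Mapping[str, object],
    day1_dose_mgkg: float,
    day2_dose_mgkg: float,
    behavior: BehaviorDraw,
    iterate: int = 0,
) -> DoseSchedule:
    """Compose the full hour-indexed schedule for one participant-iterate.

    ``individual`` must provide participant_id, body_weight, meal_hours_day1,
    collection_hour and fasting_hours.  Day-1 meal hours receive the equally
    split, washing-adjusted day-1 dose; collection-day meals not excluded by
    the fast repeat the day-1 per-meal dose at hour 24 + h.
    """
    weight = float(individual["body_weight"])
    if weight <= 0:
        raise ValueError("body_weight must be positive")
    meal_hours = sorted(set(int(h) for h in individual["meal_hours_day1"]))
    collection_hour = int(individual["collection_hour"])
    if not 0 <= collection_hour <= 23:
        raise ValueError(f"collection_hour must lie in 0..23, got {collection_hour}")
    fasting_hours = float(individual["fasting_hours"])

    adj_day1_mg = apply_washing(day1_dose_mgkg * weight, behavior)
    per_hour = split_daily_dose(adj_day1_mg, meal_hours)
    retained = build_collection_day_meals(meal_hours, collection_hour, fasting_hours)

    T = 24 + collection_hour
    doses = np.zeros(T + 1)
    for h, d in per_hour.items():
        doses[h] = d
    per_meal = adj_day1_mg / len(meal_hours)
    for h in retained:
        doses[24 + h] = per_meal

    rate = steady_state_initial_rate(day1_dose_mgkg, day2_dose_mgkg, weight, behavior)
    return DoseSchedule(
        participant_id=individual["participant_id"],
        iterate=iterate,
        doses=doses,
        day1_daily_dose_mg=float(adj_day1_mg),
        initial_mean_hourly_rate=rate,
        collection_index=T,
    )


def build_schedule_matrix(
    meal_matrix: np.ndarray,
    collection_hour: np.ndarray,
    fasting_hours: np.ndarray,
    body_weight: np.ndarray,
    p_idx: np.ndarray,
    day1_dose_mgkg: np.ndarray,
    day2_dose_mgkg: np.ndarray,
    is_washer: np.ndarray,
    washing_factor: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized schedule builder for many participant-iterates at once.

    Parameters
    ----------
    meal_matrix : bool (n_participants, 24)
        Day-1 meal indicator per hour of day.
    collection_hour, fasting_hours, body_weight : (n_participants,)
    p_idx : int (n_rows,)
        Participant index of each participant-iterate row.
    day1_dose_mgkg, day2_dose_mgkg, is_washer, washing_factor : (n_rows,)

    Returns
    -------
    doses : (n_rows, 48) mg per hour (hours 0–47; entries beyond each row's
        collection index are zero by construction),
    collection_index : int (n_rows,) = 24 + collection_hour,
    initial_rate : (n_rows,) mg/h for the steady-state initial condition.

    Semantics are identical to :func:`build_schedule` row by row.
    """
    meal_matrix = np.asarray(meal_matrix, dtype=bool)
    n_meals = meal_matrix.sum(axis=1)
    if np.any(n_meals == 0):
        raise ValueError("every participant must report >= 1 meal hour")
    if np.any(day1_dose_mgkg < 0) or np.any(day2_dose_mgkg < 0):
        raise ValueError("daily doses must be non-negative")

    wash_mult = np.where(is_washer, 1.0 - washing_factor, 1.0)
    adj1_mg = day1_dose_mgkg * body_weight[p_idx] * wash_mult
    adj2_mg = day2_dose_mgkg * body_weight[p_idx] * wash_mult
    per_meal = adj1_mg / n_meals[p_idx]

    hours = np.arange(24)
    cutoff = collection_hour - fasting_hours  # (n_participants,)
    retained = meal_matrix & (hours[None, :] < cutoff[:, None])

    doses = np.zeros((len(p_idx), 48))
    doses[:, :24] = meal_matrix[p_idx] * per_meal[:, None]
    doses[:, 24:] = retained[p_idx] * per_meal[:, None]

    collection_index = 24 + np.asarray(collection_hour, dtype=int)[p_idx]
    initial_rate = (adj1_mg + adj2_mg) / 2.0 / 24.0
    return doses, collection_index, initial_rate
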