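"""Synthetic populations, exposure iterates and biomarker measurements.

Real inputs to this analysis are a national examination survey (demographics,
24-h dietary recall, urinary 3PBA with urinary creatinine, complex survey
design) and per-iterate Monte Carlo daily dietary exposure estimates from a
regulatory exposure model.  This module generates tables with the same
statistical structure — episodic log-normal daily doses, clustered mealtimes,
LOD-censored biomarkers, a two-cycle stratified design — so the whole pipeline
is testable end to end, including parameter-recovery experiments where the
generating "truth" is known.

All generators are deterministic under a fixed seed/Generator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import doseplan, pk
from .config import BehaviorParams, ConfigError, CreatinineFormula, PKPriors, SyntheticConfig

__all__ = [
    "generate_population",
    "generate_exposure_iterates",
    "simulate_measurements",
    "generate_dosing_study_fixture",
    "meal_matrix_from_diet",
    "PARTICIPANT_COLUMNS",
    "DIET_COLUMNS",
    "EXPOSURE_COLUMNS",
    "BIOMARKER_COLUMNS",
    "DESIGN_COLUMNS",
]

# Fixed CSV schemas consumed downstream.
PARTICIPANT_COLUMNS = [
    "participant_id", "age", "sex", "body_weight", "height",
    "collection_hour", "fasting_hours",
]
DIET_COLUMNS = ["participant_id", "meal_hour"]
EXPOSURE_COLUMNS = ["participant_id", "iterate", "day1_dose", "day2_dose"]
BIOMARKER_COLUMNS = ["participant_id", "urinary_3pba", "creatinine", "below_lod"]
DESIGN_COLUMNS = ["participant_id", "survey_weight", "stratum", "psu", "cycle"]

# Age-group sampling fractions mirroring the relative sizes of the 6-11,
# 12-19, 20-59 and 60+ strata in the biomarker-eligible survey population.
_AGE_GROUPS = [(6, 11), (12, 19), (20, 59), (60, 80)]
_AGE_PROBS = [0.137, 0.147, 0.469, 0.247]

_BREAKFAST = [6, 7, 8, 9]
_LUNCH = [11, 12, 13]
_DINNER = [17, 18, 19, 20]
_SNACKS = [10, 14, 15, 16, 21, 22]


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _draw_meal_hours(rng: np.random.Generator, n_meals: int) -> list[int]:
    """Clustered mealtimes: main meals first, then distinct snack hours."""
    mains = [
        int(rng.choice(_BREAKFAST)), int(rng.choice(_LUNCH)), int(rng.choice(_DINNER)),
    ]
    if n_meals <= 3:
        # keep later meals preferentially (dinner is rarely skipped)
        hours = mains[3 - n_meals:]
    else:
        snacks = rng.choice(_SNACKS, size=n_meals - 3, replace=False)
        hours = mains + [int(s) for s in snacks]
    return sorted(set(hours))


def generate_population(
    cfg: SyntheticConfig, rng: np.random.Generator | int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate participants, diet events and survey-design tables.

    Returns ``(participants, diet, design)`` data frames following the fixed
    CSV schemas.  Ages span children through 60+, meal counts run 1–5, urine
    collection happens during examination hours on day 2, and participants
    are split across two pseudo-cycles with equal-scale examination weights.
    """
    cfg.validate()
    rng = _rng(cfg.seed if rng is None else rng)
    n = cfg.n_participants

    group = rng.choice(len(_AGE_GROUPS), size=n, p=np.asarray(_AGE_PROBS) / sum(_AGE_PROBS))
    lo = np.asarray([g[0] for g in _AGE_GROUPS])[group]
    hi = np.asarray([g[1] for g in _AGE_GROUPS])[group]
    age = lo + rng.random(n) * (hi - lo)
    sex = np.where(rng.random(n) < 0.483, "male", "female")

    # Height from a simple growth curve (linear to 17 y, then plateau), weight
    # from a log-normal BMI; crude but spans realistic child/adult anthropometry.
    adult_height = np.where(sex == "male", 176.0, 162.0) + rng.normal(0.0, 7.0, n)
    frac = np.clip((age - 2.0) / 15.0, 0.0, 1.0)
    height = np.clip(85.0 + frac * (adult_height - 85.0), 80.0, 210.0)
    bmi = np.exp(rng.normal(np.log(np.where(age <= 17, 18.5, 26.5)), 0.18, n))
    weight = np.clip(bmi * (height / 100.0) ** 2, 15.0, 200.0)

    n_meals = rng.choice([1, 2, 3, 4, 5], size=n, p=[0.05, 0.20, 0.45, 0.20, 0.10])
    collection_hour = rng.integers(7, 20, size=n)  # examination hours on day 2
    # Mixture of short (non-fasting) and overnight fasts before collection.
    fasting = np.where(
        rng.random(n) < 0.5, rng.uniform(0.0, 6.0, n), rng.uniform(8.0, 16.0, n)
    )

    pid = np.array([f"P{i:06d}" for i in range(n)])
    participants = pd.DataFrame(
        {
            "participant_id": pid,
            "age": np.round(age, 1),
            "sex": sex,
            "body_weight": np.round(weight, 1),
            "height": np.round(height, 1),
            "collection_hour": collection_hour,
            "fasting_hours": np.round(fasting, 2),
        }
    )

    diet_rows = []
    for i in range(n):
        for h in _draw_meal_hours(rng, int(n_meals[i])):
            diet_rows.append((pid[i], h))
    diet = pd.DataFrame(diet_rows, columns=DIET_COLUMNS)

    cycle = np.where(np.arange(n) % 2 == 0, 1, 2)
    design = pd.DataFrame(
        {
            "participant_id": pid,
            "survey_weight": np.exp(rng.normal(np.log(50000.0), 0.5, n)),
            "stratum": rng.integers(1, 16, size=n),
            "psu": rng.integers(1, 3, size=n),
            "cycle": cycle,
        }
    )
    return participants, diet, design


def generate_exposure_iterates(
    participants: pd.DataFrame,
    cfg: SyntheticConfig,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Per-iterate daily doses (mg/kg/day), emulating acute Monte Carlo output.

    Day-1 and day-2 doses are drawn independently from the configured
    log-normal — dietary pesticide exposure is episodic, so consecutive recall
    days are treated as independent realizations.
    """
    cfg.validate()
    if len(participants) == 0:
        raise ValueError("participants must be non-empty")
    rng = _rng(cfg.seed if rng is None else rng)
    n = len(participants) * cfg.n_iterates
    pid = np.repeat(participants["participant_id"].to_numpy(), cfg.n_iterates)
    iterate = np.tile(np.arange(cfg.n_iterates), len(participants))
    draws = np.exp(
        rng.normal(cfg.daily_dose_logmean, cfg.daily_dose_logsd, size=(n, 2))
    )
    return pd.DataFrame(
        {
            "participant_id": pid,
            "iterate": iterate,
            "day1_dose": draws[:, 0],
            "day2_dose": draws[:, 1],
        }
    )


def meal_matrix_from_diet(
    participants: pd.DataFrame, diet: pd.DataFrame
) -> np.ndarray:
    """Boolean (n_participants, 24) day-1 meal-hour indicator, participant order."""
    index = {p: i for i, p in enumerate(participants["participant_id"])}
    mat = np.zeros((len(participants), 24), dtype=bool)
    for p, h in zip(diet["participant_id"], diet["meal_hour"]):
        mat[index[p], int(h)] = True
    if not mat.any(axis=1).all():
        missing = participants["participant_id"][~mat.any(axis=1)].iloc[0]
        raise ValueError(f"participant {missing} has no reported meal hours")
    return mat


def simulate_measurements(
    participants: pd.DataFrame,
    diet: pd.DataFrame,
    exposures: pd.DataFrame,
    cfg: SyntheticConfig,
    priors: PKPriors | None = None,
    behavior: BehaviorParams | None = None,
    creatinine_formula: CreatinineFormula | None = None,
    true_iterate: int = 0,
    rng: np.random.Generator | int | None = None,
    true_params: "pk.PKParameters | None" = None,
    true_behavior: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Forward-simulate urinary 3PBA measurements from a designated true iterate.

    For each participant the exposure row with ``iterate == true_iterate``
    is pushed through the dose-schedule and pharmacokinetic forward model
    under freshly drawn "true" parameters and washing behavior; the resulting
    creatinine-standardized concentration is converted to μg/L with a
    log-normal urinary creatinine draw, perturbed by 10^ε multiplicative
    noise (ε ~ Normal(0, measurement_noise_logsd), log10 scale), and censored
    at the detection limit with the LOD/√2 substitution.

    Returns ``(biomarkers, truth)``; ``truth`` carries the generating
    parameters, behavior, doses and the noise-free standardized prediction —
    the ground truth for parameter-recovery tests.

    ``true_params`` / ``true_behavior`` override the internally drawn truth
    (one entry per participant, participant order), closing the loop exactly
    with an external prediction stage for self-consistency experiments.
    """
    cfg.validate()
    priors = priors or PKPriors()
    behavior = behavior or BehaviorParams()
    rng = _rng(cfg.seed if rng is None else rng)

    true_rows = exposures[exposures["iterate"] == true_iterate]
    merged = participants.merge(true_rows, on="participant_id", how="left")
    if merged["day1_dose"].isna().any():
        missing = merged.loc[merged["day1_dose"].isna(), "participant_id"].iloc[0]
        raise ValueError(
            f"participant {missing} has no exposure row for true iterate {true_iterate}"
        )
    n = len(merged)

    params = (
        true_params
        if true_params is not None
        else pk.sample_pk_parameters(rng, priors, size=n)
    )
    n_creat = pk.creatinine_excretion_rate(
        merged["age"].to_numpy(), merged["sex"].to_numpy(),
        merged["body_weight"].to_numpy(), merged["height"].to_numpy(),
        creatinine_formula,
    )
    params = params.with_creatinine(n_creat)
    if true_behavior is not None:
        is_washer, factor = true_behavior
    else:
        is_washer, factor = doseplan.sample_behavior_arrays(rng, n, behavior)

    meals = meal_matrix_from_diet(participants, diet)
    doses, coll_idx, init_rate = doseplan.build_schedule_matrix(
        meals,
        merged["collection_hour"].to_numpy(),
        merged["fasting_hours"].to_numpy(dtype=float),
        merged["body_weight"].to_numpy(dtype=float),
        np.arange(n),
        merged["day1_dose"].to_numpy(dtype=float),
        merged["day2_dose"].to_numpy(dtype=float),
        is_washer,
        factor,
    )
    c0 = pk.steady_state_concentration(params, init_rate)
    serum = pk.serum_series(doses[:, :-1], params.k, params.f, params.v, c0)
    urine = pk.urine_entering_bladder(params, serum)
    true_ugug = pk.bladder_average(urine, coll_idx, params.void_interval)

    creat = np.exp(
        rng.normal(cfg.creatinine_conc_logmean, cfg.creatinine_conc_logsd, n)
    )
    eps = rng.normal(0.0, cfg.measurement_noise_logsd, n)
    urinary_ugl = true_ugug * creat * 1e4 * np.power(10.0, eps)
    below = urinary_ugl < cfg.lod
    urinary_ugl = np.where(below, cfg.lod / np.sqrt(2.0), urinary_ugl)

    biomarkers = pd.DataFrame(
        {
            "participant_id": merged["participant_id"],
            "urinary_3pba": urinary_ugl,
            "creatinine": creat,
            "below_lod": below,
        }
    )
    truth = pd.DataFrame(
        {
            "participant_id": merged["participant_id"],
            "iterate": true_iterate,
            "day1_dose": merged["day1_dose"],
            "day2_dose": merged["day2_dose"],
            "k": params.k,
            "f": params.f,
            "v": params.v,
            "r": params.r,
            "void_interval": params.void_interval,
            "n_creatinine": n_creat,
            "is_washer": is_washer,
            "washing_factor": factor,
            "true_ugug": true_ugug,
            "noise_log10": eps,
        }
    )
    return biomarkers, truth


def generate_dosing_study_fixture(
    n_subjects: int = 6,
    dose_mg_per_kg: float = 0.0005,
    sampling_hours=None,
    seed: int | np.random.Generator = 0,
    priors: PKPriors | None = None,
    creatinine_formula: CreatinineFormula | None = None,
) -> pd.DataFrame:
    """Controlled oral-dosing study: one bolus at t=0, urine followed ≤ 120 h.

    Emulates a small pharmacokinetic validation study — a handful of adult
    volunteers each receive a single oral lambda-cyhalothrin bolus and their
    creatinine-standardized urinary 3PBA is simulated at the requested
    sampling hours under subject-specific parameters drawn from the priors.

    Returns a long table (subject, hour, serum_mg_l, urine_ugug).
    """
    if n_subjects < 1:
        raise ConfigError("n_subjects: must be >= 1")
    if dose_mg_per_kg < 0:
        raise ValueError("dose_mg_per_kg must be non-negative")
    hours = np.asarray(
        sorted(sampling_hours) if sampling_hours is not None else np.arange(0, 121)
    )
    if hours.size == 0:
        raise ValueError("sampling_hours must be non-empty")
    if hours.min() < 0 or hours.max() > 120:
        raise ValueError("sampling beyond 120 h postdosing is not supported")
    rng = _rng(seed)
    priors = priors or PKPriors()

    params = pk.sample_pk_parameters(rng, priors, size=n_subjects)
    weight = rng.normal(75.0, 10.0, n_subjects).clip(50.0, 110.0)
    height = rng.normal(172.0, 8.0, n_subjects).clip(150.0, 200.0)
    age = rng.uniform(20.0, 50.0, n_subjects)
    sex = np.where(rng.random(n_subjects) < 0.5, "male", "female")
    n_creat = pk.creatinine_excretion_rate(age, sex, weight, height, creatinine_formula)
    params = params.with_creatinine(n_creat)

    doses = np.zeros((n_subjects, 120))
    doses[:, 0] = dose_mg_per_kg * weight  # single bolus during hour [0, 1)
    serum = pk.serum_series(doses, params.k, params.f, params.v, c0=0.0)
    urine = pk.urine_entering_bladder(params, serum)

    records = []
    for s in range(n_subjects):
        for h in hours:
            records.append((s, int(h), serum[s, int(h)], urine[s, int(h)]))
    return pd.DataFrame(
        records, columns=["subject", "hour", "serum_mg_l", "urine_ugug"]
    )
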