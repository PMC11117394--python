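"""Orchestration: simulate → predict → ABC filter → summarize, with CSV I/O.

Each stage has an in-memory function operating on data frames (used by tests
and the acceptance experiments) and the :func:`run_pipeline` driver that wires
them to a directory of CSV artifacts with a manifest and log.  The global seed
is expanded through ``numpy.random.SeedSequence`` into independent per-stage
substreams (population, exposures, measurement truth, prediction parameters)
so any stage can be rerun in isolation without disturbing the others.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import abcfilter, doseplan, pk, summarize, synth
from .config import PipelineConfig

__all__ = [
    "SchemaError",
    "stage_rngs",
    "read_table",
    "simulate_tables",
    "predict_records",
    "abc_stage",
    "summarize_stage",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

STAGES = ("population", "exposures", "measurements", "prediction")

SCHEMAS = {
    "participants.csv": synth.PARTICIPANT_COLUMNS,
    "diet.csv": synth.DIET_COLUMNS,
    "exposures.csv": synth.EXPOSURE_COLUMNS,
    "biomarkers.csv": synth.BIOMARKER_COLUMNS,
    "design.csv": synth.DESIGN_COLUMNS,
}


class SchemaError(ValueError):
    """An input table is missing a required column; the message names it."""


def stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    """Independent per-stage random generators derived from one global seed."""
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {name: np.random.default_rng(ss) for name, ss in zip(STAGES, children)}


def read_table(path: Path, name: str) -> pd.DataFrame:
    """Read one of the fixed CSV schemas, failing fast on missing columns."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in SCHEMAS[name] if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing required column(s) {missing}")
    return df


# ---------------------------------------------------------------------------
# stages (in-memory)
# ---------------------------------------------------------------------------

def simulate_tables(cfg: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Generate the five input tables plus the generating truth."""
    cfg.validate()
    rngs = stage_rngs(cfg.seed)
    synth_cfg = cfg.synth
    participants, diet, design = synth.generate_population(
        synth_cfg, rngs["population"]
    )
    exposures = synth.generate_exposure_iterates(
        participants, synth_cfg, rngs["exposures"]
    )
    biomarkers, truth = synth.simulate_measurements(
        participants, diet, exposures, synth_cfg,
        priors=cfg.priors, behavior=cfg.behavior,
        creatinine_formula=cfg.creatinine,
        true_iterate=cfg.true_iterate, rng=rngs["measurements"],
    )
    return {
        "participants": participants,
        "diet": diet,
        "design": design,
        "exposures": exposures,
        "biomarkers": biomarkers,
        "truth": truth,
    }


def predict_records(
    participants: pd.DataFrame,
    diet: pd.DataFrame,
    exposures: pd.DataFrame,
    biomarkers: pd.DataFrame,
    cfg: PipelineConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Forward-model every participant-iterate and join the measurements.

    Samples washing behavior and pharmacokinetic parameters per
    participant-iterate (or uses the point estimates when configured), builds
    the hour-indexed schedules, runs the serum/urine model and returns the
    prediction-record table with columns participant_id, iterate, predicted,
    measured (both μg/μg creatinine), exposure_day1 (mg/kg/day) and below_lod.
    """
    cfg.validate()
    rng = rng if rng is not None else stage_rngs(cfg.seed)["prediction"]

    order = {p: i for i, p in enumerate(participants["participant_id"])}
    p_idx = exposures["participant_id"].map(order).to_numpy()
    if np.any(pd.isna(p_idx)):
        raise SchemaError("exposures.csv: participant_id not present in participants.csv")
    p_idx = p_idx.astype(int)
    n_rows = len(exposures)

    if cfg.point_estimates:
        params = pk.point_estimate_parameters(cfg.points, size=n_rows)
        is_washer = np.zeros(n_rows, dtype=bool)
        factor = np.zeros(n_rows)
    else:
        params = pk.sample_pk_parameters(rng, cfg.priors, size=n_rows)
        is_washer, factor = doseplan.sample_behavior_arrays(rng, n_rows, cfg.behavior)

    n_creat_per_participant = pk.creatinine_excretion_rate(
        participants["age"].to_numpy(), participants["sex"].to_numpy(),
        participants["body_weight"].to_numpy(), participants["height"].to_numpy(),
        cfg.creatinine,
    )
    params = params.with_creatinine(np.asarray(n_creat_per_participant)[p_idx])

    meals = synth.meal_matrix_from_diet(participants, diet)
    doses, coll_idx, init_rate = doseplan.build_schedule_matrix(
        meals,
        participants["collection_hour"].to_numpy(),
        participants["fasting_hours"].to_numpy(dtype=float),
        participants["body_weight"].to_numpy(dtype=float),
        p_idx,
        exposures["day1_dose"].to_numpy(dtype=float),
        exposures["day2_dose"].to_numpy(dtype=float),
        is_washer,
        factor,
    )
    c0 = pk.steady_state_concentration(params, init_rate)
    serum = pk.serum_series(doses[:, :-1], params.k, params.f, params.v, c0)
    urine = pk.urine_entering_bladder(params, serum)
    predicted = np.maximum(
        pk.bladder_average(urine, coll_idx, params.void_interval), cfg.floor
    )

    bio = biomarkers.set_index("participant_id")
    measured = pk.standardize_measurement(
        bio["urinary_3pba"].reindex(exposures["participant_id"]).to_numpy(),
        bio["creatinine"].reindex(exposures["participant_id"]).to_numpy(),
    )
    if np.any(~np.isfinite(measured)):
        raise SchemaError("biomarkers.csv: missing measurement for some participant")

    return pd.DataFrame(
        {
            "participant_id": exposures["participant_id"],
            "iterate": exposures["iterate"],
            "predicted": predicted,
            "measured": measured,
            "exposure_day1": exposures["day1_dose"],
            "below_lod": bio["below_lod"].reindex(exposures["participant_id"]).to_numpy(),
        }
    )


def abc_stage(records: pd.DataFrame, cfg: PipelineConfig) -> dict:
    """Annotate records with accept flags and summarize acceptance."""
    annotated = abcfilter.annotate(records, cfg.thresholds, cfg.floor)
    report = abcfilter.acceptance_summary(records, cfg.thresholds, cfg.floor)
    for c in cfg.thresholds:
        _, counts, dropped = abcfilter.filter_iterates(records, c, cfg.floor)
        report["thresholds"][f"{c:g}"]["n_participants_dropped"] = len(dropped)
    return {"records": annotated, "report": report}


def summarize_stage(
    records: pd.DataFrame, design: pd.DataFrame, cfg: PipelineConfig
) -> dict:
    """Survey-weighted percentile tables and unweighted diagnostics per filter."""
    quantities = {
        "exposure_day1": "exposure_mgkgday",
        "predicted": "predicted_ugug",
        "measured": "measured_ugug",
    }
    tables = [
        summarize.summary_table(records, design, quantities, "unfiltered", cfg.n_cycles)
    ]
    diagnostics = {
        "unfiltered": {
            **summarize.log_correlation(records, cfg.floor),
            "coverage": {
                f"{c:g}": summarize.coverage_fraction(records, c, cfg.floor)
                for c in cfg.thresholds
            },
        }
    }
    for c in cfg.thresholds:
        accepted, _, dropped = abcfilter.filter_iterates(records, c, cfg.floor)
        name = f"c={c:g}"
        if len(accepted):
            tables.append(
                summarize.summary_table(
                    accepted, design, quantities, name, cfg.n_cycles
                )
            )
        diagnostics[name] = {
            **(
                summarize.log_correlation(accepted, cfg.floor)
                if len(accepted) >= 3
                else {"n": int(len(accepted)), "degenerate": True}
            ),
            "n_participants_dropped": len(dropped),
        }
    return {"tables": pd.concat(tables, ignore_index=True), "diagnostics": diagnostics}


def calibration_experiment(cfg: PipelineConfig) -> dict:
    """One full synthetic calibration run with known ground truth.

    Simulates a population, forward-models every participant-iterate, applies
    rejection ABC at the configured thresholds and reports, per filter level:
    the unweighted log10-scale correlation of predicted vs measured, the
    coverage fraction, the median predicted and measured concentrations
    (μg/μg), survey-weighted exposure percentiles (mg/kg/day), and the median
    absolute log10 error of the retained day-1 exposure iterates against the
    generating truth (exposure recovery).

    Medians follow the summary-statistics convention: retained iterates are
    averaged within participant first, then the median is taken across
    participants.
    """
    tables = simulate_tables(cfg)
    records = predict_records(
        tables["participants"], tables["diet"], tables["exposures"],
        tables["biomarkers"], cfg,
    )
    truth = tables["truth"].set_index("participant_id")["day1_dose"]
    design = tables["design"]
    weighted = summarize.construct_weights(design, cfg.n_cycles)
    w_by_id = weighted.set_index("participant_id")["analysis_weight"]

    def _exposure_error(subset: pd.DataFrame) -> float:
        true_dose = truth.reindex(subset["participant_id"]).to_numpy()
        err = np.abs(
            np.log10(subset["exposure_day1"].to_numpy()) - np.log10(true_dose)
        )
        return float(np.median(err))

    def _metrics(subset: pd.DataFrame) -> dict:
        means = summarize.per_participant_mean(subset, ["exposure_day1", "predicted"])
        w = w_by_id.reindex(means["participant_id"]).to_numpy()
        pcts = summarize.weighted_percentiles(
            means["exposure_day1"].to_numpy(), w, (0.50, 0.90, 0.95, 0.99)
        )
        return {
            "r_log10": summarize.log_correlation(subset, cfg.floor)["r_log10"],
            "median_predicted": float(np.median(means["predicted"])),
            "median_exposure_error": _exposure_error(subset),
            "exposure_percentiles": {f"p{100 * p:g}": v for p, v in pcts.items()},
            "n_records": int(len(subset)),
        }

    measured_by_participant = records.groupby("participant_id")["measured"].first()
    out = {
        "median_measured": float(np.median(measured_by_participant)),
        "n_participants": int(len(tables["participants"])),
        "unfiltered": {
            **_metrics(records),
            "coverage": {
                f"{c:g}": summarize.coverage_fraction(records, c, cfg.floor)
                for c in cfg.thresholds
            },
        },
    }
    for c in cfg.thresholds:
        accepted, _, dropped = abcfilter.filter_iterates(records, c, cfg.floor)
        out[f"c={c:g}"] = {**_metrics(accepted), "n_participants_dropped": len(dropped)}
    return out


# ---------------------------------------------------------------------------
# CSV-backed driver
# ---------------------------------------------------------------------------

def _write_simulated(tables: dict[str, pd.DataFrame], outdir: Path) -> None:
    tables["participants"].to_csv(outdir / "participants.csv", index=False)
    tables["diet"].to_csv(outdir / "diet.csv", index=False)
    tables["design"].to_csv(outdir / "design.csv", index=False)
    tables["exposures"].to_csv(outdir / "exposures.csv", index=False)
    tables["biomarkers"].to_csv(outdir / "biomarkers.csv", index=False)
    tables["truth"].to_csv(outdir / "truth.csv", index=False)


def run_pipeline(
    cfg: PipelineConfig,
    outdir: str | Path,
    stages: tuple[str, ...] = ("simulate", "predict", "abc", "summarize"),
    indir: str | Path | None = None,
    write_schedules: bool = False,
) -> dict:
    """Run the requested stages against a directory of CSV artifacts.

    With "simulate" among the stages the five input tables are generated;
    otherwise they are read (and schema-checked) from ``indir``/``outdir``.
    Writes predictions.csv, accepted_c*.csv, acceptance_report.json,
    summary_tables.csv, diagnostics.json, run.log and manifest.json.
    Deterministic under a fixed config seed.
    """
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    indir = Path(indir) if indir is not None else outdir

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("pkabc")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    counts: dict[str, int] = {}
    try:
        if "simulate" in stages:
            tables = simulate_tables(cfg)
            _write_simulated(tables, outdir)
            logger.info("simulate: %d participants, %d exposure rows",
                        len(tables["participants"]), len(tables["exposures"]))
        else:
            tables = {
                "participants": read_table(indir / "participants.csv", "participants.csv"),
                "diet": read_table(indir / "diet.csv", "diet.csv"),
                "design": read_table(indir / "design.csv", "design.csv"),
                "exposures": read_table(indir / "exposures.csv", "exposures.csv"),
                "biomarkers": read_table(indir / "biomarkers.csv", "biomarkers.csv"),
            }
        counts["participants"] = len(tables["participants"])
        counts["exposure_rows"] = len(tables["exposures"])

        result: dict = {"tables": tables}
        if "predict" in stages:
            records = predict_records(
                tables["participants"], tables["diet"], tables["exposures"],
                tables["biomarkers"], cfg,
            )
            if write_schedules:
                records.to_csv(outdir / "schedule_debug.csv", index=False)
            records.to_csv(outdir / "predictions.csv", index=False)
            counts["prediction_rows"] = len(records)
            logger.info("predict: %d records", len(records))
            result["records"] = records
        elif ("abc" in stages) or ("summarize" in stages):
            records = pd.read_csv(
                indir / "predictions.csv", float_precision="round_trip"
            )
            result["records"] = records

        if "abc" in stages:
            abc_out = abc_stage(records, cfg)
            abc_out["records"].to_csv(outdir / "predictions.csv", index=False)
            for c in cfg.thresholds:
                accepted, _, _ = abcfilter.filter_iterates(records, c, cfg.floor)
                accepted.to_csv(
                    outdir / f"accepted_{abcfilter.threshold_label(c)[9:]}.csv",
                    index=False,
                )
            with open(outdir / "acceptance_report.json", "w") as fh:
                json.dump(abc_out["report"], fh, indent=2)
            logger.info("abc: %s", abc_out["report"]["thresholds"])
            result["abc"] = abc_out

        if "summarize" in stages:
            summary = summarize_stage(records, tables["design"], cfg)
            summary["tables"].to_csv(outdir / "summary_tables.csv", index=False)
            with open(outdir / "diagnostics.json", "w") as fh:
                json.dump(summary["diagnostics"], fh, indent=2)
            logger.info("summarize: %d table rows", len(summary["tables"]))
            result["summary"] = summary

        manifest = {
            "config_hash": cfg.config_hash(),
            "seed": cfg.seed,
            "stages": list(stages),
            "row_counts": counts,
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        result["manifest"] = manifest
        return result
    finally:
        root.removeHandler(handler)
        handler.close()
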