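"""Survey-weighted summary tables and unweighted fit diagnostics.

Survey-weighted percentiles follow the left-continuous inverse of the
empirical weighted CDF: the p-quantile is the smallest observed value whose
cumulative weight share reaches p.  With equal weights this reduces to the
ordinary sample quantile of the same definition, and for integer weights it
coincides with expanding each value ``weight`` times.  Monte Carlo iterates
are first averaged within participant, and pooled-cycle examination weights
are divided by the number of cycles.

Model-fit diagnostics (coverage within a log10 threshold, Pearson correlation
of predicted vs measured) are unweighted, computed on the supplied record set.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from . import abcfilter

__all__ = [
    "per_participant_mean",
    "construct_weights",
    "weighted_percentiles",
    "coverage_fraction",
    "log_correlation",
    "summary_table",
    "plot_predicted_vs_measured",
]

logger = logging.getLogger(__name__)

DEFAULT_PROBS = (0.50, 0.90, 0.95, 0.99)


def per_participant_mean(
    records: pd.DataFrame,
    value_cols,
    id_col: str = "participant_id",
    expected_ids=None,
) -> pd.DataFrame:
    """Average the retained Monte Carlo iterates within each participant.

    ``expected_ids`` (optional) is the full participant list; members with no
    retained records are excluded from the result and logged.
    """
    if isinstance(value_cols, str):
        value_cols = [value_cols]
    out = records.groupby(id_col, sort=False)[list(value_cols)].mean().reset_index()
    if expected_ids is not None:
        missing = set(expected_ids) - set(out[id_col])
        if missing:
            logger.info(
                "per_participant_mean: %d participant(s) with zero retained "
                "iterates excluded", len(missing),
            )
    return out


def construct_weights(design: pd.DataFrame, n_cycles: int = 2) -> pd.DataFrame:
    """Analysis weights for pooled survey cycles: weight / n_cycles.

    Strata and PSU labels are carried through unchanged.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    w = design["survey_weight"].to_numpy(dtype=float)
    if np.any(w <= 0):
        raise ValueError("survey_weight must be positive")
    out = design.copy()
    out["analysis_weight"] = w / n_cycles
    return out


def weighted_percentiles(values, weights, probs=DEFAULT_PROBS) -> dict[float, float]:
    """Weighted quantiles via the left-continuous inverse weighted CDF.

    For each p the result is the smallest value v with F(v) ≥ p, where F is
    the weight-normalized empirical CDF; every output is an element of
    ``values``.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.size == 0:
        raise ValueError("values must be non-empty")
    if values.shape != weights.shape:
        raise ValueError("values and weights must have equal length")
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")
    probs = np.atleast_1d(np.asarray(probs, dtype=float))
    if np.any((probs <= 0) | (probs >= 1)):
        raise ValueError("probs must lie strictly inside (0, 1)")
    order = np.argsort(values, kind="stable")
    v = values[order]
    cw = np.cumsum(weights[order])
    targets = probs * cw[-1]
    # smallest index where cumulative weight >= target (left-continuous inverse)
    idx = np.searchsorted(cw, targets, side="left")
    idx = np.minimum(idx, len(v) - 1)
    return {float(p): float(v[i]) for p, i in zip(probs, idx)}


def coverage_fraction(
    records: pd.DataFrame, c: float, floor: float = 1e-12
) -> float:
    """Fraction of predictions within a log10 distance ``c`` of the measurement."""
    summary = abcfilter.acceptance_summary(records, thresholds=(c,), floor=floor)
    return summary["thresholds"][f"{c:g}"]["fraction"]


def log_correlation(records: pd.DataFrame, floor: float = 1e-12) -> dict:
    """Pearson correlation of predicted vs measured, log10 and raw scale.

    Unweighted, on the supplied (filtered or unfiltered) record set; values
    are floored before the log10 transform.  Zero variance on either axis
    yields ``degenerate=True`` with NaN correlations.
    """
    if len(records) < 3:
        raise ValueError("need >= 3 records for a correlation")
    measured = np.asarray(records["measured"], dtype=float)
    predicted = np.maximum(np.asarray(records["predicted"], dtype=float), floor)
    lm, lp = np.log10(measured), np.log10(predicted)
    out = {"n": int(len(records)), "degenerate": False}
    if np.ptp(lm) == 0 or np.ptp(lp) == 0:
        out.update(r_log10=float("nan"), p_log10=float("nan"),
                   r_raw=float("nan"), p_raw=float("nan"), degenerate=True)
        return out
    r_log, p_log = stats.pearsonr(lm, lp)
    r_raw, p_raw = stats.pearsonr(measured, predicted)
    out.update(r_log10=float(r_log), p_log10=float(p_log),
               r_raw=float(r_raw), p_raw=float(p_raw))
    return out


def summary_table(
    records: pd.DataFrame,
    design: pd.DataFrame,
    quantities: dict[str, str],
    filter_name: str,
    n_cycles: int = 2,
    probs=DEFAULT_PROBS,
) -> pd.DataFrame:
    """Long-format survey-weighted percentile table for one filter level.

    ``quantities`` maps record columns to output names (e.g.
    ``{"exposure_day1": "exposure_mgkgday"}``).  Iterates are averaged within
    participant, joined to the design table, and the weighted percentiles are
    computed with cycle-adjusted weights.
    """
    rows = []
    weighted = construct_weights(design, n_cycles)
    means = per_participant_mean(
        records, list(quantities), expected_ids=design["participant_id"]
    )
    merged = means.merge(
        weighted[["participant_id", "analysis_weight"]], on="participant_id"
    )
    for col, name in quantities.items():
        pcts = weighted_percentiles(
            merged[col].to_numpy(), merged["analysis_weight"].to_numpy(), probs
        )
        for p, value in pcts.items():
            rows.append(
                {
                    "quantity": name,
                    "filter": filter_name,
                    "percentile": 100.0 * p,
                    "value": value,
                    "n": int(len(merged)),
                }
            )
    return pd.DataFrame(rows)


def plot_predicted_vs_measured(
    records: pd.DataFrame, c: float, path: str, floor: float = 1e-12
) -> None:
    """Accept/reject scatter of predicted vs measured on log-log axes."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    measured = np.asarray(records["measured"], dtype=float)
    predicted = np.maximum(np.asarray(records["predicted"], dtype=float), floor)
    accepted = abcfilter.abc_accept(measured, predicted, c, floor)

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.loglog(measured[accepted], predicted[accepted], "k.", ms=3, label="accepted")
    ax.loglog(measured[~accepted], predicted[~accepted], "r.", ms=3, label="rejected")
    lims = [
        min(measured.min(), predicted.min()) / 2,
        max(measured.max(), predicted.max()) * 2,
    ]
    ax.plot(lims, lims, "b-", lw=0.8)
    ax.set_xlim(lims), ax.set_ylim(lims)
    ax.set_xlabel("measured urinary 3PBA (μg/μg creatinine)")
    ax.set_ylabel("predicted urinary 3PBA (μg/μg creatinine)")
    ax.set_title(f"rejection ABC, c = {c:g}")
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
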