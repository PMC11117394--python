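"""Rejection ABC: keep Monte Carlo iterates whose predicted biomarker is close
to the measurement.

The simplest form of approximate Bayesian computation is used: a
participant-iterate is accepted iff

    |log10(measured) − log10(predicted)| < c        (strict inequality)

with c = 1 for an "order of magnitude" threshold and c = 0.5 for half an
order of magnitude.  Unfiltered results keep every iterate.  Predictions are
floored before the log10 transform so zero-exposure iterates remain
comparable in log space.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "threshold_label",
    "log10_distance",
    "abc_accept",
    "annotate",
    "filter_iterates",
    "acceptance_summary",
]

#: Columns a prediction-record table must carry.
RECORD_COLUMNS = ["participant_id", "iterate", "predicted", "measured"]


def threshold_label(c: float) -> str:
    """Column label for a threshold: c=1.0 → 'accepted_c10', c=0.5 → 'accepted_c05'."""
    return f"accepted_c{int(round(c * 10)):02d}"


def log10_distance(measured, predicted, floor: float = 1e-12):
    """|log10 measured − log10 predicted| after flooring the prediction."""
    measured = np.asarray(measured, dtype=float)
    predicted = np.maximum(np.asarray(predicted, dtype=float), floor)
    if np.any(measured <= 0):
        raise ValueError("measured values must be positive")
    if np.any(predicted <= 0):
        raise ValueError("predicted values must be positive after flooring")
    out = np.abs(np.log10(measured) - np.log10(predicted))
    return float(out) if np.ndim(out) == 0 else out


def abc_accept(measured, predicted, c: float, floor: float = 1e-12):
    """Accept iff the log10 distance is strictly below the threshold ``c``.

    Ties at exactly ``c`` are rejected.  Symmetric in (measured, predicted)
    and invariant to rescaling both by a common positive factor.
    """
    if c <= 0:
        raise ValueError("threshold c must be positive")
    out = log10_distance(measured, predicted, floor) < c
    return bool(out) if np.ndim(out) == 0 else out


def annotate(
    records: pd.DataFrame,
    thresholds=(1.0, 0.5),
    floor: float = 1e-12,
) -> pd.DataFrame:
    """Return a copy of ``records`` with one boolean accept column per threshold."""
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records table is missing column(s) {missing}")
    out = records.copy()
    for c in thresholds:
        out[threshold_label(c)] = abc_accept(
            out["measured"].to_numpy(), out["predicted"].to_numpy(), c, floor
        )
    return out


def filter_iterates(
    records: pd.DataFrame, c: float, floor: float = 1e-12
) -> tuple[pd.DataFrame, pd.Series, list]:
    """Accepted subset at threshold ``c`` plus per-participant acceptance counts.

    Returns ``(accepted, counts, dropped)`` where ``counts`` indexes every
    participant present in ``records`` (zero where no iterate survived) and
    ``dropped`` lists participants losing all iterates — these are excluded
    from filtered summaries and reported separately.
    """
    keep = abc_accept(
        records["measured"].to_numpy(), records["predicted"].to_numpy(), c, floor
    )
    accepted = records.loc[keep]
    counts = (
        pd.Series(keep, index=records["participant_id"])
        .groupby(level=0, sort=False)
        .sum()
        .astype(int)
    )
    dropped = counts.index[counts == 0].tolist()
    return accepted, counts, dropped


def acceptance_summary(
    records: pd.DataFrame,
    thresholds=(1.0, 0.5),
    floor: float = 1e-12,
    by: str | None = None,
) -> dict:
    """Acceptance fractions (with counts) per threshold, optionally per stratum.

    ``by`` names a column of ``records`` (e.g. a demographic group) for a
    per-stratum breakdown alongside the overall fractions.
    """
    if len(records) == 0:
        raise ValueError("records must be non-empty")
    dist = log10_distance(
        records["measured"].to_numpy(), records["predicted"].to_numpy(), floor
    )
    out: dict = {"n_records": int(len(records)), "thresholds": {}}
    for c in thresholds:
        entry = {
            "c": float(c),
            "n_accepted": int((dist < c).sum()),
            "fraction": float((dist < c).mean()),
        }
        if by is not None:
            groups = {}
            for key, idx in records.groupby(by).indices.items():
                d = dist[idx]
                groups[str(key)] = {
                    "n": int(len(d)),
                    "n_accepted": int((d < c).sum()),
                    "fraction": float((d < c).mean()),
                }
            entry["by_" + by] = groups
        out["thresholds"][f"{c:g}"] = entry
    return out
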