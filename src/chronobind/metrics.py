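"""Descriptive summaries of trial tables: estimation errors and binding.

Action binding is the shift of the mean operant keypress error from
its baseline mean (positive: the action is reported later, toward the
tone).  Outcome binding is the corresponding shift of the tone error
(negative: the tone is reported earlier, toward the action).  Their
difference, action_shift - outcome_shift, sums the overestimation of
the action and the underestimation of the outcome; it is positive when
the perceived action-outcome interval contracted (intentional binding)
and negative for repulsion.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["estimation_errors", "binding_indices"]


def estimation_errors(trials: pd.DataFrame) -> pd.DataFrame:
    """Per observer x condition cell: mean, SD and count of errors."""
    table = (
        trials.groupby(["observer_id", "task", "target", "t_AO"], sort=True)["error"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    return table


def binding_indices(error_table: pd.DataFrame) -> pd.DataFrame:
    """Binding summary per observer x operant interval.

    Expects the output of :func:`estimation_errors`.  Returns columns
    observer_id, interval, action_shift, outcome_shift, compression,
    with compression = action_shift - outcome_shift.
    """
    base = error_table[error_table["task"] == "baseline"]
    operant = error_table[error_table["task"] == "operant"]
    if operant.empty:
        raise ValueError("no operant cells in error table")

    base_means = base.pivot_table(index="observer_id", columns="target", values="mean")
    for target in ("action", "outcome"):
        if target not in base_means.columns or base_means[target].isna().any():
            raise ValueError(f"missing baseline {target} cell for some observer")

    wide = operant.pivot_table(
        index=["observer_id", "t_AO"], columns="target", values="mean"
    ).reset_index()
    for target in ("action", "outcome"):
        if target not in wide.columns:
            raise ValueError(f"missing operant {target} cells")
    wide = wide.merge(
        base_means.rename(columns={"action": "base_action", "outcome": "base_outcome"}),
        left_on="observer_id",
        right_index=True,
    )
    out = pd.DataFrame(
        {
            "observer_id": wide["observer_id"],
            "interval": wide["t_AO"],
            "action_shift": wide["action"] - wide["base_action"],
            "outcome_shift": wide["outcome"] - wide["base_outcome"],
        }
    )
    out["compression"] = out["action_shift"] - out["outcome_shift"]
    return out.sort_values(["observer_id", "interval"], ignore_index=True)
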