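"""Epoch aggregation of per-trial measures.

Behavior is summarized over fixed trial windows chosen to track the
experiment's dynamics: wider windows where behavior is steady, narrow
ones where rapid transients are expected.

==============  ========  ===============
epoch           block     window
==============  ========  ===============
baseline        baseline  last 10 trials
end_learning    learning  last 10 trials
early_clamp     clamp     first 3 trials
end_clamp       clamp     last 3 trials
early_washout   washout   first 3 trials
end_washout     washout   last 10 trials
==============  ========  ===============

Invalid trials are dropped from the mean with the trial count
decremented (no imputation); an epoch with zero valid trials is omitted
with a logged reason.  SDs use the n-1 denominator.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EPOCHS",
    "extract_epochs",
    "variability_summary",
    "epoch_means",
]

log = logging.getLogger(__name__)

#: epoch -> (block, take, n_trials)
EPOCHS: dict[str, tuple[str, str, int]] = {
    "baseline": ("baseline", "last", 10),
    "end_learning": ("learning", "last", 10),
    "early_clamp": ("clamp", "first", 3),
    "end_clamp": ("clamp", "last", 3),
    "early_washout": ("washout", "first", 3),
    "end_washout": ("washout", "last", 10),
}

_DEFAULT_MEASURES = [
    "initial_angle_deg",
    "final_angle_deg",
    "compensation_angle_deg",
    "launch_angle_deg",
    "path_length_ratio",
    "norm_correction_time",
    "angle_spread_deg",
    "reaction_ms",
    "stationary_ms",
    "movement_ms",
    "ia_time_ms",
]

EPOCH_COLUMNS = ["participant_id", "age_mo", "epoch", "measure", "mean", "sd", "n_trials"]


def _epoch_window(block_df: pd.DataFrame, take: str, n: int) -> pd.DataFrame:
    block_df = block_df.sort_values("trial_index")
    return block_df.head(n) if take == "first" else block_df.tail(n)


def extract_epochs(
    measures: pd.DataFrame, measure_cols: Sequence[str] | None = None
) -> pd.DataFrame:
    """Tidy per-participant epoch summaries (mean, sd, n) of each measure.

    ``measures`` is the per-trial table produced by the kinematics stage;
    it must carry ``participant_id``, ``block``, ``trial_index`` and a
    ``valid`` flag.
    """
    required = {"participant_id", "block", "trial_index"}
    missing = required - set(measures.columns)
    if missing:
        raise ValueError(f"measures table missing column(s): {sorted(missing)}")
    if measure_cols is None:
        measure_cols = [c for c in _DEFAULT_MEASURES if c in measures.columns]
    rows = []
    for pid, pdf in measures.groupby("participant_id", sort=True):
        age = float(pdf["age_mo"].iloc[0]) if "age_mo" in pdf.columns else np.nan
        for epoch, (block, take, n) in EPOCHS.items():
            window = _epoch_window(pdf[pdf["block"] == block], take, n)
            if "valid" in window.columns:
                window = window[window["valid"].astype(bool)]
            for col in measure_cols:
                vals = window[col].dropna().to_numpy(dtype=float)
                if vals.size == 0:
                    log.info("participant %s epoch %s: no valid %s values", pid, epoch, col)
                    continue
                rows.append(
                    {
                        "participant_id": pid,
                        "age_mo": age,
                        "epoch": epoch,
                        "measure": col,
                        "mean": float(vals.mean()),
                        "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                        "n_trials": int(vals.size),
                    }
                )
    return pd.DataFrame(rows, columns=EPOCH_COLUMNS)


def epoch_means(
    epochs: pd.DataFrame, measure: str, epoch: str, stat: str = "mean"
) -> pd.DataFrame:
    """Per-participant values of one measure in one epoch, with ages —
    the fitting surface for the developmental curve models."""
    sel = epochs[(epochs["measure"] == measure) & (epochs["epoch"] == epoch)]
    return sel[["participant_id", "age_mo", stat]].rename(columns={stat: measure}).reset_index(drop=True)


def variability_summary(measures: pd.DataFrame) -> pd.DataFrame:
    """Per-participant SDs of the initial and final angle at baseline and
    at the end of learning (the precision measures fed to the reference
    curves)."""
    epochs = extract_epochs(measures, ["initial_angle_deg", "final_angle_deg"])
    sel = epochs[epochs["epoch"].isin(["baseline", "end_learning"])]
    return sel[["participant_id", "age_mo", "epoch", "measure", "sd", "n_trials"]].reset_index(
        drop=True
    )
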