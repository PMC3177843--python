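"""Per-participant, per-character gaze-interference indices.

The accuracy index is the congruent-minus-incongruent percentage of correct
responses (positive = the distractor's gaze helped when congruent, i.e.
stronger capture).  The RT index is the incongruent-minus-congruent mean
saccadic latency over kept, correct trials (positive = incongruent slower).
A single-pass outlier rule removes any participant whose index in any
character condition lies beyond k standard deviations from their own
group's mean for that condition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .saccades import STATUS_KEPT


def interference_accuracy(trials: pd.DataFrame) -> float:
    """Accuracy interference for one participant x character cell pair.

    100 * (proportion correct in congruent kept trials minus proportion
    correct in incongruent kept trials); NaN when either condition has no
    kept trial.
    """
    kept = trials[trials["status"] == STATUS_KEPT]
    props = {}
    for cond in ("congruent", "incongruent"):
        sub = kept[kept["congruency"] == cond]
        if len(sub) == 0:
            return np.nan
        props[cond] = sub["correct"].astype(bool).mean()
    return 100.0 * (props["congruent"] - props["incongruent"])


def interference_rt(trials: pd.DataFrame) -> float:
    """RT interference for one cell pair: mean incongruent minus mean
    congruent latency over kept, correct trials; NaN if a side is empty."""
    kept = trials[(trials["status"] == STATUS_KEPT)
                  & trials["correct"].astype(bool)]
    means = {}
    for cond in ("congruent", "incongruent"):
        sub = kept[kept["congruency"] == cond]
        if len(sub) == 0:
            return np.nan
        means[cond] = sub["rt_ms"].mean()
    return float(means["incongruent"] - means["congruent"])


def interference_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Build the participant x character interference table.

    Returns one row per (participant_id, group, character) with columns
    acc_interference (percentage points), rt_interference (ms) and the kept
    trial count; empty conditions yield NaN, never zero.
    """
    rows = []
    for (pid, group, char), sub in trials.groupby(
            ["participant_id", "group", "character"], sort=True):
        rows.append({
            "participant_id": pid, "group": group, "character": char,
            "acc_interference": interference_accuracy(sub),
            "rt_interference": interference_rt(sub),
            "n_kept": int((sub["status"] == STATUS_KEPT).sum()),
        })
    return pd.DataFrame(rows)


def to_wide(table: pd.DataFrame, value: str = "acc_interference") -> pd.DataFrame:
    """Pivot the long interference table to participants x characters, with
    the group label as a column."""
    wide = table.pivot_table(index="participant_id", columns="character",
                             values=value, aggfunc="first")
    groups = table.drop_duplicates("participant_id").set_index(
        "participant_id")["group"]
    wide.insert(0, "group", groups)
    wide.columns.name = None
    return wide


def exclude_outlier_participants(
    wide: pd.DataFrame,
    k_sd: float = 3.0,
    within_group: bool = True,
) -> tuple[pd.DataFrame, list]:
    """Remove participants lying beyond ``k_sd`` SDs in any condition.

    The criterion is evaluated in a single pass on the original table:
    means and SDs (n-1 denominator) are computed per condition within the
    participant's own group (or over the whole sample if ``within_group``
    is False), and a participant is excluded if any condition value exceeds
    the band.  Zero-variance conditions exclude nobody.
    """
    cond_cols = [c for c in wide.columns if c != "group"]
    if within_group:
        for g, sub in wide.groupby("group"):
            if len(sub) < 3:
                raise ValueError(f"group {g!r} needs at least 3 participants")
        mean = wide.groupby("group")[cond_cols].transform("mean")
        sd = wide.groupby("group")[cond_cols].transform("std")
    else:
        if len(wide) < 3:
            raise ValueError("need at least 3 participants")
        mean = wide[cond_cols].transform(lambda c: np.full(len(c), c.mean()))
        sd = wide[cond_cols].transform(lambda c: np.full(len(c), c.std()))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (wide[cond_cols] - mean).abs() / sd
    z = z.where(sd > 0)          # degenerate conditions exclude nobody
    flagged = z.gt(k_sd).any(axis=1)
    excluded = list(wide.index[flagged])
    return wide.loc[~flagged].copy(), excluded
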