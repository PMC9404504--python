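"""Anesthesia-stage windows and the patient x stage x measure table.

Five 1-min stages anchor the statistics: two minutes before loss of
consciousness (LOC-2), one minute before (LOC-1), the LOC minute, the midpoint
minute between LOC and the effect-site concentration maximum (LOC-CeMax), and
the CeMax minute itself.  The midpoint rounds half to even; collisions between
post-LOC stages (short inductions) are flagged and share one value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["STAGE_LABELS", "StageWindows", "define_stages", "build_stage_table",
           "age_group"]

STAGE_LABELS = ("LOC-2", "LOC-1", "LOC", "LOC-CeMax", "CeMax")

#: group boundary in years; "elderly" is age >= 65
ELDERLY_AGE = 65.0


def age_group(age_years: float) -> str:
    return "elderly" if age_years >= ELDERLY_AGE else "young"


@dataclass
class StageWindows:
    """Minute index (relative to the same grid as ``loc_minute``) per stage."""

    minutes: dict
    collisions: list = field(default_factory=list)

    def __post_init__(self):
        if tuple(self.minutes) != STAGE_LABELS:
            raise ValueError(f"stage labels must be {STAGE_LABELS}")


def define_stages(loc_minute: int, cemax_minute: int) -> StageWindows:
    """Map the five stages to minute indices; flag degenerate collisions."""
    if cemax_minute < loc_minute:
        raise ValueError(
            f"CeMax minute {cemax_minute} precedes LOC minute {loc_minute}"
        )
    mid = int(np.round((loc_minute + cemax_minute) / 2.0))  # half -> even
    minutes = {
        "LOC-2": loc_minute - 2,
        "LOC-1": loc_minute - 1,
        "LOC": loc_minute,
        "LOC-CeMax": mid,
        "CeMax": cemax_minute,
    }
    collisions = []
    if mid == loc_minute and cemax_minute != loc_minute:
        collisions.append(("LOC-CeMax", "LOC"))
    if mid == cemax_minute and cemax_minute != loc_minute:
        collisions.append(("LOC-CeMax", "CeMax"))
    if cemax_minute == loc_minute:
        collisions.extend(
            [("LOC-CeMax", "LOC"), ("CeMax", "LOC"), ("LOC-CeMax", "CeMax")]
        )
    return StageWindows(minutes=minutes, collisions=collisions)


def build_stage_table(
    minute_values: dict,
    stage_windows: dict,
    ages: dict,
) -> pd.DataFrame:
    """Assemble the tidy patient x stage x measure table.

    Parameters
    ----------
    minute_values : dict
        subject_id -> DataFrame of minute-averaged measures (index
        ``minute_index``, one column per measure; NaN = missing minute).
    stage_windows : dict
        subject_id -> :class:`StageWindows`.
    ages : dict
        subject_id -> age in years.

    Returns
    -------
    DataFrame with columns subject_id, age_years, age_group, stage, measure,
    value.  Missing minutes yield no row (downstream ANOVA applies listwise
    deletion).
    """
    rows = []
    for sid, per_minute in minute_values.items():
        sw = stage_windows[sid]
        age = ages[sid]
        grp = age_group(age)
        for stage in STAGE_LABELS:
            minute = sw.minutes[stage]
            if minute not in per_minute.index:
                continue
            for measure in per_minute.columns:
                value = per_minute.loc[minute, measure]
                if pd.isna(value):
                    continue
                rows.append((sid, age, grp, stage, measure, float(value)))
    return pd.DataFrame(
        rows,
        columns=["subject_id", "age_years", "age_group", "stage", "measure", "value"],
    )
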