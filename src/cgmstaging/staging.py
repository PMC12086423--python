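"""Consensus metabolic staging of presymptomatic type 1 diabetes.

Stages are assigned from the islet-autoantibody count, the OGTT panel
(plasma glucose at 0/30/60/90/120 min, mg/dL) and HbA1c (%):

* fewer than 2 confirmed islet autoantibodies -> ``control``;
* stage 3 (provisional, pending confirmatory testing): fasting >= 126, or
  120-min >= 200, or HbA1c > 6.5;
* stage 2 (dysglycemia): fasting 110-125, or 120-min 140-199, or any of the
  30/60/90-min values >= 200, or HbA1c 5.7-6.4;
* stage 1 (normoglycemia): fasting < 110 and 120-min < 140 and all
  intermediate values < 200 and HbA1c < 5.7.

Stage 3 is evaluated before stage 2 so overlapping criteria resolve upward.
Values that fall in the narrow gaps between the normoglycemia and
dysglycemia definitions (e.g. HbA1c in (6.4, 6.5] with an otherwise normal
OGTT) are labeled stage 2 with an explicit ``range_gap`` criterion — the
dysglycemia bands are read as reaching up to the stage-3 cutoffs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .data import ParticipantRecord

STAGE_ORDER = {"control": 0, "stage1": 1, "stage2": 2, "stage3_provisional": 3}


@dataclass(frozen=True)
class StageLabel:
    label: str
    fired_criteria: tuple[str, ...]


def classify_stage(record: ParticipantRecord) -> StageLabel:
    """Assign exactly one stage label to a complete participant record."""
    for name in ("aab_count", "hba1c"):
        v = getattr(record, name)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise ValueError(f"missing field: {name}")
    if any(v is None or math.isnan(v) for v in record.ogtt):
        raise ValueError("incomplete OGTT panel")

    if record.aab_count < 2:
        return StageLabel("control", ("aab_count_lt_2",))

    g0, g30, g60, g90, g120 = record.ogtt
    h = record.hba1c

    fired: list[str] = []
    if g0 >= 126:
        fired.append("stage3:fasting_ge_126")
    if g120 >= 200:
        fired.append("stage3:120min_ge_200")
    if h > 6.5:
        fired.append("stage3:hba1c_gt_6.5")
    if fired:
        return StageLabel("stage3_provisional", tuple(fired))

    if 110 <= g0 <= 125:
        fired.append("stage2:fasting_110_125")
    if 140 <= g120 <= 199:
        fired.append("stage2:120min_140_199")
    if any(v >= 200 for v in (g30, g60, g90)):
        fired.append("stage2:intermediate_ge_200")
    if 5.7 <= h <= 6.4:
        fired.append("stage2:hba1c_5.7_6.4")
    if fired:
        return StageLabel("stage2", tuple(fired))

    if g0 < 110 and g120 < 140 and all(v < 200 for v in (g30, g60, g90)) and h < 5.7:
        return StageLabel("stage1", ("stage1:normoglycemia",))

    # between the normoglycemia ceiling and the dysglycemia band (continuous
    # inputs only, e.g. HbA1c 6.45): treat as dysglycemic, flag explicitly
    return StageLabel("stage2", ("stage2:range_gap",))


def stage_participants(records: Sequence[ParticipantRecord]) -> pd.DataFrame:
    """Staging output table: one labeled row per participant."""
    rows = []
    for r in records:
        lab = classify_stage(r)
        rows.append(
            {
                "participant_id": r.participant_id,
                "aab_count": r.aab_count,
                "label": lab.label,
                "fired_criteria": ";".join(lab.fired_criteria),
            }
        )
    return pd.DataFrame(rows)


def staging_truth_table(
    fasting_values: Sequence[float],
    g120_values: Sequence[float],
    hba1c_values: Sequence[float],
    intermediate_values: Sequence[float] = (130.0,),
    aab_count: int = 2,
) -> pd.DataFrame:
    """Exhaustive boundary audit: label every grid point of the rule space."""
    rows = []
    for g0, g120, g_mid, h in itertools.product(
        fasting_values, g120_values, intermediate_values, hba1c_values
    ):
        rec = ParticipantRecord(
            participant_id="grid",
            age=10.0,
            sex="female",
            aab_count=aab_count,
            ogtt=(g0, g_mid, g_mid, g_mid, g120),
            hba1c=h,
            followup_years=1.0,
            progressed_stage3=False,
            progression_time=1.0,
        )
        lab = classify_stage(rec)
        rows.append(
            {
                "fasting": g0,
                "g120": g120,
                "intermediate": g_mid,
                "hba1c": h,
                "label": lab.label,
                "fired_criteria": ";".join(lab.fired_criteria),
            }
        )
    return pd.DataFrame(rows)
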