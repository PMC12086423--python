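"""Core data containers and plain-text I/O.

Two containers travel through the whole pipeline:

``GlucoseTrace``
    one sensor wear period — uniform 5-minute interstitial glucose readings in
    mg/dL with per-sample QC flags;
``ParticipantRecord``
    demographics, islet-autoantibody count, the OGTT panel (plasma glucose at
    0/30/60/90/120 min), HbA1c, and progression follow-up.

All glucose values are mg/dL throughout; conversion to mmol/L is provided for
display only.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: mg/dL per mmol/L for glucose
MGDL_PER_MMOL = 18.016

#: sensor reporting limits, mg/dL
SENSOR_FLOOR = 40.0
SENSOR_CEIL = 400.0

TRACE_COLUMNS = ["participant_id", "session_id", "lot_id", "timestamp", "glucose_mg_dl"]

PARTICIPANT_COLUMNS = [
    "participant_id",
    "age",
    "sex",
    "aab_count",
    "ogtt_0",
    "ogtt_30",
    "ogtt_60",
    "ogtt_90",
    "ogtt_120",
    "hba1c",
    "followup_years",
    "progressed_stage3",
    "progression_time",
]


def mgdl_to_mmol(value: float) -> float:
    """Convert mg/dL to mmol/L, rounded to one decimal (display convention)."""
    return round(float(value) / MGDL_PER_MMOL, 1)


@dataclass
class GlucoseTrace:
    """A single CGM wear session.

    ``times`` are timezone-naive local clock timestamps, strictly increasing,
    nominally on a uniform cadence (gaps allowed).  ``flags`` marks samples
    judged implausible by QC; flagged samples are retained in the container but
    excluded from metric computation.  ``trimmed_hours`` records how many
    initial wear hours have already been discarded, so that QC is idempotent.
    """

    participant_id: str
    session_id: str
    lot_id: str
    times: pd.DatetimeIndex
    glucose: np.ndarray
    flags: np.ndarray | None = None
    trimmed_hours: float = 0.0

    def __post_init__(self) -> None:
        self.times = pd.DatetimeIndex(self.times)
        self.glucose = np.asarray(self.glucose, dtype=float)
        if self.flags is None:
            self.flags = np.zeros(len(self.glucose), dtype=bool)
        else:
            self.flags = np.asarray(self.flags, dtype=bool)
        if len(self.times) != len(self.glucose) or len(self.flags) != len(self.glucose):
            raise ValueError("times, glucose and flags must have equal length")
        if len(self.times) > 1 and not (np.diff(self.times.asi8) > 0).all():
            raise ValueError("timestamps must be strictly increasing")
        if np.any(~np.isfinite(self.glucose)):
            raise ValueError("glucose readings must be finite")

    @property
    def n_samples(self) -> int:
        return len(self.glucose)

    @property
    def interval_minutes(self) -> float:
        """Nominal sampling interval, estimated as the median timestamp step."""
        if self.n_samples < 2:
            return float("nan")
        return float(np.median(np.diff(self.times.asi8)) / 60e9)

    def retained(self) -> "GlucoseTrace":
        """Return a copy with flagged samples dropped."""
        keep = ~self.flags
        return replace(
            self,
            times=self.times[keep],
            glucose=self.glucose[keep],
            flags=np.zeros(int(keep.sum()), dtype=bool),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": self.participant_id,
                "session_id": self.session_id,
                "lot_id": self.lot_id,
                "timestamp": self.times.strftime("%Y-%m-%dT%H:%M:%S"),
                "glucose_mg_dl": self.glucose,
            }
        )


def traces_to_frame(traces: Iterable[GlucoseTrace]) -> pd.DataFrame:
    frames = [t.to_frame() for t in traces]
    if not frames:
        return pd.DataFrame(columns=TRACE_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def write_traces_csv(traces: Iterable[GlucoseTrace], path) -> None:
    traces_to_frame(traces).to_csv(path, index=False)


def read_traces_csv(path, dialect: str = "simple", **dexcom_kwargs) -> list[GlucoseTrace]:
    """Read CGM traces from CSV.

    ``dialect='simple'`` expects the columns in :data:`TRACE_COLUMNS`, one row
    per reading.  ``dialect='dexcom'`` accepts a Dexcom-G6-export-like layout:
    a metadata preamble before the header row, EGV (estimated glucose value)
    rows identified by an ``Event Type`` column, glucose in a column whose
    name contains ``Glucose Value``, and ``Low``/``High`` rail readings mapped
    to the 40/400 mg/dL sensor limits.  For the Dexcom dialect pass
    ``participant_id``/``session_id``/``lot_id`` since the export carries none.
    """
    if dialect == "simple":
        df = pd.read_csv(path)
        missing = set(TRACE_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"trace CSV missing columns: {sorted(missing)}")
        out = []
        for (pid, sid), grp in df.groupby(["participant_id", "session_id"], sort=True):
            grp = grp.sort_values("timestamp")
            out.append(
                GlucoseTrace(
                    participant_id=str(pid),
                    session_id=str(sid),
                    lot_id=str(grp["lot_id"].iloc[0]),
                    times=pd.DatetimeIndex(pd.to_datetime(grp["timestamp"])),
                    glucose=grp["glucose_mg_dl"].to_numpy(dtype=float),
                )
            )
        return out
    if dialect == "dexcom":
        return [_read_dexcom_csv(path, **dexcom_kwargs)]
    raise ValueError(f"unknown dialect: {dialect!r}")


def _read_dexcom_csv(
    path,
    participant_id: str = "unknown",
    session_id: str = "1",
    lot_id: str = "unknown",
) -> GlucoseTrace:
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path, "r", encoding="utf-8-sig") as fh:
            text = fh.read()
    lines = text.splitlines()
    header_idx = next(
        (i for i, ln in enumerate(lines) if "Timestamp" in ln and "Event Type" in ln),
        None,
    )
    if header_idx is None:
        raise ValueError("no Dexcom-style header row found (need Timestamp + Event Type)")
    df = pd.read_csv(io.StringIO("\n".join(lines[header_idx:])))
    ts_col = next(c for c in df.columns if "Timestamp" in c)
    glu_col = next(c for c in df.columns if "Glucose Value" in c)
    egv = df[df["Event Type"].astype(str).str.strip() == "EGV"].copy()
    if egv.empty:
        raise ValueError("no EGV rows in Dexcom export")
    glucose = (
        egv[glu_col]
        .astype(str)
        .str.strip()
        .replace({"Low": str(SENSOR_FLOOR), "High": str(SENSOR_CEIL)})
        .astype(float)
        .to_numpy()
    )
    times = pd.DatetimeIndex(pd.to_datetime(egv[ts_col]))
    order = np.argsort(times.asi8, kind="stable")
    return GlucoseTrace(
        participant_id=participant_id,
        session_id=session_id,
        lot_id=lot_id,
        times=times[order],
        glucose=glucose[order],
    )


@dataclass
class ParticipantRecord:
    """One study participant.

    ``aab_count`` is the number of confirmed islet autoantibodies (>= 2
    defines early-stage type 1 diabetes); ``ogtt`` holds plasma glucose at
    0/30/60/90/120 minutes in mg/dL; ``progression_time`` is the observed
    time (years) to stage 3 onset or censoring.
    """

    participant_id: str
    age: float
    sex: str
    aab_count: int
    ogtt: tuple[float, float, float, float, float]
    hba1c: float
    followup_years: float
    progressed_stage3: bool
    progression_time: float

    def __post_init__(self) -> None:
        self.ogtt = tuple(float(v) for v in self.ogtt)
        if len(self.ogtt) != 5:
            raise ValueError("OGTT panel needs glucose at 0/30/60/90/120 min")
        if any(v <= 0 for v in self.ogtt):
            raise ValueError("OGTT glucose values must be positive")
        if not (0.0 <= self.hba1c <= 20.0):
            raise ValueError("HbA1c out of plausible range")
        if self.progressed_stage3 and self.progression_time > self.followup_years + 1e-9:
            raise ValueError("progression_time exceeds follow-up for a progressor")


def participants_to_frame(records: Sequence[ParticipantRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "participant_id": r.participant_id,
                "age": r.age,
                "sex": r.sex,
                "aab_count": r.aab_count,
                "ogtt_0": r.ogtt[0],
                "ogtt_30": r.ogtt[1],
                "ogtt_60": r.ogtt[2],
                "ogtt_90": r.ogtt[3],
                "ogtt_120": r.ogtt[4],
                "hba1c": r.hba1c,
                "followup_years": r.followup_years,
                "progressed_stage3": r.progressed_stage3,
                "progression_time": r.progression_time,
            }
        )
    return pd.DataFrame(rows, columns=PARTICIPANT_COLUMNS)


def frame_to_participants(df: pd.DataFrame) -> list[ParticipantRecord]:
    missing = set(PARTICIPANT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"participant table missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            ParticipantRecord(
                participant_id=str(row["participant_id"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                aab_count=int(row["aab_count"]),
                ogtt=(
                    row["ogtt_0"],
                    row["ogtt_30"],
                    row["ogtt_60"],
                    row["ogtt_90"],
                    row["ogtt_120"],
                ),
                hba1c=float(row["hba1c"]),
                followup_years=float(row["followup_years"]),
                progressed_stage3=bool(row["progressed_stage3"]),
                progression_time=float(row["progression_time"]),
            )
        )
    return out


def write_participants_csv(records: Sequence[ParticipantRecord], path) -> None:
    participants_to_frame(records).to_csv(path, index=False)


def read_participants_csv(path) -> list[ParticipantRecord]:
    return frame_to_participants(pd.read_csv(path))
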