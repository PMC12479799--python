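"""Readers and writers for the on-disk dialects.

* CGM CSV (LibreView-style): ``device,serial,timestamp,record_type,
  glucose_mmol_l``; record_type 0 = historic (15-min), 1 = scan; ISO-8601
  naive local timestamps.  A flag accepts mg/dL exports.
* Event log: JSON Lines, one record per diary event.
* Therapy parameters and titration prior state: JSON.
* Therapy history and trial summaries: CSV.

All writers produce files their readers accept losslessly (to timestamp
minute resolution).
"""

from __future__ import annotations

import json
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .core import MealStrategy, TherapyParameters, InvalidArgument
from .events import DoseEvent, EventLog, datetime_to_minutes, minutes_to_datetime
from .model import CgmTrace
from .titration import Recommendation, TitrationState

ISO = "%Y-%m-%dT%H:%M:%S"

CGM_COLUMNS = ["device", "serial", "timestamp", "record_type", "glucose_mmol_l"]


class ParseError(ValueError):
    """Malformed input file; the message names the offending line/record."""


def _fmt_time(minutes: float) -> str:
    return minutes_to_datetime(minutes).strftime(ISO)


def _parse_time(text: str) -> float:
    return datetime_to_minutes(datetime.strptime(text, ISO))


# -- CGM CSV ----------------------------------------------------------------


def write_cgm_csv(trace: CgmTrace, path, device: str = "sim", serial: str = "0") -> None:
    df = pd.DataFrame(
        {
            "device": device,
            "serial": serial,
            "timestamp": [_fmt_time(t) for t in trace.times],
            "record_type": trace.record_type,
            "glucose_mmol_l": np.round(trace.glucose, 4),
        }
    )
    df.to_csv(path, index=False)


def read_cgm_csv(path, mgdl: bool = False) -> CgmTrace:
    """Read a CGM export; set ``mgdl=True`` for mg/dL files.

    Rows are sorted; duplicate timestamps collapse keeping the last row.
    Malformed rows raise :class:`ParseError` naming the line number.
    """
    from .core import MGDL_PER_MMOLL

    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty file") from None
    if df.empty:
        raise ParseError(f"{path}: no records")
    missing = set(CGM_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    times, glucose, rtype = [], [], []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            times.append(_parse_time(row["timestamp"]))
            g = float(row["glucose_mmol_l"])
            rt = int(row["record_type"])
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: malformed row at line {line}: {exc}") from None
        if rt not in (0, 1):
            raise ParseError(f"{path}: bad record_type at line {line}")
        glucose.append(g / MGDL_PER_MMOLL if mgdl else g)
        rtype.append(rt)
    out = pd.DataFrame({"t": times, "g": glucose, "r": rtype})
    out = out.sort_values("t", kind="stable").drop_duplicates("t", keep="last")
    return CgmTrace(out["t"].to_numpy(), out["g"].to_numpy(), out["r"].to_numpy())


# -- event log JSONL --------------------------------------------------------

_EVENT_FIELDS = {
    "timestamp", "kind", "delivered", "carbs", "glucose", "arrow",
    "recommended", "overridden", "override_reason", "meal_type", "event_id",
}


def write_event_log(log: EventLog, path) -> None:
    with open(path, "w") as fh:
        for ev in log:
            rec = {
                "timestamp": _fmt_time(ev.timestamp),
                "kind": ev.kind.value,
                "delivered": round(ev.delivered, 4),
            }
            if ev.carbs is not None:
                rec["carbs"] = round(ev.carbs, 2)
            if ev.glucose is not None:
                rec["glucose"] = round(ev.glucose, 4)
            if ev.arrow is not None:
                rec["arrow"] = ev.arrow.value
            if ev.recommended is not None:
                rec["recommended"] = round(ev.recommended, 4)
            if ev.overridden:
                rec["overridden"] = True
                rec["override_reason"] = ev.override_reason.value
            if ev.meal_type is not None:
                rec["meal_type"] = ev.meal_type
            if ev.event_id is not None:
                rec["event_id"] = ev.event_id
            fh.write(json.dumps(rec) + "\n")


def read_event_log(path) -> EventLog:
    log = EventLog()
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"{path}: record {i}: invalid JSON ({exc})") from None
            unknown = set(rec) - _EVENT_FIELDS
            if unknown:
                raise ParseError(f"{path}: record {i}: unknown fields {sorted(unknown)}")
            try:
                ev = DoseEvent(
                    timestamp=_parse_time(rec["timestamp"]),
                    kind=rec["kind"],
                    delivered=float(rec["delivered"]),
                    carbs=rec.get("carbs"),
                    glucose=rec.get("glucose"),
                    arrow=rec.get("arrow"),
                    recommended=rec.get("recommended"),
                    override_reason=rec.get("override_reason", "none"),
                    meal_type=rec.get("meal_type"),
                    event_id=rec.get("event_id"),
                )
            except (KeyError, ValueError, InvalidArgument) as exc:
                raise ParseError(f"{path}: record {i}: {exc}") from None
            log.append(ev)
    return log


# -- therapy JSON -----------------------------------------------------------


def therapy_to_dict(t: TherapyParameters) -> dict:
    return {
        "basal_dose": t.basal_dose,
        "meal_strategy": t.meal_strategy.value,
        "carb_ratio": t.carb_ratio,
        "fixed_dose": t.fixed_dose,
        "isf": t.isf,
        "glucose_target": t.glucose_target,
        "active_insulin_time": t.active_insulin_time,
        "basal_increment": t.basal_increment,
        "bolus_increment": t.bolus_increment,
    }


def therapy_from_dict(d: dict) -> TherapyParameters:
    return TherapyParameters(**d)


def write_therapy(t: TherapyParameters, path) -> None:
    with open(path, "w") as fh:
        json.dump(therapy_to_dict(t), fh, indent=2)


def read_therapy(path) -> TherapyParameters:
    with open(path) as fh:
        return therapy_from_dict(json.load(fh))


# -- titration prior state JSON --------------------------------------------


def write_state(state: TitrationState, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "prior_log_median": state.prior_log_median.tolist(),
                "prior_log_sd": state.prior_log_sd.tolist(),
                "initial_log_sd": state.initial_log_sd.tolist(),
                "reference": therapy_to_dict(state.reference),
                "week": state.week,
            },
            fh, indent=2,
        )


def read_state(path) -> TitrationState:
    with open(path) as fh:
        d = json.load(fh)
    return TitrationState(
        prior_log_median=np.array(d["prior_log_median"]),
        prior_log_sd=np.array(d["prior_log_sd"]),
        initial_log_sd=np.array(d["initial_log_sd"]),
        reference=therapy_from_dict(d["reference"]),
        week=d["week"],
    )


# -- recommendation JSON ----------------------------------------------------


def recommendation_to_dict(rec: Recommendation) -> dict:
    return {
        "therapy": therapy_to_dict(rec.therapy),
        "weights": {k: float(v) for k, v in rec.weights.items()},
        "attenuations": rec.attenuations,
        "flagged": rec.flagged,
        "approved": rec.approved,
        "rationale": rec.rationale,
    }


def write_recommendation(rec: Recommendation, path) -> None:
    with open(path, "w") as fh:
        json.dump(recommendation_to_dict(rec), fh, indent=2)


# -- therapy history CSV ----------------------------------------------------


def therapy_history_row(week: int, t: TherapyParameters, flagged: bool, approved: bool) -> dict:
    cc = t.meal_strategy is MealStrategy.carb_counting
    return {
        "week": week,
        "basal_u": t.basal_dose,
        "cr_b": t.carb_ratio["breakfast"] if cc else "",
        "cr_l": t.carb_ratio["lunch"] if cc else "",
        "cr_d": t.carb_ratio["dinner"] if cc else "",
        "fd_b": "" if cc else t.fixed_dose["breakfast"],
        "fd_l": "" if cc else t.fixed_dose["lunch"],
        "fd_d": "" if cc else t.fixed_dose["dinner"],
        "flagged": flagged,
        "approved": approved,
    }


def write_therapy_history(rows: list[dict], path) -> None:
    pd.DataFrame(rows).to_csv(path, index=False)
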