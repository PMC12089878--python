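"""CSV schemas and (de)serialization for the five event-table families.

All tables are UTF-8, comma-separated, header row required, timestamps
ISO-8601 at second precision, one file per table.  Round-tripping any
bundle through these writers and readers is lossless at second-level
timestamp precision.
"""

from __future__ import annotations

from datetime import datetime
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .data_model import (
    ADRecord,
    AlarmEvent,
    MedicationAdministration,
    Prescription,
    StayInterval,
    VentParamSetting,
    VentParameter,
    VentStateRecord,
    classify_pac,
)

FILES = {
    "alarms": "alarms.csv",
    "stays": "stays.csv",
    "ads": "ad_records.csv",
    "vent_states": "vent_states.csv",
    "settings": "vent_settings.csv",
    "administrations": "medication_administrations.csv",
    "prescriptions": "prescriptions.csv",
}


def _ts(t: Optional[datetime]) -> str:
    return "" if t is None else t.strftime("%Y-%m-%dT%H:%M:%S")


def _parse_ts(s) -> Optional[datetime]:
    if s is None or (isinstance(s, float) and pd.isna(s)) or s == "":
        return None
    return datetime.strptime(str(s), "%Y-%m-%dT%H:%M:%S")


def _opt_float(v) -> Optional[float]:
    if v is None or v == "" or (isinstance(v, float) and pd.isna(v)):
        return None
    return float(v)


def write_bundle(bundle, directory: Path | str) -> None:
    """Write all tables of a bundle (and its ground-truth ledger, when
    present) to *directory*."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "alarm_id": a.alarm_id,
                "bed_id": a.bed_id,
                "start_time": _ts(a.start_time),
                "alarm_label": a.alarm_label,
                "threshold_direction": a.pac.direction.value,
            }
            for a in bundle.alarms
        ]
    , columns=['alarm_id', 'bed_id', 'start_time', 'alarm_label', 'threshold_direction']).to_csv(d / FILES["alarms"], index=False)
    pd.DataFrame(
        [
            {
                "stay_id": s.stay_id,
                "bed_id": s.bed_id,
                "admit_time": _ts(s.admit_time),
                "discharge_time": _ts(s.discharge_time),
            }
            for s in bundle.stays
        ]
    , columns=['stay_id', 'bed_id', 'admit_time', 'discharge_time']).to_csv(d / FILES["stays"], index=False)
    pd.DataFrame(
        [
            {
                "record_id": r.record_id,
                "stay_ref": r.stay_ref,
                "entry_text": r.entry_text,
                "insert_time": _ts(r.insert_time),
                "removal_time": _ts(r.removal_time),
            }
            for r in bundle.ads
        ]
    , columns=['record_id', 'stay_ref', 'entry_text', 'insert_time', 'removal_time']).to_csv(d / FILES["ads"], index=False)
    pd.DataFrame(
        [
            {
                "record_id": r.record_id,
                "stay_ref": r.stay_ref,
                "vd_text": r.vd_text,
                "vm_text": r.vm_text,
                "standby": int(r.standby),
                "time": _ts(r.time),
            }
            for r in bundle.vent_states
        ]
    , columns=['record_id', 'stay_ref', 'vd_text', 'vm_text', 'standby', 'time']).to_csv(d / FILES["vent_states"], index=False)
    pd.DataFrame(
        [
            {
                "record_id": r.record_id,
                "stay_ref": r.stay_ref,
                "parameter": r.parameter.value,
                "value": r.value,
                "time": _ts(r.time),
            }
            for r in bundle.settings
        ]
    , columns=['record_id', 'stay_ref', 'parameter', 'value', 'time']).to_csv(d / FILES["settings"], index=False)
    pd.DataFrame(
        [
            {
                "record_id": r.record_id,
                "stay_ref": r.stay_ref,
                "order_id": r.order_id,
                "drug_id": r.drug_id,
                "start_time": _ts(r.start_time),
                "end_time": _ts(r.end_time),
                "rate": r.rate,
                "rate_unit": r.rate_unit or "",
                "concentration": r.concentration,
                "concentration_unit": r.concentration_unit or "",
                "amount": r.amount,
                "amount_unit": r.amount_unit or "",
                "route_text": r.route_text,
            }
            for r in bundle.administrations
        ]
    , columns=['record_id', 'stay_ref', 'order_id', 'drug_id', 'start_time', 'end_time', 'rate', 'rate_unit', 'concentration', 'concentration_unit', 'amount', 'amount_unit', 'route_text']).to_csv(d / FILES["administrations"], index=False)
    pd.DataFrame(
        [
            {
                "order_id": p.order_id,
                "scheduled_time": _ts(p.scheduled_time),
                "stay_ref": p.stay_ref,
            }
            for p in bundle.prescriptions
        ]
    , columns=['order_id', 'scheduled_time', 'stay_ref']).to_csv(d / FILES["prescriptions"], index=False)
    if getattr(bundle, "ledger", None):
        bundle.ledger_frame().to_csv(d / "ledger.csv", index=False)


def _read(d: Path, key: str, required: Sequence[str]) -> pd.DataFrame:
    path = d / FILES[key]
    if not path.exists():
        return pd.DataFrame(columns=list(required))
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=list(required))
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required column(s) {missing}")
    return df


def read_bundle(directory: Path | str):
    """Read a directory of event tables into record lists.

    Returns a synthetic-data ``Bundle`` (without ledger) so the same object
    flows through the pipeline regardless of origin.
    """
    from .synthetic import Bundle

    d = Path(directory)
    b = Bundle()
    df = _read(d, "alarms", ["alarm_id", "bed_id", "start_time", "alarm_label"])
    for i, row in df.iterrows():
        try:
            direction = row.get("threshold_direction") or None
            b.alarms.append(
                AlarmEvent(
                    alarm_id=row["alarm_id"],
                    bed_id=row["bed_id"],
                    start_time=_parse_ts(row["start_time"]),
                    alarm_label=row["alarm_label"],
                    pac=classify_pac(row["alarm_label"], direction),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{FILES['alarms']} row {i + 2}: {exc}") from exc
    df = _read(d, "stays", ["stay_id", "bed_id", "admit_time", "discharge_time"])
    for i, row in df.iterrows():
        b.stays.append(
            StayInterval(
                row["stay_id"], row["bed_id"],
                _parse_ts(row["admit_time"]), _parse_ts(row["discharge_time"]),
            )
        )
    df = _read(d, "ads", ["record_id", "stay_ref", "entry_text", "insert_time"])
    for i, row in df.iterrows():
        b.ads.append(
            ADRecord(
                entry_text=row["entry_text"],
                insert_time=_parse_ts(row["insert_time"]),
                removal_time=_parse_ts(row.get("removal_time", "")),
                stay_ref=row["stay_ref"],
                record_id=row["record_id"],
            )
        )
    df = _read(d, "vent_states", ["record_id", "stay_ref", "vd_text", "vm_text", "standby", "time"])
    for i, row in df.iterrows():
        b.vent_states.append(
            VentStateRecord(
                vd_text=row["vd_text"],
                vm_text=row["vm_text"],
                standby=bool(int(row["standby"])),
                time=_parse_ts(row["time"]),
                stay_ref=row["stay_ref"],
                record_id=row["record_id"],
            )
        )
    df = _read(d, "settings", ["record_id", "stay_ref", "parameter", "value", "time"])
    for i, row in df.iterrows():
        try:
            b.settings.append(
                VentParamSetting(
                    parameter=VentParameter(row["parameter"]),
                    value=float(row["value"]),
                    time=_parse_ts(row["time"]),
                    stay_ref=row["stay_ref"],
                    record_id=row["record_id"],
                )
            )
        except ValueError as exc:
            raise ValueError(f"{FILES['settings']} row {i + 2}: {exc}") from exc
    df = _read(
        d, "administrations",
        ["record_id", "stay_ref", "order_id", "drug_id", "start_time", "end_time"],
    )
    for i, row in df.iterrows():
        try:
            b.administrations.append(
                MedicationAdministration(
                    order_id=row["order_id"],
                    drug_id=row["drug_id"],
                    start_time=_parse_ts(row["start_time"]),
                    end_time=_parse_ts(row["end_time"]),
                    stay_ref=row["stay_ref"],
                    rate=_opt_float(row.get("rate", "")),
                    rate_unit=(row.get("rate_unit") or None),
                    concentration=_opt_float(row.get("concentration", "")),
                    concentration_unit=(row.get("concentration_unit") or None),
                    amount=_opt_float(row.get("amount", "")),
                    amount_unit=(row.get("amount_unit") or None),
                    route_text=row.get("route_text", ""),
                    record_id=row["record_id"],
                )
            )
        except ValueError as exc:
            raise ValueError(f"{FILES['administrations']} row {i + 2}: {exc}") from exc
    df = _read(d, "prescriptions", ["order_id", "scheduled_time", "stay_ref"])
    for i, row in df.iterrows():
        b.prescriptions.append(
            Prescription(
                order_id=row["order_id"],
                scheduled_time=_parse_ts(row["scheduled_time"]),
                stay_ref=row["stay_ref"],
            )
        )
    return b
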