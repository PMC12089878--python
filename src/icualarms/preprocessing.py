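"""Turn raw alarm logs and PDMS extracts into clean, linked, rule-ready streams.

Four concerns live here:

* linking alarms to patient stays through bed id + timestamp,
* removing documented values not compatible with life (range table adapted
  from the MIMIC-III project conventions: physiological range, range
  compatible with life, min/max acceptable outliers),
* excluding regular planned interventions (matched against prescriptions
  made in advance — those are not reactions to an alarm), and
* modelling documentation-timestamp uncertainty: the PDMS input dialog
  rounds a large share of medication timestamps down to the nearest 5
  minutes, so a rounded timestamp really means "somewhere in the following
  5-minute interval".
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from typing import Optional, Sequence

import pandas as pd

from .data_model import (
    AlarmEvent,
    MedicationAdministration,
    Prescription,
    StayInterval,
    VentParamSetting,
)

__all__ = [
    "PhysiologicalRangeTable",
    "load_range_table",
    "link_alarms_to_stays",
    "filter_incompatible_values",
    "exclude_planned",
    "timestamp_uncertainty",
    "deduplicate",
]


@dataclass(frozen=True)
class VariableRange:
    phys_low: float
    phys_high: float
    life_low: float
    life_high: float
    outlier_low: float
    outlier_high: float

    def __post_init__(self) -> None:
        ok = (
            self.outlier_low <= self.life_low <= self.phys_low <= self.phys_high
            <= self.life_high <= self.outlier_high
        )
        if not ok:
            raise ValueError(
                "ranges must nest: physiological within compatible-with-life within outlier bounds"
            )


@dataclass(frozen=True)
class PhysiologicalRangeTable:
    """Per-variable plausibility bounds used to drop impossible documented values."""

    ranges: dict[str, VariableRange]

    def bounds(self, variable: str, which: str) -> Optional[tuple[float, float]]:
        r = self.ranges.get(variable)
        if r is None:
            return None
        if which == "life":
            return r.life_low, r.life_high
        if which == "outlier":
            return r.outlier_low, r.outlier_high
        raise ValueError("which must be 'life' or 'outlier'")


def load_range_table(path) -> PhysiologicalRangeTable:
    df = pd.read_csv(path)
    ranges = {
        str(row["variable"]): VariableRange(
            phys_low=float(row["phys_low"]),
            phys_high=float(row["phys_high"]),
            life_low=float(row["life_low"]),
            life_high=float(row["life_high"]),
            outlier_low=float(row["outlier_low"]),
            outlier_high=float(row["outlier_high"]),
        )
        for _, row in df.iterrows()
    }
    return PhysiologicalRangeTable(ranges=ranges)


def link_alarms_to_stays(
    alarms: Sequence[AlarmEvent],
    stays: Sequence[StayInterval],
) -> tuple[list[AlarmEvent], list[AlarmEvent]]:
    """Attach a stay reference to every alarm via its bed and timestamp.

    Stays are half-open [admission, discharge) intervals; intervals on one
    bed must not overlap.  Returns ``(linked, unlinked)``; unlinked alarms
    are excluded from annotation downstream.
    """
    by_bed: dict[str, list[StayInterval]] = {}
    for s in stays:
        by_bed.setdefault(s.bed_id, []).append(s)
    for bed, lst in by_bed.items():
        lst.sort(key=lambda s: s.admit_time)
        for a, b in zip(lst, lst[1:]):
            if b.admit_time < a.discharge_time:
                raise ValueError(
                    f"overlapping stays on bed {bed}: {a.stay_id} and {b.stay_id}"
                )

    linked: list[AlarmEvent] = []
    unlinked: list[AlarmEvent] = []
    for alarm in alarms:
        hit = next(
            (s for s in by_bed.get(alarm.bed_id, []) if s.contains(alarm.start_time)),
            None,
        )
        if hit is None:
            unlinked.append(alarm)
        else:
            linked.append(replace(alarm, stay_ref=hit.stay_id))
    return linked, unlinked


@dataclass
class FilterLog:
    kept: int = 0
    removed: int = 0
    unchecked: int = 0  # variable absent from the range table (passed with warning)
    removed_records: list = field(default_factory=list)


def filter_incompatible_values(
    settings: Sequence[VentParamSetting],
    range_table: PhysiologicalRangeTable,
    which: str = "life",
) -> tuple[list[VentParamSetting], FilterLog]:
    """Drop documented parameter values outside the chosen plausibility bounds.

    ``which`` selects the compatible-with-life range (default) or the wider
    acceptable-outlier bounds.  Order of surviving events is preserved and
    the log reconciles: input = kept + removed.
    """
    kept: list[VentParamSetting] = []
    log = FilterLog()
    for s in settings:
        b = range_table.bounds(s.parameter.value, which)
        if b is None:
            log.unchecked += 1
            kept.append(s)
            log.kept += 1
            continue
        lo, hi = b
        if lo <= s.value <= hi:
            kept.append(s)
            log.kept += 1
        else:
            log.removed += 1
            log.removed_records.append(s)
    return kept, log


def exclude_planned(
    administrations: Sequence[MedicationAdministration],
    prescriptions: Sequence[Prescription],
    tolerance: timedelta = timedelta(minutes=30),
) -> tuple[list[MedicationAdministration], list[MedicationAdministration]]:
    """Remove administrations that execute a prescription made in advance.

    An administration is planned iff a prescription shares its order id and
    its scheduled time lies within *tolerance* of the administration start.
    Returns ``(retained, excluded)``.
    """
    sched: dict[str, list[datetime]] = {}
    for p in prescriptions:
        sched.setdefault(p.order_id, []).append(p.scheduled_time)
    retained: list[MedicationAdministration] = []
    excluded: list[MedicationAdministration] = []
    for adm in administrations:
        times = sched.get(adm.order_id, ())
        if any(abs(adm.start_time - t) <= tolerance for t in times):
            excluded.append(adm)
        else:
            retained.append(adm)
    return retained, excluded


def timestamp_uncertainty(
    ts: datetime, granularity: timedelta
) -> tuple[datetime, datetime]:
    """Uncertainty interval of a possibly round-down-documented timestamp.

    A timestamp sitting exactly on the rounding grid may have been rounded
    down, so its true time lies in ``[ts, ts + granularity)``.  Off-grid
    timestamps were typed exactly: the degenerate interval ``[ts, ts]``.
    The grid is anchored at midnight of the timestamp's day.
    """
    if granularity <= timedelta(0):
        raise ValueError("granularity must be positive")
    midnight = ts.replace(hour=0, minute=0, second=0, microsecond=0)
    offset = ts - midnight
    if offset % granularity == timedelta(0):
        return ts, ts + granularity
    return ts, ts


def in_window_with_uncertainty(
    ts: datetime,
    window: tuple[datetime, datetime],
    granularity: timedelta,
    compensate: bool,
) -> bool:
    """Whether an event time falls in the half-open *window*, optionally
    treating on-grid timestamps as round-down uncertainty intervals.

    With compensation, the event matches iff its uncertainty interval
    intersects the window; without, iff the literal timestamp is inside.
    """
    lo, hi = window
    if not compensate:
        return lo <= ts < hi
    a, b = timestamp_uncertainty(ts, granularity)
    if a == b:
        return lo <= ts < hi
    return a < hi and b > lo


def deduplicate(records: Sequence) -> tuple[list, int]:
    """Drop exactly identical records, preserving first occurrence order."""
    seen: set = set()
    out: list = []
    dropped = 0
    for r in records:
        if r in seen:
            dropped += 1
        else:
            seen.add(r)
            out.append(r)
    return out, dropped
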