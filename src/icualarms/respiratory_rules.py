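"""Respiratory-management rules for oxygen-desaturation alarms.

Three rules decide whether respiratory care escalated in the 30 minutes
after an SpO2-low alarm:

1. **Change of airway device (AD)** — the maximum AD level documented in the
   window exceeds the level at alarm start, and no removal of the escalated
   device is logged in the window.
2. **Change of respiratory support therapy (RST)** — the maximum effective
   RST level in the window exceeds the effective level at alarm start.
   "Effective" handles ventilator standby: a device in standby delivers
   nothing, so its level counts as 0 — except during spontaneous breathing
   and plain oxygen therapy, where standby documentation carries no meaning
   and the mapped level is kept.
3. **Increase of a set ventilation parameter** — for each of six settable
   parameters (oxygen flow, FiO2, PEEP, pressure support, inspiratory
   pressure, set rate), the peak value set in the window exceeds the last
   value before the alarm.  A setting only counts when the parameter is
   actually settable under the effective RST level at the setting's time;
   incompatible or standby-time settings count as 0.

Escalations only: de-escalations of respiratory therapy are not
interventions under this rule set.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Optional, Sequence

from .data_model import (
    ADRecord,
    AlarmEvent,
    AnnotationConfig,
    MatchedIntervention,
    PAC,
    VentParamSetting,
    VentStateRecord,
    LOGICAL_PARAMETERS,
)
from .mappings import (
    MappingTables,
    STANDBY_EXEMPT_RST_LEVELS,
    UNMAPPED,
    is_settable,
    resolve_ad_level,
    resolve_rst,
)

__all__ = [
    "last_before",
    "max_in_window",
    "effective_rst_level",
    "rule_ad_change",
    "rule_rst_change",
    "rule_param_increase",
    "RuleOutcome",
]


@dataclass(frozen=True)
class RuleOutcome:
    fired: bool
    matches: tuple[MatchedIntervention, ...] = ()


_NOT_FIRED = RuleOutcome(False)


def last_before(series: Sequence[tuple[datetime, float]], t: datetime) -> Optional[float]:
    """Value of the latest event with time <= *t*; ``None`` if there is none.

    *series* must be time-sorted.  An event exactly at the alarm instant
    counts as "last before" — the state at alarm start includes entries
    documented at that instant.
    """
    idx = bisect.bisect_right([time for time, _ in series], t)
    if idx == 0:
        return None
    return series[idx - 1][1]


def max_in_window(
    series: Sequence[tuple[datetime, float]], t: datetime, w: timedelta
) -> Optional[float]:
    """Peak value among events in the half-open window ``[t, t + w)``."""
    if w <= timedelta(0):
        raise ValueError("window must be positive")
    vals = [v for time, v in series if t <= time < t + w]
    return max(vals) if vals else None


def _ad_category_at(
    t: datetime, ads: Sequence[ADRecord], mapping: MappingTables
) -> Optional[str]:
    """Category of the airway device in place at time *t* (None if none)."""
    current: Optional[ADRecord] = None
    for r in sorted(ads, key=lambda r: r.insert_time):
        if r.insert_time > t:
            break
        if resolve_ad_level(r.entry_text, mapping) is UNMAPPED:
            continue
        if r.removal_time is not None and r.removal_time <= t:
            current = None
            continue
        current = r
    if current is None:
        return None
    rows = mapping.ad[(mapping.ad["raw_text"] == current.entry_text) & mapping.ad["annotation_flag"]]
    return None if rows.empty else str(rows["category"].iloc[0])


def ad_level_at(t: datetime, ads: Sequence[ADRecord], mapping: MappingTables) -> int:
    """AD level in place at *t*: the latest inserted, not-yet-removed device.

    With nothing documented (or everything removed) the level is 1, "no AD".
    A newly documented device supersedes its predecessor even without a
    removal timestamp.
    """
    level = 1
    for r in sorted(ads, key=lambda r: r.insert_time):
        if r.insert_time > t:
            break
        lv = resolve_ad_level(r.entry_text, mapping)
        if lv is UNMAPPED:
            continue
        if r.removal_time is not None and r.removal_time <= t:
            level = 1
            continue
        level = int(lv)
    return level


def effective_rst_level(
    t: datetime,
    vent_states: Sequence[VentStateRecord],
    mapping: MappingTables,
    ads: Sequence[ADRecord] = (),
) -> Optional[int]:
    """Standby-aware RST level at time *t* (0-7), ``None`` when unresolvable.

    The governing record is the last VD-VM documentation at or before *t*.
    In standby the level is 0, except for spontaneous breathing and oxygen
    therapy, whose standby flag is meaningless and whose mapped level is
    kept.  With no documentation at all the patient counts as breathing
    spontaneously (level 1).  An unmapped VD-VM pair yields ``None``; rules
    consuming it do not fire on it.
    """
    current: Optional[VentStateRecord] = None
    for r in sorted(vent_states, key=lambda r: r.time):
        if r.time > t:
            break
        current = r
    if current is None:
        return 1
    ad_cat = _ad_category_at(t, ads, mapping) if ads else None
    resolved = resolve_rst(current.vd_text, current.vm_text, ad_cat, mapping)
    if resolved is UNMAPPED:
        return None
    _, level = resolved
    if current.standby and level not in STANDBY_EXEMPT_RST_LEVELS:
        return 0
    return level


def rule_ad_change(
    alarm: AlarmEvent,
    ads: Sequence[ADRecord],
    mapping: MappingTables,
    config: AnnotationConfig,
) -> RuleOutcome:
    """Fire iff an airway device above the alarm-start level is documented in
    the respiratory window and not removed again within it.

    A removal logged up to ``ad_removal_tolerance`` around the successor's
    insertion belongs to the *previous* device (late documentation of one
    change), so it does not veto the escalation.
    """
    if alarm.pac is not PAC.SPO2_LOW:
        return _NOT_FIRED
    t = alarm.start_time
    hi = t + config.resp_window
    last_level = ad_level_at(t, ads, mapping)
    matches = []
    for r in ads:
        if not (t <= r.insert_time < hi):
            continue
        lv = resolve_ad_level(r.entry_text, mapping)
        if lv is UNMAPPED or int(lv) <= last_level:
            continue
        removed_in_window = (
            r.removal_time is not None
            and r.insert_time + config.ad_removal_tolerance < r.removal_time < hi
        )
        if removed_in_window:
            continue
        matches.append(
            MatchedIntervention(
                rule_id="ad_change",
                record_id=r.record_id,
                matched_time=r.insert_time,
                detail=f"AD level {last_level} -> {int(lv)} ({r.entry_text})",
            )
        )
    return RuleOutcome(bool(matches), tuple(matches))


def rule_rst_change(
    alarm: AlarmEvent,
    vent_states: Sequence[VentStateRecord],
    mapping: MappingTables,
    config: AnnotationConfig,
    ads: Sequence[ADRecord] = (),
) -> RuleOutcome:
    """Fire iff the effective RST level rises above its alarm-start value
    within the respiratory window.

    Changes documented while the ventilator is in standby are effective
    level 0 and therefore never count as escalations.
    """
    if alarm.pac is not PAC.SPO2_LOW:
        return _NOT_FIRED
    t = alarm.start_time
    hi = t + config.resp_window
    last = effective_rst_level(t, vent_states, mapping, ads)
    if last is None:
        return _NOT_FIRED
    matches = []
    for r in sorted(vent_states, key=lambda r: r.time):
        if not (t <= r.time < hi):
            continue
        lvl = effective_rst_level(r.time, vent_states, mapping, ads)
        if lvl is None or lvl <= last:
            continue
        matches.append(
            MatchedIntervention(
                rule_id="rst_change",
                record_id=r.record_id,
                matched_time=r.time,
                detail=f"RST level {last} -> {lvl} ({r.vd_text}/{r.vm_text})",
            )
        )
    return RuleOutcome(bool(matches), tuple(matches))


def _setting_value(
    s: VentParamSetting,
    vent_states: Sequence[VentStateRecord],
    mapping: MappingTables,
    ads: Sequence[ADRecord],
) -> float:
    """Value a setting contributes: 0 when the parameter cannot be set under
    the effective RST level at the setting's time (incompatible therapy, or
    standby outside spontaneous breathing / oxygen therapy)."""
    lvl = effective_rst_level(s.time, vent_states, mapping, ads)
    if lvl is None or not is_settable(lvl, s.parameter, mapping):
        return 0.0
    return s.value


def rule_param_increase(
    alarm: AlarmEvent,
    logical_parameter: str,
    settings: Sequence[VentParamSetting],
    vent_states: Sequence[VentStateRecord],
    mapping: MappingTables,
    config: AnnotationConfig,
    ads: Sequence[ADRecord] = (),
) -> RuleOutcome:
    """Fire iff the peak settable value of the parameter in the window
    strictly exceeds the last value before the alarm.

    *logical_parameter* is one of the six rule-level parameters; the two
    oxygen-flow documentation variants count as one parameter, each variant
    checked against its own compatibility column.
    """
    if alarm.pac is not PAC.SPO2_LOW:
        return _NOT_FIRED
    variants = dict(LOGICAL_PARAMETERS).get(logical_parameter)
    if variants is None:
        raise ValueError(f"unknown logical parameter {logical_parameter!r}")
    t = alarm.start_time
    hi = t + config.resp_window
    relevant = sorted(
        (s for s in settings if s.parameter in variants), key=lambda s: s.time
    )
    before = [s for s in relevant if s.time <= t]
    if before:
        s = before[-1]
        lvl = effective_rst_level(t, vent_states, mapping, ads)
        last = (
            s.value
            if lvl is not None and is_settable(lvl, s.parameter, mapping)
            else 0.0
        )
    else:
        last = 0.0
    best: Optional[VentParamSetting] = None
    best_val = None
    for s in relevant:
        if not (t <= s.time < hi):
            continue
        v = _setting_value(s, vent_states, mapping, ads)
        if best_val is None or v > best_val:
            best, best_val = s, v
    if best is None or best_val is None or not best_val > last:
        return _NOT_FIRED
    return RuleOutcome(
        True,
        (
            MatchedIntervention(
                rule_id="param_increase",
                record_id=best.record_id,
                matched_time=best.time,
                detail=f"{logical_parameter} {last:g} -> {best_val:g}",
            ),
        ),
    )
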