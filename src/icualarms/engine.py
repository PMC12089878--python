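"""Orchestration: per-alarm rule selection, evaluation and dataset output.

The registry holds the method's eight general rules — three respiratory
(airway-device change, respiratory-support-therapy change, set-parameter
increase), applicable only to oxygen-desaturation alarms, and five
medication rules (bolus, start, increase, stop, decrease), applicable to
every alarm condition except that stop/decrease are excluded for
desaturation.  An alarm is actionable iff at least one applicable rule
fires; the result lists every fired rule and the matched intervention
records, so the annotation is auditable.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .data_model import (
    ADRecord,
    AlarmEvent,
    AnnotationConfig,
    AnnotationResult,
    Label,
    LOGICAL_PARAMETERS,
    MatchedIntervention,
    MedicationAdministration,
    PAC,
    VentParamSetting,
    VentStateRecord,
)
from .mappings import MappingTables
from . import medication_rules as med
from . import respiratory_rules as resp

__all__ = [
    "RULE_REGISTRY",
    "RuleDescriptor",
    "INTERVENTION_ACTIONS",
    "StayContext",
    "annotate_alarm",
    "annotate_dataset",
    "DatasetSummary",
    "RunCounts",
    "run_pipeline",
    "results_to_frame",
]


@dataclass(frozen=True)
class RuleDescriptor:
    rule_id: str
    family: str  # respiratory | medication
    applicable_pacs: frozenset[PAC]
    window: str  # resp_window | med_window


_ALL_PACS = frozenset(PAC)
_SPO2_ONLY = frozenset({PAC.SPO2_LOW})
_NO_SPO2 = frozenset(PAC) - {PAC.SPO2_LOW}

#: The eight general annotation rules.
RULE_REGISTRY: tuple[RuleDescriptor, ...] = (
    RuleDescriptor("ad_change", "respiratory", _SPO2_ONLY, "resp_window"),
    RuleDescriptor("rst_change", "respiratory", _SPO2_ONLY, "resp_window"),
    RuleDescriptor("param_increase", "respiratory", _SPO2_ONLY, "resp_window"),
    RuleDescriptor("bolus", "medication", _ALL_PACS, "med_window"),
    RuleDescriptor("start", "medication", _ALL_PACS, "med_window"),
    RuleDescriptor("increase", "medication", _ALL_PACS, "med_window"),
    RuleDescriptor("stop", "medication", _NO_SPO2, "med_window"),
    RuleDescriptor("decrease", "medication", _NO_SPO2, "med_window"),
)

#: The thirteen intervention actions the method recognises: the parameter
#: increase rule expands into one action per settable logical parameter.
INTERVENTION_ACTIONS: tuple[str, ...] = tuple(
    [f"param_increase:{name}" for name, _ in LOGICAL_PARAMETERS]
    + [d.rule_id for d in RULE_REGISTRY if d.rule_id != "param_increase"]
)


def applicable_rules(pac: PAC) -> list[RuleDescriptor]:
    return [d for d in RULE_REGISTRY if pac in d.applicable_pacs]


@dataclass(frozen=True)
class StayContext:
    """All intervention documentation of one stay, pre-sorted by the caller
    or not — rule outcomes are order-independent."""

    ads: tuple[ADRecord, ...] = ()
    vent_states: tuple[VentStateRecord, ...] = ()
    settings: tuple[VentParamSetting, ...] = ()
    episodes: tuple[med.AdministrationEpisode, ...] = ()


def annotate_alarm(
    alarm: AlarmEvent,
    context: StayContext,
    mapping: MappingTables,
    config: AnnotationConfig,
) -> AnnotationResult:
    """Evaluate every rule applicable to the alarm's condition.

    An alarm without a stay linkage cannot be matched to documentation and
    is labelled ``unlinked`` (excluded from actionability statistics).
    """
    if alarm.stay_ref is None:
        return AnnotationResult(alarm_id=alarm.alarm_id, pac=alarm.pac, label=Label.UNLINKED)

    t = alarm.start_time
    fired: set[str] = set()
    matches: list[MatchedIntervention] = []

    for desc in applicable_rules(alarm.pac):
        if desc.rule_id == "ad_change":
            out = resp.rule_ad_change(alarm, context.ads, mapping, config)
        elif desc.rule_id == "rst_change":
            out = resp.rule_rst_change(
                alarm, context.vent_states, mapping, config, context.ads
            )
        elif desc.rule_id == "param_increase":
            outs = [
                resp.rule_param_increase(
                    alarm, name, context.settings, context.vent_states,
                    mapping, config, context.ads,
                )
                for name, _ in LOGICAL_PARAMETERS
            ]
            out = resp.RuleOutcome(
                any(o.fired for o in outs),
                tuple(m for o in outs for m in o.matches),
            )
        elif desc.rule_id == "bolus":
            out = med.rule_bolus(alarm, context.episodes, mapping, config)
        elif desc.rule_id == "start":
            out = med.rule_start(alarm, context.episodes, mapping, config)
        elif desc.rule_id == "increase":
            out = med.rule_increase(alarm, context.episodes, mapping, config)
        elif desc.rule_id == "stop":
            out = med.rule_stop(alarm, context.episodes, mapping, config)
        elif desc.rule_id == "decrease":
            out = med.rule_decrease(alarm, context.episodes, mapping, config)
        else:  # pragma: no cover
            raise AssertionError(desc.rule_id)
        if out.fired:
            fired.add(desc.rule_id)
            matches.extend(out.matches)

    label = Label.ACTIONABLE if fired else Label.NONACTIONABLE
    return AnnotationResult(
        alarm_id=alarm.alarm_id,
        pac=alarm.pac,
        label=label,
        fired_rules=frozenset(fired),
        matched_interventions=tuple(matches),
        window_resp=(t, t + config.resp_window),
        window_med=(t, t + config.med_window),
    )


@dataclass
class DatasetSummary:
    n_alarms: int = 0
    n_actionable: int = 0
    n_nonactionable: int = 0
    n_unlinked: int = 0
    per_rule: dict[str, int] = field(default_factory=dict)
    per_pac: dict[str, dict[str, int]] = field(default_factory=dict)


def annotate_dataset(
    alarms: Sequence[AlarmEvent],
    contexts: dict[str, StayContext],
    mapping: MappingTables,
    config: AnnotationConfig,
) -> tuple[list[AnnotationResult], DatasetSummary]:
    """Annotate every alarm against its stay's documentation.

    Deterministic: results are returned in alarm order and are independent
    of the order of the context records.  Exactly one result per alarm.
    """
    empty = StayContext()
    results: list[AnnotationResult] = []
    summary = DatasetSummary()
    for alarm in alarms:
        ctx = contexts.get(alarm.stay_ref, empty) if alarm.stay_ref else empty
        res = annotate_alarm(alarm, ctx, mapping, config)
        results.append(res)
        summary.n_alarms += 1
        if res.label is Label.ACTIONABLE:
            summary.n_actionable += 1
        elif res.label is Label.NONACTIONABLE:
            summary.n_nonactionable += 1
        else:
            summary.n_unlinked += 1
        for rid in res.fired_rules:
            summary.per_rule[rid] = summary.per_rule.get(rid, 0) + 1
        pac_key = res.pac.value if res.pac else "unknown"
        bucket = summary.per_pac.setdefault(pac_key, {})
        bucket[res.label.value] = bucket.get(res.label.value, 0) + 1
    return results, summary


@dataclass
class RunCounts:
    """Reconciliation counters for the run manifest."""

    alarms_in: int = 0
    alarms_linked: int = 0
    alarms_unlinked: int = 0
    duplicates_dropped: int = 0
    settings_removed: int = 0
    administrations_excluded_planned: int = 0


def run_pipeline(
    alarms: Sequence[AlarmEvent],
    stays,
    ads: Sequence[ADRecord],
    vent_states: Sequence[VentStateRecord],
    settings: Sequence[VentParamSetting],
    administrations: Sequence[MedicationAdministration],
    prescriptions,
    mapping: MappingTables,
    config: AnnotationConfig,
    range_table=None,
) -> tuple[list[AnnotationResult], DatasetSummary, RunCounts]:
    """Full annotation run: deduplicate, link, filter, exclude planned
    interventions, build episodes, and annotate every alarm.

    Unlinked alarms are annotated with the ``unlinked`` label and excluded
    from actionability statistics.  Output order follows input alarm order.
    """
    from . import preprocessing as prep

    counts = RunCounts(alarms_in=len(alarms))
    alarms, d0 = prep.deduplicate(list(alarms))
    ads, d1 = prep.deduplicate(list(ads))
    vent_states, d2 = prep.deduplicate(list(vent_states))
    settings, d3 = prep.deduplicate(list(settings))
    administrations, d4 = prep.deduplicate(list(administrations))
    counts.duplicates_dropped = d0 + d1 + d2 + d3 + d4

    linked, unlinked = prep.link_alarms_to_stays(alarms, stays)
    counts.alarms_linked = len(linked)
    counts.alarms_unlinked = len(unlinked)

    if range_table is None:
        range_table = prep.load_range_table(
            str(importlib.resources.files("icualarms") / "data" / "range_table.csv")
        )
    settings, flog = prep.filter_incompatible_values(settings, range_table, config.range_bound)
    counts.settings_removed = flog.removed

    administrations, excluded = prep.exclude_planned(
        administrations, prescriptions, config.planned_match_tolerance
    )
    counts.administrations_excluded_planned = len(excluded)

    episodes = med.build_episodes(administrations, mapping, config)

    contexts: dict[str, dict] = {}
    for r in ads:
        contexts.setdefault(r.stay_ref, {"ads": [], "vs": [], "sp": [], "ep": []})["ads"].append(r)
    for r in vent_states:
        contexts.setdefault(r.stay_ref, {"ads": [], "vs": [], "sp": [], "ep": []})["vs"].append(r)
    for r in settings:
        contexts.setdefault(r.stay_ref, {"ads": [], "vs": [], "sp": [], "ep": []})["sp"].append(r)
    by_record = {a.record_id: a.stay_ref for a in administrations}
    for e in episodes:
        stay = by_record.get(e.record_id)
        if stay is not None:
            contexts.setdefault(stay, {"ads": [], "vs": [], "sp": [], "ep": []})["ep"].append(e)
    stay_contexts = {
        s: StayContext(
            ads=tuple(sorted(v["ads"], key=lambda r: (r.insert_time, r.record_id))),
            vent_states=tuple(sorted(v["vs"], key=lambda r: (r.time, r.record_id))),
            settings=tuple(sorted(v["sp"], key=lambda r: (r.time, r.record_id))),
            episodes=tuple(sorted(v["ep"], key=lambda e: (e.start, e.end, e.record_id))),
        )
        for s, v in contexts.items()
    }

    # keep input order, unlinked alarms included with stay_ref None
    unlinked_ids = {a.alarm_id for a in unlinked}
    linked_by_id = {a.alarm_id: a for a in linked}
    ordered = [
        linked_by_id.get(a.alarm_id, a) if a.alarm_id not in unlinked_ids else a
        for a in alarms
    ]
    results, summary = annotate_dataset(ordered, stay_contexts, mapping, config)
    return results, summary, counts


def results_to_frame(results: Sequence[AnnotationResult]) -> pd.DataFrame:
    """Long-format results table: one row per fired rule and matched
    intervention, plus one row with empty rule for alarms that fired none —
    each actionable alarm carries the reason it is actionable."""
    rows = []
    for r in results:
        base = {
            "alarm_id": r.alarm_id,
            "pac": r.pac.value if r.pac else "",
            "label": r.label.value,
            "window_resp_start": r.window_resp[0] if r.window_resp else None,
            "window_resp_end": r.window_resp[1] if r.window_resp else None,
            "window_med_start": r.window_med[0] if r.window_med else None,
            "window_med_end": r.window_med[1] if r.window_med else None,
        }
        if r.matched_interventions:
            for m in r.matched_interventions:
                rows.append(
                    base
                    | {
                        "rule_id": m.rule_id,
                        "matched_record": m.record_id,
                        "matched_time": m.matched_time,
                        "detail": m.detail,
                    }
                )
        else:
            rows.append(base | {"rule_id": "", "matched_record": "", "matched_time": None, "detail": ""})
    columns = [
        "alarm_id", "pac", "label", "rule_id", "matched_record", "matched_time",
        "detail", "window_resp_start", "window_resp_end",
        "window_med_start", "window_med_end",
    ]
    return pd.DataFrame(rows, columns=columns)
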