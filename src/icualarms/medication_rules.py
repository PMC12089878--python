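"""Medication-management rules over the 15-minute post-alarm window.

Two intervention families are recognised, each per single active ingredient
(mixtures count as one ingredient-unit via the mixture mapping):

* administration or increase in dosage — for every alarm condition;
* administration stopped or reduction in dosage — for every alarm condition
  except oxygen desaturation (stopping a drug does not raise SpO2).

Administration technique is derived from the documented timestamps: a row
whose start equals its end is a bolus, anything else is a continuous
intravenous administration.  Continuous rates are only comparable in the
same unit and concentration; with differing concentrations the administered
dose per time (rate x concentration) is compared instead.

Intravenous fluids play a double role: below 500 mL/h a fluid is a carrier
(diluent) for another drug and is ignored by all rules; at or above the
threshold it is a volume therapy in its own right.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from datetime import datetime, timedelta
from functools import lru_cache
from typing import Optional, Sequence

import pandas as pd

from .data_model import (
    AlarmEvent,
    AnnotationConfig,
    MatchedIntervention,
    MedicationAdministration,
    PAC,
)
from .mappings import MappingTables, medication_relevant
from .preprocessing import in_window_with_uncertainty, timestamp_uncertainty
from .respiratory_rules import RuleOutcome

__all__ = [
    "AdministrationEpisode",
    "build_episodes",
    "classify_technique",
    "comparable_rate",
    "fluid_role",
    "rule_bolus",
    "rule_start",
    "rule_increase",
    "rule_stop",
    "rule_decrease",
]

_NOT_FIRED = RuleOutcome(False)


# ---- units ---------------------------------------------------------------


@lru_cache(maxsize=1)
def _unit_table() -> dict[str, tuple[str, float]]:
    path = importlib.resources.files("icualarms") / "data" / "units.csv"
    df = pd.read_csv(str(path))
    return {
        str(r["unit"]): (str(r["dimension"]), float(r["factor"]))
        for _, r in df.iterrows()
    }


def _to_base(value: float, unit: str) -> Optional[tuple[str, float]]:
    """Convert a value to its base unit; ``None`` for an unknown unit.

    Base units: mL (volume), mg (mass), per hour (time denominators),
    mg/mL (concentration).
    """
    entry = _unit_table().get(unit)
    if entry is None:
        return None
    dim, factor = entry
    return dim, value * factor


# ---- episodes ------------------------------------------------------------


def classify_technique(admin: MedicationAdministration) -> str:
    """Administration technique: bolus iff start time equals end time."""
    return "bolus" if admin.start_time == admin.end_time else "continuous"


@dataclass(frozen=True)
class AdministrationEpisode:
    """One administration of one ingredient-unit, ready for rule evaluation.

    ``ingredient_key`` is a single active ingredient, or the sorted
    pipe-joined set for a mixture product (rules treat a relevant mixture as
    one ingredient).
    """

    ingredient_key: str
    technique: str  # bolus | continuous
    start: datetime
    end: datetime
    order_id: str
    drug_id: str
    rate: Optional[float] = None
    rate_unit: Optional[str] = None
    concentration: Optional[float] = None
    concentration_unit: Optional[str] = None
    amount: Optional[float] = None
    amount_unit: Optional[str] = None
    record_id: str = ""

    def __post_init__(self) -> None:
        if self.technique == "continuous" and self.end <= self.start:
            raise ValueError("continuous episode needs end > start")


def fluid_role(
    admin_or_episode, threshold_ml_per_h: float = 500.0
) -> str:
    """Role of an intravenous fluid: ``"carrier"`` below the threshold
    (rate, or bolus amount, under 500 mL/h resp. 500 mL), ``"therapy"``
    at or above it.  With neither rate nor amount documented the fluid is
    conservatively a carrier.
    """
    e = admin_or_episode
    if e.rate is not None and e.rate_unit is not None:
        conv = _to_base(e.rate, e.rate_unit)
        if conv is not None and conv[0] == "volume_per_time":
            return "therapy" if conv[1] >= threshold_ml_per_h else "carrier"
    if e.amount is not None and e.amount_unit is not None:
        conv = _to_base(e.amount, e.amount_unit)
        if conv is not None and conv[0] == "volume":
            return "therapy" if conv[1] >= threshold_ml_per_h else "carrier"
    return "carrier"


def build_episodes(
    administrations: Sequence[MedicationAdministration],
    mapping: MappingTables,
    config: AnnotationConfig,
) -> list[AdministrationEpisode]:
    """Resolve administration rows to ingredient-level episodes.

    Rows with an unknown drug id are dropped (they can never be
    annotation-relevant); carrier fluids are dropped as vehicles, not
    therapies.
    """
    episodes: list[AdministrationEpisode] = []
    med = mapping.medication
    for adm in administrations:
        if adm.drug_id not in med.index:
            continue
        row = med.loc[adm.drug_id]
        ingredients = sorted(str(row["active_ingredients"]).split("|"))
        key = "|".join(ingredients)
        ep = AdministrationEpisode(
            ingredient_key=key,
            technique=classify_technique(adm),
            start=adm.start_time,
            end=adm.end_time,
            order_id=adm.order_id,
            drug_id=adm.drug_id,
            rate=adm.rate,
            rate_unit=adm.rate_unit,
            concentration=adm.concentration,
            concentration_unit=adm.concentration_unit,
            amount=adm.amount,
            amount_unit=adm.amount_unit,
            record_id=adm.record_id,
        )
        if bool(row["is_iv_fluid"]) and fluid_role(
            ep, config.fluid_carrier_threshold_ml_per_h
        ) == "carrier":
            continue
        episodes.append(ep)
    episodes.sort(key=lambda e: (e.start, e.end, e.record_id))
    return episodes


# ---- rate comparison -----------------------------------------------------


def _dose_per_time(e: AdministrationEpisode) -> Optional[tuple[str, float]]:
    """Episode throughput in a comparable base dimension.

    A mass-per-time rate converts directly; a volume-per-time rate needs the
    concentration to become a dose per time.  Returns ``None`` when the
    episode cannot be expressed canonically (unknown unit, missing
    concentration, or per-kilogram rate without a bodyweight).
    """
    if e.rate is None or e.rate_unit is None:
        return None
    conv = _to_base(e.rate, e.rate_unit)
    if conv is None:
        return None
    dim, val = conv
    if dim == "mass_per_time":
        return dim, val
    if dim == "volume_per_time":
        if e.concentration is None or e.concentration_unit is None:
            return None
        cconv = _to_base(e.concentration, e.concentration_unit)
        if cconv is None or cconv[0] != "mass_per_volume":
            return None
        return "mass_per_time", val * cconv[1]
    return None


def comparable_rate(
    a: AdministrationEpisode, b: AdministrationEpisode
) -> str:
    """Ordered comparison of two continuous administrations of one ingredient.

    Returns ``"greater"`` / ``"less"`` / ``"equal"`` (of *a* relative to
    *b*) or ``"incomparable"``.  Same unit and same concentration compare by
    rate; differing concentrations compare by administered dose per time.
    """
    if a.technique != "continuous" or b.technique != "continuous":
        return "incomparable"
    same_conc = (
        a.concentration == b.concentration
        and a.concentration_unit == b.concentration_unit
    )
    if a.rate is None or b.rate is None or a.rate_unit is None or b.rate_unit is None:
        return "incomparable"
    if same_conc:
        ca = _to_base(a.rate, a.rate_unit)
        cb = _to_base(b.rate, b.rate_unit)
        if ca is None or cb is None or ca[0] != cb[0]:
            return "incomparable"
        va, vb = ca[1], cb[1]
    else:
        da = _dose_per_time(a)
        db = _dose_per_time(b)
        if da is None or db is None or da[0] != db[0]:
            return "incomparable"
        va, vb = da[1], db[1]
    if va > vb:
        return "greater"
    if va < vb:
        return "less"
    return "equal"


# ---- the five rules ------------------------------------------------------


def _relevant(
    episodes: Sequence[AdministrationEpisode],
    pac: PAC,
    intervention_type: str,
    mapping: MappingTables,
) -> list[AdministrationEpisode]:
    out = []
    for e in episodes:
        ingredients = e.ingredient_key.split("|")
        if len(ingredients) >= 2:
            rel = medication_relevant(frozenset(ingredients), pac, intervention_type, mapping)
        else:
            rel = medication_relevant(e.drug_id, pac, intervention_type, mapping)
        if rel:
            out.append(e)
    return out


def _same_ingredient(
    episodes: Sequence[AdministrationEpisode], e: AdministrationEpisode
) -> list[AdministrationEpisode]:
    return [o for o in episodes if o.ingredient_key == e.ingredient_key and o is not e]


def _uncertain(ts: datetime, config: AnnotationConfig) -> tuple[datetime, datetime]:
    """Uncertainty interval of a documented time under the active
    compensation policy (degenerate when compensation is off or the
    timestamp is off the rounding grid)."""
    if config.compensate_rounding:
        return timestamp_uncertainty(ts, config.rounding_granularity)
    return ts, ts


def _possibly_adjacent(
    end_ts: datetime, start_ts: datetime, gap: timedelta, config: AnnotationConfig
) -> bool:
    """Whether some realization of the two uncertain timestamps satisfies
    ``0 <= start - end <= gap`` — an episode pair that may be one continued
    administration rather than an independent stop plus start.

    With degenerate intervals this is the literal adjacency test.
    """
    x0, x1 = _uncertain(end_ts, config)
    y0, y1 = _uncertain(start_ts, config)
    return x0 <= y1 and y0 - x1 <= gap


def _certainly_parallel(
    o: AdministrationEpisode, t: datetime, config: AnnotationConfig
) -> bool:
    """Whether *o* runs at instant *t* under every realization of the
    uncertain timestamps.  Parallel lines only veto a start/stop when the
    overlap is certain; an overlap that exists merely in some realization
    must not suppress an otherwise-documented intervention."""
    s0, s1 = _uncertain(o.start, config)
    e0, e1 = _uncertain(o.end, config)
    t0, t1 = _uncertain(t, config)
    if t0 == t1:
        return s1 <= t0 < e0
    return s1 <= t0 and t1 <= e0


def _parallel_at(
    episodes: Sequence[AdministrationEpisode],
    e: AdministrationEpisode,
    t: datetime,
    config: AnnotationConfig,
) -> bool:
    """A same-ingredient continuous episode certainly overlapping instant *t*."""
    return any(
        o.technique == "continuous" and _certainly_parallel(o, t, config)
        for o in _same_ingredient(episodes, e)
    )


def _in_med_window(ts: datetime, alarm: AlarmEvent, config: AnnotationConfig) -> bool:
    window = (alarm.start_time, alarm.start_time + config.med_window)
    return in_window_with_uncertainty(
        ts, window, config.rounding_granularity, config.compensate_rounding
    )


def _predecessor(
    episodes: Sequence[AdministrationEpisode],
    e: AdministrationEpisode,
    gap: timedelta,
    config: AnnotationConfig,
) -> Optional[AdministrationEpisode]:
    """Latest same-ingredient continuous episode possibly ending within
    [start - gap, start]."""
    cands = [
        o
        for o in _same_ingredient(episodes, e)
        if o.technique == "continuous" and _possibly_adjacent(o.end, e.start, gap, config)
    ]
    return max(cands, key=lambda o: (o.end, o.record_id)) if cands else None


def _successor(
    episodes: Sequence[AdministrationEpisode],
    e: AdministrationEpisode,
    gap: timedelta,
    config: AnnotationConfig,
) -> Optional[AdministrationEpisode]:
    """Earliest same-ingredient continuous episode possibly starting within
    [end, end + gap]."""
    cands = [
        o
        for o in _same_ingredient(episodes, e)
        if o.technique == "continuous" and _possibly_adjacent(e.end, o.start, gap, config)
    ]
    return min(cands, key=lambda o: (o.start, o.record_id)) if cands else None


def rule_bolus(
    alarm: AlarmEvent,
    episodes: Sequence[AdministrationEpisode],
    mapping: MappingTables,
    config: AnnotationConfig,
) -> RuleOutcome:
    """A relevant bolus administered within the medication window."""
    rel = _relevant(episodes, alarm.pac, "give_or_increase", mapping)
    matches = tuple(
        MatchedIntervention("bolus", e.record_id, e.start, f"bolus {e.ingredient_key}")
        for e in rel
        if e.technique == "bolus" and _in_med_window(e.start, alarm, config)
    )
    return RuleOutcome(bool(matches), matches)


def rule_start(
    alarm: AlarmEvent,
    episodes: Sequence[AdministrationEpisode],
    mapping: MappingTables,
    config: AnnotationConfig,
) -> RuleOutcome:
    """A genuinely new continuous administration starts within the window:
    no predecessor of the same ingredient ended within the adjacency gap
    before it (that would be a rate change) and none runs in parallel."""
    rel = _relevant(episodes, alarm.pac, "give_or_increase", mapping)
    matches = []
    for e in rel:
        if e.technique != "continuous" or not _in_med_window(e.start, alarm, config):
            continue
        if _predecessor(rel, e, config.med_adjacency_gap, config) is not None:
            continue  # candidate for the increase rule instead
        if _parallel_at(rel, e, e.start, config):
            continue
        matches.append(
            MatchedIntervention("start", e.record_id, e.start, f"start {e.ingredient_key}")
        )
    return RuleOutcome(bool(matches), tuple(matches))


def rule_increase(
    alarm: AlarmEvent,
    episodes: Sequence[AdministrationEpisode],
    mapping: MappingTables,
    config: AnnotationConfig,
) -> RuleOutcome:
    """A continuous administration starting in the window continues a
    predecessor that ended within the adjacency gap, at a higher rate
    (dose per time when concentrations differ)."""
    rel = _relevant(episodes, alarm.pac, "give_or_increase", mapping)
    matches = []
    for e in rel:
        if e.technique != "continuous" or not _in_med_window(e.start, alarm, config):
            continue
        prev = _predecessor(rel, e, config.med_adjacency_gap, config)
        if prev is None:
            continue
        if comparable_rate(e, prev) == "greater":
            matches.append(
                MatchedIntervention(
                    "increase", e.record_id, e.start,
                    f"increase {e.ingredient_key} ({prev.rate}{prev.rate_unit} -> {e.rate}{e.rate_unit})",
                )
            )
    return RuleOutcome(bool(matches), tuple(matches))


def rule_stop(
    alarm: AlarmEvent,
    episodes: Sequence[AdministrationEpisode],
    mapping: MappingTables,
    config: AnnotationConfig,
) -> RuleOutcome:
    """A continuous administration ends within the window with no restart of
    the same ingredient within the adjacency gap and none running in
    parallel.  Never fires for oxygen-desaturation alarms."""
    if alarm.pac is PAC.SPO2_LOW:
        return _NOT_FIRED
    rel = _relevant(episodes, alarm.pac, "stop_or_decrease", mapping)
    matches = []
    for e in rel:
        if e.technique != "continuous" or not _in_med_window(e.end, alarm, config):
            continue
        if _successor(rel, e, config.med_adjacency_gap, config) is not None:
            continue  # candidate for the decrease rule instead
        if _parallel_at(rel, e, e.end, config):
            continue
        matches.append(
            MatchedIntervention("stop", e.record_id, e.end, f"stop {e.ingredient_key}")
        )
    return RuleOutcome(bool(matches), tuple(matches))


def rule_decrease(
    alarm: AlarmEvent,
    episodes: Sequence[AdministrationEpisode],
    mapping: MappingTables,
    config: AnnotationConfig,
) -> RuleOutcome:
    """A continuous administration ending in the window is continued within
    the adjacency gap at a lower rate.  Never fires for oxygen-desaturation
    alarms."""
    if alarm.pac is PAC.SPO2_LOW:
        return _NOT_FIRED
    rel = _relevant(episodes, alarm.pac, "stop_or_decrease", mapping)
    matches = []
    for e in rel:
        if e.technique != "continuous" or not _in_med_window(e.end, alarm, config):
            continue
        nxt = _successor(rel, e, config.med_adjacency_gap, config)
        if nxt is None:
            continue
        if comparable_rate(e, nxt) == "greater":
            matches.append(
                MatchedIntervention(
                    "decrease", nxt.record_id, nxt.start,
                    f"decrease {e.ingredient_key} ({e.rate}{e.rate_unit} -> {nxt.rate}{nxt.rate_unit})",
                )
            )
    return RuleOutcome(bool(matches), tuple(matches))
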