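"""Brute-force reference evaluator for the annotation rules.

Re-derives every rule condition with plain exhaustive scans over all
records, independent of the windowed engine implementation.  Used to check
engine/oracle equivalence on small random instances.
"""

from datetime import timedelta

from icualarms.data_model import PAC, LOGICAL_PARAMETERS
from icualarms.mappings import (
    STANDBY_EXEMPT_RST_LEVELS,
    UNMAPPED,
    is_settable,
    medication_relevant,
    resolve_ad_level,
    resolve_rst,
)


def _interval(ts, config):
    """Round-down uncertainty interval, re-derived."""
    if not config.compensate_rounding:
        return ts, ts
    day = ts.replace(hour=0, minute=0, second=0, microsecond=0)
    if (ts - day) % config.rounding_granularity == timedelta(0):
        return ts, ts + config.rounding_granularity
    return ts, ts


def _in_window(ts, lo, hi, config):
    a, b = _interval(ts, config)
    if a == b:
        return lo <= ts < hi
    return a < hi and b > lo


def _possibly_adjacent(end_ts, start_ts, gap, config):
    x0, x1 = _interval(end_ts, config)
    y0, y1 = _interval(start_ts, config)
    return x0 <= y1 and y0 - x1 <= gap


def _certainly_parallel(o, t, config):
    s0, s1 = _interval(o.start, config)
    e0, e1 = _interval(o.end, config)
    t0, t1 = _interval(t, config)
    if t0 == t1:
        return s1 <= t0 < e0
    return s1 <= t0 and t1 <= e0


def _ad_level_at(t, ads, mapping):
    level = 1
    for r in sorted(ads, key=lambda r: r.insert_time):
        if r.insert_time > t:
            break
        lv = resolve_ad_level(r.entry_text, mapping)
        if lv is UNMAPPED:
            continue
        if r.removal_time is not None and r.removal_time <= t:
            level = 1
        else:
            level = int(lv)
    return level


def _ad_category_at(t, ads, mapping):
    current = None
    for r in sorted(ads, key=lambda r: r.insert_time):
        if r.insert_time > t:
            break
        if resolve_ad_level(r.entry_text, mapping) is UNMAPPED:
            continue
        if r.removal_time is not None and r.removal_time <= t:
            current = None
        else:
            current = r
    if current is None:
        return None
    rows = mapping.ad[
        (mapping.ad["raw_text"] == current.entry_text) & mapping.ad["annotation_flag"]
    ]
    return None if rows.empty else str(rows["category"].iloc[0])


def _eff_level(t, vents, ads, mapping):
    current = None
    for r in sorted(vents, key=lambda r: r.time):
        if r.time > t:
            break
        current = r
    if current is None:
        return 1
    cat = _ad_category_at(t, ads, mapping) if ads else None
    res = resolve_rst(current.vd_text, current.vm_text, cat, mapping)
    if res is UNMAPPED:
        return None
    _, lvl = res
    if current.standby and lvl not in STANDBY_EXEMPT_RST_LEVELS:
        return 0
    return lvl


def oracle_fired_rules(alarm, ads, vents, settings, episodes, mapping, config):
    """All rules that fire for one alarm, by exhaustive scanning."""
    fired = set()
    t = alarm.start_time

    if alarm.pac is PAC.SPO2_LOW:
        hi = t + config.resp_window
        last_ad = _ad_level_at(t, ads, mapping)
        for r in ads:
            if not (t <= r.insert_time < hi):
                continue
            lv = resolve_ad_level(r.entry_text, mapping)
            if lv is UNMAPPED or int(lv) <= last_ad:
                continue
            removed = (
                r.removal_time is not None
                and r.insert_time + config.ad_removal_tolerance < r.removal_time < hi
            )
            if not removed:
                fired.add("ad_change")

        last_eff = _eff_level(t, vents, ads, mapping)
        if last_eff is not None:
            for r in vents:
                if t <= r.time < hi:
                    lvl = _eff_level(r.time, vents, ads, mapping)
                    if lvl is not None and lvl > last_eff:
                        fired.add("rst_change")

        for name, variants in LOGICAL_PARAMETERS:
            series = sorted(
                (s for s in settings if s.parameter in variants), key=lambda s: s.time
            )
            before = [s for s in series if s.time <= t]
            last = 0.0
            if before:
                s = before[-1]
                lvl = _eff_level(t, vents, ads, mapping)
                if lvl is not None and is_settable(lvl, s.parameter, mapping):
                    last = s.value
            for s in series:
                if not (t <= s.time < hi):
                    continue
                lvl = _eff_level(s.time, vents, ads, mapping)
                v = s.value if (lvl is not None and is_settable(lvl, s.parameter, mapping)) else 0.0
                if v > last:
                    fired.add("param_increase")

    med_hi = t + config.med_window
    gap = config.med_adjacency_gap

    def relevant(kind):
        out = []
        for e in episodes:
            ing = e.ingredient_key.split("|")
            key = frozenset(ing) if len(ing) >= 2 else e.drug_id
            if medication_relevant(key, alarm.pac, kind, mapping):
                out.append(e)
        return out

    gi = relevant("give_or_increase")
    for e in gi:
        if e.technique == "bolus" and _in_window(e.start, t, med_hi, config):
            fired.add("bolus")

    for e in gi:
        if e.technique != "continuous" or not _in_window(e.start, t, med_hi, config):
            continue
        others = [o for o in gi if o is not e and o.ingredient_key == e.ingredient_key]
        preds = [
            o for o in others
            if o.technique == "continuous" and _possibly_adjacent(o.end, e.start, gap, config)
        ]
        if preds:
            prev = max(preds, key=lambda o: (o.end, o.record_id))
            from icualarms.medication_rules import comparable_rate

            if comparable_rate(e, prev) == "greater":
                fired.add("increase")
        else:
            if not any(
                o.technique == "continuous" and _certainly_parallel(o, e.start, config)
                for o in others
            ):
                fired.add("start")

    if alarm.pac is not PAC.SPO2_LOW:
        sd = relevant("stop_or_decrease")
        for e in sd:
            if e.technique != "continuous" or not _in_window(e.end, t, med_hi, config):
                continue
            others = [o for o in sd if o is not e and o.ingredient_key == e.ingredient_key]
            succs = [
                o for o in others
                if o.technique == "continuous" and _possibly_adjacent(e.end, o.start, gap, config)
            ]
            if succs:
                nxt = min(succs, key=lambda o: (o.start, o.record_id))
                from icualarms.medication_rules import comparable_rate

                if comparable_rate(e, nxt) == "greater":
                    fired.add("decrease")
            else:
                if not any(
                    o.technique == "continuous" and _certainly_parallel(o, e.end, config)
                    for o in others
                ):
                    fired.add("stop")
    return fired
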