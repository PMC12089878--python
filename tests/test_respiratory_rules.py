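"""Respiratory rules: window extraction, standby semantics, the three rules."""

import random
from datetime import datetime, timedelta

import pytest
from hypothesis import given, strategies as st

from icualarms import AnnotationConfig, PAC
from icualarms.data_model import (
    ADRecord,
    AlarmEvent,
    VentParamSetting,
    VentParameter,
    VentStateRecord,
)
from icualarms.respiratory_rules import (
    effective_rst_level,
    last_before,
    max_in_window,
    rule_ad_change,
    rule_param_increase,
    rule_rst_change,
)

T = datetime(2024, 1, 1, 12, 0, 7)


def _alarm(t=T):
    return AlarmEvent("a1", "B1", t, "Desat", PAC.SPO2_LOW, stay_ref="s1")


def _mins(m):
    return T + timedelta(minutes=m)


class TestSeriesExtraction:
    def test_last_before_takes_latest_at_or_before(self):
        series = [(_mins(-30), 0.3), (_mins(-10), 0.4)]
        assert last_before(series, T) == 0.4

    def test_last_before_empty(self):
        assert last_before([], T) is None

    def test_event_exactly_at_alarm_counts_as_last(self):
        series = [(_mins(-30), 0.3), (T, 0.5)]
        assert last_before(series, T) == 0.5

    def test_max_in_window_peak(self):
        series = [(_mins(5), 0.4), (_mins(12), 0.6), (_mins(40), 0.5)]
        assert max_in_window(series, T, timedelta(minutes=30)) == 0.6

    def test_max_in_window_empty(self):
        assert max_in_window([(_mins(40), 1.0)], T, timedelta(minutes=30)) is None

    @given(
        st.lists(
            st.tuples(st.integers(-120, 120), st.floats(0, 100, allow_nan=False)),
            max_size=30,
        ),
        st.integers(1, 60),
    )
    def test_against_exhaustive_scan(self, events, w_min):
        series = sorted(((_mins(m), v) for m, v in events), key=lambda e: e[0])
        w = timedelta(minutes=w_min)
        in_w = [v for t, v in series if T <= t < T + w]
        assert max_in_window(series, T, w) == (max(in_w) if in_w else None)
        before = [v for t, v in series if t <= T]
        assert last_before(series, T) == (before[-1] if before else None)


class TestEffectiveRSTLevel:
    def test_no_documentation_means_spontaneous(self, mapping):
        assert effective_rst_level(T, [], mapping) == 1

    def test_mapped_level_without_standby(self, mapping):
        vents = [VentStateRecord("Evita", "BIPAP/ASB", False, _mins(-60), "s1")]
        assert effective_rst_level(T, vents, mapping) == 6

    def test_standby_zeroes_higher_therapies(self, mapping):
        vents = [VentStateRecord("Evita", "BIPAP/ASB", True, _mins(-60), "s1")]
        assert effective_rst_level(T, vents, mapping) == 0

    @pytest.mark.parametrize("vd,vm", [("none", "spontan"), ("O2-Brille", "O2-Insufflation")])
    def test_standby_meaningless_for_spontaneous_and_oxygen_therapy(self, mapping, vd, vm):
        vents = [VentStateRecord(vd, vm, True, _mins(-60), "s1")]
        assert effective_rst_level(T, vents, mapping) >= 1

    def test_unmapped_pair_is_unresolvable(self, mapping):
        vents = [VentStateRecord("Mars", "Warp", False, _mins(-60), "s1")]
        assert effective_rst_level(T, vents, mapping) is None


class TestADChangeRule:
    def _ad(self, text, at, removal=None, rid="ad1"):
        return ADRecord(text, at, removal, "s1", rid)

    def test_escalation_without_removal_fires(self, mapping, config):
        out = rule_ad_change(_alarm(), [self._ad("Tubus", _mins(10))], mapping, config)
        assert out.fired and out.matches[0].matched_time == _mins(10)

    def test_no_new_device_does_not_fire(self, mapping, config):
        ads = [self._ad("Tubus", _mins(-120))]
        assert not rule_ad_change(_alarm(), ads, mapping, config).fired

    def test_escalation_removed_within_window_does_not_fire(self, mapping, config):
        ads = [self._ad("Tubus", _mins(10), removal=_mins(12))]
        assert not rule_ad_change(_alarm(), ads, mapping, config).fired

    def test_removal_within_tolerance_still_counts_as_one_change(self, mapping, config):
        # removal documented 30 s after insertion: documentation noise, not
        # a genuine de-escalation
        ads = [self._ad("Tubus", _mins(10), removal=_mins(10) + timedelta(seconds=30))]
        assert rule_ad_change(_alarm(), ads, mapping, config).fired

    def test_deescalation_does_not_fire(self, mapping, config):
        ads = [self._ad("Tubus", _mins(-120), rid="a"), self._ad("NIV-Maske", _mins(10), rid="b")]
        assert not rule_ad_change(_alarm(), ads, mapping, config).fired

    def test_other_pacs_never_fire(self, mapping, config):
        hr = AlarmEvent("a2", "B1", T, "xBrady", PAC.HR_LOW, stay_ref="s1")
        assert not rule_ad_change(hr, [self._ad("Tubus", _mins(10))], mapping, config).fired


class TestRSTChangeRule:
    def _vents(self, *recs):
        return [
            VentStateRecord(vd, vm, sb, at, "s1", f"v{i}")
            for i, (vd, vm, sb, at) in enumerate(recs)
        ]

    def test_escalation_fires(self, mapping, config):
        vents = self._vents(
            ("Optiflow", "High-Flow", False, _mins(-60)),
            ("Evita", "NIV-ASB", False, _mins(8)),
        )
        assert rule_rst_change(_alarm(), vents, mapping, config).fired

    def test_standby_at_alarm_then_any_active_support_fires(self, mapping, config):
        # effective level at alarm is 0; resuming active therapy in the
        # window is an escalation from 0
        vents = self._vents(
            ("Evita", "BIPAP/ASB", True, _mins(-60)),
            ("Evita", "BIPAP/ASB", False, _mins(10)),
        )
        assert rule_rst_change(_alarm(), vents, mapping, config).fired

    def test_change_documented_during_standby_does_not_fire(self, mapping, config):
        vents = self._vents(
            ("Optiflow", "High-Flow", False, _mins(-60)),
            ("Evita", "BIPAP/ASB", True, _mins(10)),
        )
        assert not rule_rst_change(_alarm(), vents, mapping, config).fired

    def test_same_level_change_does_not_fire(self, mapping, config):
        vents = self._vents(
            ("Evita", "BIPAP/ASB", False, _mins(-60)),
            ("Servo-i", "PS", False, _mins(10)),
        )
        assert not rule_rst_change(_alarm(), vents, mapping, config).fired


class TestParamIncreaseRule:
    def _setting(self, param, value, at, rid=""):
        return VentParamSetting(param, value, at, "s1", rid or f"s{at.minute}")

    def test_fio2_increase_fires(self, mapping, config):
        vents = [VentStateRecord("Evita", "NIV-ASB", False, _mins(-60), "s1", "v0")]
        settings = [
            self._setting(VentParameter.FIO2, 0.4, _mins(-50)),
            self._setting(VentParameter.FIO2, 0.6, _mins(10)),
        ]
        out = rule_param_increase(_alarm(), "fio2", settings, vents, mapping, config)
        assert out.fired

    def test_equal_peak_does_not_fire(self, mapping, config):
        vents = [VentStateRecord("Evita", "NIV-ASB", False, _mins(-60), "s1", "v0")]
        settings = [
            self._setting(VentParameter.FIO2, 0.6, _mins(-50)),
            self._setting(VentParameter.FIO2, 0.6, _mins(10)),
        ]
        assert not rule_param_increase(_alarm(), "fio2", settings, vents, mapping, config).fired

    def test_peep_entry_during_oxygen_therapy_counts_as_zero(self, mapping, config):
        # PEEP cannot be set on a high-flow device: the faulty entry is
        # neutralized, so no increase is detected
        vents = [VentStateRecord("Optiflow", "High-Flow", False, _mins(-60), "s1", "v0")]
        settings = [self._setting(VentParameter.PEEP, 8.0, _mins(10))]
        assert not rule_param_increase(_alarm(), "peep", settings, vents, mapping, config).fired

    def test_oxygen_flow_during_oxygen_therapy_survives_standby(self, mapping, config):
        vents = [VentStateRecord("O2-Brille", "O2-Insufflation", True, _mins(-60), "s1", "v0")]
        settings = [
            self._setting(VentParameter.O2_FLOW_FLOWMETER, 2.0, _mins(-50)),
            self._setting(VentParameter.O2_FLOW_FLOWMETER, 6.0, _mins(10)),
        ]
        assert rule_param_increase(_alarm(), "o2_flow", settings, vents, mapping, config).fired

    def test_setting_under_standby_is_zero(self, mapping, config):
        vents = [VentStateRecord("Evita", "NIV-ASB", True, _mins(-60), "s1", "v0")]
        settings = [self._setting(VentParameter.FIO2, 0.9, _mins(10))]
        assert not rule_param_increase(_alarm(), "fio2", settings, vents, mapping, config).fired

    @given(st.integers(30, 120))
    def test_monotone_in_window_length(self, mapping, w_min):
        config = AnnotationConfig()
        vents = [VentStateRecord("Evita", "NIV-ASB", False, _mins(-60), "s1", "v0")]
        settings = [
            VentParamSetting(VentParameter.FIO2, 0.4, _mins(-50), "s1", "p0"),
            VentParamSetting(VentParameter.FIO2, 0.6, _mins(10), "s1", "p1"),
        ]
        base = rule_param_increase(_alarm(), "fio2", settings, vents, mapping, config)
        wider = rule_param_increase(
            _alarm(), "fio2", settings, vents, mapping,
            config.with_(resp_window=timedelta(minutes=w_min)),
        )
        assert not (base.fired and not wider.fired)


def test_rules_are_invariant_to_input_order(mapping, config):
    rng = random.Random(5)
    ads = [
        ADRecord("Wendl-Tubus", _mins(-60), _mins(5), "s1", "r1"),
        ADRecord("Tubus", _mins(5), None, "s1", "r2"),
    ]
    vents = [
        VentStateRecord("Optiflow", "High-Flow", False, _mins(-60), "s1", "v1"),
        VentStateRecord("Evita", "PCV", False, _mins(9), "s1", "v2"),
    ]
    settings = [
        VentParamSetting(VentParameter.FIO2, 0.4, _mins(-50), "s1", "p1"),
        VentParamSetting(VentParameter.FIO2, 0.7, _mins(11), "s1", "p2"),
    ]
    ref = (
        rule_ad_change(_alarm(), ads, mapping, config).fired,
        rule_rst_change(_alarm(), vents, mapping, config, ads).fired,
        rule_param_increase(_alarm(), "fio2", settings, vents, mapping, config, ads).fired,
    )
    for _ in range(5):
        rng.shuffle(ads), rng.shuffle(vents), rng.shuffle(settings)
        got = (
            rule_ad_change(_alarm(), ads, mapping, config).fired,
            rule_rst_change(_alarm(), vents, mapping, config, ads).fired,
            rule_param_increase(_alarm(), "fio2", settings, vents, mapping, config, ads).fired,
        )
        assert got == ref
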