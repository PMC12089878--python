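"""Medication rules: technique, rate comparison, fluid roles, the five rules."""

from datetime import datetime, timedelta

import pytest
from hypothesis import given, strategies as st

from icualarms import MedicationAdministration, PAC
from icualarms.data_model import AlarmEvent
from icualarms.medication_rules import (
    AdministrationEpisode,
    build_episodes,
    classify_technique,
    comparable_rate,
    fluid_role,
    rule_bolus,
    rule_decrease,
    rule_increase,
    rule_start,
    rule_stop,
)

T = datetime(2024, 1, 1, 12, 0, 7)


def _alarm(pac=PAC.IBP_LOW, label="ABPs"):
    return AlarmEvent("a1", "B1", T, label, pac, stay_ref="s1")


def _mins(m):
    return T + timedelta(minutes=m)


def _episode(
    drug="D1001", ingredient="norepinephrine", start=None, end=None,
    rate=10.0, unit="mL/h", conc=1.0, conc_unit="mg/mL", rid="e1",
):
    start = start if start is not None else _mins(-120)
    end = end if end is not None else _mins(120)
    technique = "bolus" if start == end else "continuous"
    return AdministrationEpisode(
        ingredient_key=ingredient, technique=technique, start=start, end=end,
        order_id="o-" + rid, drug_id=drug, rate=rate, rate_unit=unit,
        concentration=conc, concentration_unit=conc_unit, record_id=rid,
    )


class TestTechnique:
    def test_equal_timestamps_mean_bolus(self):
        adm = MedicationAdministration("o", "D1001", T, T, "s1")
        assert classify_technique(adm) == "bolus"

    @pytest.mark.parametrize("delta", [timedelta(seconds=1), timedelta(hours=2)])
    def test_any_positive_duration_means_continuous(self, delta):
        adm = MedicationAdministration("o", "D1001", T, T + delta, "s1")
        assert classify_technique(adm) == "continuous"


class TestRateComparison:
    def test_doses_per_time_decide_across_concentrations(self):
        # 10 mg/mL at 10 mL/h = 100 mg/h vs 20 mg/mL at 6 mL/h = 120 mg/h
        a = _episode(rate=10.0, conc=10.0, rid="a")
        b = _episode(rate=6.0, conc=20.0, rid="b")
        assert comparable_rate(a, b) == "less"
        assert comparable_rate(b, a) == "greater"

    def test_identical_episodes_equal(self):
        assert comparable_rate(_episode(rid="a"), _episode(rid="b")) == "equal"

    def test_unit_conversion_same_concentration(self):
        a = _episode(rate=120.0, unit="mL/h", rid="a")
        b = _episode(rate=1.0, unit="mL/min", rid="b")  # 60 mL/h
        assert comparable_rate(a, b) == "greater"
        c = _episode(rate=2.0, unit="mL/min", rid="c")  # 120 mL/h
        assert comparable_rate(a, c) == "equal"

    def test_unknown_unit_is_incomparable(self):
        a = _episode(unit="drops/min", rid="a")
        assert comparable_rate(a, _episode(rid="b")) == "incomparable"

    def test_per_kg_rate_without_weight_is_incomparable(self):
        a = _episode(rate=0.1, unit="ug/kg/min", conc=2.0, rid="a")
        b = _episode(rate=5.0, unit="mL/h", conc=1.0, rid="b")
        assert comparable_rate(a, b) == "incomparable"

    @given(st.floats(0.1, 100, allow_nan=False), st.floats(0.1, 100, allow_nan=False))
    def test_antisymmetric(self, ra, rb):
        a = _episode(rate=ra, rid="a")
        b = _episode(rate=rb, rid="b")
        flipped = {"greater": "less", "less": "greater", "equal": "equal"}
        assert comparable_rate(b, a) == flipped[comparable_rate(a, b)]


class TestFluidRole:
    def test_below_threshold_is_carrier(self):
        assert fluid_role(_episode(drug="D1070", rate=400.0, conc=None, conc_unit=None)) == "carrier"

    def test_exactly_at_threshold_is_therapy(self):
        assert fluid_role(_episode(drug="D1070", rate=500.0, conc=None, conc_unit=None)) == "therapy"

    def test_large_bolus_amount_is_therapy(self):
        e = AdministrationEpisode(
            ingredient_key="nacl_0_9", technique="bolus", start=T, end=T,
            order_id="o", drug_id="D1070", amount=1000.0, amount_unit="mL",
        )
        assert fluid_role(e) == "therapy"

    def test_undocumented_quantities_default_to_carrier(self):
        e = AdministrationEpisode(
            ingredient_key="nacl_0_9", technique="continuous",
            start=T, end=_mins(60), order_id="o", drug_id="D1070",
        )
        assert fluid_role(e) == "carrier"

    def test_carrier_dropped_from_episodes(self, mapping, config):
        adm = MedicationAdministration(
            "o", "D1070", _mins(2), _mins(60), "s1", rate=100.0, rate_unit="mL/h"
        )
        assert build_episodes([adm], mapping, config) == []


class TestFiveRules:
    def test_bolus_in_window_fires(self, mapping, config):
        at = _mins(7)
        ep = _episode(drug="D1002", ingredient="epinephrine", start=at, end=at, rid="b1")
        out = rule_bolus(_alarm(), [ep], mapping, config)
        assert out.fired and out.matches[0].matched_time == at

    def test_bolus_outside_window_does_not_fire(self, mapping, config):
        at = _mins(16)
        ep = _episode(drug="D1002", ingredient="epinephrine", start=at, end=at, rid="b1")
        assert not rule_bolus(_alarm(), [ep], mapping, config).fired

    def test_new_start_fires(self, mapping, config):
        ep = _episode(start=_mins(4), end=_mins(120), rid="s1")
        assert rule_start(_alarm(), [ep], mapping, config).fired

    def test_start_with_recent_predecessor_becomes_increase(self, mapping, config):
        # predecessor ends 3 min before the new start at a lower rate: the
        # pair is one continued administration at a higher dose
        prev = _episode(start=_mins(-120), end=_mins(7), rate=10.0, rid="p")
        new = _episode(start=_mins(10), end=_mins(120), rate=15.0, rid="n")
        assert not rule_start(_alarm(), [prev, new], mapping, config).fired
        assert rule_increase(_alarm(), [prev, new], mapping, config).fired

    def test_increase_needs_strictly_higher_rate(self, mapping, config):
        prev = _episode(start=_mins(-120), end=_mins(7), rate=10.0, rid="p")
        new = _episode(start=_mins(10), end=_mins(120), rate=10.0, rid="n")
        assert not rule_increase(_alarm(), [prev, new], mapping, config).fired

    def test_incomparable_rates_block_increase(self, mapping, config):
        prev = _episode(start=_mins(-120), end=_mins(7), rate=10.0, rid="p")
        new = _episode(start=_mins(10), end=_mins(120), rate=3.0, unit="drops/min", rid="n")
        assert not rule_increase(_alarm(), [prev, new], mapping, config).fired

    def test_parallel_line_blocks_start(self, mapping, config):
        running = _episode(start=_mins(-120), end=_mins(120), rid="r")
        new = _episode(start=_mins(5), end=_mins(60), rid="n")
        assert not rule_start(_alarm(), [running, new], mapping, config).fired

    def test_stop_fires_for_vasodilator_after_hypotension_alarm(self, mapping, config):
        ep = _episode(
            drug="D1020", ingredient="nitroglycerin", start=_mins(-120), end=_mins(5), rid="s"
        )
        assert rule_stop(_alarm(), [ep], mapping, config).fired

    def test_restart_within_gap_blocks_stop_enables_decrease(self, mapping, config):
        prev = _episode(
            drug="D1020", ingredient="nitroglycerin",
            start=_mins(-120), end=_mins(5), rate=15.0, rid="p",
        )
        nxt = _episode(
            drug="D1020", ingredient="nitroglycerin",
            start=_mins(8), end=_mins(120), rate=8.0, rid="n",
        )
        assert not rule_stop(_alarm(), [prev, nxt], mapping, config).fired
        assert rule_decrease(_alarm(), [prev, nxt], mapping, config).fired

    def test_stop_and_decrease_never_fire_for_desaturation(self, mapping, config):
        spo2 = AlarmEvent("a2", "B1", T, "Desat", PAC.SPO2_LOW, stay_ref="s1")
        ep = _episode(
            drug="D1052", ingredient="theophylline", start=_mins(-120), end=_mins(5), rid="s"
        )
        assert not rule_stop(spo2, [ep], mapping, config).fired
        assert not rule_decrease(spo2, [ep], mapping, config).fired

    def test_irrelevant_ingredient_never_fires(self, mapping, config):
        at = _mins(5)
        ep = _episode(drug="D1081", ingredient="paracetamol", start=at, end=at, rid="b")
        assert not rule_bolus(_alarm(), [ep], mapping, config).fired

    def test_mixture_treated_as_one_ingredient(self, mapping, config):
        ep = _episode(
            drug="D2001", ingredient="glucose_5|norepinephrine",
            start=_mins(4), end=_mins(120), rid="m",
        )
        assert rule_start(_alarm(), [ep], mapping, config).fired
        assert not rule_start(_alarm(PAC.HR_HIGH, "xTachy"), [ep], mapping, config).fired


class TestMutualExclusion:
    """The rule chains make start/increase and stop/decrease exclusive for
    one episode pair."""

    @pytest.mark.parametrize("new_rate", [5.0, 10.0, 15.0])
    def test_start_increase_exclusive(self, mapping, config, new_rate):
        prev = _episode(start=_mins(-120), end=_mins(7), rate=10.0, rid="p")
        new = _episode(start=_mins(10), end=_mins(120), rate=new_rate, rid="n")
        s = rule_start(_alarm(), [prev, new], mapping, config).fired
        i = rule_increase(_alarm(), [prev, new], mapping, config).fired
        assert not (s and i)

    @pytest.mark.parametrize("new_rate", [5.0, 10.0, 15.0])
    def test_stop_decrease_exclusive(self, mapping, config, new_rate):
        prev = _episode(
            drug="D1020", ingredient="nitroglycerin",
            start=_mins(-120), end=_mins(5), rate=10.0, rid="p",
        )
        nxt = _episode(
            drug="D1020", ingredient="nitroglycerin",
            start=_mins(8), end=_mins(120), rate=new_rate, rid="n",
        )
        s = rule_stop(_alarm(), [prev, nxt], mapping, config).fired
        d = rule_decrease(_alarm(), [prev, nxt], mapping, config).fired
        assert not (s and d)
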