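"""Synthetic generator: scenario correctness, ledger soundness, seeding,
documentation-error injection."""

import numpy as np
import pytest

from icualarms import (
    ErrorInjectionParams,
    Label,
    PAC,
    ScenarioSpec,
    ad_change_stats,
    generate_dataset,
    generate_scenario,
    generate_stay,
    inject_errors,
    run_pipeline,
)
from icualarms.synthetic import (
    NEGATIVE_VARIANTS,
    POSITIVE_VARIANTS,
    applicable_rule_ids,
)


def _annotate(bundle, mapping, config):
    results, _, _ = run_pipeline(
        bundle.alarms, bundle.stays, bundle.ads, bundle.vent_states,
        bundle.settings, bundle.administrations, bundle.prescriptions,
        mapping, config,
    )
    return results


def _all_scenarios(positive):
    table = POSITIVE_VARIANTS if positive else NEGATIVE_VARIANTS
    for rule, variants in table.items():
        for pac in PAC:
            if rule not in applicable_rule_ids(pac):
                continue
            for variant in variants:
                yield rule, pac, variant


class TestScenarios:
    @pytest.mark.parametrize(
        "rule,pac,variant", list(_all_scenarios(positive=True)),
        ids=lambda v: getattr(v, "value", v),
    )
    def test_positive_scenarios_fire_their_rule(self, mapping, config, rule, pac, variant):
        bundle = generate_scenario(ScenarioSpec(rule, pac, True, variant, seed=9))
        (res,) = _annotate(bundle, mapping, config)
        assert res.label is Label.ACTIONABLE
        assert rule in res.fired_rules

    @pytest.mark.parametrize(
        "rule,pac,variant", list(_all_scenarios(positive=False)),
        ids=lambda v: getattr(v, "value", v),
    )
    def test_negative_scenarios_fire_nothing(self, mapping, config, rule, pac, variant):
        bundle = generate_scenario(ScenarioSpec(rule, pac, False, variant, seed=9))
        (res,) = _annotate(bundle, mapping, config)
        assert res.label is Label.NONACTIONABLE

    @pytest.mark.parametrize("rule", ["ad_change", "rst_change", "param_increase"])
    @pytest.mark.parametrize("pac", [p for p in PAC if p is not PAC.SPO2_LOW])
    def test_respiratory_scenarios_refused_outside_desaturation(self, rule, pac):
        with pytest.raises(ValueError):
            ScenarioSpec(rule, pac)

    @pytest.mark.parametrize("rule", ["stop", "decrease"])
    def test_stop_decrease_refused_for_desaturation(self, rule):
        with pytest.raises(ValueError):
            ScenarioSpec(rule, PAC.SPO2_LOW)

    def test_unknown_rule_refused(self):
        with pytest.raises(ValueError):
            ScenarioSpec("teleport", PAC.IBP_LOW)


class TestStayGeneration:
    def test_same_seed_gives_identical_bundles(self):
        a = generate_stay(seed=13)
        b = generate_stay(seed=13)
        assert a.alarms == b.alarms
        assert a.ads == b.ads
        assert a.vent_states == b.vent_states
        assert a.settings == b.settings
        assert a.administrations == b.administrations
        assert a.ledger == b.ledger

    def test_zero_alarm_rate_gives_no_alarms(self):
        b = generate_stay(seed=1, alarm_rate_per_hour=0.0)
        assert b.alarms == [] and b.ledger == []

    def test_propensity_one_makes_every_alarm_actionable(self, mapping, config):
        b = generate_dataset(seed=21, n_stays=6, intervention_propensity=1.0)
        assert all(r["true_label"] == "actionable" for r in b.ledger)
        results = _annotate(b, mapping, config)
        assert all(r.label is Label.ACTIONABLE for r in results)

    def test_ledger_covers_every_alarm(self):
        b = generate_dataset(seed=22, n_stays=5)
        assert {r["alarm_id"] for r in b.ledger} == {a.alarm_id for a in b.alarms}

    def test_clean_bundle_labels_match_ledger_exactly(self, mapping, config):
        b = generate_dataset(seed=23, n_stays=15)
        truth = {r["alarm_id"]: r["true_label"] for r in b.ledger}
        results = _annotate(b, mapping, config)
        assert all(r.label.value == truth[r.alarm_id] for r in results)

    def test_all_rules_represented_in_large_bundle(self):
        b = generate_dataset(seed=24, n_stays=40)
        planted = {r["rule_id"] for r in b.ledger if r["rule_id"]}
        assert planted == {
            "ad_change", "rst_change", "param_increase",
            "bolus", "start", "increase", "stop", "decrease",
        }


class TestErrorInjection:
    def test_rate_one_removes_every_predecessor_removal(self):
        b = generate_dataset(seed=30, n_stays=10, alarm_rate_per_hour=0.0,
                             background_ad_changes=10)
        corrupted, ledger = inject_errors(
            b, ErrorInjectionParams(missing_removal_rate=1.0, rounding_fraction=0.0), seed=1
        )
        n, missing = ad_change_stats(corrupted.ads)
        assert n > 0 and missing == n
        assert len([c for c in ledger if c["kind"] == "missing_removal"]) == n

    def test_empirical_missing_removal_rate_matches_parameter(self):
        b = generate_dataset(seed=31, n_stays=40, alarm_rate_per_hour=0.0,
                             background_ad_changes=30)
        p = 0.09
        corrupted, _ = inject_errors(
            b, ErrorInjectionParams(missing_removal_rate=p, rounding_fraction=0.0), seed=2
        )
        n, missing = ad_change_stats(corrupted.ads)
        assert n >= 1000
        se = (p * (1 - p) / n) ** 0.5
        assert abs(missing / n - p) < 3 * se

    def test_rounding_fraction_reflected_on_grid(self):
        b = generate_dataset(seed=32, n_stays=30)
        corrupted, _ = inject_errors(
            b, ErrorInjectionParams(missing_removal_rate=0.0, rounding_fraction=0.6), seed=3
        )
        on_grid = [
            adm.start_time.second == 0 and adm.start_time.minute % 5 == 0
            for adm in corrupted.administrations
        ]
        n = len(on_grid)
        frac = sum(on_grid) / n
        se = (0.6 * 0.4 / n) ** 0.5
        assert abs(frac - 0.6) < 4 * se

    def test_standby_injection_adds_delayed_deactivation(self):
        b = generate_dataset(seed=33, n_stays=20)
        params = ErrorInjectionParams(
            missing_removal_rate=0.0, rounding_fraction=0.0, standby_error_rate=1.0
        )
        corrupted, ledger = inject_errors(b, params, seed=4)
        delays = [c["deactivation_delay_min"] for c in ledger if c["kind"] == "standby_error"]
        assert delays and all(d > 0 for d in delays)
        # log-normal fitted to median 7 min: the sample median should sit
        # in that vicinity
        assert 3 < float(np.median(delays)) < 14

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            ErrorInjectionParams(missing_removal_rate=1.5)

    def test_delay_quantiles_must_be_ordered(self):
        with pytest.raises(ValueError):
            ErrorInjectionParams(standby_delay_median_min=20, standby_delay_p75_min=7)


class TestRoundingCompensation:
    def test_compensation_restores_recovery_on_rounded_data(self, mapping):
        from icualarms import AnnotationConfig

        cfg_on = AnnotationConfig()
        cfg_off = cfg_on.with_(compensate_rounding=False)
        b = generate_dataset(seed=40, n_stays=25)
        corrupted, _ = inject_errors(
            b, ErrorInjectionParams(missing_removal_rate=0.0, rounding_fraction=0.6), seed=5
        )
        truth = {r["alarm_id"]: r["true_label"] for r in b.ledger}

        def recovered(bundle, cfg):
            results = _annotate(bundle, mapping, cfg)
            act = [r for r in results if truth[r.alarm_id] == "actionable"]
            return sum(1 for r in act if r.label is Label.ACTIONABLE), len(act)

        rec_off, n_off = recovered(corrupted, cfg_off)
        rec_on, n_on = recovered(corrupted, cfg_on)
        assert n_off == n_on > 0
        assert rec_off < n_off          # round-down causes false negatives
        assert rec_on == n_on           # interval compensation recovers all
        assert rec_on > rec_off
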