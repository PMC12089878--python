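"""Synthetic alarm-log and PDMS-table generator with known ground truth.

Real ICU alarm logs and their patient-data-management-system (PDMS) context
are not publicly available, so the package ships a generator that emulates
the five input streams — alarms, airway-device documentation, ventilation
states, set ventilation parameters, medication administrations (plus
prescriptions of planned interventions) — together with a ground-truth
ledger that records, for every alarm, which intervention (if any) was
planted in its window and hence its true actionability label.

Scenario builders produce minimal fixtures per rule: positives satisfy
exactly the targeted rule, negatives violate exactly one of its conditions.
Stay-level generation draws Poisson alarm arrivals with a dead time long
enough that one alarm's planted interventions cannot leak into a
neighbouring alarm's window — the ledger is sound only under that
isolation.

A separate error-injection pass reproduces the documentation-error
processes observed in real PDMS data: missing removals of superseded airway
devices, ventilation changes mis-documented during ventilator standby with
a delayed deactivation, and medication timestamps rounded down to the
5-minute grid by the charting dialog.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    ADRecord,
    AlarmEvent,
    MedicationAdministration,
    PAC,
    Prescription,
    StayInterval,
    VentParamSetting,
    VentParameter,
    classify_pac,
)

__all__ = [
    "ScenarioSpec",
    "ErrorInjectionParams",
    "Bundle",
    "generate_scenario",
    "generate_stay",
    "generate_dataset",
    "inject_errors",
    "ad_change_stats",
    "POSITIVE_VARIANTS",
    "NEGATIVE_VARIANTS",
]

_EPOCH = datetime(2024, 1, 1, 0, 0, 0)

#: Alarm label (and threshold direction where the label does not carry it)
#: used for each condition.
_PAC_LABEL: dict[PAC, tuple[str, Optional[str]]] = {
    PAC.SPO2_LOW: ("Desat", None),
    PAC.HR_LOW: ("xBrady", None),
    PAC.HR_HIGH: ("xTachy", None),
    PAC.IBP_LOW: ("ABPs", "low"),
    PAC.IBP_HIGH: ("ABPm", "high"),
}

# Drug choices per condition (ids from the shipped medication mapping).
_GI_BOLUS = {
    PAC.SPO2_LOW: "D1050",
    PAC.HR_LOW: "D1040",
    PAC.HR_HIGH: "D1030",
    PAC.IBP_LOW: "D1002",
    PAC.IBP_HIGH: "D1021",
}
_GI_CONT = {
    PAC.SPO2_LOW: "D1052",
    PAC.HR_LOW: "D1002",
    PAC.HR_HIGH: "D1031",
    PAC.IBP_LOW: "D1001",
    PAC.IBP_HIGH: "D1020",
}
_SD_CONT = {
    PAC.HR_LOW: "D1010",
    PAC.HR_HIGH: "D1002",
    PAC.IBP_LOW: "D1020",
    PAC.IBP_HIGH: "D1001",
}
_IRRELEVANT_DRUG = "D1081"
_FLUID_DRUG = "D1070"
_MIXTURE_DRUG = "D2001"

_RESP_RULES = ("ad_change", "rst_change", "param_increase")
_MED_GI_RULES = ("bolus", "start", "increase")
_MED_SD_RULES = ("stop", "decrease")

POSITIVE_VARIANTS: dict[str, tuple[str, ...]] = {
    "ad_change": ("mask_to_niv", "escalate_to_ett"),
    "rst_change": ("hfno_to_bipap", "o2_to_cpap"),
    "param_increase": ("fio2", "o2_flow", "peep"),
    "bolus": ("simple",),
    "start": ("simple", "fluid_therapy", "mixture"),
    "increase": ("rate", "concentration"),
    "stop": ("simple",),
    "decrease": ("rate",),
}

NEGATIVE_VARIANTS: dict[str, tuple[str, ...]] = {
    "ad_change": ("removed_in_window", "outside_window", "deescalation"),
    "rst_change": ("standby_change", "same_level", "deescalation"),
    "param_increase": ("equal", "decrease", "incompatible_param", "outside_window"),
    "bolus": ("outside_window", "irrelevant_drug"),
    "start": ("outside_window", "parallel", "carrier_fluid"),
    "increase": ("equal_rate", "incomparable_units"),
    "stop": ("outside_window", "parallel"),
    "decrease": ("equal_rate",),
}


def applicable_rule_ids(pac: PAC) -> tuple[str, ...]:
    if pac is PAC.SPO2_LOW:
        return _RESP_RULES + _MED_GI_RULES
    return _MED_GI_RULES + _MED_SD_RULES


@dataclass(frozen=True)
class ScenarioSpec:
    """One minimal fixture request: a rule to exercise (or ``"negative"``
    for an intervention-free alarm), the alarm condition, whether the
    planted pattern should satisfy the rule, and a variant name."""

    rule_id: str
    pac: PAC
    positive: bool = True
    variant: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rule_id == "negative":
            return
        if self.rule_id not in POSITIVE_VARIANTS:
            raise ValueError(f"unknown rule id {self.rule_id!r}")
        if self.rule_id in _RESP_RULES and self.pac is not PAC.SPO2_LOW:
            raise ValueError(f"{self.rule_id} applies only to the SpO2-low condition")
        if self.rule_id in _MED_SD_RULES and self.pac is PAC.SPO2_LOW:
            raise ValueError(f"{self.rule_id} never applies to the SpO2-low condition")


@dataclass(frozen=True)
class ErrorInjectionParams:
    """Rates of the documentation-error processes observed in PDMS data.

    Defaults are the observed magnitudes: 9.0% of airway-device changes lack
    the removal of the superseded device; standby mis-documentation is
    deactivated after a delay with median 7 min and 75th percentile 20 min;
    roughly 60% of medication timestamps sit rounded-down on the 5-minute
    grid.
    """

    missing_removal_rate: float = 0.090
    standby_error_rate: float = 0.0
    standby_delay_median_min: float = 7.0
    standby_delay_p75_min: float = 20.0
    rounding_fraction: float = 0.60

    def __post_init__(self) -> None:
        for name in ("missing_removal_rate", "standby_error_rate", "rounding_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0 < self.standby_delay_median_min < self.standby_delay_p75_min:
            raise ValueError("standby delay quantiles must be ordered: 0 < median < p75")

    @property
    def lognormal_params(self) -> tuple[float, float]:
        """(mu, sigma) of the log-normal delay fitted to the two quantiles."""
        mu = math.log(self.standby_delay_median_min)
        z75 = 0.6744897501960817  # standard-normal 75th percentile
        sigma = (math.log(self.standby_delay_p75_min) - mu) / z75
        return mu, sigma


@dataclass
class Bundle:
    """Full synthetic table bundle plus ground-truth ledger.

    ``ledger`` holds one row per alarm: alarm_id, pac, planted rule (empty
    for negatives), variant, and the implied true label.
    """

    stays: list[StayInterval] = field(default_factory=list)
    alarms: list[AlarmEvent] = field(default_factory=list)
    ads: list[ADRecord] = field(default_factory=list)
    vent_states: list = field(default_factory=list)
    settings: list[VentParamSetting] = field(default_factory=list)
    administrations: list[MedicationAdministration] = field(default_factory=list)
    prescriptions: list[Prescription] = field(default_factory=list)
    ledger: list[dict] = field(default_factory=list)

    def merge(self, other: "Bundle") -> None:
        for name in (
            "stays", "alarms", "ads", "vent_states", "settings",
            "administrations", "prescriptions", "ledger",
        ):
            getattr(self, name).extend(getattr(other, name))

    def ledger_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.ledger,
            columns=["alarm_id", "pac", "rule_id", "variant", "true_label"],
        )


def _offgrid_seconds(rng: np.random.Generator) -> int:
    """A within-minute second offset, never zero, so clean timestamps do not
    sit on the 5-minute documentation grid."""
    return int(rng.integers(1, 60))


def _jitter_min(rng: np.random.Generator, lo: float, hi: float) -> timedelta:
    # whole seconds: all generated timestamps survive second-precision CSV
    # round-trips unchanged
    return timedelta(seconds=int(rng.uniform(lo * 60, hi * 60)))


class _StayBuilder:
    """Accumulates one stay's records; AD and ventilation state are tracked
    so consecutive scenarios remain mutually consistent."""

    def __init__(
        self,
        stay_id: str,
        bed_id: str,
        start: datetime,
        duration: timedelta,
        rng: np.random.Generator,
        id_prefix: str = "",
    ) -> None:
        self.stay = StayInterval(stay_id, bed_id, start, start + duration)
        self.rng = rng
        self.prefix = id_prefix or stay_id
        self._counter = 0
        self.ads: list[dict] = []          # mutable AD rows (removal set later)
        self.vent_states: list = []
        self.settings: list[VentParamSetting] = []
        self.administrations: list[MedicationAdministration] = []
        self.prescriptions: list[Prescription] = []
        self.alarms: list[AlarmEvent] = []
        self.ledger: list[dict] = []

    # -- ids ---------------------------------------------------------------

    def _rid(self, kind: str) -> str:
        self._counter += 1
        return f"{self.prefix}-{kind}{self._counter:04d}"

    # -- low-level record emitters ----------------------------------------

    def add_ad(self, entry_text: str, t: datetime) -> dict:
        """Document a new airway device at time *t*.

        The time-wise predecessor gets a removal timestamp within +-30 s of
        the new insertion (unless it already carries an earlier removal);
        when a record later than *t* already exists, the new device is
        closed against that later insertion, keeping the documented chain
        consistent no matter in which order scenarios and background churn
        write their entries.
        """
        preds = [r for r in self.ads if r["insert_time"] <= t]
        if preds:
            prev = max(preds, key=lambda r: r["insert_time"])
            if prev["removal_time"] is None or prev["removal_time"] > t + timedelta(seconds=60):
                prev["removal_time"] = t + timedelta(seconds=int(self.rng.uniform(-30, 30)))
        row = {
            "entry_text": entry_text,
            "insert_time": t,
            "removal_time": None,
            "stay_ref": self.stay.stay_id,
            "record_id": self._rid("AD"),
        }
        future = [r for r in self.ads if r["insert_time"] > t]
        if future:
            nxt = min(future, key=lambda r: r["insert_time"])
            row["removal_time"] = nxt["insert_time"] + timedelta(
                seconds=int(self.rng.uniform(-30, 30))
            )
        self.ads.append(row)
        return row

    def add_vent(self, vd: str, vm: str, t: datetime, standby: bool = False):
        from .data_model import VentStateRecord

        rec = VentStateRecord(vd, vm, standby, t, self.stay.stay_id, self._rid("VS"))
        self.vent_states.append(rec)
        return rec

    def add_setting(self, parameter: VentParameter, value: float, t: datetime):
        rec = VentParamSetting(parameter, value, t, self.stay.stay_id, self._rid("SP"))
        self.settings.append(rec)
        return rec

    def add_admin(
        self,
        drug_id: str,
        start: datetime,
        end: datetime,
        rate: Optional[float] = None,
        rate_unit: Optional[str] = None,
        concentration: Optional[float] = None,
        concentration_unit: Optional[str] = None,
        amount: Optional[float] = None,
        amount_unit: Optional[str] = None,
        order_id: Optional[str] = None,
    ) -> MedicationAdministration:
        rec = MedicationAdministration(
            order_id=order_id or self._rid("ORD"),
            drug_id=drug_id,
            start_time=start,
            end_time=end,
            stay_ref=self.stay.stay_id,
            rate=rate,
            rate_unit=rate_unit,
            concentration=concentration,
            concentration_unit=concentration_unit,
            amount=amount,
            amount_unit=amount_unit,
            record_id=self._rid("MA"),
        )
        self.administrations.append(rec)
        return rec

    def add_alarm(self, pac: PAC, t: datetime) -> AlarmEvent:
        label, direction = _PAC_LABEL[pac]
        alarm = AlarmEvent(
            alarm_id=self._rid("AL"),
            bed_id=self.stay.bed_id,
            start_time=t,
            alarm_label=label,
            pac=classify_pac(label, direction),
        )
        self.alarms.append(alarm)
        return alarm

    # -- scenario builders -------------------------------------------------

    def plant(self, spec: ScenarioSpec, t: datetime) -> None:
        """Plant one scenario around an alarm at time *t* and record the
        implied truth in the ledger."""
        rng = self.rng
        alarm = self.add_alarm(spec.pac, t)
        rule = spec.rule_id
        if rule == "negative":
            self._ledger(alarm, "", "no_intervention", False)
            return
        variants = POSITIVE_VARIANTS[rule] if spec.positive else NEGATIVE_VARIANTS[rule]
        variant = spec.variant or variants[int(rng.integers(0, len(variants)))]
        if variant not in variants:
            raise ValueError(f"unknown {'positive' if spec.positive else 'negative'} "
                             f"variant {variant!r} for rule {rule!r}")
        getattr(self, f"_plant_{rule}")(alarm, variant, spec.positive)
        self._ledger(alarm, rule if spec.positive else "", variant, spec.positive)

    def _ledger(self, alarm: AlarmEvent, rule: str, variant: str, positive: bool) -> None:
        self.ledger.append(
            {
                "alarm_id": alarm.alarm_id,
                "pac": alarm.pac.value,
                "rule_id": rule,
                "variant": variant,
                "true_label": "actionable" if positive else "nonactionable",
            }
        )

    # baseline events go 35 min before the alarm: outside the preceding
    # alarm's windows (arrivals keep >= 90 min separation) and outside this
    # alarm's own windows.
    def _baseline_time(self, t: datetime) -> datetime:
        return t - timedelta(minutes=35) + timedelta(seconds=_offgrid_seconds(self.rng))

    def _in_window(self, t: datetime, lo_min: float, hi_min: float) -> datetime:
        return t + _jitter_min(self.rng, lo_min, hi_min)

    def _plant_ad_change(self, alarm: AlarmEvent, variant: str, positive: bool) -> None:
        # every variant re-documents a baseline device 35 min before the
        # alarm, so earlier device history on the stay cannot change the
        # escalation relation the scenario encodes
        t = alarm.start_time
        if positive:
            if variant == "mask_to_niv":
                self.add_ad("Gesichtsmaske", self._baseline_time(t))
                self.add_ad("NIV-Maske", self._in_window(t, 2, 25))
            else:  # escalate_to_ett
                self.add_ad("Wendl-Tubus", self._baseline_time(t))
                self.add_ad("Tubus", self._in_window(t, 2, 25))
            return
        if variant == "removed_in_window":
            self.add_ad("Wendl-Tubus", self._baseline_time(t))
            row = self.add_ad("NIV-Maske", self._in_window(t, 2, 10))
            row["removal_time"] = row["insert_time"] + _jitter_min(self.rng, 2, 10)
        elif variant == "outside_window":
            self.add_ad("Wendl-Tubus", self._baseline_time(t))
            self.add_ad("NIV-Maske", t + _jitter_min(self.rng, 31, 40))
        else:  # deescalation
            self.add_ad("Tubus", self._baseline_time(t))
            self.add_ad("NIV-Maske", self._in_window(t, 2, 25))

    def _plant_rst_change(self, alarm: AlarmEvent, variant: str, positive: bool) -> None:
        t = alarm.start_time
        base = self._baseline_time(t)
        if positive:
            if variant == "hfno_to_bipap":
                self.add_vent("Optiflow", "High-Flow", base)
                self.add_vent("Evita", "BIPAP/ASB", self._in_window(t, 2, 25))
            else:  # o2_to_cpap
                self.add_vent("O2-Brille", "O2-Insufflation", base)
                self.add_vent("CPAP-Geraet", "CPAP", self._in_window(t, 2, 25))
            return
        if variant == "standby_change":
            self.add_vent("Optiflow", "High-Flow", base)
            self.add_vent("Evita", "BIPAP/ASB", self._in_window(t, 2, 20), standby=True)
        elif variant == "same_level":
            self.add_vent("Evita", "BIPAP/ASB", base)
            self.add_vent("Servo-i", "PS", self._in_window(t, 2, 25))
        else:  # deescalation
            self.add_vent("Evita", "BIPAP/ASB", base)
            self.add_vent("Optiflow", "High-Flow", self._in_window(t, 2, 25))

    def _plant_param_increase(self, alarm: AlarmEvent, variant: str, positive: bool) -> None:
        t = alarm.start_time
        base = self._baseline_time(t)
        rng = self.rng
        if variant == "o2_flow":
            self.add_vent("O2-Brille", "O2-Insufflation", base)
            self.add_setting(VentParameter.O2_FLOW_FLOWMETER, 2.0, base + timedelta(minutes=1))
            self.add_setting(VentParameter.O2_FLOW_FLOWMETER, 6.0, self._in_window(t, 2, 25))
            return
        if variant == "peep":
            self.add_vent("CPAP-Geraet", "CPAP", base)
            self.add_setting(VentParameter.PEEP, 5.0, base + timedelta(minutes=1))
            self.add_setting(VentParameter.PEEP, 8.0, self._in_window(t, 2, 25))
            return
        # FiO2 family on an augmented-ventilation baseline
        self.add_vent("Evita", "BIPAP/ASB", base)
        self.add_setting(VentParameter.FIO2, 0.4, base + timedelta(minutes=1))
        if variant == "fio2":
            self.add_setting(VentParameter.FIO2, float(rng.uniform(0.5, 0.8)), self._in_window(t, 2, 25))
        elif variant == "equal":
            self.add_setting(VentParameter.FIO2, 0.4, self._in_window(t, 2, 25))
        elif variant == "decrease":
            self.add_setting(VentParameter.FIO2, 0.3, self._in_window(t, 2, 25))
        elif variant == "outside_window":
            self.add_setting(VentParameter.FIO2, 0.6, t + _jitter_min(rng, 31, 40))
        else:  # incompatible_param: pressure support cannot be set under BIPAP-free HFNO
            self.vent_states.pop()
            self.settings.pop()
            self.add_vent("Optiflow", "High-Flow", base)
            self.add_setting(VentParameter.PEEP, 8.0, self._in_window(t, 2, 25))

    # medication helpers

    def _med_times(self, t: datetime) -> tuple[datetime, datetime]:
        """(episode lead-in start, episode tail end) placed safely outside
        every alarm window on this stay."""
        start = t - timedelta(minutes=40) + timedelta(seconds=_offgrid_seconds(self.rng))
        end = t + _jitter_min(self.rng, 25, 40)
        return start, end

    def _plant_bolus(self, alarm: AlarmEvent, variant: str, positive: bool) -> None:
        t = alarm.start_time
        drug = _GI_BOLUS[alarm.pac]
        if positive:
            at = self._in_window(t, 1, 14)
            self.add_admin(drug, at, at, amount=10.0, amount_unit="mg")
            return
        if variant == "outside_window":
            at = t + _jitter_min(self.rng, 17, 25)
            self.add_admin(drug, at, at, amount=10.0, amount_unit="mg")
        else:  # irrelevant_drug
            at = self._in_window(t, 1, 14)
            self.add_admin(_IRRELEVANT_DRUG, at, at, amount=500.0, amount_unit="mg")

    def _plant_start(self, alarm: AlarmEvent, variant: str, positive: bool) -> None:
        t = alarm.start_time
        drug = _GI_CONT[alarm.pac]
        lead, tail = self._med_times(t)
        if positive:
            if variant == "fluid_therapy" and alarm.pac is PAC.IBP_LOW:
                self.add_admin(_FLUID_DRUG, self._in_window(t, 1, 14), tail,
                               rate=600.0, rate_unit="mL/h")
            elif variant == "mixture" and alarm.pac is PAC.IBP_LOW:
                self.add_admin(_MIXTURE_DRUG, self._in_window(t, 1, 14), tail,
                               rate=10.0, rate_unit="mL/h",
                               concentration=0.1, concentration_unit="mg/mL")
            else:
                self.add_admin(drug, self._in_window(t, 1, 14), tail,
                               rate=10.0, rate_unit="mL/h",
                               concentration=1.0, concentration_unit="mg/mL")
            return
        if variant == "outside_window":
            self.add_admin(drug, t + _jitter_min(self.rng, 17, 24), tail,
                           rate=10.0, rate_unit="mL/h",
                           concentration=1.0, concentration_unit="mg/mL")
        elif variant == "parallel":
            self.add_admin(drug, lead, tail, rate=8.0, rate_unit="mL/h",
                           concentration=1.0, concentration_unit="mg/mL")
            self.add_admin(drug, self._in_window(t, 1, 14),
                           t + _jitter_min(self.rng, 25, 40),
                           rate=10.0, rate_unit="mL/h",
                           concentration=1.0, concentration_unit="mg/mL")
        else:  # carrier_fluid: sub-threshold fluid is a diluent, not a therapy
            self.add_admin(_FLUID_DRUG, self._in_window(t, 1, 14), tail,
                           rate=80.0, rate_unit="mL/h")

    def _plant_increase(self, alarm: AlarmEvent, variant: str, positive: bool) -> None:
        t = alarm.start_time
        lead, tail = self._med_times(t)
        gap = _jitter_min(self.rng, 0.5, 4.0)
        switch = self._in_window(t, 1, 9)
        if positive and variant == "concentration" and alarm.pac in (PAC.HR_HIGH, PAC.IBP_HIGH):
            # same ingredient, two products: 10 mg/mL at 10 mL/h -> 20 mg/mL
            # at 8 mL/h; doses per time 100 -> 160 mg/h
            self.add_admin("D1010", lead, switch, rate=10.0, rate_unit="mL/h",
                           concentration=10.0, concentration_unit="mg/mL")
            self.add_admin("D1011", switch + gap, tail, rate=8.0, rate_unit="mL/h",
                           concentration=20.0, concentration_unit="mg/mL")
            return
        drug = _GI_CONT[alarm.pac]
        self.add_admin(drug, lead, switch, rate=10.0, rate_unit="mL/h",
                       concentration=1.0, concentration_unit="mg/mL")
        if positive:
            rate2 = 15.0
            unit2 = "mL/h"
        elif variant == "incomparable_units":
            rate2, unit2 = 3.0, "drops/min"
        else:  # equal_rate
            rate2, unit2 = 10.0, "mL/h"
        self.add_admin(drug, switch + gap, tail, rate=rate2, rate_unit=unit2,
                       concentration=1.0, concentration_unit="mg/mL")

    def _plant_stop(self, alarm: AlarmEvent, variant: str, positive: bool) -> None:
        t = alarm.start_time
        drug = _SD_CONT[alarm.pac]
        lead, tail = self._med_times(t)
        if positive:
            self.add_admin(drug, lead, self._in_window(t, 1, 14),
                           rate=10.0, rate_unit="mL/h",
                           concentration=1.0, concentration_unit="mg/mL")
            return
        if variant == "outside_window":
            self.add_admin(drug, lead, t + _jitter_min(self.rng, 17, 24),
                           rate=10.0, rate_unit="mL/h",
                           concentration=1.0, concentration_unit="mg/mL")
        else:  # parallel second line of the same ingredient keeps running
            self.add_admin(drug, lead, self._in_window(t, 1, 14),
                           rate=10.0, rate_unit="mL/h",
                           concentration=1.0, concentration_unit="mg/mL")
            self.add_admin(drug, lead - timedelta(minutes=5), tail,
                           rate=6.0, rate_unit="mL/h",
                           concentration=1.0, concentration_unit="mg/mL")

    def _plant_decrease(self, alarm: AlarmEvent, variant: str, positive: bool) -> None:
        t = alarm.start_time
        drug = _SD_CONT[alarm.pac]
        lead, tail = self._med_times(t)
        cut = self._in_window(t, 1, 9)
        gap = _jitter_min(self.rng, 0.5, 4.0)
        self.add_admin(drug, lead, cut, rate=15.0, rate_unit="mL/h",
                       concentration=1.0, concentration_unit="mg/mL")
        rate2 = 8.0 if positive else 15.0  # equal_rate negative
        self.add_admin(drug, cut + gap, tail, rate=rate2, rate_unit="mL/h",
                       concentration=1.0, concentration_unit="mg/mL")

    def add_planned_administration(self, pac: PAC, t: datetime) -> None:
        """A prescribed (planned) bolus inside the window: excluded by
        preprocessing, so it must not flip the annotation."""
        at = self._in_window(t, 1, 14)
        adm = self.add_admin(_GI_BOLUS[pac], at, at, amount=10.0, amount_unit="mg")
        self.prescriptions.append(
            Prescription(
                order_id=adm.order_id,
                scheduled_time=at - _jitter_min(self.rng, 0, 20),
                stay_ref=self.stay.stay_id,
            )
        )

    def add_background_ad_change(self, t: datetime) -> None:
        """An airway-device change unrelated to any alarm (non-escalating
        with respect to alarm windows because the caller places it outside
        them)."""
        choice = ["Wendl-Tubus", "NIV-Maske", "Tubus", "Trachealkanuele"]
        self.add_ad(choice[int(self.rng.integers(0, len(choice)))], t)

    # -- finalize ----------------------------------------------------------

    def finalize(self) -> Bundle:
        b = Bundle()
        b.stays.append(self.stay)
        b.alarms.extend(self.alarms)
        b.ads.extend(
            ADRecord(
                entry_text=r["entry_text"],
                insert_time=r["insert_time"],
                removal_time=r["removal_time"],
                stay_ref=r["stay_ref"],
                record_id=r["record_id"],
            )
            for r in self.ads
        )
        b.vent_states.extend(self.vent_states)
        b.settings.extend(self.settings)
        b.administrations.extend(self.administrations)
        b.prescriptions.extend(self.prescriptions)
        b.ledger.extend(self.ledger)
        return b


def generate_scenario(spec: ScenarioSpec) -> Bundle:
    """Minimal single-alarm fixture exercising exactly one rule.

    Positives satisfy the targeted rule; negatives violate exactly one of
    its conditions.  The alarm sits two hours into a six-hour stay.
    """
    rng = np.random.default_rng(spec.seed)
    builder = _StayBuilder(
        stay_id="S1", bed_id="B1", start=_EPOCH, duration=timedelta(hours=6), rng=rng
    )
    t = _EPOCH + timedelta(hours=2, seconds=_offgrid_seconds(rng))
    builder.plant(spec, t)
    return builder.finalize()


def generate_stay(
    seed: int,
    duration: timedelta = timedelta(hours=24),
    alarm_rate_per_hour: float = 0.4,
    intervention_propensity: float = 0.5,
    stay_id: str = "S1",
    bed_id: str = "B1",
    start_time: datetime = _EPOCH,
    background_ad_changes: int = 2,
    planned_admin_probability: float = 0.2,
    rng: Optional[np.random.Generator] = None,
) -> Bundle:
    """One stay's full table bundle with a ground-truth ledger.

    Alarm arrivals are Poisson at *alarm_rate_per_hour* with a 90-minute
    dead time so the planted scenarios of neighbouring alarms cannot
    interact.  Each alarm draws a uniformly random applicable rule; with
    probability *intervention_propensity* a positive scenario is planted,
    otherwise a negative (a near-miss pattern or nothing at all).
    Reproducible: the same seed yields an identical bundle.
    """
    if alarm_rate_per_hour < 0:
        raise ValueError("alarm rate must be >= 0")
    rng = rng if rng is not None else np.random.default_rng(seed)
    builder = _StayBuilder(stay_id, bed_id, start_time, duration, rng)
    dead_time = timedelta(minutes=90)
    pacs = list(PAC)

    alarm_times: list[datetime] = []
    t = start_time + timedelta(hours=1)
    while alarm_rate_per_hour > 0:
        gap = timedelta(seconds=int(rng.exponential(1.0 / alarm_rate_per_hour) * 3600))
        t = t + max(gap, dead_time)
        if t >= start_time + duration - timedelta(hours=1):
            break
        alarm_times.append(t + timedelta(seconds=_offgrid_seconds(rng)))

    for at in alarm_times:
        pac = pacs[int(rng.integers(0, len(pacs)))]
        rules = applicable_rule_ids(pac)
        rule = rules[int(rng.integers(0, len(rules)))]
        if rng.uniform() < intervention_propensity:
            spec = ScenarioSpec(rule, pac, positive=True)
        elif rng.uniform() < 0.5:
            spec = ScenarioSpec(rule, pac, positive=False)
        else:
            spec = ScenarioSpec("negative", pac)
        builder.plant(spec, at)
        if rng.uniform() < planned_admin_probability:
            builder.add_planned_administration(pac, at)

    # background AD churn, clear of every alarm's respiratory window and of
    # the pre-alarm baseline region the scenarios write into
    blocked = [
        (a - timedelta(minutes=40), a + timedelta(minutes=42)) for a in alarm_times
    ]
    placed = 0
    attempts = 0
    used_seconds: set[int] = set()
    while placed < background_ad_changes and attempts < background_ad_changes * 50:
        attempts += 1
        off = int(rng.uniform(0, (duration - timedelta(hours=1)).total_seconds()))
        if off in used_seconds:  # distinct seconds keep the device chain unambiguous
            continue
        ts = start_time + timedelta(seconds=off)
        if any(lo <= ts < hi for lo, hi in blocked):
            continue
        used_seconds.add(off)
        builder.add_background_ad_change(ts)
        placed += 1

    return builder.finalize()


def generate_dataset(
    seed: int,
    n_stays: int = 20,
    duration: timedelta = timedelta(hours=24),
    alarm_rate_per_hour: float = 0.4,
    intervention_propensity: float = 0.5,
    background_ad_changes: int = 2,
    planned_admin_probability: float = 0.2,
) -> Bundle:
    """Multi-stay bundle; stays occupy distinct beds, one clock."""
    rng = np.random.default_rng(seed)
    out = Bundle()
    for i in range(n_stays):
        b = generate_stay(
            seed=0,
            duration=duration,
            alarm_rate_per_hour=alarm_rate_per_hour,
            intervention_propensity=intervention_propensity,
            stay_id=f"S{i + 1:04d}",
            bed_id=f"B{i % 40 + 1:02d}",
            start_time=_EPOCH + timedelta(days=2 * (i // 40)),
            background_ad_changes=background_ad_changes,
            planned_admin_probability=planned_admin_probability,
            rng=rng,
        )
        out.merge(b)
    return out


# ---- documentation-error injection --------------------------------------


def _floor_to_grid(ts: datetime, granularity: timedelta) -> datetime:
    midnight = ts.replace(hour=0, minute=0, second=0, microsecond=0)
    n = (ts - midnight) // granularity
    return midnight + n * granularity


def inject_errors(
    bundle: Bundle,
    params: ErrorInjectionParams,
    seed: int,
) -> tuple[Bundle, list[dict]]:
    """Corrupt a clean bundle with the observed documentation-error patterns.

    * With probability ``missing_removal_rate`` an airway-device change
      loses the removal timestamp of the superseded device.
    * With probability ``standby_error_rate`` a ventilation change is marked
      as performed in standby, with the deactivation documented after a
      log-normal delay.
    * With probability ``rounding_fraction`` a medication administration has
      its start and end floored to the 5-minute grid.

    Returns the corrupted bundle and a corruption ledger (one row per
    corrupted record).
    """
    rng = np.random.default_rng(seed)
    corruptions: list[dict] = []
    out = Bundle(
        stays=list(bundle.stays),
        alarms=list(bundle.alarms),
        ads=list(bundle.ads),
        vent_states=list(bundle.vent_states),
        settings=list(bundle.settings),
        administrations=list(bundle.administrations),
        prescriptions=list(bundle.prescriptions),
        ledger=[dict(r) for r in bundle.ledger],
    )

    # missing AD removals: iterate AD changes (consecutive inserts per stay)
    by_stay: dict[str, list[int]] = {}
    for i, r in enumerate(out.ads):
        by_stay.setdefault(r.stay_ref, []).append(i)
    for stay, idxs in by_stay.items():
        idxs.sort(key=lambda i: out.ads[i].insert_time)
        for prev_i, next_i in zip(idxs, idxs[1:]):
            prev = out.ads[prev_i]
            if prev.removal_time is None:
                continue
            if rng.uniform() < params.missing_removal_rate:
                out.ads[prev_i] = replace(prev, removal_time=None)
                corruptions.append(
                    {
                        "kind": "missing_removal",
                        "record_id": prev.record_id,
                        "stay_ref": stay,
                    }
                )

    # standby mis-documentation with delayed deactivation
    if params.standby_error_rate > 0:
        mu, sigma = params.lognormal_params
        new_states = []
        for r in out.vent_states:
            new_states.append(r)
            if r.standby or rng.uniform() >= params.standby_error_rate:
                continue
            delay = timedelta(seconds=int(rng.lognormal(mu, sigma) * 60))
            idx = len(new_states) - 1
            new_states[idx] = dataclasses.replace(r, standby=True)
            new_states.append(
                dataclasses.replace(
                    r,
                    standby=False,
                    time=r.time + delay,
                    record_id=r.record_id + "-deact",
                )
            )
            corruptions.append(
                {
                    "kind": "standby_error",
                    "record_id": r.record_id,
                    "stay_ref": r.stay_ref,
                    "deactivation_delay_min": delay.total_seconds() / 60.0,
                }
            )
        out.vent_states = new_states

    # round medication timestamps down to the documentation grid
    grid = timedelta(minutes=5)
    for i, adm in enumerate(out.administrations):
        if rng.uniform() >= params.rounding_fraction:
            continue
        new_start = _floor_to_grid(adm.start_time, grid)
        new_end = _floor_to_grid(adm.end_time, grid)
        if adm.start_time == adm.end_time:
            new_end = new_start  # a bolus stays a bolus
        out.administrations[i] = replace(adm, start_time=new_start, end_time=new_end)
        corruptions.append(
            {
                "kind": "rounded_timestamp",
                "record_id": adm.record_id,
                "stay_ref": adm.stay_ref,
            }
        )
    return out, corruptions


def ad_change_stats(
    ads: Sequence[ADRecord],
    tolerance: timedelta = timedelta(minutes=1),
) -> tuple[int, int]:
    """(number of AD changes, number lacking a removal of the preceding AD).

    An AD change is a consecutive pair of device documentations on one
    stay; the preceding removal counts as logged when its timestamp exists
    and lies no later than *tolerance* after the successor's insertion.
    """
    by_stay: dict[str, list[ADRecord]] = {}
    for r in ads:
        by_stay.setdefault(r.stay_ref, []).append(r)
    n_changes = 0
    n_missing = 0
    for recs in by_stay.values():
        recs.sort(key=lambda r: r.insert_time)
        for prev, nxt in zip(recs, recs[1:]):
            n_changes += 1
            logged = (
                prev.removal_time is not None
                and prev.removal_time <= nxt.insert_time + tolerance
            )
            if not logged:
                n_missing += 1
    return n_changes, n_missing
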