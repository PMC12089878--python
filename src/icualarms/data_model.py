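"""Domain types shared by every stage of the alarm-annotation pipeline.

The package annotates ICU patient-monitoring alarms as *actionable* (health
care staff reacted to the alarm with a documented intervention) or
*nonactionable*.  Alarms are matched against respiratory-management and
medication-management interventions documented in a patient data management
system (PDMS) within fixed post-alarm time windows.

This module holds only the record types, the physiological-alarm-condition
(PAC) taxonomy, and the annotation configuration.  All computation lives in
the downstream modules.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from datetime import datetime, timedelta
from typing import Optional

__all__ = [
    "PAC",
    "VitalSign",
    "Direction",
    "ALARM_LABELS",
    "DIRECTION_AMBIGUOUS_LABELS",
    "classify_pac",
    "UnknownAlarmLabelError",
    "VentParameter",
    "LOGICAL_PARAMETERS",
    "AlarmEvent",
    "ADRecord",
    "VentStateRecord",
    "VentParamSetting",
    "MedicationAdministration",
    "Prescription",
    "StayInterval",
    "AnnotationConfig",
    "AnnotationResult",
    "Label",
]


class VitalSign(str, enum.Enum):
    SPO2 = "SpO2"
    HR = "HR"
    IBP = "invasive BP"


class Direction(str, enum.Enum):
    LOW = "low"
    HIGH = "high"


class PAC(str, enum.Enum):
    """Physiological alarm condition.

    Five conditions cover the fourteen monitor alarm labels.  Only
    ``SPO2_LOW`` is eligible for the respiratory rules; every PAC is
    eligible for medication rules (stop/decrease excluded for SPO2_LOW).
    """

    SPO2_LOW = "spo2_low"
    HR_LOW = "hr_low"
    HR_HIGH = "hr_high"
    IBP_LOW = "ibp_low"
    IBP_HIGH = "ibp_high"

    @property
    def vital_sign(self) -> VitalSign:
        return {
            PAC.SPO2_LOW: VitalSign.SPO2,
            PAC.HR_LOW: VitalSign.HR,
            PAC.HR_HIGH: VitalSign.HR,
            PAC.IBP_LOW: VitalSign.IBP,
            PAC.IBP_HIGH: VitalSign.IBP,
        }[self]

    @property
    def direction(self) -> Direction:
        return Direction.LOW if self.value.endswith("low") else Direction.HIGH


#: The fourteen monitor alarm labels, spelled as the monitoring system emits
#: them (German-flavoured vendor strings).  Mapping to a PAC; ``None`` marks
#: labels whose direction comes from the alarm-threshold column.
_LABEL_TO_PAC: dict[str, Optional[PAC]] = {
    "Desat": PAC.SPO2_LOW,
    "SpO2": PAC.SPO2_LOW,
    "SpO2l": PAC.SPO2_LOW,
    "SpO2r": PAC.SPO2_LOW,
    "SpO2po": PAC.SPO2_LOW,
    "SpO2pr": PAC.SPO2_LOW,
    "Asystolie": PAC.HR_LOW,
    "xBrady": PAC.HR_LOW,
    "xTachy": PAC.HR_HIGH,
    "HF": None,        # heart-rate limit alarm: low or high threshold
    "ABPs": None,      # systolic arterial pressure
    "ARTs": None,
    "ABPm": None,      # mean arterial pressure
    "ARTm": None,
}

ALARM_LABELS: tuple[str, ...] = tuple(_LABEL_TO_PAC)

DIRECTION_AMBIGUOUS_LABELS: frozenset[str] = frozenset(
    k for k, v in _LABEL_TO_PAC.items() if v is None
)


class UnknownAlarmLabelError(ValueError):
    """Raised for an alarm label outside the fourteen-label vocabulary."""


def classify_pac(alarm_label: str, direction: Optional[Direction | str] = None) -> PAC:
    """Resolve a monitor alarm label to its physiological alarm condition.

    Labels that name the violated threshold themselves (``Desat``,
    ``xBrady`` ...) ignore *direction*; the heart-rate and arterial-pressure
    limit alarms (``HF``, ``ABPs``, ``ARTs``, ``ABPm``, ``ARTm``) need the
    threshold direction, which real alarm logs carry in a separate column.

    Raises
    ------
    UnknownAlarmLabelError
        If *alarm_label* is not one of the fourteen known labels.
    ValueError
        If a direction-ambiguous label is given without a direction.
    """
    try:
        pac = _LABEL_TO_PAC[alarm_label]
    except KeyError:
        raise UnknownAlarmLabelError(
            f"unknown alarm label {alarm_label!r}; expected one of {sorted(_LABEL_TO_PAC)}"
        ) from None
    if pac is not None:
        return pac
    if direction is None:
        raise ValueError(
            f"alarm label {alarm_label!r} needs a threshold direction (low/high)"
        )
    direction = Direction(direction)
    vital = VitalSign.HR if alarm_label == "HF" else VitalSign.IBP
    if vital is VitalSign.HR:
        return PAC.HR_LOW if direction is Direction.LOW else PAC.HR_HIGH
    return PAC.IBP_LOW if direction is Direction.LOW else PAC.IBP_HIGH


class VentParameter(str, enum.Enum):
    """Settable ventilation parameters (the seven compatibility-table columns).

    The two oxygen-flow variants (delivered on a wall flowmeter during plain
    oxygen therapy vs. set on a ventilator/high-flow device) are distinct
    physical parameters but one logical parameter for the parameter-increase
    rule.
    """

    O2_FLOW_FLOWMETER = "o2_flow_flowmeter"
    O2_FLOW_OTHER = "o2_flow_other"
    FIO2 = "fio2"
    PEEP = "peep"
    PSUPP = "psupp"
    PINSP = "pinsp"
    SET_RATE = "set_rate"


#: Logical parameters evaluated by the parameter-increase rule (six): the two
#: oxygen-flow columns collapse into one logical oxygen-flow parameter.
LOGICAL_PARAMETERS: tuple[tuple[str, tuple[VentParameter, ...]], ...] = (
    ("o2_flow", (VentParameter.O2_FLOW_FLOWMETER, VentParameter.O2_FLOW_OTHER)),
    ("fio2", (VentParameter.FIO2,)),
    ("peep", (VentParameter.PEEP,)),
    ("psupp", (VentParameter.PSUPP,)),
    ("pinsp", (VentParameter.PINSP,)),
    ("set_rate", (VentParameter.SET_RATE,)),
)


@dataclass(frozen=True)
class AlarmEvent:
    """One monitor alarm start.  Alarms are evaluated individually."""

    alarm_id: str
    bed_id: str
    start_time: datetime
    alarm_label: str
    pac: PAC
    stay_ref: Optional[str] = None

    def __post_init__(self) -> None:
        if self.alarm_label not in _LABEL_TO_PAC:
            raise UnknownAlarmLabelError(self.alarm_label)


@dataclass(frozen=True)
class ADRecord:
    """An airway-device (AD) documentation entry.

    An AD is considered inserted when an AD type is documented with a
    timestamp, and removed when a removal timestamp is documented (or a new
    AD supersedes it).
    """

    entry_text: str
    insert_time: datetime
    removal_time: Optional[datetime]
    stay_ref: str
    record_id: str = ""

    def __post_init__(self) -> None:
        if self.removal_time is not None and self.removal_time < self.insert_time - timedelta(minutes=1):
            raise ValueError(
                f"AD removal {self.removal_time} precedes insertion {self.insert_time} "
                "beyond the documentation tolerance"
            )


@dataclass(frozen=True)
class VentStateRecord:
    """Ventilation device + mode documentation (always stored as a pair),
    with the device's standby flag."""

    vd_text: str
    vm_text: str
    standby: bool
    time: datetime
    stay_ref: str
    record_id: str = ""


@dataclass(frozen=True)
class VentParamSetting:
    """A set (not measured) ventilation parameter value."""

    parameter: VentParameter
    value: float
    time: datetime
    stay_ref: str
    record_id: str = ""

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"set ventilation parameter value must be >= 0, got {self.value}")


@dataclass(frozen=True)
class MedicationAdministration:
    """One administration row from the PDMS medication chart.

    Technique is derived from the timestamps: bolus iff ``start_time ==
    end_time``, continuous otherwise.  Rates/concentrations/amounts keep
    their documented unit strings; unit handling happens in the medication
    rules.
    """

    order_id: str
    drug_id: str
    start_time: datetime
    end_time: datetime
    stay_ref: str
    rate: Optional[float] = None
    rate_unit: Optional[str] = None
    concentration: Optional[float] = None
    concentration_unit: Optional[str] = None
    amount: Optional[float] = None
    amount_unit: Optional[str] = None
    route_text: str = ""
    record_id: str = ""

    def __post_init__(self) -> None:
        if self.end_time < self.start_time:
            raise ValueError(
                f"administration end {self.end_time} precedes start {self.start_time}"
            )

    @property
    def is_bolus(self) -> bool:
        return self.start_time == self.end_time


@dataclass(frozen=True)
class Prescription:
    """A planned (prescribed-in-advance) intervention, used to exclude
    regular planned administrations from annotation."""

    order_id: str
    scheduled_time: datetime
    stay_ref: str


@dataclass(frozen=True)
class StayInterval:
    """A patient stay on one bed, as a half-open interval [admit, discharge)."""

    stay_id: str
    bed_id: str
    admit_time: datetime
    discharge_time: datetime

    def __post_init__(self) -> None:
        if self.discharge_time <= self.admit_time:
            raise ValueError(f"stay {self.stay_id}: discharge must follow admission")

    def contains(self, t: datetime) -> bool:
        return self.admit_time <= t < self.discharge_time


@dataclass(frozen=True)
class AnnotationConfig:
    """Tunable windows, tolerances and thresholds of the annotation method.

    Defaults are the method's published constants: a 30-minute post-alarm
    window for respiratory interventions, 15 minutes for medication
    interventions, a 5-minute adjacency gap distinguishing a rate change
    from an independent start/stop, a 1-minute tolerance for airway-device
    removals documented just after their successor, a 5-minute
    documentation-rounding grid, and a 500 mL/h carrier-fluid threshold.
    """

    resp_window: timedelta = timedelta(minutes=30)
    med_window: timedelta = timedelta(minutes=15)
    med_adjacency_gap: timedelta = timedelta(minutes=5)
    ad_removal_tolerance: timedelta = timedelta(minutes=1)
    rounding_granularity: timedelta = timedelta(minutes=5)
    fluid_carrier_threshold_ml_per_h: float = 500.0
    compensate_rounding: bool = True
    planned_match_tolerance: timedelta = timedelta(minutes=30)
    #: which bounds of the physiological-range table remove values:
    #: "life" (range compatible with life) or "outlier" (acceptable outliers)
    range_bound: str = "life"

    def __post_init__(self) -> None:
        for name in (
            "resp_window",
            "med_window",
            "med_adjacency_gap",
            "ad_removal_tolerance",
            "rounding_granularity",
            "planned_match_tolerance",
        ):
            if getattr(self, name) <= timedelta(0):
                raise ValueError(f"{name} must be a positive duration")
        if self.fluid_carrier_threshold_ml_per_h <= 0:
            raise ValueError("fluid_carrier_threshold_ml_per_h must be > 0")
        if self.range_bound not in ("life", "outlier"):
            raise ValueError("range_bound must be 'life' or 'outlier'")

    def with_(self, **kw) -> "AnnotationConfig":
        return replace(self, **kw)


class Label(str, enum.Enum):
    ACTIONABLE = "actionable"
    NONACTIONABLE = "nonactionable"
    UNLINKED = "unlinked"


@dataclass(frozen=True)
class MatchedIntervention:
    """Reference to the intervention record that made a rule fire."""

    rule_id: str
    record_id: str
    matched_time: datetime
    detail: str = ""


@dataclass(frozen=True)
class AnnotationResult:
    """Per-alarm annotation outcome.

    ``label`` is actionable iff at least one rule fired; ``fired_rules``
    only ever contains rules applicable to the alarm's PAC.
    """

    alarm_id: str
    pac: Optional[PAC]
    label: Label
    fired_rules: frozenset[str] = frozenset()
    matched_interventions: tuple[MatchedIntervention, ...] = ()
    window_resp: Optional[tuple[datetime, datetime]] = None
    window_med: Optional[tuple[datetime, datetime]] = None

    def __post_init__(self) -> None:
        if self.label is Label.ACTIONABLE and not self.fired_rules:
            raise ValueError("actionable result must list at least one fired rule")
        if self.label is not Label.ACTIONABLE and self.fired_rules:
            raise ValueError(f"{self.label.value} result must not list fired rules")
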