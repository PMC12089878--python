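# icualarms

Rule-based annotation of ICU patient-monitoring alarms as **actionable** or
**nonactionable**, by linking each alarm to respiratory- and
medication-management interventions documented in PDMS-style records
(patient data management system) within fixed post-alarm time windows.

Alarm fatigue research needs large labelled alarm datasets, but hand
annotation does not scale and public ICU datasets lack alarm logs. This
package implements a deterministic, machine-readable rule set that labels
an alarm *actionable* when staff demonstrably reacted to it — escalating
airway management, escalating respiratory support, raising a ventilator
setting, or giving/adjusting a relevant drug — within a defined time
window. It is aimed at clinical-informatics researchers who have alarm
logs and PDMS extracts (or want to prototype against synthetic ones: a
seeded generator with ground-truth labels ships with the package).

## The method

Fourteen monitor alarm labels are clustered into five **physiological alarm
conditions** (PACs): SpO2 low, heart rate low/high, invasive blood pressure
low/high. Eight general rules decide actionability:

**Respiratory rules** (SpO2-low alarms only, 30-minute post-alarm window):

| rule | fires when |
|---|---|
| airway-device change | last(AD level) < max(AD level) in window, and no removal of the new device logged |
| support-therapy change | last(RST level) < max(RST level) in window, changes during ventilator standby excluded |
| parameter increase | last(set parameter) < max(set parameter) in window, only while the parameter is settable under the current therapy |

Airway devices (AD) are mapped onto an invasiveness scale, level 1 ("no
AD") to level 9 (endotracheal tube / tracheal cannula). Ventilation
device+mode pairs map to one of 7 respiratory support therapy (RST)
categories/levels; a compatibility table says which of the 7 settable
parameters (oxygen flow on/off a flowmeter, FiO2, PEEP, Psupp, Pinsp, set
rate) is meaningful under each level. During standby the effective RST
level and set parameters count as 0, except for spontaneous breathing and
plain oxygen therapy where the standby flag carries no meaning.

**Medication rules** (all PACs, 15-minute window, one active ingredient at
a time): *bolus*, *start*, *increase*, *stop*, *decrease*. Technique is
bolus iff the documented start equals the end time. An episode starting
within 5 minutes of its predecessor's end is a rate change, not an
independent start/stop; rates are compared in a common unit, or as dose per
time (rate × concentration) when concentrations differ. Stop/decrease
never apply to SpO2-low alarms. IV fluids running below 500 mL/h are
carriers (diluents) and are ignored.

An alarm is **actionable** iff at least one applicable rule fires; the
output lists every fired rule and the matched intervention record, so each
label is auditable.

Known documentation errors are handled explicitly: removals of superseded
airway devices are missing in a fraction of changes (a 1-minute tolerance
absorbs late removals), ventilation changes are sometimes mis-documented
during standby, and many medication timestamps are rounded down to a
5-minute grid — the engine can treat an on-grid timestamp as the interval
`[t, t+5 min)` so round-down cannot hide an intervention.

## Worked example

```bash
icualarms simulate demo --seed 42 --n-stays 4   # synthetic bundle + ground truth
icualarms annotate demo out                     # annotate it
```

prints

```
wrote 31 alarms across 4 stays to demo
31 alarms: 19 actionable, 12 nonactionable, 0 unlinked
```

`out/results.csv` holds one row per fired rule (plus one row for each
nonactionable alarm), e.g.

```
alarm_id,pac,label,rule_id,matched_record,matched_time,detail,...
S0001-AL0001,ibp_low,actionable,decrease,S0001-MA0005,2024-01-01 07:10:47,decrease nitroglycerin (15.0mL/h -> 8.0mL/h),...
```

— a hypotension alarm labelled actionable because a nitroglycerin infusion
was turned down from 15 to 8 mL/h shortly after the alarm. The ground
truth planted by the generator is in `demo/ledger.csv`; on clean synthetic
data the engine reproduces it exactly. `out/manifest.json` records the
config, input digests and reconciliation counts of the run.
`icualarms validate-mappings` checks the structural invariants of a
mapping directory (18 AD categories, 7 RST categories, 8 route categories,
the all-"No" level-1 compatibility row, ...).

The shipped mapping tables (`src/icualarms/data/*.csv`) are representative:
they have the method's exact schema, category counts and orderings, but
institution-specific content must be supplied by the user.

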