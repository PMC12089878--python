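# Methods

## Scope and model

The package decides, per alarm, whether health care staff reacted to it —
the alarm is *actionable* — by searching the patient's PDMS documentation
for defined interventions inside a post-alarm time window. Every alarm is
evaluated individually; co-occurring alarms may match the same
intervention. Alarm priorities, alarm durations/ends, technical alarms,
alarm trends and de-escalations of respiratory therapy are out of scope.

Five physiological alarm conditions (PACs) partition the fourteen monitor
labels. The monitor names the violated threshold for most labels (`Desat`,
`xBrady`, `xTachy`, the SpO2 variants, `Asystolie`); the generic limit
alarms (`HF`, `ABPs/ARTs`, `ABPm/ARTm`) carry the direction in a separate
threshold column, which `classify_pac` accepts as an argument.

Timestamps are timezone-naive local time at second precision; alarms and
documentation must share one clock. All windows are half-open
`[t_alarm, t_alarm + w)`, which avoids double counting at boundaries.
"Last value before the alarm" is inclusive of the alarm instant.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `resp_window` | 30 min | post-alarm window for respiratory rules |
| `med_window` | 15 min | post-alarm window for medication rules |
| `med_adjacency_gap` | 5 min | max gap for an episode pair to count as one continued administration (closed boundary: a gap of exactly 5 min still chains) |
| `ad_removal_tolerance` | 1 min | a removal documented this close to the successor's insertion belongs to the documentation of one device change |
| `rounding_granularity` | 5 min | grid of the PDMS input dialog's round-down behaviour |
| `fluid_carrier_threshold_ml_per_h` | 500 | IV fluid at or above this rate (or bolus volume) is a therapy; below, a carrier. The boundary value is a therapy ("< 500" defines the carrier) |
| `compensate_rounding` | on | treat on-grid medication timestamps as uncertainty intervals |
| `planned_match_tolerance` | 30 min | administration-to-prescription time match for planned-intervention exclusion (no published value; configurable) |
| `range_bound` | `life` | which bounds of the plausibility table remove documented values (`life` = compatible-with-life, `outlier` = acceptable-outlier bounds; both are published conventions, the choice is exposed) |

## Standby and settability

A ventilator in standby delivers nothing, so the effective RST level is 0
and set-parameter entries count as 0 — except during spontaneous breathing
and plain oxygen therapy (levels 1–2), whose standby flag is meaningless.
The implementation folds both published standby exemptions into one
mechanism: a setting contributes its value iff the parameter is settable
(per the compatibility table) under the *effective* RST level at the
setting's own time. Oxygen flow during oxygen therapy survives standby
automatically because level 2 is standby-exempt and the flowmeter column is
settable there; a PEEP entry during high-flow therapy is neutralized
because level 4 has no PEEP column. "Last value before the alarm" applies
the settability check at the alarm instant.

With no ventilation documentation at all, a patient counts as breathing
spontaneously (level 1); with no airway-device documentation, AD level 1
("no AD"). An unmapped VD-VM pair or device string yields an explicit
*unmapped* outcome: the affected rule does not fire, the event is counted
in the run log, and the batch continues.

## Rounding compensation

A timestamp sitting exactly on the 5-minute grid may have been rounded
down, so its true time lies in `[t, t + 5 min)`; off-grid timestamps were
typed exactly. With compensation on (the default):

* window membership holds iff the uncertainty interval intersects the
  window;
* an episode pair chains as predecessor/successor iff *some* realization
  of the two intervals satisfies the adjacency condition (possibilistic);
* a parallel same-ingredient line vetoes a start/stop only when the
  overlap holds under *every* realization (certainty).

Enabling conditions are evaluated optimistically and vetoing conditions
pessimistically so that round-down corruption can only add, never remove,
detected interventions; on exact (off-grid) timestamps every relation
degenerates to the literal comparison, so compensation has no effect on
clean data. The cost is a small optimistic bias on rounded data: an event
truly just before the alarm can be counted as in-window. The published
account reports the round-down problem but not a correction; interval
intersection is the minimal sound fix for it and is this package's design
choice.

## Mappings

Shipped tables are *representative*: schema, category counts and orderings
are the method's (18 AD categories on levels 1–9, 7 RST categories/levels,
the exact 7×7 compatibility matrix, 8 route categories, 2 techniques,
mixtures with ≥ 2 ingredients); the row content (device strings, drug
identifiers, relevance flags) is a plausible synthetic institution, since
real mapping content is institution-specific. Category names beyond the
published anchors (level 1 "no AD", level 9 endotracheal tube/tracheal
cannula, RST level ordering implied by the compatibility matrix) are
placeholders with correct counts. `validate-mappings` enforces the
structural invariants on user-supplied tables, including that
stop/decrease relevance is never set for SpO2-low and that each raw AD
string has exactly one annotation-flagged resolution.

## Synthetic data generator

`generate_stay` emulates one stay's five input streams with a ground-truth
ledger. Design choices:

* **Alarm arrivals** are Poisson (rate 0.4/h by default; the real
  inter-arrival distribution is unpublished) with a 90-minute dead time.
  The dead time guarantees that one alarm's planted scenario cannot reach a
  neighbouring alarm's windows, which is what makes the intent ledger a
  sound ground truth. PAC is drawn uniformly.
* **Scenarios**: each alarm draws a uniformly random applicable rule and,
  with probability `intervention_propensity` (default 0.5), a positive
  pattern satisfying exactly that rule; otherwise a near-miss negative
  violating exactly one condition, or no intervention at all. Respiratory
  scenarios re-document a baseline device/therapy 35 minutes before the
  alarm so stay history cannot change the planted escalation relation.
* **Clean timestamps** carry a nonzero within-minute second component, as
  pump and monitor clocks do, so they never sit on the 5-minute grid and
  rounding compensation is a no-op on clean bundles.
* **Error injection** is a separate pass: deleting predecessor removals of
  device changes (default rate 9.0%), marking ventilation changes as made
  in standby with a deactivation after a log-normal delay fitted to the
  two published quantiles (median 7 min, 75th percentile 20 min — the
  minimal positive-support two-parameter choice), and flooring medication
  timestamps to the 5-minute grid (default fraction 60%). Every corruption
  is itself ledgered.

What the generator does **not** emulate: vital-sign waveforms (rules never
read them), free-text spelling noise beyond the shipped vocabulary,
clinically correlated intervention choices, overlapping alarm bursts, or
inter-stream inconsistencies other than the three injected error
processes. Passing tests therefore demonstrate the rule engine's
correctness against the stated rule semantics and its robustness to those
three documented error patterns — not performance on real hospital data,
where unmodelled documentation behaviour will add noise.

## Numerical and tie-break choices

* Rates compare after unit normalization (mL, mg, hours as base units);
  differing concentrations compare by dose per time. Unknown units or
  per-kg rates without a bodyweight are *incomparable* and block the
  increase/decrease rules rather than guessing.
* The predecessor of an episode is the latest possibly-adjacent one (ties
  by record id); the successor the earliest.
* A removal of an escalated airway device within `ad_removal_tolerance` of
  its own insertion is treated as documentation noise, not a genuine
  de-escalation.
* Stays are half-open `[admission, discharge)`; a boundary-instant alarm
  belongs to the later stay.
* Duplicate identical rows are dropped with a counter; filtering never
  reorders surviving events.

## Problem sizes

The bundled checks run at desk scale: clean-recovery uses 80 stays
(≈ 600 alarms, all 8 rules represented), oracle equivalence 1,000 random
instances per compensation mode against an exhaustive-scan evaluator, and
the missing-removal rate is measured over ≥ 40,000 synthetic device
changes. Throughput is linear in alarms × window-local events.

## Known limitations

* The planned-intervention exclusion matches on order id plus scheduled
  time only; recurring prescriptions with rewritten order ids will not be
  excluded.
* An airway-device removal alone (without a new device) never counts as an
  intervention; the rule set has no such rule.
* Standby mis-documentation is detected only through the level-0
  semantics; the engine does not attempt to repair the standby flag, so
  injected standby errors can produce false negatives by design.
* Bodyweight-based rates (µg/kg/min) are supported in the unit table but
  compare only between per-kg episodes with matching concentrations;
  converting them to absolute doses would need a bodyweight, which the
  administration records do not carry.
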