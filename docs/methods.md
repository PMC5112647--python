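# Methods

## Scope and structure

`orsim` models one operating room in isolation: a strictly sequential
timeline of first-patient delay, procedures, turnovers and cleanup,
with no contention between rooms, no PACU stage, and no intra-procedure
event timing. Because activities on a single resource are totally
ordered, the engine is a direct event timeline rather than a
process-interaction framework: each day is replayed slot by slot from a
pre-generated draw table, which makes the paired-arm design exact (see
*Random-number architecture*).

A *replication* is one simulated month of 21 working days; reported
outputs are means over replications. The default of 50 replications
(1,050 OR days) reproduces the scale of sampling error in the reference
tabulations this model was calibrated against; analyses in the test
suite and acceptance script use 300–400 replications to shrink Monte
Carlo error below their tolerance bands.

## Duration model

Four stochastic inputs drive the day, in Arena-style moment
parameterizations (minutes):

| input | family | parameters | analytic mean / SD |
|---|---|---|---|
| procedure time | lognormal | arithmetic mean 72.9, SD 29.2 | 72.9 / 29.2 |
| turnover | shifted exponential | offset 10, mean-of-excess 25.6 | 35.6 / 25.6 |
| first-patient delay | discrete inverse-CDF | (0.5, 5), (1.0, 15) | 10 / 5 |
| cleanup | triangular | 7.5 / 15 / 22.5 | 15 / ~3.06 |

The lognormal is parameterized by the *arithmetic* moments of the
variate itself; the underlying normal parameters are
σ² = ln(1 + (s/m)²), μ = ln m − σ²/2 (for the base procedure time,
σ ≈ 0.3857, μ ≈ 4.2147). This convention is what makes the entered
mean equal the realized mean procedure time.

When a point estimate is changed (e.g. 145-minute deep-block
procedures), the SD follows a **fixed variability ratio**: the SD is
rescaled proportionally to the mean (`scaled_sd`), keeping the
coefficient of variation at 29.2/72.9 ≈ 0.4005. Deep-block procedure
times therefore have SD ≈ 58.1 min, which is why reference-arm
overtime is much higher there despite the same expected daily workload.

## Day-timeline conventions

Clock minutes run from the day start; the regular day is
`day_end − day_start` = 510 min. The conventions below are the
behaviourally meaningful choices the model's published tabulations do
not state explicitly; they were fixed by calibrating candidate
conventions against the full set of reference outputs (base case,
never-cancel and move-up sensitivity rows), and are deliberate model
semantics, not incidental implementation detail:

* **Turnovers precede activities.** A turnover separates consecutive
  slot activities; the first activity of the day needs none. A slot's
  *proposed start* includes the preceding turnover, and the
  time-cancellation policy is evaluated at that proposed start against
  the slot's drawn (true) duration.
* **Other-reason cancellations are resolved first.** A no-show or
  patient-unavailability cancellation is exogenous — decided before the
  OR's clock matters — so each slot draws its 10.7% other-reason
  cancellation before the time policy is consulted. When the next case
  is not moved up (the default), the cancelled slot still occupies its
  effective duration — including the arm's time delta — plus the
  preceding turnover, as idle time, even late in the day. With
  `move_up_on_cancel` the slot is skipped entirely.
* **Time-cancelled slots consume nothing.** If the policy cancels a
  surviving slot, the clock does not advance; the day effectively ends
  earlier. Under the base policy ("no case may start at or after the
  day end"), subsequent non-cancelled slots are then usually cancelled
  as well.
* **Emergencies bump, never cancel.** With per-slot probability
  `p_emergency`, an emergency case (same duration distribution) is
  inserted before the scheduled slot; it is always performed, whatever
  the clock says. A semi-emergency may be appended after the last slot.
* **Overtime includes cleanup.** Staff stay through the end-of-day
  cleanup; the day *close* is the last activity's end plus the cleanup
  draw, and the overrun past 510 min is rounded up to whole 30-minute
  blocks paid to each of the 5 eligible staff
  (`ceil(overrun/30) × 0.5 h × 5`).
* **A day is "complete"** when no slot was cancelled for lack of OR
  time *and* the room closed (cleanup included) within the regular day.
  Both conditions are needed: a day that only finished "on time"
  because a case was pushed off the schedule did not complete all its
  procedures.
* **Effective durations are floored at 1 min** after applying a
  negative arm delta; at the modelled means the floor essentially never
  binds.

## Intervention arms

An arm is (time delta if verified, time delta if unverified, RNMB risk
if unverified). Defaults: neostigmine (0, 0, 0.60); sugammadex
(−14 min, 0, 0.042 = 0.60 × (1 − 0.93)). Verification (TOF ≥ 0.9
confirmed before extubation) is a per-patient Bernoulli(p) shared
across arms; scenario sweeps vary p from 0 to 1. A verified patient has
no residual block in either arm. Conditional on residual block,
hypoxemia and upper-airway obstruction occur independently with
absolute excess probabilities 0.245 and 0.442; background complication
incidence in block-free patients is set to zero because only
between-arm differences are reported and background cancels under the
paired design. The deep-block exploratory applies its hypothetical
saving to *all* comparator procedures (verification does not gate the
time channel there) and is reported at p = 0.

The per-patient absolute risk reduction reported in the sweep is
analytic, `(1 − p) × (risk_ref − risk_cmp)`: the reference tabulation
is exactly linear in 1 − p, so this row was evidently not a Monte Carlo
estimate, and the simulated estimator would sit on a rounding boundary
(55.8% → "56%") that its own sampling noise straddles.

## Random-number architecture

All randomness derives from one master seed through named substreams:
generator = f(master seed, purpose label, replication, day), with the
purpose label hashed (CRC-32) into the seed sequence. Every quantity a
day needs — durations, turnovers, delay, cleanup, cancellation/
emergency/verification uniforms, and the RNMB/complication uniforms —
is drawn once per (replication, day) into a draw table, indexed by slot,
*before* either arm is simulated. Both arms then replay the same table;
only the arm parameters differ. Consequences, each holding in every
replication (and asserted in the test suite):

* identical arms produce exactly zero differences;
* the comparator (non-positive deltas) can only rescue
  time-cancellations, never create them, so cancellations avoided and
  procedures gained are non-negative;
* RNMB events are monotonically coupled (each patient's uniform is
  compared against nested thresholds 0.042 < 0.60), so cases avoided
  are non-negative, and likewise for the shared complication uniforms.

Slot-indexed (rather than sequentially consumed) draws keep the arms
aligned even when they disagree about which slots are performed.

## Reported outputs and rounding

Per scenario: OR minutes saved per day (applied per-procedure
reductions summed over performed comparator procedures, divided by 21
— not the end-of-day clock difference, which would conflate savings
with rescued cancellations); % of days complete; procedures performed
(emergencies included, tallied separately for slot conservation);
cancellations by cause; paid overtime hours; RNMB/hypoxemia/airway
cases avoided (means of replication-wise differences); absolute risk
reduction; NNTs (comparator procedures performed / cases avoided,
reported to one decimal, not-applicable when nothing is avoided). CSV
tables round counts and hours to one decimal, percentages to one
decimal and minutes to integers.

## Numerical choices

* Overrun-to-blocks division is rounded at 10⁻⁹ before the ceiling to
  keep exact block boundaries (e.g. a 30.0-min overrun is one block).
* Per-procedure applied savings are rounded at 10⁻⁹ min in the tally so
  a zero-delta arm reports exactly zero minutes saved.
* Boundary semantics: a slot proposed exactly at the day end is
  cancelled under the base policy; exactly half-completable is *not*
  cancelled under the 50% rule; a day closing exactly at the day end
  incurs no overtime.
* Degenerate inputs: zero-SD lognormals and `fixed` distributions give
  point masses, which the test suite uses for hand-computable oracle
  schedules (e.g. 10 + 5×72.9 + 4×35.6 = 516.9 min to last procedure
  end, day close 531.9, one overtime block).

## What the generator does and does not emulate

Simulated months capture scheduling variability (duration tails,
turnover variation, cancellations, emergency insertions) under
stationary, independent draws. They do not capture: correlation between
a day's case durations (e.g. one surgeon running late all day),
case-mix heterogeneity across slots or days, adaptive scheduling
behaviour (staff speeding up when running late, case re-ordering),
seasonal or weekday effects, or multi-room interactions. Passing the
reproduction tests therefore shows fidelity to this stylized OR, not to
any particular hospital's empirical performance; the one-way
sensitivity suite (cancellation policy, move-up rule, emergency rate,
time-saving CI bounds) is the intended way to probe how conclusions
move with those assumptions.

## Known limitations

* Aspiration and post-operative muscle weakness are not modelled as
  residual-block sequelae, and no costs, drug doses or vial wastage are
  computed; outputs are operational and clinical counts only.
* The emergency probability is interpreted per scheduled slot (at most
  one insertion per slot); under heavy emergency load the monthly
  emergency count is capped at the slot count.
* The 50%-completable cancellation rule uses the slot's drawn (true)
  duration, which the scheduler would not actually know; using the
  scheduled mean instead would be an easy variant but is not what the
  fixed draw-table design calibrates against.
* Replication means of small counts (monthly time-cancellations ≈ 3–4)
  carry relative Monte Carlo errors of a few percent even at 400
  replications; comparisons on those outputs should use the paired
  differences, whose variance the common-random-numbers design
  suppresses.
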