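# Methods

## Task engine

The engine is a deterministic discrete-event state machine over integer
milliseconds from session start (button ids 1-based). State: clock, current
cue (a button id, or ANY on the 1-button task), an optional time-out deadline,
and the trial history. Scoring rules for a press `(button, t_down, duration)`:

1. If a time-out is active at `t_down`, the press is a TIMEOUT_PRESS and the
   time-out is prolonged. Under the default RESTART policy the full period
   restarts at `t_down`; under EXTEND one period is appended to the current
   deadline.
2. Otherwise, if the button matches the cue (any button matches ANY) and
   `duration ≥ hold_time_ms`, the press is a SUCCESS. Success is decided at
   hold *completion*: the criterion is a continuous hold, not a release, so
   holding longer than required never hurts.
3. A non-matching button is a WRONG_BUTTON; the error is registered at press
   onset (the device can detect a wrong button instantly) and the time-out
   runs from `t_down`.
4. A matching button released before the hold time is an EARLY_RELEASE; the
   failure is only knowable at release, so the time-out runs from
   `t_down + duration`.

After a SUCCESS a new cue is drawn uniformly over the active buttons
(immediate repeats allowed); after any error the same cue re-illuminates and
persists until correctly pressed. A cue is lit from t = 0. `refractory_ms`
(default 0) can delay cue re-illumination after reward for display realism;
scoring ignores it. Defaults: hold 50 ms, time-out 3000 ms (the time-out is an
adjustable device parameter with no canonical value; 3 s is a typical choice),
session cap 30 min, 4 physical buttons.

Invariants that hold by construction and are property-tested: outcome counts
sum to attempts; the cue is constant between an error and the next success;
after a TIMEOUT_PRESS no press is scored normally for at least one full
time-out period. **Hold-time monotonicity** (raising the hold requirement for
a fixed press script never increases the success count) is a theorem only on
the 1-button task: on multi-button variants changing the hold changes which
presses succeed and hence the cue resampling sequence, which can in contrived
scripts create new successes. The property suite therefore asserts strict
monotonicity on the 1-button variant.

## Protocol rules

Progression to the next task variant (RF: 1-button → 4-button; lab: 1-button →
2-button) fires when any session of the current stage reaches the threshold.
The criterion has two formulations in circulation — per session and per hour —
which coincide for the common 1-hour session; the default here is
**≥ 100 successes per session**, with a per-hour basis available in
`ProtocolConfig`. It is evaluated after every session. The laboratory
session-duration ramp interpolates linearly from 10 to 36 min across 8
sessions, rounded half-up to whole minutes (only the endpoints are canonical;
linearity is this package's choice). On arrival at the research facility a
subject continues with the task settings it last used at the breeding
facility. "Week" means 5 working days throughout; simulated sessions are
scheduled on consecutive working days.

## Simulated subjects

Each subject is an agent with fixed parameters drawn once per subject from
archetype-specific truncated normals (see `calibration.py`), deterministic in
`(master_seed, subject_id)`:

- `engage_prob` — probability of interacting at all in a given session
  (engagement is all-or-none per session);
- `engage_rate_per_min` — Poisson press rate while engaged (exponential
  inter-press intervals);
- `p0, p∞, τ` — the learning curve `p_correct(r) = p∞ − (p∞ − p0)·e^(−r/τ)`
  in cumulative rewards r, advanced only by rewarded trials and persistent
  across sessions and facilities;
- `hold_mean_ms, hold_sd_ms` — truncated-normal hold durations (floor 1 ms).

With a visible cue the agent presses it with probability `p_correct`,
otherwise uniformly among the other active buttons; with no visible cue
(time-out, or the any-button task) uniformly over active buttons. On the
4-button task a naive agent therefore hits the cue at chance 0.25.

Archetype calibration was set by desk arithmetic from the engine's mechanics:
an engaged subject produces ≈ rate·60 presses/hour of which
`p_correct · P(hold ≥ 50 ms)` succeed, minus time-out losses. USERs
(engage 0.95, ≈4 presses/min, p∞ ≈ 0.9, long holds) plateau near 200
successful presses/hour; UNEXPOSED (0.8, ≈3.2/min) near 120; NON_USERs
(0.3, ≈0.5/min, short holds) produce ≈10–25 successes per engaged 30-min
session — comfortably below the 30-success User threshold, so the breeding
facility classifier can recover the generating archetypes. The default
itinerary is 10 BF individual sessions (UNEXPOSED subjects skip the BF), 30 RF
sessions of 30 min, and 10 lab sessions on the duration ramp; the BF
group-exposure phase is treated as unlogged exposure because per-animal
attribution is impossible in a shared-access session.

What the generator deliberately does **not** emulate: engagement and press
rate do not grow with training (only cue-following learns), so simulated
non-users never reach the 100-successes criterion that real animals — all of
them, eventually — did; there are no social/hierarchy effects, no session-to-
session motivation drift, no satiation within a session, and no device
failures. Passing tests on this cohort show the pipeline recovers a known
generating structure (classification, group ordering), not that real training
data will show any particular effect size; group means for well-engaged
archetypes land in the right ballpark of observed cohorts, while non-user
rates are deliberately conservative.

## Log format and dataset

Session logs are UTF-8 CSV with `#key=value` header lines (identity plus a
full task-parameter echo) and one row per press; all times integer ms,
timestamps ISO-8601, 1-based buttons and session indices. The reader validates
every invariant (monotone times, presses within the session duration, reward
flag consistent with outcome, contiguous per-facility session indices in a
cohort bundle) and rejects anything outside the dialect with a line number —
no silent coercion. Unknown header keys are preserved in the annotation
field. A cohort bundle is a directory of `<subject>_<facility>_<index>.csv`
files plus `subjects.csv`.

## Analysis conventions

- `% correct` uses *all* recorded presses in the denominator, including
  time-out presses (switchable via `include_timeout_presses=False`); a session
  with zero presses has an undefined percentage (None), never 0.
- `cp/hr` divides by the actual logged session duration, not the scheduled
  cap.
- Analysis windows are inclusive 1-based slices anchored either on facility
  arrival (RF sessions 5–27; 5–12; lab 1–8) or on stage onset (first 13
  sessions after the 4-button task begins). The first four RF sessions are
  excluded from the main window because individual attribution is unreliable
  early after arrival.
- Group summaries average within subject first, then across subjects; the
  standard error uses n = subjects (each animal one independent observation),
  never n = sessions.
- Mann-Whitney U is reported as min(U₁, U₂) with mid-rank ties. The two-sided
  p is the exact permutation-null probability P(min(U₁,U₂) ≤ observed) by full
  enumeration whenever C(n₁+n₂, n₁) ≤ 10⁶, otherwise a tie-corrected normal
  approximation with continuity correction (the switch is size-based and
  documented here; at study scale, group sizes ≤ 8, enumeration always
  applies).
- Kruskal-Wallis H uses the standard tie correction; its p comes from the
  χ²(k−1) approximation, which is anti-conservative for very small groups —
  hence the exact Mann-Whitney backs up pairwise contrasts.
- Two-sided p-values throughout; no multiple-testing correction is applied.
- OLS regression delegates to `scipy.stats.linregress`; a constant response is
  returned as slope 0, R² 0, p 1 rather than an error.

## Problem sizes and determinism

The default simulated cohort (16 subjects, ≈770 sessions, ≈10⁵ presses)
simulates in about a second; property suites use 1000 random 20-press scripts
and 500 random logs for the round-trip check. One master seed determines
everything: per-subject parameters, per-session engine and agent streams
(derived via `numpy.random.SeedSequence` with a fixed counter scheme), and
session dates. Identical spec + seed reproduces byte-identical log bundles.

## Known limitations

- The agent model is intentionally minimal (no engagement learning, no
  forgetting, no within-session dynamics); it is a test harness for the
  pipeline, not a behavioural model to fit to animals.
- Kruskal-Wallis p-values at n ≤ 8 per group should be read qualitatively.
- The RFID identity stream, reward-pump timing and other hardware concerns are
  out of scope; logs assume the subject of record produced every press.
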