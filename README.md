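# autoprt

Tools for **automated positive-reinforcement training (PRT)** of group-housed
non-human primates on a cued button-press task: a deterministic task engine, the
training-protocol progression rules, a seeded simulator of learner cohorts, a
plain-CSV session-log format, and the behavioural group-analysis pipeline.

Automated home-cage devices let macaques train themselves voluntarily — no food
or fluid control, no handler — by rewarding presses of a cued button. This
package is for researchers and facility staff who run such devices and need to
(a) score presses reproducibly, (b) decide when an animal progresses to a
harder task variant, and (c) compare how prior device experience shapes later
performance.

## The task and the measures

Whenever an LED cue is lit, pressing the cued button continuously for at least
the **hold time** *h* (default 50 ms) is a *success* (reward); pressing a wrong
button or releasing early starts a **time-out** *T* (default 3 s) with all cues
dark, during which any press prolongs the time-out. After an error the same cue
re-illuminates until correctly pressed. Task variants: 1-button (any press
rewardable), 2-button, 4-button.

Per-session performance is measured as

- `cp/hr` — successful presses per hour of session time,
- `% correct` — 100 · successes / all recorded presses.

Subjects are classified from breeding-facility (BF) sessions as **User**
(≥ 30 successes in at least one session), **Non-user** (exposed, never reached
30) or **Unexposed** (no BF sessions). At the research facility (RF), subjects
progress from the 1-button to the 4-button task once a session reaches ≥ 100
successes; laboratory sessions ramp from 10 to 36 minutes over 8 sessions.
Group comparisons treat each animal as one independent observation and use an
**exact Mann-Whitney U** (full enumeration of all C(n₁+n₂, n₁) assignments,
mid-rank ties, U = min(U₁, U₂)), **Kruskal-Wallis H** with tie correction, and
OLS regression with R².

Simulated subjects learn by an exponential approach in cumulative rewards,

    p_correct(r) = p∞ − (p∞ − p₀) · exp(−r / τ),

pressing at exponential inter-press intervals with truncated-normal hold
durations; archetype parameters live in `autoprt/calibration.py`.

## Worked example

Simulate the default 16-subject cohort (8 Users, 5 Non-users, 3 Unexposed)
and analyze every built-in window:

```sh
autoprt report --seed 20210104 --out demo
autoprt analyze --cohort demo/cohort --window rf_main --measure cphr --out rf_main.csv
```

The second command prints:

```
Kruskal-Wallis H=12.153 p=0.002
Mann-Whitney (Users vs Non-users) U=0 p=0.002
```

and `demo/report.csv` contains, for the lab window (first 8 lab sessions,
successful presses per hour; `se` over subjects, n = subjects per group):

```
   window measure     group  mean   se  n
lab_early   cp_hr      USER 209.0  8.4  8
lab_early   cp_hr  NON_USER   9.6  2.3  5
lab_early   cp_hr UNEXPOSED 155.1 14.2  3
```

i.e. animals that used the device at the breeding facility press at the highest
rate in the laboratory, never-exposed animals are intermediate, and exposed
non-users lag far behind — the qualitative ordering the analysis pipeline is
designed to detect. The cohort itself is written as one CSV log per session
plus a `subjects.csv` table, and every run records its seed in
`manifest.json`.

The same pieces are available as a library:

```python
from autoprt import CohortSpec, simulate_cohort, group_summary, BUILTIN_WINDOWS, Measure
cohort = simulate_cohort(CohortSpec())
comp = group_summary(cohort, BUILTIN_WINDOWS["lab_early"], Measure.CP_HR)
print(comp.group_stats)
```

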