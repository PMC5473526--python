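"""Default archetype parameters for simulated subjects.

Three archetypes mirror the breeding-facility classification of the study
cohort: USER animals engaged readily with the device and pressed at a high
rate with long, reliable holds; NON_USER animals rarely engaged and pressed
slowly with short holds; UNEXPOSED animals never saw the device before the
research facility but engage well once there.

Each per-subject parameter is drawn from a truncated normal
``(mean, sd, lo, hi)`` so subjects within an archetype vary, while the
truncation bounds keep the archetypes well separated. The values below were
set by desk arithmetic against the engine: an engaged subject produces about
``rate * 60`` presses per hour, of which a fraction ``p_correct * P(hold >=
50 ms)`` succeed, so USERs plateau near 200 successful presses/hour, UNEXPOSED
near 120, and NON_USERs stay far below the 30-successes-per-session
classification threshold at the breeding facility.
"""

from __future__ import annotations

#: (mean, sd, lo, hi) truncated-normal specs per archetype.
ARCHETYPE_DEFAULTS: dict[str, dict] = {
    "USER": dict(
        engage_prob=0.95,
        engage_rate_per_min=(4.0, 0.8, 2.5, 6.0),
        p0_correct=0.25,
        p_inf_correct=(0.90, 0.03, 0.80, 0.97),
        tau_trials=(60.0, 15.0, 25.0, 120.0),
        hold_mean_ms=(250.0, 40.0, 150.0, 400.0),
        hold_sd_ms=120.0,
    ),
    "NON_USER": dict(
        engage_prob=0.30,
        engage_rate_per_min=(0.5, 0.12, 0.25, 0.75),
        p0_correct=0.25,
        p_inf_correct=(0.75, 0.05, 0.60, 0.88),
        tau_trials=(150.0, 30.0, 80.0, 260.0),
        hold_mean_ms=(120.0, 20.0, 80.0, 160.0),
        hold_sd_ms=90.0,
    ),
    "UNEXPOSED": dict(
        engage_prob=0.80,
        engage_rate_per_min=(3.2, 0.6, 1.8, 4.5),
        p0_correct=0.25,
        p_inf_correct=(0.85, 0.04, 0.72, 0.94),
        tau_trials=(80.0, 20.0, 35.0, 160.0),
        hold_mean_ms=(220.0, 35.0, 140.0, 360.0),
        hold_sd_ms=110.0,
    ),
}

#: Default cohort composition (16 subjects, as in the study dataset).
DEFAULT_N_PER_ARCHETYPE = {"USER": 8, "NON_USER": 5, "UNEXPOSED": 3}

#: Housing-group sizes; USER subjects fill the first groups, NON_USERs the
#: next, and the UNEXPOSED subjects share one final group (the study's
#: unexposed animals were a whole housing group).
DEFAULT_HOUSING_GROUP_SIZES = (4, 4, 3, 2, 3)

#: Per-facility session schedule: daily sessions on working days.
DEFAULT_ITINERARY = dict(
    bf_sessions=10,  # individual-exposure phase, 2 working weeks
    rf_sessions=30,  # >= the study minimum of 27
    lab_sessions=10,  # >= the study minimum of 8
    bf_session_min=30,
    rf_session_min=30,
)

DEFAULT_MASTER_SEED = 20210104
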