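"""Tests for performance measures, classification, windows and statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from autoprt.analysis import (
    BUILTIN_WINDOWS,
    NOT_REACHED,
    ClassificationRule,
    Measure,
    WindowAnchor,
    WindowSpec,
    classify_bf,
    group_summary,
    kruskal_wallis,
    mann_whitney_exact,
    ols_regression,
    select_window,
    session_metrics,
    sessions_to_criterion,
)
from autoprt.subject_sim import Archetype, CohortDataset
from autoprt.task_engine import (
    InputError,
    Outcome,
    PressAttempt,
    TaskConfig,
    TaskVariant,
    run_session,
)

from conftest import make_success_log


def mixed_log(n_success, n_wrong, n_early, *, cap_min=30, variant=TaskVariant.FOUR_BUTTON,
              **kwargs):
    """A log with a controlled outcome mix, built by replay through the engine."""
    cfg = TaskConfig(task_variant=variant, n_buttons=4,
                     session_cap_ms=cap_min * 60_000, timeout_ms=0, rng_seed=3)
    # with timeout_ms=0 no press can land inside a time-out window
    from autoprt.task_engine import init_session, score_press

    state = init_session(cfg)
    t = 1000
    remaining = {"s": n_success, "w": n_wrong, "e": n_early}
    while any(remaining.values()):
        kind = next(k for k in ("s", "w", "e") if remaining[k])
        cue = state.cue if isinstance(state.cue, int) else 1
        if kind == "s":
            press = PressAttempt(cue, t, 100)
        elif kind == "w":
            press = PressAttempt(cue % 4 + 1, t, 100)
        else:
            press = PressAttempt(cue, t, 10)
        _, rec = score_press(state, press, cfg)
        expected = {"s": Outcome.SUCCESS, "w": Outcome.WRONG_BUTTON,
                    "e": Outcome.EARLY_RELEASE}[kind]
        assert rec.outcome is expected
        remaining[kind] -= 1
        t += 2000
    from autoprt.task_engine import SessionLog

    return SessionLog(subject_id=kwargs.get("subject_id", "S01"),
                      facility=kwargs.get("facility", "RF"),
                      session_index=kwargs.get("session_index", 1),
                      start=state.start, config=cfg,
                      actual_duration_ms=cfg.session_cap_ms,
                      trials=state.trial_history)


class TestSessionMetrics:
    def test_rates_on_a_30_min_session(self):
        log = mixed_log(60, 30, 10)
        m = session_metrics(log)
        assert m.successes == 60 and m.attempts == 100
        assert m.cp_per_hr == pytest.approx(120.0)
        assert m.pct_correct == pytest.approx(60.0)

    def test_empty_session_has_undefined_percentage(self):
        log = mixed_log(0, 0, 0)
        m = session_metrics(log)
        assert m.cp_per_hr == 0.0 and m.pct_correct is None

    def test_one_button_task_can_be_under_100_pct_via_early_release(self):
        log = mixed_log(20, 0, 5, variant=TaskVariant.ONE_BUTTON)
        m = session_metrics(log)
        assert m.pct_correct == pytest.approx(80.0)

    def test_timeout_presses_switchable_in_denominator(self):
        cfg = TaskConfig(task_variant=TaskVariant.ONE_BUTTON, rng_seed=0)
        presses = [PressAttempt(1, 1000, 10),  # early release -> timeout
                   PressAttempt(1, 1500, 100),  # timeout press
                   PressAttempt(1, 10_000, 100)]  # success
        log = run_session(cfg, presses)
        assert [t.outcome for t in log.trials] == [
            Outcome.EARLY_RELEASE, Outcome.TIMEOUT_PRESS, Outcome.SUCCESS]
        assert session_metrics(log).pct_correct == pytest.approx(100 / 3)
        assert session_metrics(log, include_timeout_presses=False).pct_correct == pytest.approx(50.0)


class TestClassifyBF:
    @pytest.mark.parametrize(
        "counts,expected",
        [([12, 30, 4], Archetype.USER),
         ([29, 29], Archetype.NON_USER),
         ([], Archetype.UNEXPOSED)],
    )
    def test_threshold_rule(self, counts, expected):
        logs = [make_success_log(k, session_index=i + 1) for i, k in enumerate(counts)]
        assert classify_bf(logs) is expected

    def test_monotone_in_added_sessions(self):
        logs = [make_success_log(k, session_index=i + 1)
                for i, k in enumerate([5, 50, 2])]
        seen_user = False
        for n in range(1, len(logs) + 1):
            c = classify_bf(logs[:n])
            if seen_user:
                assert c is Archetype.USER
            seen_user = c is Archetype.USER

    def test_non_bf_logs_rejected(self):
        with pytest.raises(InputError):
            classify_bf([make_success_log(5, facility="RF")])


class TestSessionsToCriterion:
    @pytest.mark.parametrize(
        "counts,expected",
        [([150, 10], 1), ([10, 99, 100], 3), ([10, 20], NOT_REACHED)],
    )
    def test_first_session_meeting_threshold(self, counts, expected):
        logs = [make_success_log(k, facility="RF", session_index=i + 1)
                for i, k in enumerate(counts)]
        assert sessions_to_criterion(logs, 100) == expected

    def test_non_increasing_as_threshold_decreases(self):
        logs = [make_success_log(k, facility="RF", session_index=i + 1)
                for i, k in enumerate([10, 60, 120, 200])]
        results = [sessions_to_criterion(logs, th) for th in (200, 120, 60, 10)]
        assert results == sorted(results, reverse=True)


class TestSelectWindow:
    def rf_logs(self, n, four_button_from=None):
        logs = []
        for i in range(1, n + 1):
            variant = (TaskVariant.FOUR_BUTTON
                       if four_button_from and i >= four_button_from
                       else TaskVariant.ONE_BUTTON)
            logs.append(make_success_log(5, facility="RF", session_index=i,
                                         variant=variant))
        return logs

    def test_rf_main_on_30_sessions_gives_23(self):
        out = select_window(self.rf_logs(30), BUILTIN_WINDOWS["rf_main"])
        assert len(out) == 23
        assert out[0].session_index == 5 and out[-1].session_index == 27

    def test_stage_onset_anchor(self):
        out = select_window(self.rf_logs(30, four_button_from=9), BUILTIN_WINDOWS["rf_4b"])
        assert [lg.session_index for lg in out] == list(range(9, 22))

    def test_lab_early_takes_all_8(self):
        logs = [make_success_log(5, facility="LAB", session_index=i) for i in range(1, 9)]
        assert len(select_window(logs, BUILTIN_WINDOWS["lab_early"])) == 8

    def test_absent_anchor_raises(self):
        with pytest.raises(InputError):
            select_window(self.rf_logs(10), BUILTIN_WINDOWS["rf_4b"])
        with pytest.raises(InputError):
            select_window([], BUILTIN_WINDOWS["rf_main"])


def _cohort_from_specs(spec):
    """spec: {subject_id: (bf_successes list, rf_successes list)}"""
    logs = []
    for sid, (bf, rf) in spec.items():
        logs += [make_success_log(k, subject_id=sid, facility="BF", session_index=i + 1)
                 for i, k in enumerate(bf)]
        logs += [make_success_log(k, subject_id=sid, facility="RF", session_index=i + 1)
                 for i, k in enumerate(rf)]
    subjects = pd.DataFrame({"subject_id": list(spec)})
    return CohortDataset(subjects=subjects, logs=logs)


WINDOW_RF_1_2 = WindowSpec("rf_12", "RF", WindowAnchor.ARRIVAL, 1, 2)


class TestGroupSummary:
    def test_hand_computed_group_means_and_se_over_subjects(self):
        # subjects have unequal session counts, so SE over sessions would differ
        cohort = _cohort_from_specs({
            "U1": ([40], [30, 60]),   # USER, subject mean cp/hr = (60+120)/2 = 90
            "U2": ([50], [60, 0]),    # USER, mean = 60
            "N1": ([5], [15, 15]),    # NON_USER, mean = 30
            "X1": ([], [20, 20]),     # UNEXPOSED (no BF sessions)
        })
        comp = group_summary(cohort, WINDOW_RF_1_2, Measure.CP_HR)
        user = comp.group_stats.loc["USER"]
        assert user["mean"] == pytest.approx(75.0)
        # SE over the 2 subjects: sd([90,60])/sqrt(2)
        assert user["se"] == pytest.approx(np.std([90, 60], ddof=1) / math.sqrt(2))
        assert user["n"] == 2
        non = comp.group_stats.loc["NON_USER"]
        assert non["mean"] == pytest.approx(30.0) and math.isnan(non["se"])

    def test_identical_subjects_have_zero_se(self):
        cohort = _cohort_from_specs({
            "U1": ([40], [30, 30]), "U2": ([40], [30, 30]),
            "N1": ([5], [10, 10]), "X1": ([], [20, 20]),
        })
        comp = group_summary(cohort, WINDOW_RF_1_2, Measure.CP_HR)
        assert comp.group_stats.loc["USER", "se"] == pytest.approx(0.0)

    def test_empty_group_omitted_with_warning(self):
        cohort = _cohort_from_specs({"U1": ([40], [30, 30]), "U2": ([50], [10, 20])})
        with pytest.warns(UserWarning, match="empty"):
            comp = group_summary(cohort, WINDOW_RF_1_2, Measure.CP_HR)
        assert list(comp.group_stats.index) == ["USER"]

    def test_learning_curves_are_per_session_group_means(self):
        cohort = _cohort_from_specs({
            "U1": ([40], [30, 60]), "U2": ([50], [60, 0]),
            "N1": ([5], [15, 15]), "X1": ([], [20, 20]),
        })
        comp = group_summary(cohort, WINDOW_RF_1_2, Measure.CP_HR)
        c = comp.learning_curves
        u1 = c[(c.group == "USER") & (c.session == 1)]["value"].iloc[0]
        assert u1 == pytest.approx((60 + 120) / 2)


def brute_force_mw(x, y):
    """Independent oracle: U by direct pairwise counting, p by enumeration."""
    x, y = list(x), list(y)

    def u_pair(a, b):
        return sum(1.0 if ai > bi else 0.5 if ai == bi else 0.0
                   for ai in a for bi in b)

    u_obs = min(u_pair(x, y), u_pair(y, x))
    pooled = x + y
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), len(x)):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = min(u_pair(xs, ys), u_pair(ys, xs))
        hits += u <= u_obs + 1e-9
        total += 1
    return u_obs, hits / total


class TestMannWhitneyExact:
    @pytest.mark.parametrize(
        "x,y,u,p",
        [([1, 2, 3], [4, 5, 6], 0.0, 0.1),
         ([1], [2], 0.0, 1.0)],
    )
    def test_worked_examples(self, x, y, u, p):
        assert mann_whitney_exact(x, y) == (pytest.approx(u), pytest.approx(p))

    def test_identical_samples_give_p_one(self):
        u, p = mann_whitney_exact([3, 3, 5], [5, 3, 3])
        assert p == pytest.approx(1.0)

    def test_matches_brute_force_oracle_with_ties(self):
        rng = np.random.default_rng(11)
        for nx, ny in [(2, 3), (3, 3), (4, 2), (5, 4)]:
            x = rng.integers(0, 5, nx).astype(float)
            y = rng.integers(0, 5, ny).astype(float)
            assert mann_whitney_exact(x, y) == pytest.approx(brute_force_mw(x, y))

    def test_large_sample_approximation_close_to_scipy(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 60)
        y = rng.normal(0.5, 1, 55)
        u, p = mann_whitney_exact(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(min(ref.statistic, len(x) * len(y) - ref.statistic))
        assert p == pytest.approx(ref.pvalue, rel=0.05)


class TestKruskalWallis:
    def test_identical_groups_give_zero(self):
        h, p = kruskal_wallis([[2, 2], [2, 2], [2, 2]])
        assert h == 0.0 and p == 1.0

    def test_hand_formula_on_fully_separated_groups(self):
        h, p = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        # ranks 1..6, group mean ranks 1.5/3.5/5.5
        expected = 12 / (6 * 7) * 2 * ((1.5 - 3.5) ** 2 + 0 + (5.5 - 3.5) ** 2)
        assert h == pytest.approx(expected)
        assert p == pytest.approx(float(sps.chi2.sf(expected, 2)))

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(4)
        groups = [rng.integers(0, 6, n).astype(float) for n in (5, 7, 6)]
        h, p = kruskal_wallis(groups)
        ref = sps.kruskal(*groups)
        assert h == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_two_group_agreement_with_mann_whitney(self):
        # the more separated pair must score higher on both tests
        near = ([1.0, 2, 3, 4], [2.0, 3, 4, 5])
        far = ([1.0, 2, 3, 4], [10.0, 11, 12, 13])
        h_near, _ = kruskal_wallis(near)
        h_far, _ = kruskal_wallis(far)
        _, p_near = mann_whitney_exact(*near)
        _, p_far = mann_whitney_exact(*far)
        assert h_far > h_near and p_far < p_near

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(InputError):
            kruskal_wallis([[1, 2, 3]])


class TestOLSRegression:
    def test_perfect_line(self):
        x = [1, 2, 3, 4]
        y = [3, 5, 7, 9]
        slope, intercept, r2, _ = ols_regression(x, y)
        assert (slope, intercept, r2) == (pytest.approx(2.0), pytest.approx(1.0),
                                          pytest.approx(1.0))

    def test_constant_response(self):
        slope, intercept, r2, p = ols_regression([1, 2, 3], [4, 4, 4])
        assert slope == 0.0 and r2 == 0.0 and p == 1.0

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 10, 12)
        y = 2.5 * x - 1 + rng.normal(0, 2, 12)
        slope, intercept, r2, p = ols_regression(x, y)
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        r2_hand = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        assert intercept == pytest.approx(beta[0])
        assert slope == pytest.approx(beta[1])
        assert r2 == pytest.approx(r2_hand)

    def test_constant_x_rejected(self):
        with pytest.raises(InputError):
            ols_regression([2, 2, 2], [1, 2, 3])
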