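"""Stress-trial engine: contingency rules, yoking, pseudo-yoking, sessions."""

import numpy as np
import pytest
from scipy import stats as sps

from triadsim.agents import AgentSpec, LearnerSpec, RTModel, get_preset
from triadsim.config import build_study_config, build_trial_timeline
from triadsim.engine import (
    YokingError,
    derive_pseudo_yoked_schedule,
    derive_yoked_schedule,
    run_ec_trial,
    run_yc_trial,
    sample_truth_map,
    simulate_session,
)


def _template(config, index=1, seed=0):
    return build_trial_timeline(config, seed)[index - 1]


def constant_agent(rt=0.3, name="const"):
    return AgentSpec(
        name=name,
        rt_model=RTModel(family="constant", shift=rt, miss_prob=0.0),
        learner=LearnerSpec(family="elimination", lapse_prob=0.0),
        rating_model=get_preset("ec_like").rating_model,
        affect_model=get_preset("ec_like").affect_model,
    )


class TestEscapableTrials:
    def test_fast_response_terminates(self, study1_config):
        t = _template(study1_config)
        rec = run_ec_trial(t, (0.4, "space"), study1_config)
        assert rec.stress_duration == pytest.approx(6.4)
        assert rec.terminated_by_response

    def test_late_response_runs_to_cap(self, study1_config):
        t = _template(study1_config)
        rec = run_ec_trial(t, (1.3, "space"), study1_config)
        assert rec.stress_duration == 15.0
        assert not rec.terminated_by_response

    def test_miss_runs_to_cap(self, study1_config):
        t = _template(study1_config)
        rec = run_ec_trial(t, None, study1_config)
        assert rec.stress_duration == 15.0
        assert rec.response_time is None

    def test_study2_wrong_button_uses_decremented_cap(self, study2_config):
        t = _template(study2_config, index=20)
        truth = {c: "b1" for c in study2_config.cue_set}
        rec = run_ec_trial(t, (0.4, "b2"), study2_config, truth)
        assert rec.stress_duration == pytest.approx(9.5)
        assert rec.response_correct is False

    def test_study2_correct_button_terminates(self, study2_config):
        t = _template(study2_config, index=20)
        truth = {c: "b1" for c in study2_config.cue_set}
        rec = run_ec_trial(t, (0.4, "b1"), study2_config, truth)
        assert rec.stress_duration == pytest.approx(6.4)
        assert rec.terminated_by_response

    def test_study2_requires_truth_map(self, study2_config):
        with pytest.raises(ValueError):
            run_ec_trial(_template(study2_config), (0.4, "b1"), study2_config)

    def test_duration_set_membership(self, study1_config):
        # escapable single-cue durations live in [pre_cue, pre_cue + window] or at the cap
        for rt in (0.0, 0.2, 0.5, 0.99, 1.0, 1.01, 2.0):
            rec = run_ec_trial(_template(study1_config), (rt, "space"), study1_config)
            d = rec.stress_duration
            assert (6.0 <= d <= 7.0) or d == 15.0


class TestYokedTrials:
    def test_duration_ignores_response(self, study1_config):
        t = _template(study1_config)
        rec = run_yc_trial(t, (6.4, 3.1), (0.3, "space"))
        assert rec.stress_duration == 6.4
        assert not rec.terminated_by_response
        assert rec.response_time == 0.3

    def test_no_response_logged(self, study1_config):
        rec = run_yc_trial(_template(study1_config), (6.4, 3.1), None)
        assert rec.stress_duration == 6.4
        assert rec.response_time is None

    def test_cap_violation_rejected(self, study1_config):
        with pytest.raises(YokingError):
            run_yc_trial(_template(study1_config), (16.0, 13.0), None)


class TestYokedSchedules:
    def _ec_session(self, config, seed=0, rt=0.4):
        return simulate_session("EC", constant_agent(rt), config, seed)

    def test_durations_copied_exactly(self, study1_config):
        ec = self._ec_session(study1_config)
        schedule = derive_yoked_schedule(ec, seed=1)
        assert schedule.durations == tuple(t.stress_duration for t in ec.trials)
        assert schedule.provenance == "one_to_one"

    def test_onset_gap_law(self, study1_config):
        ec = self._ec_session(study1_config)
        schedule = derive_yoked_schedule(ec, seed=2)
        for d, o in zip(schedule.durations, schedule.cue_onsets):
            assert 1.0 - 1e-12 <= d - o <= 4.0 + 1e-12

    def test_onset_uniformity(self):
        # onsets for a fixed duration follow Uniform(d-4, d-1)
        rng = np.random.default_rng(0)
        from triadsim.engine import _sample_onset

        draws = np.array([_sample_onset(10.0, rng) for _ in range(10_000)])
        assert draws.min() >= 6.0 and draws.max() <= 9.0
        assert sps.kstest(draws, sps.uniform(loc=6.0, scale=3.0).cdf).pvalue > 0.01

    def test_requires_ec_source(self, study1_config):
        ec = self._ec_session(study1_config)
        ec.condition = "YC"
        with pytest.raises(YokingError):
            derive_yoked_schedule(ec, seed=0)

    def test_pseudo_schedule_is_permutation_of_means(self, study2_config):
        sessions = [
            simulate_session(
                "EC", get_preset("ec_like"), study2_config, seed=s, participant_id=f"EC{s}"
            )
            for s in range(4)
        ]
        schedule = derive_pseudo_yoked_schedule(sessions, study2_config, seed=9)
        means = np.mean(
            [[t.stress_duration for t in s.trials] for s in sessions], axis=0
        )
        assert sorted(schedule.durations) == pytest.approx(sorted(means))
        assert sum(schedule.durations) == pytest.approx(means.sum())
        assert schedule.provenance == "pseudo"

    def test_pseudo_simple_mean(self, study2_config):
        a = self._ec_session(study2_config, seed=0)
        b = self._ec_session(study2_config, seed=1)
        # trial-level means of the two sessions all appear somewhere
        schedule = derive_pseudo_yoked_schedule([a, b], study2_config, seed=3)
        mean_1 = (a.trials[0].stress_duration + b.trials[0].stress_duration) / 2
        assert any(d == pytest.approx(mean_1) for d in schedule.durations)

    def test_pseudo_rejects_empty_and_ragged(self, study2_config):
        with pytest.raises(YokingError):
            derive_pseudo_yoked_schedule([], study2_config, seed=0)
        a = self._ec_session(study2_config, seed=0)
        b = self._ec_session(study2_config, seed=1)
        b.trials = b.trials[:-1]
        with pytest.raises(YokingError):
            derive_pseudo_yoked_schedule([a, b], study2_config, seed=0)

    def test_pseudo_cap_overflow_warns_but_conserves(self, study2_config):
        # a session of max-duration trials: the 10.0-s trial-1 mean can land
        # on a late trial whose decremented cap is lower; the schedule warns
        # but stays an exact permutation bounded by the base maximum
        never = AgentSpec(name="never", rt_model=RTModel(miss_prob=1.0),
                          rating_model=get_preset("ec_like").rating_model,
                          affect_model=get_preset("ec_like").affect_model)
        ec = simulate_session("EC", never, study2_config, seed=0)
        with pytest.warns(UserWarning, match="decremented cap"):
            schedule = derive_pseudo_yoked_schedule([ec], study2_config, seed=1)
        means = sorted(t.stress_duration for t in ec.trials)
        assert sorted(schedule.durations) == pytest.approx(means, abs=0)
        assert max(schedule.durations) <= study2_config.max_duration_base + 1e-9
        # and a YC session accepts the schedule
        yc = simulate_session("YC", get_preset("yc_like"), study2_config,
                              seed=2, yoke_source=schedule)
        assert sorted(t.stress_duration for t in yc.trials) == pytest.approx(means, abs=0)


class TestSessions:
    def test_ec_constant_responder_totals(self, study1_config):
        session = simulate_session("EC", constant_agent(0.3), study1_config, seed=5)
        assert all(t.terminated_by_response for t in session.trials)
        total = sum(t.stress_duration for t in session.trials)
        assert total == pytest.approx(40 * 6.3)

    def test_yoked_session_conserves_total_stress(self, study1_config):
        ec = simulate_session("EC", get_preset("ec_like"), study1_config, seed=7)
        schedule = derive_yoked_schedule(ec, seed=8)
        yc = simulate_session(
            "YC", get_preset("yc_like"), study1_config, seed=9, yoke_source=schedule
        )
        assert [t.stress_duration for t in yc.trials] == [
            t.stress_duration for t in ec.trials
        ]

    def test_cc_receives_no_stress(self, study1_config):
        cc = simulate_session("CC", get_preset("ec_like"), study1_config, seed=4)
        assert all(t.stress_duration == 0.0 for t in cc.trials)

    def test_session_determinism(self, study2_config):
        a = simulate_session("EC", get_preset("ec_like"), study2_config, seed=11)
        b = simulate_session("EC", get_preset("ec_like"), study2_config, seed=11)
        assert a.trials == b.trials
        assert a.ratings == b.ratings
        assert a.affect_pre == b.affect_pre

    def test_ratings_cover_probe_grid(self, study1_config):
        session = simulate_session("EC", get_preset("ec_like"), study1_config, seed=2)
        keys = {(p.after_trial, p.item) for p in session.ratings}
        assert keys == {
            (t, item)
            for t in (10, 20, 30, 40)
            for item in study1_config.rating_items
        }
        assert all(1 <= p.value <= 7 for p in session.ratings)

    def test_yoke_source_requirements(self, study1_config):
        with pytest.raises(YokingError):
            simulate_session("YC", get_preset("yc_like"), study1_config, seed=0)
        ec = simulate_session("EC", constant_agent(), study1_config, seed=0)
        schedule = derive_yoked_schedule(ec, seed=1)
        with pytest.raises(YokingError):
            simulate_session(
                "EC", constant_agent(), study1_config, seed=0, yoke_source=schedule
            )

    def test_study2_elimination_learner_gets_accurate(self, study2_config):
        session = simulate_session(
            "EC", constant_agent(0.3), study2_config, seed=13
        )
        correct = [t.response_correct for t in session.trials[-30:]]
        # zero-lapse elimination: the tail of the session is error-free
        assert all(correct)

    def test_truth_map_is_permutation(self, study2_config, rng):
        tm = sample_truth_map(study2_config, rng)
        assert sorted(tm.values()) == ["b1", "b2", "b3"]
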