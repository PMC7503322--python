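"""Stress-induction trial engine and yoked/pseudo-yoked scheduling.

A trial runs as: pre-cue aversive stimulation (noise, plus shocks in the
original variant), a cue at ``pre_cue_duration`` seconds, and a response
window.  In the escapable condition (EC) a valid response -- any press in the
single-cue variant, the correct button in the three-cue variant -- terminates
the stressor at ``cue_onset + response_time``; otherwise stimulation runs to
the trial's maximum duration (the cap covers total stimulation, pre-cue
included).  Yoked participants (YC) receive predetermined durations: copied
one-to-one from a partner session in the original design, or a shuffled
per-trial average over the whole EC pool in the pseudo-yoked design.  Their
cue is shifted to 1-4 s before stressor offset, so termination never follows
their own response.  Controls (CC) go through the same trial structure with
no stimulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .agents import (
    AgentSpec,
    BUTTONS,
    choose_button,
    generate_rating,
    new_learner_state,
    sample_affect,
    sample_rt,
    update_learner,
)
from .config import RatingProbe, StudyConfig, TrialTemplate, build_trial_timeline, rating_probe_indices
from .seeding import stream_rng

__all__ = [
    "TrialRecord",
    "YokedSchedule",
    "SessionRecord",
    "YokingError",
    "run_ec_trial",
    "run_yc_trial",
    "run_cc_trial",
    "derive_yoked_schedule",
    "derive_pseudo_yoked_schedule",
    "simulate_session",
    "sample_truth_map",
]

# the shifted YC cue precedes stressor offset by 1-4 s
ONSET_GAP_MIN = 1.0
ONSET_GAP_MAX = 4.0


class YokingError(ValueError):
    """Raised on invalid yoking input (wrong condition, mismatched trials)."""


@dataclass(frozen=True)
class TrialRecord:
    """Outcome of one stress-induction trial."""

    trial_index: int
    condition: str  # EC | YC | CC
    cue_id: str
    cue_onset: float  # seconds from trial start
    response_time: float | None  # seconds from cue onset; None = miss
    response_button: str | None
    response_correct: bool | None  # None where not applicable
    stress_duration: float  # seconds; 0 for CC
    terminated_by_response: bool
    max_duration: float


@dataclass(frozen=True)
class YokedSchedule:
    """Predetermined (stress_duration, cue_onset) pairs for a YC session."""

    durations: tuple[float, ...]
    cue_onsets: tuple[float, ...]
    provenance: str  # "one_to_one" | "pseudo"
    source_ids: tuple[str, ...]


@dataclass
class SessionRecord:
    """One participant's full stress-induction session."""

    participant_id: str
    condition: str
    study_id: int
    seed: int
    trials: list[TrialRecord]
    ratings: list[RatingProbe]
    affect_pre: dict
    affect_post: dict


def _sample_onset(duration: float, rng: np.random.Generator) -> float:
    onset = rng.uniform(duration - ONSET_GAP_MAX, duration - ONSET_GAP_MIN)
    return max(onset, 0.0)


def run_ec_trial(
    template: TrialTemplate,
    response: tuple[float, str] | None,
    config: StudyConfig,
    truth_map: dict | None = None,
) -> TrialRecord:
    """Run one escapable-condition trial.

    ``response`` is ``(response_time, button)`` relative to cue onset, or
    ``None`` for a miss.  In the three-cue variant correctness is judged
    against ``truth_map`` (cue -> button); in the single-cue variant any
    press counts.
    """
    if config.study_id == 2 and truth_map is None:
        raise ValueError("truth_map is required for the three-cue (study 2) task")
    rt, button = (None, None) if response is None else response
    if rt is not None and rt < 0:
        raise ValueError("response_time must be >= 0")

    in_window = rt is not None and rt <= config.response_window
    if config.study_id == 2:
        correct = None if button is None else bool(truth_map[template.cue_id] == button)
        terminates = bool(in_window and correct)
    else:
        correct = None if button is None else in_window
        terminates = in_window

    if terminates:
        stress = min(template.nominal_cue_onset + rt, template.max_duration)
    else:
        stress = template.max_duration
    return TrialRecord(
        trial_index=template.trial_index,
        condition="EC",
        cue_id=template.cue_id,
        cue_onset=template.nominal_cue_onset,
        response_time=rt,
        response_button=button,
        response_correct=correct,
        stress_duration=stress,
        terminated_by_response=terminates,
        max_duration=template.max_duration,
    )


def run_yc_trial(
    template: TrialTemplate,
    yoked: tuple[float, float],
    response: tuple[float, str] | None,
    cap: float | None = None,
) -> TrialRecord:
    """Run one yoked trial: stress duration and cue onset come from the
    schedule; the response is logged verbatim but never terminates anything.

    The per-trial decremented maximum bounds *response-contingent*
    stimulation; a predetermined yoked duration is checked against ``cap``
    (the session's base maximum) when given, else the trial's own maximum.
    """
    duration, onset = yoked
    limit = template.max_duration if cap is None else cap
    if duration > limit + 1e-9:
        raise YokingError(
            f"yoked duration {duration} exceeds the cap {limit}"
        )
    rt, button = (None, None) if response is None else response
    return TrialRecord(
        trial_index=template.trial_index,
        condition="YC",
        cue_id=template.cue_id,
        cue_onset=onset,
        response_time=rt,
        response_button=button,
        response_correct=None,
        stress_duration=duration,
        terminated_by_response=False,
        max_duration=template.max_duration,
    )


def run_cc_trial(
    template: TrialTemplate,
    response: tuple[float, str] | None,
    config: StudyConfig,
) -> TrialRecord:
    """Run one no-stress control trial: EC timing, zero stimulation; a press
    within the window ends the trial early (shortening the session)."""
    rt, button = (None, None) if response is None else response
    in_window = rt is not None and rt <= config.response_window
    return TrialRecord(
        trial_index=template.trial_index,
        condition="CC",
        cue_id=template.cue_id,
        cue_onset=template.nominal_cue_onset,
        response_time=rt,
        response_button=button,
        response_correct=None if button is None else in_window,
        stress_duration=0.0,
        terminated_by_response=False,
        max_duration=template.max_duration,
    )


def derive_yoked_schedule(ec_session: SessionRecord, seed: int) -> YokedSchedule:
    """One-to-one yoking: copy the EC partner's per-trial stress durations
    exactly and sample each cue onset uniformly from 4 s to 1 s before
    stressor offset (clipped at 0, which never triggers for durations >= 4 s).
    """
    if ec_session.condition != "EC":
        raise YokingError("one-to-one yoking requires an EC source session")
    rng = np.random.default_rng(seed)
    durations = tuple(t.stress_duration for t in ec_session.trials)
    onsets = tuple(_sample_onset(d, rng) for d in durations)
    return YokedSchedule(
        durations=durations,
        cue_onsets=onsets,
        provenance="one_to_one",
        source_ids=(ec_session.participant_id,),
    )


def derive_pseudo_yoked_schedule(
    ec_sessions: list[SessionRecord],
    config: StudyConfig,
    seed: int,
) -> YokedSchedule:
    """Pseudo-yoking for group testing: per-trial-index mean duration over
    the EC pool, randomly shuffled; onsets sampled as in one-to-one yoking.

    The shuffled vector is an exact permutation of the per-trial means (the
    conservation property of pseudo-yoking).  Because the decremented cap
    only constrains response-contingent escapable trials, a shuffled mean
    may exceed the destination trial's decremented cap -- this is warned
    about but not altered; durations never exceed the session's base
    maximum by construction.
    """
    if not ec_sessions:
        raise YokingError("pseudo-yoking requires at least one EC session")
    n_trials = len(ec_sessions[0].trials)
    for s in ec_sessions:
        if s.condition != "EC":
            raise YokingError("pseudo-yoking requires EC source sessions")
        if len(s.trials) != n_trials:
            raise YokingError("EC sessions have unequal trial counts")
    rng = np.random.default_rng(seed)
    durations_matrix = np.array(
        [[t.stress_duration for t in s.trials] for s in ec_sessions]
    )
    means = durations_matrix.mean(axis=0)
    shuffled = means[rng.permutation(n_trials)]
    from .config import max_stress_duration  # local import avoids cycle at module load

    caps = np.array([max_stress_duration(config, i + 1) for i in range(n_trials)])
    if np.any(shuffled > caps + 1e-9):
        warnings.warn(
            f"{int(np.sum(shuffled > caps + 1e-9))} pseudo-yoked duration(s) exceed "
            "the destination trial's decremented cap (predetermined durations are "
            "bounded by the session base maximum instead)",
            stacklevel=2,
        )
    onsets = tuple(_sample_onset(float(d), rng) for d in shuffled)
    return YokedSchedule(
        durations=tuple(float(d) for d in shuffled),
        cue_onsets=onsets,
        provenance="pseudo",
        source_ids=tuple(s.participant_id for s in ec_sessions),
    )


def sample_truth_map(config: StudyConfig, rng: np.random.Generator) -> dict:
    """Random cue -> button assignment (a permutation) for the three-cue task."""
    buttons = list(BUTTONS[: len(config.cue_set)])
    perm = rng.permutation(len(buttons))
    return {cue: buttons[perm[i]] for i, cue in enumerate(config.cue_set)}


def simulate_session(
    condition: str,
    agent: AgentSpec,
    config: StudyConfig,
    seed: int,
    yoke_source: YokedSchedule | None = None,
    participant_id: str = "p0",
    truth_map: dict | None = None,
) -> SessionRecord:
    """Simulate one full stress-induction session for one agent.

    EC/CC sessions must not pass a ``yoke_source``; YC sessions require one.
    The trial timeline, reaction times, learner lapses, ratings, and affect
    scores each use an independent stream derived from ``seed``, so the
    session is a pure function of its arguments.
    """
    if condition not in ("EC", "YC", "CC"):
        raise ValueError(f"unknown condition {condition!r}")
    if condition == "YC" and yoke_source is None:
        raise YokingError("YC sessions require a yoke_source schedule")
    if condition != "YC" and yoke_source is not None:
        raise YokingError(f"{condition} sessions must not pass a yoke_source")
    config.validate()
    agent.validate()

    timeline = build_trial_timeline(config, stream_rng(seed, 0, "trial-timeline").integers(2**31))
    rng_rt = stream_rng(seed, 0, "agent-rt")
    rng_learn = stream_rng(seed, 0, "agent-learner")
    rng_rate = stream_rng(seed, 0, "agent-ratings")
    rng_affect = stream_rng(seed, 0, "agent-affect")

    if config.study_id == 2 and condition != "CC":
        if truth_map is None:
            truth_map = sample_truth_map(config, stream_rng(seed, 0, "truth-map"))
        learner = new_learner_state(config.cue_set, BUTTONS[: len(config.cue_set)])
    else:
        learner = None

    trials: list[TrialRecord] = []
    for i, template in enumerate(timeline):
        rt = sample_rt(agent.rt_model, rng_rt)
        if rt is None:
            response = None
        elif config.study_id == 2 and learner is not None:
            button = choose_button(
                learner, template.cue_id, agent.learner.lapse_prob, rng_learn,
                BUTTONS[: len(config.cue_set)],
            )
            response = (rt, button)
        else:
            response = (rt, "space")

        if condition == "EC":
            record = run_ec_trial(template, response, config, truth_map)
        elif condition == "YC":
            yoked = (yoke_source.durations[i], yoke_source.cue_onsets[i])
            record = run_yc_trial(
                template, yoked, response, cap=config.max_duration_base
            )
        else:
            record = run_cc_trial(template, response, config)

        # the learner only updates on the actual feedback signal: for EC the
        # stressor stops (or not); YC feedback is non-contingent noise the
        # elimination rule would be misled by, so only EC learns
        if condition == "EC" and learner is not None and response is not None:
            learner = update_learner(
                learner, template.cue_id, response[1], record.terminated_by_response
            )
        trials.append(record)

    ratings = [
        RatingProbe(after_trial=after, item=item,
                    value=generate_rating(agent.rating_model[item], probe_number, rng_rate))
        for probe_number, after in enumerate(rating_probe_indices(config), start=1)
        for item in config.rating_items
    ]

    affect_pre: dict = {}
    affect_post: dict = {}
    for score in sorted(agent.affect_model):
        pre, post = sample_affect(agent.affect_model[score], rng_affect)
        affect_pre[score] = pre
        affect_post[score] = post

    return SessionRecord(
        participant_id=participant_id,
        condition=condition,
        study_id=config.study_id,
        seed=seed,
        trials=trials,
        ratings=ratings,
        affect_pre=affect_pre,
        affect_post=affect_post,
    )
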