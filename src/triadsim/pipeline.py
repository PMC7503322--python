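"""End-to-end simulated experiments.

Orchestrates the full paradigm for groups of simulated participants:
stress-induction sessions (with one-to-one yoking in the three-group design
and pseudo-yoking in the two-group design), escape behaviour tests, metric
tables, and the group-comparison report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .agents import AgentSpec, get_preset, individualize
from .config import StudyConfig, build_study_config
from .engine import (
    SessionRecord,
    derive_pseudo_yoked_schedule,
    derive_yoked_schedule,
    sample_truth_map,
    simulate_session,
)
from .grid import EscapeTestRecord, run_escape_test
from .metrics import metrics_table, participant_table
from .seeding import derive_seed, stream_rng
from .stats import analysis_report

__all__ = ["ExperimentResult", "run_study1_experiment", "run_study2_experiment",
           "efficiency_interaction_replicates"]


@dataclass
class ExperimentResult:
    """All artefacts of one simulated experiment."""

    study_id: int
    seed: int
    sessions: list[SessionRecord]
    escape_records: list[EscapeTestRecord]
    participant_df: pd.DataFrame = field(repr=False, default=None)
    block_df: pd.DataFrame = field(repr=False, default=None)
    report: pd.DataFrame = field(repr=False, default=None)


def _escape_variant(study_id: int) -> str:
    return "study1" if study_id == 1 else "study2"


def _finish(study_id, seed, sessions, escape_records, truth_maps) -> ExperimentResult:
    conditions = {s.participant_id: s.condition for s in sessions}
    participant_df = participant_table(sessions, truth_maps)
    block_df = metrics_table(escape_records, conditions)
    report = analysis_report(participant_df, block_df, study_id=study_id)
    return ExperimentResult(
        study_id=study_id, seed=seed, sessions=sessions,
        escape_records=escape_records, participant_df=participant_df,
        block_df=block_df, report=report,
    )


def run_study1_experiment(
    n_per_group: int = 27,
    seed: int = 0,
    agents: dict[str, AgentSpec] | None = None,
    config: StudyConfig | None = None,
) -> ExperimentResult:
    """Three-group design with one-to-one yoking: each yoked participant
    receives, trial for trial, the stress durations its escapable partner
    produced.  Yoked pairs are matched by index; the control group runs the
    same timeline with no stimulation."""
    config = config or build_study_config(1)
    agents = agents or {
        "EC": get_preset("ec_like"),
        "YC": get_preset("yc_like"),
        "CC": get_preset("ec_like"),
    }
    sessions: list[SessionRecord] = []
    escape_records: list[EscapeTestRecord] = []
    ec_sessions = []
    for i in range(n_per_group):
        pid = f"EC{i:03d}"
        s = simulate_session(
            "EC", individualize(agents["EC"], stream_rng(seed, i, "indiv-EC")), config,
            seed=derive_seed(seed, i, "session-EC"), participant_id=pid,
        )
        ec_sessions.append(s)
        sessions.append(s)
    for i in range(n_per_group):
        pid = f"YC{i:03d}"
        schedule = derive_yoked_schedule(
            ec_sessions[i], derive_seed(seed, i, "yoke")
        )
        sessions.append(
            simulate_session(
                "YC", individualize(agents["YC"], stream_rng(seed, i, "indiv-YC")), config,
                seed=derive_seed(seed, i, "session-YC"),
                yoke_source=schedule, participant_id=pid,
            )
        )
    for i in range(n_per_group):
        pid = f"CC{i:03d}"
        sessions.append(
            simulate_session(
                "CC", individualize(agents["CC"], stream_rng(seed, i, "indiv-CC")), config,
                seed=derive_seed(seed, i, "session-CC"), participant_id=pid,
            )
        )
    for s in sessions:
        agent = agents[s.condition]
        escape_records.append(
            run_escape_test(
                _escape_variant(1), agent,
                seed=derive_seed(seed, int(s.participant_id[2:]), f"escape-{s.condition}"),
                participant_id=s.participant_id,
            )
        )
    return _finish(1, seed, sessions, escape_records, None)


def run_study2_experiment(
    n_ec: int = 62,
    n_yc: int = 38,
    seed: int = 0,
    agents: dict[str, AgentSpec] | None = None,
    config: StudyConfig | None = None,
) -> ExperimentResult:
    """Two-group design with pseudo-yoking: the escapable group is simulated
    first; every yoked participant receives an independently shuffled copy of
    the escapable group's per-trial mean stress durations."""
    config = config or build_study_config(2)
    agents = agents or {"EC": get_preset("ec_like"), "YC": get_preset("yc_like")}
    sessions: list[SessionRecord] = []
    truth_maps: dict[str, dict] = {}
    ec_sessions = []
    for i in range(n_ec):
        pid = f"EC{i:03d}"
        tm = sample_truth_map(config, stream_rng(seed, i, "truth-map"))
        truth_maps[pid] = tm
        s = simulate_session(
            "EC", individualize(agents["EC"], stream_rng(seed, i, "indiv-EC")), config,
            seed=derive_seed(seed, i, "session-EC"),
            participant_id=pid, truth_map=tm,
        )
        ec_sessions.append(s)
        sessions.append(s)
    for i in range(n_yc):
        pid = f"YC{i:03d}"
        schedule = derive_pseudo_yoked_schedule(
            ec_sessions, config, derive_seed(seed, i, "pseudo-yoke")
        )
        sessions.append(
            simulate_session(
                "YC", individualize(agents["YC"], stream_rng(seed, i, "indiv-YC")), config,
                seed=derive_seed(seed, i, "session-YC"),
                yoke_source=schedule, participant_id=pid,
            )
        )
    escape_records = [
        run_escape_test(
            _escape_variant(2), agents[s.condition],
            seed=derive_seed(seed, int(s.participant_id[2:]), f"escape-{s.condition}"),
            participant_id=s.participant_id,
        )
        for s in sessions
    ]
    return _finish(2, seed, sessions, escape_records, truth_maps)


def efficiency_interaction_replicates(
    n_replicates: int = 100,
    seed: int = 0,
    n_ec: int = 50,
    n_yc: int = 50,
    alpha: float = 0.05,
) -> dict:
    """Replicate the two-group experiment and score, per replicate, whether
    the efficiency group x block interaction is significant (family-wise
    Bonferroni over the three escape indices) *and* in the expected
    direction (the yoked group less efficient in block 2 than in block 1).

    Returns recovery counts and the fraction of successful replicates.
    """
    hits = 0
    significant = 0
    for r in range(n_replicates):
        result = run_study2_experiment(
            n_ec=n_ec, n_yc=n_yc, seed=derive_seed(seed, r, "replicate")
        )
        row = result.report.query(
            "family == 'escape' and variable == 'efficiency' "
            "and effect_name == 'interaction'"
        ).iloc[0]
        yc = result.block_df.query("condition == 'YC'")
        yc_means = yc.groupby("block")["efficiency"].mean()
        worsening = bool(yc_means.loc[2] > yc_means.loc[1])
        sig = bool(row["p_adj"] < alpha)
        significant += sig
        hits += sig and worsening
    return {
        "n_replicates": n_replicates,
        "n_significant": significant,
        "n_recovered": hits,
        "recovery_rate": hits / n_replicates,
    }
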