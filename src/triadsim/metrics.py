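"""Behavioural read-outs from session and trajectory logs.

Three escape-test indices, per block:

* exploration -- unique cells visited per minute of stress-free exploration
  (distinct cells per trial, summed over trials, start cell included, divided
  by pooled exploration time);
* escapes -- number of stress phases terminated by reaching a safe cell;
* efficiency -- (stress-phase moves per minute of time actually spent under
  stress) divided by the number of escapes.  Higher values mean more activity
  per successful escape, i.e. *less* efficient behaviour; with zero escapes
  the quotient is undefined and propagates as missing into the statistics.

Plus two session indices: mean cue-locked reaction time over in-window
responses, and (three-cue escapable condition only) the fraction of trials
answered with the correct button in time.

All metrics are pure functions of the logs; recomputing them from a written
CSV gives identical values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import SessionRecord
from .grid import EscapeTestRecord, TrajectoryRecord

__all__ = [
    "MetricSet",
    "exploration_rate",
    "escape_count",
    "efficiency",
    "mean_rt",
    "correct_rate",
    "block_metrics",
    "metrics_table",
    "participant_table",
]


@dataclass(frozen=True)
class MetricSet:
    exploration_per_min: float
    escapes: int
    moves_per_min: float
    efficiency: float | None  # None when escapes == 0
    stress_minutes: float


def _require_phase(trajectories, phase: str) -> list[TrajectoryRecord]:
    records = list(trajectories)
    if not records:
        raise ValueError("no trajectories supplied")
    for rec in records:
        if rec.phase != phase:
            raise ValueError(f"expected {phase} trajectories, got {rec.phase!r}")
    return records


def exploration_rate(explore_trajectories) -> float:
    """Unique cells per minute over stress-free exploration: per-trial
    distinct-cell counts (start cell included) summed, divided by the pooled
    exploration time in minutes."""
    records = _require_phase(explore_trajectories, "explore")
    total_cells = sum(len(rec.visited_cells) for rec in records)
    total_minutes = sum(rec.phase_duration for rec in records) / 60.0
    return total_cells / total_minutes


def escape_count(stress_trajectories) -> int:
    """Number of stress phases terminated by reaching a safe cell."""
    records = _require_phase(stress_trajectories, "stress")
    return sum(1 for rec in records if rec.escaped)


def efficiency(stress_trajectories) -> float | None:
    """(moves per minute of stress time) / escapes; ``None`` with zero
    escapes.  Time is the sum of actual stress-phase durations (an escaped
    phase contributes its escape latency, not the cap)."""
    records = _require_phase(stress_trajectories, "stress")
    escapes = sum(1 for rec in records if rec.escaped)
    if escapes == 0:
        return None
    total_moves = sum(rec.n_moves for rec in records)
    total_minutes = sum(rec.phase_duration for rec in records) / 60.0
    return (total_moves / total_minutes) / escapes


def mean_rt(session: SessionRecord, response_window: float = 1.0) -> float | None:
    """Mean cue-locked RT over trials answered within the response window;
    misses and late presses excluded.  ``None`` flags a participant who never
    responded to any cue."""
    rts = [
        t.response_time
        for t in session.trials
        if t.response_time is not None and t.response_time <= response_window
    ]
    if not rts:
        return None
    return float(np.mean(rts))


def correct_rate(session: SessionRecord, truth_map: dict | None = None,
                 response_window: float = 1.0) -> float:
    """Fraction of three-cue EC trials answered with the correct button in
    time.  Uses the logged correctness flags; ``truth_map`` re-derives them
    when given (e.g. for logs written without the flag)."""
    if session.condition != "EC" or session.study_id != 2:
        raise ValueError("correct_rate applies to three-cue (study 2) EC sessions")
    hits = 0
    for t in session.trials:
        if truth_map is not None:
            ok = (
                t.response_button is not None
                and t.response_time is not None
                and t.response_time <= response_window
                and truth_map[t.cue_id] == t.response_button
            )
        else:
            ok = bool(t.response_correct) and (
                t.response_time is not None and t.response_time <= response_window
            )
        hits += ok
    return hits / len(session.trials)


def block_metrics(record: EscapeTestRecord, block: int) -> MetricSet:
    """All escape-test metrics for one 1-based block of one participant."""
    pairs = record.blocks[block - 1]
    explores = [e for e, _ in pairs]
    stresses = [s for _, s in pairs]
    escapes = escape_count(stresses)
    stress_minutes = sum(s.phase_duration for s in stresses) / 60.0
    total_moves = sum(s.n_moves for s in stresses)
    moves_per_min = total_moves / stress_minutes
    return MetricSet(
        exploration_per_min=exploration_rate(explores),
        escapes=escapes,
        moves_per_min=moves_per_min,
        efficiency=(moves_per_min / escapes) if escapes else None,
        stress_minutes=stress_minutes,
    )


def metrics_table(escape_records, conditions: dict | None = None) -> pd.DataFrame:
    """One row per participant x block with the escape-test metrics.

    ``conditions`` optionally maps participant_id -> condition label.
    Undefined efficiency appears as NaN.
    """
    rows = []
    for rec in escape_records:
        for b in range(1, len(rec.blocks) + 1):
            m = block_metrics(rec, b)
            rows.append(
                {
                    "participant_id": rec.participant_id,
                    "condition": (conditions or {}).get(rec.participant_id),
                    "variant": rec.variant,
                    "block": b,
                    "exploration_per_min": m.exploration_per_min,
                    "escapes": m.escapes,
                    "moves_per_min": m.moves_per_min,
                    "efficiency": math.nan if m.efficiency is None else m.efficiency,
                    "stress_minutes": m.stress_minutes,
                }
            )
    return pd.DataFrame(rows)


def participant_table(sessions, truth_maps: dict | None = None) -> pd.DataFrame:
    """One row per participant: condition, mean RT, mean rating per item,
    and pre/post affect totals."""
    rows = []
    for s in sessions:
        row = {
            "participant_id": s.participant_id,
            "condition": s.condition,
            "study_id": s.study_id,
            "mean_rt": mean_rt(s),
        }
        items = sorted({p.item for p in s.ratings})
        for item in items:
            values = [p.value for p in s.ratings if p.item == item]
            row[f"rating_{item}"] = float(np.mean(values))
        for score, value in s.affect_pre.items():
            row[f"{score}_pre"] = value
        for score, value in s.affect_post.items():
            row[f"{score}_post"] = value
        if s.condition == "EC" and s.study_id == 2:
            tm = (truth_maps or {}).get(s.participant_id)
            row["correct_rate"] = correct_rate(s, tm)
        rows.append(row)
    return pd.DataFrame(rows)
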