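"""Readers and writers for the package's file formats.

Everything tabular is plain CSV (UTF-8, header row); per-session metadata
(participant, condition, seed, affect totals) is a small JSON sidecar.
Round-trips are exact: floats are serialised with ``repr``-style shortest
round-trip precision, missing values as empty fields.  Unknown extra columns
in a future file version are preserved on read.

A :class:`RunManifest` records the command, configuration snapshot, root
seed, and a checksum inventory of every file a CLI run wrote, so a run can
be audited and reproduced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from .config import RatingProbe
from .engine import SessionRecord, TrialRecord
from .grid import EscapeTestRecord, TrajectoryRecord

__all__ = [
    "SchemaError",
    "write_session",
    "read_session",
    "write_escape_test",
    "read_escape_test",
    "RunManifest",
    "write_manifest",
]

TRIAL_COLUMNS = [
    "participant_id", "condition", "study_id", "trial_index", "cue_id",
    "cue_onset", "response_time", "response_button", "response_correct",
    "stress_duration", "terminated_by_response", "max_duration",
]
RATING_COLUMNS = ["participant_id", "after_trial", "item", "value"]
TRAJECTORY_COLUMNS = [
    "participant_id", "block", "trial", "phase", "timestamp", "move",
    "row", "col", "on_safe",
]


class SchemaError(ValueError):
    """Raised when a file does not match the expected column schema."""


def _check_columns(df: pd.DataFrame, required: list[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _opt(value):
    """None-preserving cell."""
    return "" if value is None else value


def _to_bool(cell):
    if cell in ("", None) or pd.isna(cell):
        return None
    if isinstance(cell, (bool,)):
        return bool(cell)
    return str(cell) == "True"


def write_session(session: SessionRecord, directory) -> list[Path]:
    """Write one session as ``trials.csv``, ``ratings.csv``, ``meta.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    trials = pd.DataFrame(
        [
            {
                "participant_id": session.participant_id,
                "condition": session.condition,
                "study_id": session.study_id,
                "trial_index": t.trial_index,
                "cue_id": t.cue_id,
                "cue_onset": t.cue_onset,
                "response_time": _opt(t.response_time),
                "response_button": _opt(t.response_button),
                "response_correct": _opt(t.response_correct),
                "stress_duration": t.stress_duration,
                "terminated_by_response": t.terminated_by_response,
                "max_duration": t.max_duration,
            }
            for t in session.trials
        ],
        columns=TRIAL_COLUMNS,
    )
    ratings = pd.DataFrame(
        [
            {
                "participant_id": session.participant_id,
                "after_trial": p.after_trial,
                "item": p.item,
                "value": p.value,
            }
            for p in session.ratings
        ],
        columns=RATING_COLUMNS,
    )
    meta = {
        "participant_id": session.participant_id,
        "condition": session.condition,
        "study_id": session.study_id,
        "seed": session.seed,
        "affect_pre": session.affect_pre,
        "affect_post": session.affect_post,
    }
    paths = [directory / "trials.csv", directory / "ratings.csv", directory / "meta.json"]
    trials.to_csv(paths[0], index=False)
    ratings.to_csv(paths[1], index=False)
    paths[2].write_text(json.dumps(meta, indent=1, sort_keys=True))
    return paths


def read_session(directory) -> SessionRecord:
    """Read a session written by :func:`write_session` (exact round-trip)."""
    directory = Path(directory)
    trials_path = directory / "trials.csv"
    ratings_path = directory / "ratings.csv"
    meta_path = directory / "meta.json"
    for p in (trials_path, ratings_path, meta_path):
        if not p.exists():
            raise SchemaError(f"missing session file {p}")
    meta = json.loads(meta_path.read_text())
    trials_df = pd.read_csv(trials_path, dtype={"response_button": "string"},
                            float_precision="round_trip")
    _check_columns(trials_df, TRIAL_COLUMNS, trials_path)
    ratings_df = pd.read_csv(ratings_path)
    _check_columns(ratings_df, RATING_COLUMNS, ratings_path)

    trials = []
    for i, row in trials_df.iterrows():
        if int(row["trial_index"]) != i + 1:
            raise SchemaError(
                f"{trials_path}: row {i}: trial_index {row['trial_index']} out of order"
            )
        rt = None if pd.isna(row["response_time"]) else float(row["response_time"])
        button = None if pd.isna(row["response_button"]) else str(row["response_button"])
        trials.append(
            TrialRecord(
                trial_index=int(row["trial_index"]),
                condition=str(row["condition"]),
                cue_id=str(row["cue_id"]),
                cue_onset=float(row["cue_onset"]),
                response_time=rt,
                response_button=button,
                response_correct=_to_bool(row["response_correct"]),
                stress_duration=float(row["stress_duration"]),
                terminated_by_response=bool(row["terminated_by_response"]),
                max_duration=float(row["max_duration"]),
            )
        )
    ratings = [
        RatingProbe(after_trial=int(r["after_trial"]), item=str(r["item"]),
                    value=int(r["value"]))
        for _, r in ratings_df.iterrows()
    ]
    return SessionRecord(
        participant_id=meta["participant_id"],
        condition=meta["condition"],
        study_id=int(meta["study_id"]),
        seed=int(meta["seed"]),
        trials=trials,
        ratings=ratings,
        affect_pre=meta["affect_pre"],
        affect_post=meta["affect_post"],
    )


def write_escape_test(record: EscapeTestRecord, directory) -> list[Path]:
    """Write one escape test as ``trajectories.csv`` (one row per move
    event), ``layout.csv`` (safe cells per block), ``escape_meta.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    event_rows = []
    phase_rows = []
    for b, block in enumerate(record.blocks, start=1):
        for t, (explore, stress) in enumerate(block, start=1):
            for rec in (explore, stress):
                phase_rows.append(
                    {
                        "block": b, "trial": t, "phase": rec.phase,
                        "start_row": rec.start[0], "start_col": rec.start[1],
                        "escaped": rec.escaped,
                        "escape_latency": _opt(rec.escape_latency),
                        "phase_duration": rec.phase_duration,
                    }
                )
                layout = record.safe_layouts[b - 1]
                for ts, move, cell in rec.events:
                    event_rows.append(
                        {
                            "participant_id": record.participant_id,
                            "block": b, "trial": t, "phase": rec.phase,
                            "timestamp": ts, "move": move,
                            "row": cell[0], "col": cell[1],
                            "on_safe": cell in layout,
                        }
                    )
    layout_rows = [
        {"block": b, "row": r, "col": c}
        for b, layout in enumerate(record.safe_layouts, start=1)
        for r, c in sorted(layout)
    ]
    meta = {
        "participant_id": record.participant_id,
        "variant": record.variant,
        "seed": record.seed,
        "layout_repeat": record.layout_repeat,
        "phases": phase_rows,
    }
    paths = [
        directory / "trajectories.csv",
        directory / "layout.csv",
        directory / "escape_meta.json",
    ]
    pd.DataFrame(event_rows, columns=TRAJECTORY_COLUMNS).to_csv(paths[0], index=False)
    pd.DataFrame(layout_rows, columns=["block", "row", "col"]).to_csv(paths[1], index=False)
    paths[2].write_text(json.dumps(meta, indent=1, sort_keys=True))
    return paths


def read_escape_test(directory) -> EscapeTestRecord:
    """Read an escape test written by :func:`write_escape_test`."""
    directory = Path(directory)
    events_path = directory / "trajectories.csv"
    layout_path = directory / "layout.csv"
    meta_path = directory / "escape_meta.json"
    for p in (events_path, layout_path, meta_path):
        if not p.exists():
            raise SchemaError(f"missing escape-test file {p}")
    meta = json.loads(meta_path.read_text())
    events = pd.read_csv(events_path, float_precision="round_trip")
    _check_columns(events, TRAJECTORY_COLUMNS, events_path)
    layouts_df = pd.read_csv(layout_path)
    _check_columns(layouts_df, ["block", "row", "col"], layout_path)

    n_blocks = int(layouts_df["block"].max())
    layouts = tuple(
        frozenset(
            (int(r["row"]), int(r["col"]))
            for _, r in layouts_df[layouts_df["block"] == b].iterrows()
        )
        for b in range(1, n_blocks + 1)
    )
    phase_meta = {
        (p["block"], p["trial"], p["phase"]): p for p in meta["phases"]
    }
    blocks = []
    for b in range(1, n_blocks + 1):
        trials = sorted(
            {p["trial"] for p in meta["phases"] if p["block"] == b}
        )
        pairs = []
        for t in trials:
            pair = []
            for phase in ("explore", "stress"):
                info = phase_meta[(b, t, phase)]
                sub = events.query(
                    "block == @b and trial == @t and phase == @phase"
                )
                evs = tuple(
                    (float(r["timestamp"]), str(r["move"]),
                     (int(r["row"]), int(r["col"])))
                    for _, r in sub.iterrows()
                )
                latency = info["escape_latency"]
                pair.append(
                    TrajectoryRecord(
                        phase=phase, block=b, trial=t,
                        start=(int(info["start_row"]), int(info["start_col"])),
                        events=evs,
                        escaped=bool(info["escaped"]),
                        escape_latency=None if latency in ("", None) else float(latency),
                        phase_duration=float(info["phase_duration"]),
                    )
                )
            pairs.append(tuple(pair))
        blocks.append(tuple(pairs))
    return EscapeTestRecord(
        participant_id=meta["participant_id"],
        variant=meta["variant"],
        seed=int(meta["seed"]),
        safe_layouts=layouts,
        blocks=tuple(blocks),
        layout_repeat=bool(meta["layout_repeat"]),
    )


@dataclass
class RunManifest:
    """Audit record of one CLI run."""

    package_version: str
    command: str
    config: dict
    root_seed: int
    participant_seeds: dict = field(default_factory=dict)
    timestamp: str = ""
    outputs: dict = field(default_factory=dict)  # path -> sha256


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(
    manifest: RunManifest, directory, output_files=()
) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest.timestamp = manifest.timestamp or datetime.now(timezone.utc).isoformat()
    for f in output_files:
        f = Path(f)
        manifest.outputs[str(f.relative_to(directory))] = _sha256(f)
    path = directory / "manifest.json"
    path.write_text(json.dumps(dataclasses.asdict(manifest), indent=1, sort_keys=True))
    return path
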