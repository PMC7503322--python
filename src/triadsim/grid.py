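"""Grid-based escape behaviour test.

A translation of the shuttle-box escape task: a 15 x 15 grid with four safe
cells hidden at random locations.  Each trial has a stress-free exploration
phase and a stress phase; during stress, stepping onto a safe cell terminates
the stressor (an escape).  Safe cells light up when encountered in either
phase, so their locations are learnable.  The original variant runs one block
of five trials with the position persisting from exploration into stress; the
improved variant runs two blocks of five shorter trials with the position
reset to the centre at every phase start and the safe cells relocated --
unannounced -- for block 2, introducing a loss-of-control element.

Moves are discrete orthogonal key presses emitted by the agent's navigation
policy at its move interval; a press into the edge leaves the position
unchanged but still counts as activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .agents import AgentSpec, BasePolicy, MOVES, _DELTA, make_policy
from .config import GridConfig, build_study_config
from .seeding import stream_rng

__all__ = [
    "GridState",
    "TrajectoryRecord",
    "EscapeTestRecord",
    "place_safe_spaces",
    "apply_move",
    "run_phase",
    "run_escape_test",
    "START_CELL",
    "grid_config_for_variant",
]

START_CELL = (7, 7)  # middle of a 15 x 15 grid, 0-based


@dataclass
class GridState:
    """Mutable state of the grid environment during one phase."""

    position: tuple[int, int]
    safe_cells: frozenset
    known_safes: set = field(default_factory=set)  # revealed so far
    visited: set = field(default_factory=set)  # cells entered this phase
    phase: str = "explore"
    clock: float = 0.0


@dataclass(frozen=True)
class TrajectoryRecord:
    """All move events of one phase of one trial."""

    phase: str  # explore | stress
    block: int  # 1-based
    trial: int  # 1-based within block
    start: tuple[int, int]
    events: tuple  # of (timestamp, move, (row, col))
    escaped: bool
    escape_latency: float | None
    phase_duration: float

    @property
    def visited_cells(self) -> set:
        cells = {self.start}
        cells.update(cell for _, _, cell in self.events)
        return cells

    @property
    def n_moves(self) -> int:
        return len(self.events)


@dataclass(frozen=True)
class EscapeTestRecord:
    """One participant's complete escape behaviour test."""

    participant_id: str
    variant: str  # study1 | study2
    seed: int
    safe_layouts: tuple  # frozenset per block
    blocks: tuple  # per block: tuple of (explore, stress) TrajectoryRecord pairs
    layout_repeat: bool = False  # block layouts happened to coincide

    def trajectories(self, phase: str | None = None):
        for block in self.blocks:
            for explore, stress in block:
                if phase in (None, "explore"):
                    yield explore
                if phase in (None, "stress"):
                    yield stress


def place_safe_spaces(
    grid: GridConfig, excluded: set, rng_or_seed
) -> frozenset:
    """Sample ``n_safe`` distinct cells uniformly from the grid minus
    ``excluded``; deterministic given the seed."""
    rng = (
        rng_or_seed
        if isinstance(rng_or_seed, np.random.Generator)
        else np.random.default_rng(rng_or_seed)
    )
    eligible = [
        (r, c)
        for r in range(grid.size)
        for c in range(grid.size)
        if (r, c) not in excluded
    ]
    if grid.n_safe > len(eligible):
        raise ValueError(
            f"cannot place {grid.n_safe} safe cells on {len(eligible)} eligible cells"
        )
    idx = rng.choice(len(eligible), size=grid.n_safe, replace=False)
    return frozenset(eligible[i] for i in idx)


def apply_move(position: tuple[int, int], move: str, size: int) -> tuple[int, int]:
    """One orthogonal step; moves off the edge leave the position unchanged
    (the press still counts as a move event)."""
    if move not in MOVES:
        raise ValueError(f"invalid move token {move!r}")
    dr, dc = _DELTA[move]
    r, c = position[0] + dr, position[1] + dc
    if 0 <= r < size and 0 <= c < size:
        return (r, c)
    return position


def run_phase(
    state: GridState,
    policy: BasePolicy,
    duration: float,
    stress: bool,
    rng: np.random.Generator,
    block: int = 1,
    trial: int = 1,
    size: int = 15,
) -> TrajectoryRecord:
    """Run one phase: query the policy at its move interval until the clock
    passes ``duration`` or, in a stress phase, a safe cell is entered.

    Entering any safe cell reveals it (``known_safes``) in both phases; in
    a stress phase it additionally terminates the phase with an escape.
    """
    if duration <= 0:
        raise ValueError("phase duration must be positive")
    state.phase = "stress" if stress else "explore"
    state.visited = {state.position}
    state.clock = 0.0
    policy.on_phase_start(state.phase)

    interval = policy.move_interval
    events = []
    start = state.position
    escaped = False
    latency = None
    k = 1
    # tolerance so e.g. 0.25-s steps fill a 5-s phase exactly
    while k * interval <= duration + 1e-9:
        t = k * interval
        move = policy.step(state.position, state.phase, rng)
        if move not in MOVES:
            raise ValueError(f"policy returned invalid move {move!r}")
        new_pos = apply_move(state.position, move, size)
        state.position = new_pos
        state.visited.add(new_pos)
        state.clock = t
        is_safe = new_pos in state.safe_cells
        if is_safe:
            state.known_safes.add(new_pos)
        policy.observe(new_pos, is_safe, rng)
        events.append((t, move, new_pos))
        if stress and is_safe:
            escaped = True
            latency = t
            break
        k += 1

    return TrajectoryRecord(
        phase=state.phase,
        block=block,
        trial=trial,
        start=start,
        events=tuple(events),
        escaped=escaped,
        escape_latency=latency,
        phase_duration=latency if escaped else duration,
    )


def grid_config_for_variant(variant: str) -> GridConfig:
    if variant == "study1":
        return build_study_config(1).grid
    if variant == "study2":
        return build_study_config(2).grid
    raise ValueError(f"unknown variant {variant!r}; expected 'study1' or 'study2'")


def run_escape_test(
    variant: str,
    agent: AgentSpec,
    seed: int,
    participant_id: str = "p0",
) -> EscapeTestRecord:
    """Run the full escape test for one agent.

    The original variant: one safe layout, five trials starting at the
    centre, 10 s exploration then stress capped at 20 s, with the position
    carried from exploration into stress.  The improved variant: two blocks
    of five trials, 5 s phases, position reset to the centre at every phase
    start, and an independent safe layout for block 2.  The agent's memory of
    safe locations persists across trials and -- stale -- across the
    relocation.  Deterministic given ``(variant, agent, seed)``.
    """
    grid = grid_config_for_variant(variant)
    agent.validate()
    policy = make_policy(agent.nav_policy, grid.size, START_CELL)
    rng_nav = stream_rng(seed, 0, "nav")

    layouts = []
    blocks = []
    for b in range(1, grid.n_blocks + 1):
        rng_layout = stream_rng(seed, 0, f"layout-block{b}")
        layout = place_safe_spaces(grid, {START_CELL}, rng_layout)
        layouts.append(layout)
        state = GridState(position=START_CELL, safe_cells=layout)
        trial_pairs = []
        for t in range(1, grid.n_trials_per_block + 1):
            policy.on_trial_start(rng_nav)
            state.position = START_CELL  # every trial starts at the centre
            explore = run_phase(
                state, policy, grid.explore_duration, stress=False,
                rng=rng_nav, block=b, trial=t, size=grid.size,
            )
            if grid.reset_between_phases:
                state.position = START_CELL
            stress_rec = run_phase(
                state, policy, grid.stress_cap, stress=True,
                rng=rng_nav, block=b, trial=t, size=grid.size,
            )
            trial_pairs.append((explore, stress_rec))
        blocks.append(tuple(trial_pairs))

    layout_repeat = len(layouts) > 1 and len(set(layouts)) < len(layouts)
    return EscapeTestRecord(
        participant_id=participant_id,
        variant=variant,
        seed=seed,
        safe_layouts=tuple(layouts),
        blocks=tuple(blocks),
        layout_repeat=layout_repeat,
    )
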