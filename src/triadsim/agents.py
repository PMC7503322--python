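"""Generative models of simulated participants.

An :class:`AgentSpec` bundles four sub-models:

* a reaction-time model (shifted lognormal or constant, with a miss
  probability) for cue-locked button presses;
* a cue-button learner for the three-cue task (elimination learning from the
  stressor-termination feedback signal, with lapses);
* a grid-navigation policy for the escape behaviour test;
* linear-Gaussian rating and affect models producing 1-7 Likert answers and
  pre/post questionnaire totals.

Two presets ship with the package.  ``ec_like`` emulates a participant with
intact control experience: fast reactions, systematic elimination learning,
and memory-guided navigation that searches the grid methodically, heads
straight for remembered safe spaces under stress, and -- on discovering that
a remembered location is no longer safe -- abandons its stale memory and
restarts a systematic search.  ``yc_like`` emulates a participant after
uncontrollable stress: slower and more variable reactions, and "frantic"
navigation -- a high-tempo, weakly directed walk that rigidly keeps
returning to remembered safe locations at the start of every phase, even
after those locations have stopped being safe.  The yoked phenotype
therefore produces more activity but converts it into fewer successful
escapes, particularly after the unannounced safe-space relocation, which is
the behavioural signature the escape test is built to detect.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "RTModel",
    "LearnerSpec",
    "NavPolicySpec",
    "RatingItemModel",
    "AffectScoreModel",
    "AgentSpec",
    "LearnerState",
    "new_learner_state",
    "sample_rt",
    "choose_button",
    "update_learner",
    "generate_rating",
    "sample_affect",
    "make_policy",
    "nav_policy_step",
    "get_preset",
    "PRESETS",
    "BUTTONS",
]

MOVES = ("up", "down", "left", "right")
_DELTA = {"up": (-1, 0), "down": (1, 0), "left": (0, -1), "right": (0, 1)}
BUTTONS = ("b1", "b2", "b3")


# ---------------------------------------------------------------------------
# specification dataclasses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RTModel:
    """Cue-locked reaction time distribution.

    ``shifted_lognormal`` draws ``shift + LogNormal(mu, sigma)`` seconds (so
    the median is ``shift + exp(mu)``); ``constant`` always returns ``shift``.
    With probability ``miss_prob`` no response is produced at all.
    """

    family: str = "shifted_lognormal"  # or "constant"
    shift: float = 0.2
    mu: float = float(np.log(0.3))
    sigma: float = 0.4
    miss_prob: float = 0.0

    def validate(self) -> None:
        if self.family not in ("shifted_lognormal", "constant"):
            raise ValueError(f"unknown rt family {self.family!r}")
        if not 0.0 <= self.miss_prob <= 1.0:
            raise ValueError("miss_prob must be in [0, 1]")


@dataclass(frozen=True)
class LearnerSpec:
    family: str = "elimination"  # or "random"
    lapse_prob: float = 0.0

    def validate(self) -> None:
        if self.family not in ("elimination", "random"):
            raise ValueError(f"unknown learner family {self.family!r}")
        if not 0.0 <= self.lapse_prob <= 1.0:
            raise ValueError("lapse_prob must be in [0, 1]")


@dataclass(frozen=True)
class NavPolicySpec:
    """Parameters of a grid-navigation policy.

    ``move_interval`` is the seconds between key presses.  ``memory_retention``
    is the per-trial probability of keeping each remembered safe location.
    ``stale_persistence`` bounds how many stress-phase moves a memory-guided
    agent keeps pursuing remembered locations after discovering that one of
    them is no longer safe, before it concludes the layout changed and
    restarts its search.  ``momentum``, ``goal_bias`` and ``unlearn_prob``
    only apply to the frantic policy: the probability of repeating the
    previous move, of steering toward a remembered safe space during stress,
    and of actually giving up a remembered location on finding it no longer
    safe -- values below 1 produce perseverative returns to stale locations.
    """

    family: str = "random_walk"  # random_walk | sweep | memory_guided | frantic
    move_interval: float = 0.25
    memory_retention: float = 1.0
    stale_persistence: int = 3
    momentum: float = 0.6
    goal_bias: float = 0.7
    unlearn_prob: float = 1.0

    def validate(self) -> None:
        if self.family not in ("random_walk", "sweep", "memory_guided", "frantic"):
            raise ValueError(f"unknown nav policy family {self.family!r}")
        if self.move_interval <= 0:
            raise ValueError("move_interval must be positive")
        for name in ("memory_retention", "momentum", "goal_bias", "unlearn_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.stale_persistence < 0:
            raise ValueError("stale_persistence must be >= 0")


@dataclass(frozen=True)
class RatingItemModel:
    """Linear trend with Gaussian noise, rounded and clipped to 1..7."""

    baseline: float = 4.0
    slope_per_probe: float = 0.0
    noise_sd: float = 0.0

    def validate(self) -> None:
        if not 1.0 <= self.baseline <= 7.0:
            raise ValueError("baseline must be in [1, 7]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class AffectScoreModel:
    """Pre-score distribution and additive pre-to-post shift for one total."""

    pre_mean: float = 0.0
    pre_sd: float = 1.0
    post_shift_mean: float = 0.0
    post_shift_sd: float = 1.0


@dataclass(frozen=True)
class AgentSpec:
    name: str
    rt_model: RTModel = field(default_factory=RTModel)
    learner: LearnerSpec = field(default_factory=LearnerSpec)
    nav_policy: NavPolicySpec = field(default_factory=NavPolicySpec)
    rating_model: dict = field(default_factory=dict)  # item -> RatingItemModel
    affect_model: dict = field(default_factory=dict)  # score -> AffectScoreModel

    def validate(self) -> None:
        self.rt_model.validate()
        self.learner.validate()
        self.nav_policy.validate()
        for model in self.rating_model.values():
            model.validate()


# ---------------------------------------------------------------------------
# reaction times
# ---------------------------------------------------------------------------

def sample_rt(rt_model: RTModel, rng: np.random.Generator) -> float | None:
    """Draw a cue-locked reaction time in seconds, or ``None`` for a miss."""
    rt_model.validate()
    if rt_model.miss_prob > 0 and rng.random() < rt_model.miss_prob:
        return None
    if rt_model.family == "constant":
        return rt_model.shift
    return rt_model.shift + float(rng.lognormal(rt_model.mu, rt_model.sigma))


# ---------------------------------------------------------------------------
# cue-button learning (three-cue task)
# ---------------------------------------------------------------------------

@dataclass
class LearnerState:
    """Per-cue candidate button sets; a resolved cue has a singleton set."""

    candidates: dict  # cue -> tuple of buttons (ordered)
    resolved: dict  # cue -> button

    def is_resolved(self, cue: str) -> bool:
        return cue in self.resolved


def new_learner_state(cues, buttons=BUTTONS) -> LearnerState:
    return LearnerState(
        candidates={cue: tuple(buttons) for cue in cues},
        resolved={},
    )


def choose_button(
    state: LearnerState, cue: str, lapse_prob: float, rng: np.random.Generator,
    buttons=BUTTONS,
) -> str:
    """Pick a button: a lapse is uniform over all buttons, otherwise uniform
    over the cue's remaining candidate set (singleton once resolved)."""
    if cue not in state.candidates:
        raise KeyError(f"unknown cue {cue!r}")
    if lapse_prob > 0 and rng.random() < lapse_prob:
        return str(buttons[rng.integers(len(buttons))])
    pool = state.candidates[cue]
    return str(pool[rng.integers(len(pool))])


def update_learner(state: LearnerState, cue: str, button: str, terminated: bool) -> LearnerState:
    """Apply termination feedback: success resolves the cue to ``button``;
    failure eliminates it from the candidate set (kept if removal would empty
    the set, guarding against inconsistent feedback such as a correct press
    delivered too late to stop the stressor)."""
    if cue not in state.candidates:
        raise KeyError(f"unknown cue {cue!r}")
    candidates = dict(state.candidates)
    resolved = dict(state.resolved)
    if terminated:
        candidates[cue] = (button,)
        resolved[cue] = button
    else:
        remaining = tuple(b for b in candidates[cue] if b != button)
        if remaining:
            candidates[cue] = remaining
            resolved.pop(cue, None)
    return LearnerState(candidates=candidates, resolved=resolved)


# ---------------------------------------------------------------------------
# ratings and affect
# ---------------------------------------------------------------------------

def generate_rating(
    model: RatingItemModel, probe_number: int, rng: np.random.Generator
) -> int:
    """One Likert answer for probe ``probe_number`` (1-based): the linear
    trend plus Gaussian noise, rounded and clipped to 1..7."""
    model.validate()
    raw = model.baseline + model.slope_per_probe * (probe_number - 1)
    if model.noise_sd > 0:
        raw += rng.normal(0.0, model.noise_sd)
    return int(np.clip(round(raw), 1, 7))


def sample_affect(model: AffectScoreModel, rng: np.random.Generator) -> tuple[float, float]:
    """Draw (pre, post) values of one questionnaire total."""
    pre = float(rng.normal(model.pre_mean, model.pre_sd))
    post = pre + float(rng.normal(model.post_shift_mean, model.post_shift_sd))
    return pre, post


# ---------------------------------------------------------------------------
# navigation policies
# ---------------------------------------------------------------------------

def _spiral_order(size: int, start: tuple[int, int]) -> list[tuple[int, int]]:
    """Deterministic outward coverage ordering of all cells from ``start``."""
    order = [start]
    seen = {start}
    r, c = start
    run = 1
    direction = 0
    deltas = ((0, 1), (1, 0), (0, -1), (-1, 0))
    while len(order) < size * size and run < 4 * size:
        for _ in range(2):
            dr, dc = deltas[direction % 4]
            for _ in range(run):
                r += dr
                c += dc
                if 0 <= r < size and 0 <= c < size and (r, c) not in seen:
                    order.append((r, c))
                    seen.add((r, c))
            direction += 1
        run += 1
    return order


def _step_toward(pos: tuple[int, int], target: tuple[int, int]) -> str:
    """One move along a shortest Manhattan path, rows first."""
    if pos[0] < target[0]:
        return "down"
    if pos[0] > target[0]:
        return "up"
    if pos[1] < target[1]:
        return "right"
    return "left"


def _nearest(pos: tuple[int, int], cells) -> tuple[int, int]:
    """Closest cell by Manhattan distance; ties broken row-first (smallest
    row, then smallest column)."""
    return min(cells, key=lambda c: (abs(c[0] - pos[0]) + abs(c[1] - pos[1]), c))


class BasePolicy:
    """Stateful navigation policy driven by the escape-test runner.

    The runner calls :meth:`on_trial_start` before each trial,
    :meth:`on_phase_start` before each phase, :meth:`observe` after every
    move with the resulting cell and whether it is currently a safe space,
    and :meth:`step` to obtain the next move.
    """

    def __init__(self, spec: NavPolicySpec, size: int, start: tuple[int, int]):
        spec.validate()
        self.spec = spec
        self.size = size
        self.start = start
        self.remembered: set[tuple[int, int]] = set()

    @property
    def move_interval(self) -> float:
        return self.spec.move_interval

    def on_trial_start(self, rng: np.random.Generator) -> None:
        keep = self.spec.memory_retention
        if keep < 1.0 and self.remembered:
            self.remembered = {
                cell for cell in sorted(self.remembered) if rng.random() < keep
            }

    def on_phase_start(self, phase: str) -> None:  # noqa: ARG002 - hook
        pass

    def observe(self, cell: tuple[int, int], is_safe: bool,
                rng: np.random.Generator | None = None) -> None:
        if is_safe:
            self.remembered.add(cell)
        elif cell in self.remembered:
            # remembered location is no longer safe: forget it
            self.remembered.discard(cell)

    def step(self, pos, phase, rng) -> str:
        raise NotImplementedError


class RandomWalkPolicy(BasePolicy):
    def step(self, pos, phase, rng) -> str:
        return MOVES[rng.integers(4)]


class SweepPolicy(BasePolicy):
    """Deterministic coverage scan: follows an outward spiral ordering of the
    grid from the start cell, walking toward the next cell it has not yet
    covered (every cell it passes through counts as covered)."""

    def __init__(self, spec, size, start):
        super().__init__(spec, size, start)
        self.order = _spiral_order(size, start)
        self.ptr = 0
        self.covered: set[tuple[int, int]] = set()

    def reset_coverage(self) -> None:
        self.ptr = 0
        self.covered = set()

    def observe(self, cell, is_safe, rng=None) -> None:
        super().observe(cell, is_safe, rng)
        self.covered.add(cell)

    def _sweep_step(self, pos) -> str:
        while self.ptr < len(self.order) and self.order[self.ptr] in self.covered:
            self.ptr += 1
        if self.ptr >= len(self.order):
            self.reset_coverage()
            self.ptr = 1 if self.order and self.order[0] == pos else 0
        target = self.order[self.ptr]
        if target == pos:
            self.covered.add(pos)
            return self._sweep_step(pos)
        return _step_toward(pos, target)

    def step(self, pos, phase, rng) -> str:
        return self._sweep_step(pos)


class MemoryGuidedPolicy(SweepPolicy):
    """Coverage scan that, under stress, heads straight for the nearest
    remembered safe space; when remembered locations prove stale it abandons
    them (after a bounded number of further pursuit moves) and restarts its
    coverage scan."""

    def __init__(self, spec, size, start):
        super().__init__(spec, size, start)
        self._stale_budget: int | None = None

    def observe(self, cell, is_safe, rng=None) -> None:
        was_remembered = cell in self.remembered
        super().observe(cell, is_safe, rng)
        if was_remembered and not is_safe:
            # arrived at a remembered cell that did not light up: the layout
            # may have changed -- restart the scan, tolerate a short pursuit
            # of the remaining remembered cells before giving them all up
            self.reset_coverage()
            self._stale_budget = self.spec.stale_persistence

    def on_trial_start(self, rng) -> None:
        super().on_trial_start(rng)
        self._stale_budget = None

    def step(self, pos, phase, rng) -> str:
        if phase == "stress" and self.remembered:
            if self._stale_budget is not None:
                if self._stale_budget <= 0:
                    self.remembered.clear()
                    self._stale_budget = None
                    return self._sweep_step(pos)
                self._stale_budget -= 1
            target = _nearest(pos, self.remembered)
            if target == pos:
                # standing on a stale cell (observe already dropped live ones)
                self.remembered.discard(pos)
                if not self.remembered:
                    return self._sweep_step(pos)
                target = _nearest(pos, self.remembered)
            return _step_toward(pos, target)
        return self._sweep_step(pos)


class FranticPolicy(BasePolicy):
    """Momentum-biased random walk with unreliable memory: repeats its last
    move with probability ``momentum``; under stress, steps toward the
    nearest remembered safe space with probability ``goal_bias``; forgets
    each remembered location with probability ``1 - memory_retention`` at
    every trial start.  Pursuit of remembered locations is capped at
    ``stale_persistence`` moves per phase: after that the agent falls back
    to its undirected walk for the rest of the phase.  On finding a
    remembered location no longer safe it gives it up only with probability
    ``unlearn_prob`` -- below 1 the agent perseveres, returning to stale
    locations again and again."""

    def __init__(self, spec, size, start):
        super().__init__(spec, size, start)
        self._last: str | None = None
        self._moves_this_phase = 0

    def on_phase_start(self, phase) -> None:
        self._moves_this_phase = 0

    def observe(self, cell, is_safe, rng=None) -> None:
        if not is_safe and cell in self.remembered and self.spec.unlearn_prob < 1.0:
            if rng is None or rng.random() < self.spec.unlearn_prob:
                self.remembered.discard(cell)
            return
        super().observe(cell, is_safe, rng)

    def step(self, pos, phase, rng) -> str:
        self._moves_this_phase += 1
        pursuing = (
            self.remembered
            and self._moves_this_phase <= self.spec.stale_persistence
            and rng.random() < self.spec.goal_bias
        )
        if pursuing:
            target = _nearest(pos, self.remembered)
            if target != pos:
                move = _step_toward(pos, target)
                self._last = move
                return move
        if self._last is not None and rng.random() < self.spec.momentum:
            return self._last
        move = MOVES[rng.integers(4)]
        self._last = move
        return move


_POLICY_CLASSES = {
    "random_walk": RandomWalkPolicy,
    "sweep": SweepPolicy,
    "memory_guided": MemoryGuidedPolicy,
    "frantic": FranticPolicy,
}


def make_policy(spec: NavPolicySpec, size: int, start: tuple[int, int]) -> BasePolicy:
    spec.validate()
    return _POLICY_CLASSES[spec.family](spec, size, start)


def nav_policy_step(policy: BasePolicy, observation, rng: np.random.Generator) -> str:
    """Functional wrapper around :meth:`BasePolicy.step`.

    ``observation`` is ``(position, known_safes, phase)``; the known-safe set
    replaces the policy's memory for this query.
    """
    position, known_safes, phase = observation
    if known_safes is not None:
        policy.remembered = set(known_safes)
    move = policy.step(tuple(position), phase, rng)
    if move not in MOVES:
        raise ValueError(f"policy returned invalid move {move!r}")
    return move


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def _ec_like() -> AgentSpec:
    return AgentSpec(
        name="ec_like",
        rt_model=RTModel(
            family="shifted_lognormal", shift=0.20, mu=float(np.log(0.25)),
            sigma=0.25, miss_prob=0.05,
        ),
        learner=LearnerSpec(family="elimination", lapse_prob=0.10),
        nav_policy=NavPolicySpec(
            family="memory_guided", move_interval=0.30,
            memory_retention=1.0, stale_persistence=3,
        ),
        rating_model={
            "aversiveness": RatingItemModel(5.4, 0.05, 0.8),
            "control": RatingItemModel(4.2, -0.15, 0.8),
            "exhaustion": RatingItemModel(3.5, 0.30, 0.8),
            "frustration": RatingItemModel(3.4, 0.15, 0.9),
            "helplessness": RatingItemModel(2.8, 0.10, 0.9),
        },
        affect_model={
            "stadi_total": AffectScoreModel(28.0, 5.0, 2.0, 3.0),
            "panas_pos": AffectScoreModel(30.0, 5.0, -3.0, 3.0),
            "panas_neg": AffectScoreModel(14.0, 3.0, 2.0, 2.5),
        },
    )


def _yc_like() -> AgentSpec:
    return AgentSpec(
        name="yc_like",
        rt_model=RTModel(
            family="shifted_lognormal", shift=0.25, mu=float(np.log(0.35)),
            sigma=0.30, miss_prob=0.12,
        ),
        learner=LearnerSpec(family="random", lapse_prob=1.0),
        nav_policy=NavPolicySpec(
            family="frantic", move_interval=0.12,
            memory_retention=1.0, stale_persistence=13,
            momentum=0.5, goal_bias=1.0, unlearn_prob=0.0,
        ),
        rating_model={
            "aversiveness": RatingItemModel(5.4, 0.05, 0.8),
            "control": RatingItemModel(2.8, -0.20, 0.8),
            "exhaustion": RatingItemModel(4.0, 0.30, 0.8),
            "frustration": RatingItemModel(4.2, 0.15, 0.9),
            "helplessness": RatingItemModel(3.9, 0.15, 0.9),
        },
        affect_model={
            "stadi_total": AffectScoreModel(29.5, 5.0, 2.3, 3.0),
            "panas_pos": AffectScoreModel(29.5, 5.0, -3.0, 3.0),
            "panas_neg": AffectScoreModel(15.5, 3.0, 2.3, 2.5),
        },
    )


PRESETS = {"ec_like": _ec_like, "yc_like": _yc_like}

# between-participant spread applied around a preset: SD of the RT shift
# (s), of the lognormal location (log-s), and of the rating baselines
# (scale units).  Navigation parameters are left untouched.
RT_SHIFT_SD = 0.05
RT_MU_SD = 0.20
RATING_BASELINE_SD = 0.8


def individualize(agent: AgentSpec, rng: np.random.Generator) -> AgentSpec:
    """Return a participant-level copy of ``agent`` with individual
    differences: jittered reaction-time parameters and rating baselines.
    Identical agents would otherwise differ only through sampling noise,
    which understates the between-subject variance of real groups."""
    rt = agent.rt_model
    if rt.family == "shifted_lognormal":
        rt = replace(
            rt,
            shift=max(0.05, rt.shift + float(rng.normal(0.0, RT_SHIFT_SD))),
            mu=rt.mu + float(rng.normal(0.0, RT_MU_SD)),
        )
    ratings = {
        item: replace(
            model,
            baseline=float(
                np.clip(model.baseline + rng.normal(0.0, RATING_BASELINE_SD), 1.0, 7.0)
            ),
        )
        for item, model in agent.rating_model.items()
    }
    return replace(agent, rt_model=rt, rating_model=ratings)


def get_preset(name: str) -> AgentSpec:
    """Return a fresh copy of a named preset (``ec_like`` or ``yc_like``)."""
    try:
        return PRESETS[name]()
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
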