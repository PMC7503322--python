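"""Study configuration and deterministic schedule construction.

A :class:`StudyConfig` captures every timing/structure parameter of one
variant of the stress-induction paradigm (trial counts, cue timing, the
maximum-duration decrement schedule, rating-probe spacing) together with the
geometry of the grid-based escape behaviour test.  Two variants ship as
defaults:

* study 1 — 40 trials, a single cue, shock + noise stressor capped at 15 s,
  ratings after every 10th trial, a 1-block escape test (10 s explore,
  20 s stress cap);
* study 2 — 60 trials, three cues with a hidden cue-button mapping, noise-only
  stressor starting at 10 s and decreasing by 0.5 s after every 15th trial,
  ratings after every 15th trial, a 2-block escape test (5 s phases, position
  reset between phases, safe spaces relocated for block 2).

Time is continuous seconds (event-driven); trial indices are 1-based, which
matches the "after every 10th/15th trial" phrasing used throughout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfigError",
    "GridConfig",
    "StudyConfig",
    "TrialTemplate",
    "RatingProbe",
    "build_study_config",
    "max_stress_duration",
    "build_trial_timeline",
    "rating_probe_indices",
]

CONDITIONS = ("EC", "YC", "CC")


class ConfigError(ValueError):
    """Raised when a configuration violates a structural invariant."""


@dataclass(frozen=True)
class GridConfig:
    """Geometry and timing of the escape behaviour test."""

    size: int = 15
    n_safe: int = 4
    n_blocks: int = 1
    n_trials_per_block: int = 5
    explore_duration: float = 10.0
    stress_cap: float = 20.0
    reset_between_phases: bool = False
    relocate_safes_between_blocks: bool = False

    def validate(self) -> None:
        if self.size < 2:
            raise ConfigError("grid.size must be at least 2")
        if not (0 < self.n_safe < self.size**2):
            raise ConfigError("grid.n_safe must be in (0, size^2)")
        if self.n_blocks < 1 or self.n_trials_per_block < 1:
            raise ConfigError("grid.n_blocks and grid.n_trials_per_block must be >= 1")
        if self.explore_duration <= 0 or self.stress_cap <= 0:
            raise ConfigError("grid phase durations must be positive")


@dataclass(frozen=True)
class StudyConfig:
    """All parameters of one study variant of the paradigm."""

    study_id: int
    n_trials: int
    cue_set: tuple[str, ...]
    pre_cue_duration: float
    response_window: float
    max_duration_base: float
    max_duration_decrement: float
    decrement_interval: int
    iti_base: float
    iti_jitter: float
    rating_interval: int
    rating_items: tuple[str, ...]
    n_shocks_per_precue: int
    grid: GridConfig

    def validate(self) -> None:
        if self.study_id not in (1, 2):
            raise ConfigError("study_id must be 1 or 2")
        if self.n_trials < 1:
            raise ConfigError("n_trials must be positive")
        if not self.cue_set:
            raise ConfigError("cue_set must not be empty")
        if self.n_trials % len(self.cue_set) != 0:
            raise ConfigError(
                f"n_trials={self.n_trials} not divisible by number of cues "
                f"({len(self.cue_set)})"
            )
        for name in ("pre_cue_duration", "response_window", "max_duration_base", "iti_base"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.iti_jitter < 0 or self.iti_jitter > self.iti_base:
            raise ConfigError("iti_jitter must be in [0, iti_base]")
        if self.max_duration_decrement < 0:
            raise ConfigError("max_duration_decrement must be >= 0")
        if self.max_duration_decrement > 0 and self.decrement_interval < 1:
            raise ConfigError("decrement_interval must be >= 1 when a decrement is set")
        if self.rating_interval < 1 or self.n_trials % self.rating_interval != 0:
            raise ConfigError(
                f"rating_interval={self.rating_interval} must divide n_trials={self.n_trials}"
            )
        if self.n_shocks_per_precue < 0:
            raise ConfigError("n_shocks_per_precue must be >= 0")
        # the response window must fit inside the (smallest) maximum stress
        # duration: a cue that cannot be answered before the cap is malformed
        last_max = _max_duration(self, self.n_trials)
        if self.pre_cue_duration + self.response_window > last_max:
            raise ConfigError(
                "pre_cue_duration + response_window exceeds the maximum stress "
                f"duration on the final trial ({last_max} s)"
            )
        self.grid.validate()


_STUDY1_DEFAULTS = dict(
    study_id=1,
    n_trials=40,
    cue_set=("cue",),
    pre_cue_duration=6.0,
    response_window=1.0,
    max_duration_base=15.0,
    max_duration_decrement=0.0,
    decrement_interval=0,
    iti_base=1.0,
    iti_jitter=0.25,
    rating_interval=10,
    rating_items=("aversiveness", "control", "exhaustion", "frustration", "helplessness"),
    n_shocks_per_precue=4,
    grid=GridConfig(
        size=15,
        n_safe=4,
        n_blocks=1,
        n_trials_per_block=5,
        explore_duration=10.0,
        stress_cap=20.0,
        reset_between_phases=False,
        relocate_safes_between_blocks=False,
    ),
)

# The three-cue variant inherits the pre-cue duration and ITI of the original
# design; only its stressor cap, decrement schedule, probe spacing, and the
# escape-test block structure differ.
_STUDY2_DEFAULTS = dict(
    study_id=2,
    n_trials=60,
    cue_set=("circle", "triangle", "square"),
    pre_cue_duration=6.0,
    response_window=1.0,
    max_duration_base=10.0,
    max_duration_decrement=0.5,
    decrement_interval=15,
    iti_base=1.0,
    iti_jitter=0.25,
    rating_interval=15,
    rating_items=("aversiveness", "control", "exhaustion", "helplessness"),
    n_shocks_per_precue=0,
    grid=GridConfig(
        size=15,
        n_safe=4,
        n_blocks=2,
        n_trials_per_block=5,
        explore_duration=5.0,
        stress_cap=5.0,
        reset_between_phases=True,
        relocate_safes_between_blocks=True,
    ),
)


def build_study_config(study_id: int, overrides: dict | None = None) -> StudyConfig:
    """Return a validated :class:`StudyConfig` for a study variant.

    Parameters
    ----------
    study_id
        1 or 2; selects the default parameter set.
    overrides
        Optional mapping of field names to replacement values.  Grid fields
        are addressed with a ``grid.`` prefix, e.g. ``{"grid.n_blocks": 1}``.

    Raises
    ------
    ConfigError
        On an unknown field name or any invariant violation; the message
        names the offending field.
    """
    if study_id == 1:
        base = dict(_STUDY1_DEFAULTS)
    elif study_id == 2:
        base = dict(_STUDY2_DEFAULTS)
    else:
        raise ConfigError(f"study_id must be 1 or 2, got {study_id!r}")

    overrides = dict(overrides or {})
    grid_overrides = {}
    for key in list(overrides):
        if key.startswith("grid."):
            grid_overrides[key[len("grid."):]] = overrides.pop(key)

    known = {f.name for f in dataclasses.fields(StudyConfig)}
    for key, value in overrides.items():
        if key not in known:
            raise ConfigError(f"unknown StudyConfig field: {key!r}")
        if key in ("cue_set", "rating_items"):
            value = tuple(value)
        base[key] = value

    if grid_overrides:
        grid_known = {f.name for f in dataclasses.fields(GridConfig)}
        for key in grid_overrides:
            if key not in grid_known:
                raise ConfigError(f"unknown GridConfig field: grid.{key!r}")
        base["grid"] = dataclasses.replace(base["grid"], **grid_overrides)

    config = StudyConfig(**base)
    config.validate()
    return config


def _max_duration(config: StudyConfig, trial_index: int) -> float:
    if config.max_duration_decrement == 0:
        return config.max_duration_base
    steps = (trial_index - 1) // config.decrement_interval
    return config.max_duration_base - config.max_duration_decrement * steps


def max_stress_duration(config: StudyConfig, trial_index: int) -> float:
    """Maximum stress duration (s) on a given 1-based trial.

    The cap decreases by ``max_duration_decrement`` after every
    ``decrement_interval``-th trial (constant when the decrement is zero), so
    in the three-cue variant trials 1-15 cap at 10.0 s, 16-30 at 9.5 s,
    31-45 at 9.0 s, and 46-60 at 8.5 s.
    """
    if not 1 <= trial_index <= config.n_trials:
        raise IndexError(
            f"trial_index {trial_index} out of range 1..{config.n_trials}"
        )
    return _max_duration(config, trial_index)


@dataclass(frozen=True)
class TrialTemplate:
    """Static description of one stress-induction trial."""

    trial_index: int  # 1-based
    cue_id: str
    nominal_cue_onset: float  # seconds from trial start
    max_duration: float
    iti: float


@dataclass(frozen=True)
class RatingProbe:
    """One Likert answer (1-7) to one item after a probe trial."""

    after_trial: int
    item: str
    value: int

    def __post_init__(self) -> None:
        if not 1 <= self.value <= 7:
            raise ValueError(f"rating value must be in 1..7, got {self.value}")


def build_trial_timeline(config: StudyConfig, seed: int) -> list[TrialTemplate]:
    """Build the seeded trial timeline for one session.

    Each cue appears exactly ``n_trials / len(cue_set)`` times, in a seeded
    random order; ITIs are drawn uniformly from
    ``iti_base +/- iti_jitter``; per-trial maximum durations follow the
    decrement schedule.  Pure function of ``(config, seed)``.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    per_cue = config.n_trials // len(config.cue_set)
    cues = np.repeat(np.array(config.cue_set, dtype=object), per_cue)
    cues = rng.permutation(cues)
    itis = rng.uniform(
        config.iti_base - config.iti_jitter,
        config.iti_base + config.iti_jitter,
        size=config.n_trials,
    )
    return [
        TrialTemplate(
            trial_index=i + 1,
            cue_id=str(cues[i]),
            nominal_cue_onset=config.pre_cue_duration,
            max_duration=_max_duration(config, i + 1),
            iti=float(itis[i]),
        )
        for i in range(config.n_trials)
    ]


def rating_probe_indices(config: StudyConfig) -> list[int]:
    """Trials after which ratings are collected (multiples of the interval)."""
    config.validate()
    return list(range(config.rating_interval, config.n_trials + 1, config.rating_interval))
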