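"""Seeded session/trial generators and the discrete-event trial state machine.

Three task families are modeled:

* ``thr`` — Touch-Hold-Release shaping with a difficulty ladder,
* ``search_init`` / ``search_test`` — visual search with 0/3/6/9/12 distractors,
* ``learning`` — feature-reward learning in blocks with a switching rewarded
  feature.

Time is simulated: reaction times are whatever the agent reports, truncated
at the response window.  All generation is driven by a ``numpy`` Generator,
so identical ``(config, seed)`` pairs produce identical plans and runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Protocol, Sequence

import numpy as np

from .stimulus_space import (
    Descriptor,
    FeasibilityError,
    FeatureSpace,
    neutral_dimension_count,
    sample_learning_array,
    sample_search_array,
    sample_target,
)

__all__ = [
    "OUTCOMES",
    "TrialTiming",
    "TrialSpec",
    "TrialResult",
    "BlockDef",
    "SessionPlan",
    "GridConfig",
    "SearchConfig",
    "LearningConfig",
    "ThrLevel",
    "ThrLadderConfig",
    "ThrState",
    "TaskConfigError",
    "grid_intersections",
    "place_on_grid",
    "generate_search_session",
    "generate_block_defs",
    "generate_learning_session",
    "run_trial",
    "run_session",
    "thr_next_level",
    "default_thr_ladder",
    "classify_touch",
]

OUTCOMES = ("correct", "incorrect", "abort_neutral", "timeout", "broken_hold")

TOUCH_CLASSES = (
    "valid", "tap_too_short", "hold_too_long", "late_release", "swipe", "off_target",
)


class TaskConfigError(ValueError):
    """Invalid task configuration."""


@dataclass(frozen=True)
class TrialTiming:
    """Trial timing constants (seconds)."""

    initiation_hold_s: float = 0.2
    delay_s: float = 0.4  # drawn per trial from delay_range at generation time
    response_window_s: float = 5.0
    choice_hold_s: float = 0.2


@dataclass(frozen=True)
class TrialSpec:
    """What is shown on one trial.

    ``stimuli`` pairs each descriptor with a screen position in inches
    (origin at display center).  For search trials ``target_index`` points
    into ``stimuli``; for learning trials ``rewarded_feature`` is the
    ``(dimension, value)`` pair that earns reward.
    """

    task_kind: str  # thr | search_init | search_test | learning
    block_id: int
    trial_index: int  # 1-based within the session
    stimuli: tuple[tuple[Descriptor, tuple[float, float]], ...]
    timing: TrialTiming = TrialTiming()
    target_index: int | None = None
    rewarded_feature: tuple[str, str] | None = None
    set_size: int | None = None
    varied_dims: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        positions = [pos for _, pos in self.stimuli]
        if len(set(positions)) != len(positions):
            raise TaskConfigError("stimulus positions must be unique")
        if self.target_index is not None and not (
            0 <= self.target_index < len(self.stimuli)
        ):
            raise TaskConfigError("target_index out of range")

    @property
    def n_stimuli(self) -> int:
        return len(self.stimuli)


@dataclass(frozen=True)
class TrialResult:
    """What the subject did on one trial."""

    outcome: str
    chosen_index: int | None
    reaction_time_s: float
    rewarded: bool
    delay_s: float
    seed_path: str = ""

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.rewarded and self.outcome != "correct":
            raise ValueError("rewarded implies a correct outcome")


@dataclass(frozen=True)
class BlockDef:
    """Block-level reward contingency for the learning task."""

    rewarded_dim: str
    rewarded_value: str
    n_trials: int
    varied_dims: tuple[str, ...]

    @property
    def rewarded_feature(self) -> tuple[str, str]:
        return (self.rewarded_dim, self.rewarded_value)


@dataclass
class SessionPlan:
    """Ordered trials plus the metadata needed to reproduce them."""

    task_kind: str  # "search" | "learning"
    trials: list[TrialSpec]
    blocks: list[BlockDef] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Screen geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridConfig:
    """Virtual grid of stimulus positions on a 19.5-inch (diagonal) display.

    Default: 5 columns x 3 rows of intersections within the screen minus a
    1-inch margin, centered on the display origin.
    """

    n_cols: int = 5
    n_rows: int = 3
    width_in: float = 17.0
    height_in: float = 9.6
    margin_in: float = 1.0

    def __post_init__(self) -> None:
        if self.n_cols < 1 or self.n_rows < 1:
            raise TaskConfigError("grid needs at least one row and column")
        if self.width_in - 2 * self.margin_in <= 0 or self.height_in - 2 * self.margin_in <= 0:
            raise TaskConfigError("margin leaves no usable screen area")


def grid_intersections(config: GridConfig) -> list[tuple[float, float]]:
    """All grid intersections (inches from display center), row-major."""
    usable_w = config.width_in - 2 * config.margin_in
    usable_h = config.height_in - 2 * config.margin_in
    xs = (
        [0.0]
        if config.n_cols == 1
        else [usable_w * (i / (config.n_cols - 1) - 0.5) for i in range(config.n_cols)]
    )
    ys = (
        [0.0]
        if config.n_rows == 1
        else [usable_h * (j / (config.n_rows - 1) - 0.5) for j in range(config.n_rows)]
    )
    return [(round(x, 10), round(y, 10)) for y in ys for x in xs]


def place_on_grid(
    n_items: int,
    grid_config: GridConfig,
    rng: np.random.Generator,
    mode: str = "grid",
    ring_radius_in: float = 4.1,
    ring_slots: int = 8,
) -> list[tuple[float, float]]:
    """Sample ``n_items`` distinct positions.

    ``mode="grid"`` draws without replacement from the virtual grid
    intersections.  ``mode="ring"`` (learning task) draws from equally
    spaced slots on a circle of the configured eccentricity (default
    4.1 inches from the display center).
    """
    if mode == "grid":
        points = grid_intersections(grid_config)
    elif mode == "ring":
        points = [
            (
                round(ring_radius_in * math.cos(2 * math.pi * k / ring_slots), 10),
                round(ring_radius_in * math.sin(2 * math.pi * k / ring_slots), 10),
            )
            for k in range(ring_slots)
        ]
    else:
        raise TaskConfigError(f"unknown placement mode {mode!r}")
    if n_items > len(points):
        raise TaskConfigError(
            f"cannot place {n_items} items on {len(points)} available positions"
        )
    idx = rng.choice(len(points), size=n_items, replace=False)
    return [points[i] for i in idx]


# ---------------------------------------------------------------------------
# Session generation: visual search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SearchConfig:
    """Configuration for a visual-search session.

    Default: 2 runs, each 10 initialization trials (target alone) followed
    by 100 test trials with set sizes drawn from {3, 6, 9, 12}.
    """

    n_runs: int = 2
    n_init_trials: int = 10
    n_test_trials: int = 100
    set_sizes: tuple[int, ...] = (3, 6, 9, 12)
    set_size_policy: str = "stratified"  # or "iid"
    n_shared: int = 1  # feature values each distractor shares with the target
    target_k_nonneutral: int = 3
    target_forced_neutral: tuple[str, ...] = ("body_shape",)
    delay_range_s: tuple[float, float] = (0.3, 0.5)
    grid: GridConfig = GridConfig()

    def __post_init__(self) -> None:
        allowed = {0, 3, 6, 9, 12}
        if not set(self.set_sizes) <= allowed:
            raise TaskConfigError(f"set sizes must be within {sorted(allowed)}")
        if not self.set_sizes:
            raise TaskConfigError("set-size menu is empty")
        if self.n_runs < 1:
            raise TaskConfigError("n_runs must be >= 1")
        if self.set_size_policy not in ("stratified", "iid"):
            raise TaskConfigError(f"unknown set-size policy {self.set_size_policy!r}")
        lo, hi = self.delay_range_s
        if not 0 <= lo <= hi:
            raise TaskConfigError("invalid delay range")


def _set_size_sequence(config: SearchConfig, rng: np.random.Generator) -> list[int]:
    menu = list(config.set_sizes)
    n = config.n_test_trials
    if config.set_size_policy == "iid":
        return [menu[i] for i in rng.integers(len(menu), size=n)]
    # stratified: as-equal-as-possible counts, remainder assigned at random
    base, rem = divmod(n, len(menu))
    seq = []
    for m in menu:
        seq.extend([m] * base)
    if rem:
        extra = rng.choice(len(menu), size=rem, replace=False)
        seq.extend(menu[i] for i in extra)
    rng.shuffle(seq)
    return seq


def _draw_timing(config_range: tuple[float, float], rng: np.random.Generator) -> TrialTiming:
    delay = float(rng.uniform(*config_range))
    return TrialTiming(delay_s=delay)


def generate_search_session(
    space: FeatureSpace, config: SearchConfig, rng: np.random.Generator
) -> SessionPlan:
    """Generate a search session: per run, one fixed target shown alone on the
    initialization trials and embedded among distractors on the test trials."""
    trials: list[TrialSpec] = []
    trial_index = 0
    for run in range(config.n_runs):
        target = sample_target(
            space,
            k_nonneutral=config.target_k_nonneutral,
            forced_neutral_dims=config.target_forced_neutral,
            rng=rng,
        )
        for _ in range(config.n_init_trials):
            trial_index += 1
            pos = place_on_grid(1, config.grid, rng)
            trials.append(
                TrialSpec(
                    task_kind="search_init",
                    block_id=run,
                    trial_index=trial_index,
                    stimuli=((target, pos[0]),),
                    target_index=0,
                    set_size=0,
                    timing=_draw_timing(config.delay_range_s, rng),
                )
            )
        for set_size in _set_size_sequence(config, rng):
            trial_index += 1
            if set_size > 0:
                distractors = sample_search_array(
                    space, target, set_size, config.n_shared, rng
                )
            else:
                distractors = []
            stims: list[Descriptor] = [target] + distractors
            order = rng.permutation(len(stims))
            positions = place_on_grid(len(stims), config.grid, rng)
            arranged = tuple((stims[i], positions[j]) for j, i in enumerate(order))
            target_index = int(np.argwhere(order == 0)[0][0])
            trials.append(
                TrialSpec(
                    task_kind="search_test",
                    block_id=run,
                    trial_index=trial_index,
                    stimuli=arranged,
                    target_index=target_index,
                    set_size=set_size,
                    timing=_draw_timing(config.delay_range_s, rng),
                )
            )
    return SessionPlan(
        task_kind="search",
        trials=trials,
        metadata={"n_runs": config.n_runs, "config": config},
    )


# ---------------------------------------------------------------------------
# Session generation: feature-reward learning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LearningConfig:
    """Configuration for a feature-reward learning session.

    Default: 40 blocks of 45-60 trials, 3 objects per trial placed on a
    4.1-inch eccentricity ring, one varied feature dimension per block.
    """

    n_blocks: int = 40
    block_len_range: tuple[int, int] = (45, 60)
    n_objects: int = 3
    n_varied_dims: int | str = 1  # 1..3 or "random"
    eligible_dims: tuple[str, ...] | None = None  # None = all dimensions
    ring_radius_in: float = 4.1
    ring_slots: int = 8
    delay_range_s: tuple[float, float] = (0.3, 0.5)
    grid: GridConfig = GridConfig()

    def __post_init__(self) -> None:
        lo, hi = self.block_len_range
        if not (1 <= lo <= hi):
            raise TaskConfigError(f"invalid block length range {self.block_len_range}")
        if self.n_blocks < 1:
            raise TaskConfigError("n_blocks must be >= 1")
        if isinstance(self.n_varied_dims, str):
            if self.n_varied_dims != "random":
                raise TaskConfigError("n_varied_dims must be an integer or 'random'")
        elif not 1 <= self.n_varied_dims:
            raise TaskConfigError("n_varied_dims must be >= 1")


def generate_block_defs(
    space: FeatureSpace, config: LearningConfig, rng: np.random.Generator
) -> list[BlockDef]:
    """Draw the block sequence: rewarded dimension uniform over eligible
    dimensions, rewarded value uniform over that dimension's non-neutral
    values, never repeating the immediately preceding (dimension, value)."""
    eligible = (
        list(config.eligible_dims) if config.eligible_dims else list(space.names)
    )
    for name in eligible:
        space.index(name)
    n_candidates = sum(len(space.dimension(d).non_neutral_values) for d in eligible)
    if n_candidates < 2:
        raise TaskConfigError(
            "need at least two candidate rewarded features to switch between blocks"
        )
    lo, hi = config.block_len_range
    blocks: list[BlockDef] = []
    prev: tuple[str, str] | None = None
    for _ in range(config.n_blocks):
        while True:
            dim = eligible[rng.integers(len(eligible))]
            pool = space.dimension(dim).non_neutral_values
            value = pool[rng.integers(len(pool))]
            if (dim, value) != prev:
                break
        if config.n_varied_dims == "random":
            k = int(rng.integers(1, min(3, space.n_dimensions) + 1))
        else:
            k = int(config.n_varied_dims)
        if k > space.n_dimensions:
            raise TaskConfigError("n_varied_dims exceeds the number of dimensions")
        others = [d for d in space.names if d != dim]
        extra = rng.choice(len(others), size=k - 1, replace=False) if k > 1 else []
        varied = tuple([dim] + [others[i] for i in extra])
        n_trials = int(rng.integers(lo, hi + 1))
        blocks.append(
            BlockDef(
                rewarded_dim=dim,
                rewarded_value=value,
                n_trials=n_trials,
                varied_dims=varied,
            )
        )
        prev = (dim, value)
    return blocks


def generate_learning_session(
    space: FeatureSpace, config: LearningConfig, rng: np.random.Generator
) -> SessionPlan:
    """Generate a learning session: blocks from :func:`generate_block_defs`,
    each trial an array from the stimulus sampler with exactly one object
    carrying the block's rewarded feature."""
    blocks = generate_block_defs(space, config, rng)
    trials: list[TrialSpec] = []
    trial_index = 0
    for block_id, block in enumerate(blocks):
        for _ in range(block.n_trials):
            trial_index += 1
            objects = sample_learning_array(
                space,
                block.rewarded_dim,
                block.rewarded_value,
                config.n_objects,
                block.varied_dims,
                rng,
            )
            positions = place_on_grid(
                config.n_objects,
                config.grid,
                rng,
                mode="ring",
                ring_radius_in=config.ring_radius_in,
                ring_slots=config.ring_slots,
            )
            trials.append(
                TrialSpec(
                    task_kind="learning",
                    block_id=block_id,
                    trial_index=trial_index,
                    stimuli=tuple(zip(objects, positions)),
                    rewarded_feature=block.rewarded_feature,
                    varied_dims=block.varied_dims,
                    timing=_draw_timing(config.delay_range_s, rng),
                )
            )
    return SessionPlan(
        task_kind="learning",
        trials=trials,
        blocks=blocks,
        metadata={"config": config},
    )


# ---------------------------------------------------------------------------
# Trial state machine
# ---------------------------------------------------------------------------

class Agent(Protocol):
    def respond(
        self, spec: TrialSpec, rng: np.random.Generator
    ) -> tuple[int | None, float]: ...


def _carries_feature(
    descriptor: Descriptor, feature: tuple[str, str], space: FeatureSpace
) -> bool:
    dim, value = feature
    return descriptor[space.index(dim)] == value


def run_trial(
    spec: TrialSpec,
    agent: Agent,
    rng: np.random.Generator,
    space: FeatureSpace,
    abort_on_neutral: bool = True,
    seed_path: str = "",
) -> TrialResult:
    """Execute one trial: query the agent, classify the outcome.

    Outcome order of precedence: timeout (no choice, or reported RT past the
    response window), abort on a fully neutral object, correct (target /
    rewarded feature), else incorrect.  Reward is delivered iff correct.
    """
    chosen, rt = agent.respond(spec, rng)
    window = spec.timing.response_window_s
    if chosen is None or rt > window:
        return TrialResult(
            outcome="timeout",
            chosen_index=None,
            reaction_time_s=window,
            rewarded=False,
            delay_s=spec.timing.delay_s,
            seed_path=seed_path,
        )
    if not isinstance(chosen, (int, np.integer)) or not 0 <= chosen < spec.n_stimuli:
        raise ValueError(f"agent chose index {chosen!r}, out of range")
    if rt < 0:
        raise ValueError(f"agent reported negative reaction time {rt}")
    chosen = int(chosen)
    descriptor = spec.stimuli[chosen][0]
    _, fully_neutral = neutral_dimension_count(descriptor, space)
    if abort_on_neutral and fully_neutral:
        outcome = "abort_neutral"
        correct = False
    elif spec.target_index is not None:
        correct = chosen == spec.target_index
        outcome = "correct" if correct else "incorrect"
    elif spec.rewarded_feature is not None:
        correct = _carries_feature(descriptor, spec.rewarded_feature, space)
        outcome = "correct" if correct else "incorrect"
    else:
        raise TaskConfigError("trial has neither a target nor a rewarded feature")
    return TrialResult(
        outcome=outcome,
        chosen_index=chosen,
        reaction_time_s=float(rt),
        rewarded=correct,
        delay_s=spec.timing.delay_s,
        seed_path=seed_path,
    )


def run_session(
    plan: SessionPlan,
    agent: Agent,
    rng: np.random.Generator,
    sink: Callable[[TrialSpec, TrialResult], None] | None = None,
    space: FeatureSpace | None = None,
    abort_on_neutral: bool = True,
) -> list[TrialResult]:
    """Run every trial in order, flushing each result to ``sink`` immediately
    after the trial completes (incremental persistence: interrupting after
    trial k leaves exactly k complete records).

    Agents with an ``update(spec, result)`` method have their state threaded
    through the session.
    """
    if space is None:
        space = getattr(agent, "space", None)
    if space is None:
        raise TaskConfigError("a feature space is required (pass space=...)")
    results: list[TrialResult] = []
    update = getattr(agent, "update", None)
    for spec in plan.trials:
        result = run_trial(spec, agent, rng, space, abort_on_neutral=abort_on_neutral)
        if update is not None:
            update(spec, result)
        if sink is not None:
            sink(spec, result)
        results.append(result)
    return results


# ---------------------------------------------------------------------------
# Touch-Hold-Release ladder
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThrLevel:
    square_size_in: float
    hold_min_ms: float = 200.0
    hold_max_ms: float = 300.0
    release_max_ms: float = 500.0
    randomize_position: bool = True


@dataclass(frozen=True)
class ThrLadderConfig:
    levels: tuple[ThrLevel, ...]
    window: int = 10
    promote_threshold: float = 0.8
    demote_threshold: float = 0.4

    def __post_init__(self) -> None:
        if not self.levels:
            raise TaskConfigError("THR ladder has no levels")
        sizes = [lvl.square_size_in for lvl in self.levels]
        if any(later > earlier for earlier, later in zip(sizes, sizes[1:])):
            raise TaskConfigError("square size must be non-increasing with level")
        if self.window < 1:
            raise TaskConfigError("window must be >= 1")


def default_thr_ladder() -> ThrLadderConfig:
    sizes = (4.0, 3.0, 2.0, 1.5, 1.0)
    return ThrLadderConfig(levels=tuple(ThrLevel(square_size_in=s) for s in sizes))


@dataclass(frozen=True)
class ThrState:
    level: int = 0
    touch_ready: bool = False

    def __post_init__(self) -> None:
        if self.level < 0:
            raise ValueError("level must be >= 0")

    def current_level(self, config: ThrLadderConfig) -> ThrLevel:
        return config.levels[self.level]


def thr_next_level(
    state: ThrState, recent_outcomes: Sequence[int], config: ThrLadderConfig
) -> ThrState:
    """One ladder update from the rolling outcome window.

    Promote (one level) when rolling accuracy over the window reaches the
    promote threshold, demote when below the demote threshold; the level is
    clamped to [0, top].  ``touch_ready`` is set while holding the top level
    at promote-threshold accuracy.
    """
    top = len(config.levels) - 1
    if len(recent_outcomes) < config.window:
        return state
    acc = float(np.mean(np.asarray(recent_outcomes[-config.window :], dtype=float)))
    level = state.level
    if acc >= config.promote_threshold:
        level = min(level + 1, top)
    elif acc < config.demote_threshold:
        level = max(level - 1, 0)
    touch_ready = state.level == top and acc >= config.promote_threshold
    return ThrState(level=level, touch_ready=touch_ready)


# ---------------------------------------------------------------------------
# Touch classification
# ---------------------------------------------------------------------------

def classify_touch(
    touch_trace: Sequence[tuple[float, float, float, str]],
    object_bounds: tuple[float, float, float, float],
    hold_min_ms: float = 200.0,
    hold_max_ms: float = 300.0,
    release_max_ms: float = 500.0,
    swipe_tolerance_in: float = 0.25,
) -> str:
    """Classify a touch trace against the hold/release windows.

    ``touch_trace`` is a time-ordered list of ``(t_ms, x, y, event)`` with
    ``event`` in {"down", "move", "up"}.  ``object_bounds`` is
    ``(xmin, ymin, xmax, ymax)`` in inches.

    Returns one of ``valid``, ``tap_too_short``, ``hold_too_long``,
    ``late_release``, ``swipe``, ``off_target``.  A swipe is a contact path
    that leaves the bounds by more than the tolerance before release.
    """
    if not touch_trace:
        raise ValueError("empty touch trace")
    times = [e[0] for e in touch_trace]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("touch trace timestamps are not ordered")
    xmin, ymin, xmax, ymax = object_bounds

    def inside(x: float, y: float, tol: float = 0.0) -> bool:
        return (xmin - tol) <= x <= (xmax + tol) and (ymin - tol) <= y <= (ymax + tol)

    down = next((e for e in touch_trace if e[3] == "down"), None)
    if down is None:
        raise ValueError("touch trace has no 'down' event")
    if not inside(down[1], down[2]):
        return "off_target"
    up = next((e for e in touch_trace if e[3] == "up" and e[0] >= down[0]), None)
    contact = [e for e in touch_trace if down[0] <= e[0] <= (up[0] if up else math.inf)]
    if any(not inside(x, y, swipe_tolerance_in) for _, x, y, _ in contact):
        return "swipe"
    if up is None:
        return "late_release"
    duration = up[0] - down[0]
    if duration < hold_min_ms:
        return "tap_too_short"
    if duration <= hold_max_ms:
        return "valid"
    if duration <= release_max_ms:
        return "hold_too_long"
    return "late_release"
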