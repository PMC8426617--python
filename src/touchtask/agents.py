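"""Synthetic subjects that generate behavior with the statistical structure
the analyses assume.

Two families:

* :class:`RTAgent` — a search responder whose reaction times rise linearly
  with the number of distractors (RT = b0 + b1 * set_size + noise) and whose
  choices hit the target with a fixed probability.
* :class:`FeatureRLAgent` — a delta-rule feature learner with softmax choice,
  producing within-block learning curves that rise from chance to a plateau.

Both expose ``respond(spec, rng)`` as required by the trial state machine;
the RL agent additionally exposes ``update(spec, result)``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml

from .stimulus_space import Descriptor, FeatureSpace
from .task_engine import TrialSpec, TrialResult

__all__ = [
    "RTAgentParams",
    "FeatureRLParams",
    "AgentState",
    "RTAgent",
    "FeatureRLAgent",
    "OmniscientAgent",
    "rt_agent_respond",
    "rl_agent_respond",
    "rl_agent_update",
    "load_presets",
    "agent_from_preset",
]


@dataclass(frozen=True)
class RTAgentParams:
    """Parameters of the linear-RT search responder."""

    p_correct: float = 0.9
    b0: float = 0.9        # base RT, seconds
    b1: float = 0.06       # RT increment per distractor, seconds
    sigma: float = 0.15    # RT noise SD, seconds
    lapse_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_correct <= 1.0:
            raise ValueError("p_correct must be in [0, 1]")
        if not 0.0 <= self.lapse_rate <= 1.0:
            raise ValueError("lapse_rate must be in [0, 1]")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.b0 <= 0:
            raise ValueError("b0 must be > 0")


def rt_agent_respond(
    spec: TrialSpec, params: RTAgentParams, rng: np.random.Generator
) -> tuple[int | None, float]:
    """One response from the linear-RT agent.

    With probability ``lapse_rate`` no response is made (timeout).  Otherwise
    the target is chosen with probability ``p_correct``, else a uniform
    distractor; RT = b0 + b1 * set_size + Normal(0, sigma), truncated to
    (choice_hold_s, response_window_s].
    """
    if spec.target_index is None:
        raise ValueError("RT agent requires a search trial with a target")
    if params.lapse_rate > 0 and rng.random() < params.lapse_rate:
        return None, spec.timing.response_window_s
    set_size = spec.set_size if spec.set_size is not None else spec.n_stimuli - 1
    rt = params.b0 + params.b1 * set_size
    if params.sigma > 0:
        rt += rng.normal(0.0, params.sigma)
    lo = np.nextafter(spec.timing.choice_hold_s, np.inf)
    rt = float(min(max(rt, lo), spec.timing.response_window_s))
    n = spec.n_stimuli
    if n == 1 or rng.random() < params.p_correct:
        chosen = spec.target_index
    else:
        others = [i for i in range(n) if i != spec.target_index]
        chosen = others[rng.integers(len(others))]
    return chosen, rt


class RTAgent:
    """Stateless wrapper giving :func:`rt_agent_respond` the agent protocol."""

    def __init__(self, params: RTAgentParams, space: FeatureSpace | None = None):
        self.params = params
        self.space = space

    def respond(
        self, spec: TrialSpec, rng: np.random.Generator
    ) -> tuple[int | None, float]:
        return rt_agent_respond(spec, self.params, rng)


@dataclass(frozen=True)
class FeatureRLParams:
    """Parameters of the delta-rule feature learner."""

    alpha: float = 0.3   # learning rate in [0, 1]
    beta: float = 5.0    # softmax inverse temperature, >= 0
    v0: float = 0.0      # initial feature value

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")


@dataclass
class AgentState:
    """Feature-value table V(dimension, value) -> real, plus a trial counter."""

    v0: float = 0.0
    values: dict[tuple[str, str], float] = field(default_factory=dict)
    trial_count: int = 0

    def value(self, dim: str, val: str) -> float:
        return self.values.get((dim, val), self.v0)

    def set_value(self, dim: str, val: str, v: float) -> None:
        if not np.isfinite(v):
            raise ValueError("feature values must stay finite")
        self.values[(dim, val)] = v


def _object_values(
    spec: TrialSpec, state: AgentState, space: FeatureSpace
) -> np.ndarray:
    # object value = mean of V over the object's feature values
    # (mean, not sum, so the scale is invariant to the dimension count)
    vals = np.empty(spec.n_stimuli)
    for i, (descriptor, _) in enumerate(spec.stimuli):
        vals[i] = np.mean(
            [state.value(d, v) for d, v in zip(space.names, descriptor)]
        )
    return vals


def _softmax(x: np.ndarray) -> np.ndarray:
    z = x - np.max(x)
    e = np.exp(z)
    return e / e.sum()


def rl_agent_respond(
    spec: TrialSpec,
    params: FeatureRLParams,
    state: AgentState,
    space: FeatureSpace,
    rng: np.random.Generator,
) -> int:
    """Softmax choice over object values (mean of feature values per object)."""
    values = _object_values(spec, state, space)
    probs = _softmax(params.beta * values)
    return int(rng.choice(spec.n_stimuli, p=probs))


def rl_agent_update(
    state: AgentState,
    chosen: Descriptor,
    reward: float,
    params: FeatureRLParams,
    space: FeatureSpace,
) -> AgentState:
    """Delta-rule update of the chosen object's features only:
    V(f) <- V(f) + alpha * (reward - V(f))."""
    for dim, val in zip(space.names, chosen):
        v = state.value(dim, val)
        state.set_value(dim, val, v + params.alpha * (reward - v))
    state.trial_count += 1
    return state


class FeatureRLAgent:
    """Delta-rule feature learner with softmax choice.

    ``reset_between_blocks=False`` (the default) lets feature values carry
    over between blocks, producing interference when the rewarded feature
    switches.
    """

    def __init__(
        self,
        params: FeatureRLParams,
        space: FeatureSpace,
        reset_between_blocks: bool = False,
        response_time_s: float = 1.0,
    ):
        self.params = params
        self.space = space
        self.reset_between_blocks = reset_between_blocks
        self.response_time_s = response_time_s
        self.state = AgentState(v0=params.v0)
        self._last_block: int | None = None

    def respond(
        self, spec: TrialSpec, rng: np.random.Generator
    ) -> tuple[int | None, float]:
        if self.reset_between_blocks and spec.block_id != self._last_block:
            self.state = AgentState(v0=self.params.v0)
        self._last_block = spec.block_id
        idx = rl_agent_respond(spec, self.params, self.state, self.space, rng)
        return idx, self.response_time_s

    def update(self, spec: TrialSpec, result: TrialResult) -> None:
        if result.chosen_index is None:
            return
        chosen = spec.stimuli[result.chosen_index][0]
        rl_agent_update(
            self.state, chosen, 1.0 if result.rewarded else 0.0, self.params, self.space
        )


class OmniscientAgent:
    """Always picks the target / rewarded object. Oracle fixture for tests."""

    def __init__(self, space: FeatureSpace, response_time_s: float = 1.0):
        self.space = space
        self.response_time_s = response_time_s

    def respond(
        self, spec: TrialSpec, rng: np.random.Generator
    ) -> tuple[int | None, float]:
        if spec.target_index is not None:
            return spec.target_index, self.response_time_s
        dim, value = spec.rewarded_feature  # type: ignore[misc]
        i = self.space.index(dim)
        for j, (descriptor, _) in enumerate(spec.stimuli):
            if descriptor[i] == value:
                return j, self.response_time_s
        raise ValueError("no stimulus carries the rewarded feature")


def load_presets() -> dict:
    """Load the shipped agent presets (parameter sets labelled M1-M4,
    tuned to produce realistic slopes and learning speeds; presets, not
    claims about any real subject)."""
    text = (
        importlib.resources.files("touchtask").joinpath("presets.yaml").read_text()
    )
    return yaml.safe_load(text)


def agent_from_preset(name: str, space: FeatureSpace):
    """Instantiate an agent from a named preset ('M1'..'M4' for search RT
    agents, 'L1'..'L4' for learning agents)."""
    presets = load_presets()
    if name in presets.get("rt_agents", {}):
        return RTAgent(RTAgentParams(**presets["rt_agents"][name]), space=space)
    if name in presets.get("rl_agents", {}):
        return FeatureRLAgent(FeatureRLParams(**presets["rl_agents"][name]), space=space)
    raise KeyError(f"unknown agent preset {name!r}")
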