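"""Generative models of the original and reduced two-step tasks.

The two-step task is a sequential decision task: a first-step choice
between two actions (A, B) leads probabilistically to one of two
second-step states (a, b), where reward is delivered stochastically.
Action A commonly leads to state a and action B to state b; on a
minority of trials a rare transition occurs and the mapping is flipped.

Two task variants are implemented:

* **original** — common-transition probability 0.7, two actions in each
  second-step state, reward probabilities for the four second-step
  actions drifting as reflecting Gaussian random walks on [0.25, 0.75]
  with per-trial step SD 0.025.
* **reduced** — common-transition probability 0.8, a single action in
  each second-step state, reward probabilities alternating between
  0.8/0.2 and 0.2/0.8 in states a/b every 50 trials.  Variants of the
  reduced task with random-walk or fixed reward probabilities are also
  supported.

Conventions used throughout the package: first-step actions are indexed
0 (= A) and 1 (= B); second-step states 0 (= a) and 1 (= b).  The
common transition maps action i to state i.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

FIRST_STEP_ACTIONS = ("A", "B")
SECOND_STEP_STATES = ("a", "b")

#: integer codes for the reward-probability process
REWARD_PROCESSES = ("blocks", "random_walk", "fixed")


def action_index(choice) -> int:
    """Map a first-step action label ('A'/'B' or 0/1) to its index."""
    if isinstance(choice, str):
        try:
            return FIRST_STEP_ACTIONS.index(choice)
        except ValueError:
            raise ValueError(f"unknown first-step action label {choice!r}; "
                             f"expected one of {FIRST_STEP_ACTIONS}")
    choice = int(choice)
    if choice not in (0, 1):
        raise ValueError(f"first-step action index must be 0 or 1, got {choice}")
    return choice


def state_index(state) -> int:
    """Map a second-step state label ('a'/'b' or 0/1) to its index."""
    if isinstance(state, str):
        try:
            return SECOND_STEP_STATES.index(state)
        except ValueError:
            raise ValueError(f"unknown second-step state label {state!r}; "
                             f"expected one of {SECOND_STEP_STATES}")
    state = int(state)
    if state not in (0, 1):
        raise ValueError(f"second-step state index must be 0 or 1, got {state}")
    return state


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of a two-step task variant.

    Parameters
    ----------
    variant:
        'original' (two second-step actions) or 'reduced' (one).
    p_common:
        Probability of a common transition (first-step action i leads to
        second-step state i).
    reward_process:
        How true reward probabilities evolve: 'blocks' (alternating
        between ``block_probs`` and its reverse every ``block_length``
        trials), 'random_walk' (independent reflecting Gaussian walks)
        or 'fixed'.
    block_length, block_probs:
        Block regime parameters (reduced task default: 50 trials,
        0.8/0.2).
    walk_bounds, walk_sd:
        Reflecting-walk bounds and per-trial step standard deviation.
    fixed_probs:
        Reward probability of each second-step state under the 'fixed'
        regime (reduced task only).
    n_second_actions:
        2 for the original task, 1 for the reduced task.
    """

    variant: str = "reduced"
    p_common: float = 0.8
    reward_process: str = "blocks"
    block_length: int = 50
    block_probs: Tuple[float, float] = (0.8, 0.2)
    walk_bounds: Tuple[float, float] = (0.25, 0.75)
    walk_sd: float = 0.025
    fixed_probs: Tuple[float, float] = (0.8, 0.2)
    n_second_actions: int = 1

    def __post_init__(self):
        # coerce pair fields so configs deserialised from JSON compare equal
        for name in ("block_probs", "walk_bounds", "fixed_probs"):
            object.__setattr__(self, name, tuple(getattr(self, name)))
        if self.variant not in ("original", "reduced"):
            raise ValueError(f"unknown task variant {self.variant!r}")
        if self.reward_process not in REWARD_PROCESSES:
            raise ValueError(f"unknown reward process {self.reward_process!r}")
        if not 0.0 <= self.p_common <= 1.0:
            raise ValueError("p_common must lie in [0, 1]")
        for p in (*self.block_probs, *self.fixed_probs, *self.walk_bounds):
            if not 0.0 <= p <= 1.0:
                raise ValueError("all probabilities must lie in [0, 1]")
        if not self.walk_bounds[0] < self.walk_bounds[1]:
            raise ValueError("walk_bounds must satisfy lower < upper")
        if self.block_length < 1:
            raise ValueError("block_length must be >= 1")
        if self.walk_sd < 0:
            raise ValueError("walk_sd must be non-negative")
        expected_n2 = 2 if self.variant == "original" else 1
        if self.n_second_actions != expected_n2:
            raise ValueError(
                f"{self.variant} task requires n_second_actions={expected_n2}")

    # ------------------------------------------------------------------
    # Standard configurations
    # ------------------------------------------------------------------
    @classmethod
    def original(cls) -> "TaskConfig":
        """Original two-step task: p_common 0.7, four drifting reward
        probabilities on [0.25, 0.75], step SD 0.025."""
        return cls(variant="original", p_common=0.7,
                   reward_process="random_walk",
                   walk_bounds=(0.25, 0.75), walk_sd=0.025,
                   n_second_actions=2)

    @classmethod
    def reduced(cls) -> "TaskConfig":
        """Reduced task: p_common 0.8, reward probabilities 0.8/0.2
        alternating between states every 50 trials."""
        return cls(variant="reduced", p_common=0.8, reward_process="blocks",
                   block_length=50, block_probs=(0.8, 0.2),
                   n_second_actions=1)

    @classmethod
    def reduced_walk(cls, walk_sd: float = 0.1,
                     walk_bounds: Tuple[float, float] = (0.0, 1.0)) -> "TaskConfig":
        """Reduced task with reward probabilities drifting as reflecting
        Gaussian random walks on [0, 1] with step SD 0.1."""
        return cls(variant="reduced", p_common=0.8,
                   reward_process="random_walk",
                   walk_bounds=walk_bounds, walk_sd=walk_sd,
                   n_second_actions=1)

    @classmethod
    def reduced_fixed(cls, probs: Tuple[float, float] = (0.8, 0.2)) -> "TaskConfig":
        """Reduced task with static reward probabilities in states a/b."""
        return cls(variant="reduced", p_common=0.8, reward_process="fixed",
                   fixed_probs=probs, n_second_actions=1)


@dataclass
class TaskState:
    """Mutable state of the reward-probability process.

    ``reward_probs`` is a (2, 2) array indexed [second-step state,
    second-step action]; the reduced task uses only column 0.
    ``block_phase`` counts trials since the last reversal (block regime).
    """

    trial_index: int = 0
    reward_probs: np.ndarray = field(
        default_factory=lambda: np.full((2, 2), 0.5))
    block_phase: int = 0

    def copy(self) -> "TaskState":
        return TaskState(self.trial_index, self.reward_probs.copy(),
                         self.block_phase)


@dataclass(frozen=True)
class TrialEvents:
    """Observable events of a single trial, in integer coding.

    ``choice1`` and ``second_state`` are 0/1 indices (A/B, a/b);
    ``common`` is True for a common transition; ``choice2`` is the
    second-step action index (always 0 on the reduced task);
    ``outcome`` is the binary reward.
    """

    choice1: int
    common: bool
    second_state: int
    choice2: int
    outcome: int

    def __post_init__(self):
        if self.choice1 not in (0, 1) or self.second_state not in (0, 1):
            raise ValueError("choice1 and second_state must be 0 or 1")
        if self.outcome not in (0, 1):
            raise ValueError("outcome must be 0 or 1")
        # common transition maps action i to state i
        if (self.choice1 == self.second_state) != self.common:
            raise ValueError(
                "inconsistent trial events: transition type does not match "
                f"choice1={self.choice1}, second_state={self.second_state}")

    @property
    def transition(self) -> str:
        return "common" if self.common else "rare"


def init_task_state(config: TaskConfig, rng: np.random.Generator) -> TaskState:
    """Draw the initial reward probabilities for a session.

    Blocks: the identity of the first good state is drawn at random so
    sessions are exchangeable.  Random walk: each probability starts
    uniformly within the walk bounds.  Fixed: the configured values.
    """
    probs = np.full((2, 2), 0.5)
    if config.reward_process == "blocks":
        good, bad = config.block_probs
        if rng.random() < 0.5:
            probs[0, :], probs[1, :] = good, bad
        else:
            probs[0, :], probs[1, :] = bad, good
    elif config.reward_process == "random_walk":
        lo, hi = config.walk_bounds
        probs[:] = rng.uniform(lo, hi, size=(2, 2))
    else:  # fixed
        probs[0, :] = config.fixed_probs[0]
        probs[1, :] = config.fixed_probs[1]
    if config.n_second_actions == 1:
        probs[:, 1] = probs[:, 0]
    return TaskState(trial_index=0, reward_probs=probs, block_phase=0)


def sample_transition(choice1, p_common: float,
                      rng: np.random.Generator) -> Tuple[int, str]:
    """Sample the second-step state reached after a first-step choice.

    Returns ``(second_state, transition)`` where transition is 'common'
    or 'rare'.  The common transition maps action i to state i.
    """
    if not 0.0 <= p_common <= 1.0:
        raise ValueError("p_common must lie in [0, 1]")
    c = action_index(choice1)
    common = rng.random() < p_common
    second_state = c if common else 1 - c
    return second_state, ("common" if common else "rare")


def sample_outcome(task_state: TaskState, second_state, choice2,
                   rng: np.random.Generator, *,
                   n_second_actions: int = 2) -> int:
    """Bernoulli reward draw from the current true reward probability."""
    s = state_index(second_state)
    a = int(choice2)
    if not 0 <= a < n_second_actions:
        raise ValueError(
            f"second-step action {a} out of range for a task with "
            f"{n_second_actions} second-step action(s)")
    p = task_state.reward_probs[s, a]
    return int(rng.random() < p)


def reflect_into_interval(x: float, lo: float, hi: float) -> float:
    """Fold a value into [lo, hi] by repeated reflection at the bounds.

    Reflection is applied iteratively, so steps that overshoot both
    bounds are still mapped inside the interval.
    """
    if lo >= hi:
        raise ValueError("require lo < hi")
    while x < lo or x > hi:
        if x > hi:
            x = 2.0 * hi - x
        elif x < lo:
            x = 2.0 * lo - x
    return x


def advance_reward_probs(task_state: TaskState, config: TaskConfig,
                         rng: np.random.Generator) -> TaskState:
    """Advance the reward-probability process by one trial.

    Called at the end of each trial, after the outcome draw: trial t's
    outcome uses the probabilities in force at trial t.  Blocks flip
    exactly every ``block_length`` trials; each random-walk probability
    takes an independent Gaussian step reflected at the bounds; fixed
    probabilities never change.
    """
    new = task_state.copy()
    new.trial_index += 1
    if config.reward_process == "blocks":
        new.block_phase += 1
        if new.block_phase >= config.block_length:
            new.reward_probs = new.reward_probs[::-1].copy()
            new.block_phase = 0
    elif config.reward_process == "random_walk":
        lo, hi = config.walk_bounds
        n2 = config.n_second_actions
        for s in range(2):
            for a in range(n2):
                step = rng.normal(0.0, config.walk_sd)
                new.reward_probs[s, a] = reflect_into_interval(
                    new.reward_probs[s, a] + step, lo, hi)
        if n2 == 1:
            new.reward_probs[:, 1] = new.reward_probs[:, 0]
    # fixed: unchanged
    return new
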