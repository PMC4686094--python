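"""Reinforcement-learning agents for the two-step task.

Five agent families are implemented:

* ``QLambdaAgent`` — model-free Q-learning with an eligibility-trace
  parameter lambda interpolating between updating the first-step value
  directly from the trial outcome (lambda = 1) and from the value of the
  second-step state (lambda = 0).
* ``ModelBasedAgent`` — prospective evaluation: first-step action values
  are recomputed at each trial start as the transition-probability-
  weighted value of the second-step states.  The transition matrix is
  either known (the true one) or learned online with rate eta.
* ``RewardAsCueAgent`` — model-free learning in an extended state space:
  the previous trial's (outcome, second-step state) pair acts as a
  discriminative cue defining one of four first-step decision states.
* ``LatentStateAgent`` — Bayesian inference over which second-step state
  currently has the high reward probability, assuming a per-trial
  reversal probability omega, with a fixed (lapse epsilon) mapping from
  the inferred state to choice.
* ``DeterministicRewardAsCueAgent`` — the fixed cue-to-action mapping
  used for performance evaluation (reward in a -> A, reward in b -> B,
  non-reward in a -> B, non-reward in b -> A).

Every agent exposes the same interface — ``first_step_probs``,
``second_step_probs`` and ``update`` — so the identical code path serves
both simulation and likelihood evaluation.  Numerical conventions (value
initialisation at 0.5, update ordering) match the compiled kernels in
``twostep._kernels`` exactly; a replay of recorded events through these
classes reproduces the kernel's stored choice probabilities.
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np

from .task_env import TaskConfig, TrialEvents

Q_INIT = 0.5  # chance reward rate; unbiased between actions


# ----------------------------------------------------------------------
# Elementary operations
# ----------------------------------------------------------------------

def softmax_choice_probs(values, T: float, persev_bonus=None) -> np.ndarray:
    """Softmax choice probabilities with inverse temperature T.

    Computes exp(T * (v_i + bias_i)) normalised, in an overflow-safe
    way (the maximum is subtracted before exponentiation).  T = 0 gives
    the uniform distribution.
    """
    v = np.asarray(values, dtype=float)
    if persev_bonus is not None:
        v = v + np.asarray(persev_bonus, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("action values must be finite")
    if T < 0:
        raise ValueError("inverse temperature must be >= 0")
    z = T * (v - v.max())
    e = np.exp(z)
    return e / e.sum()


def perseveration_bonus(last_choice1: Optional[int], p: float,
                        n_actions: int = 2) -> np.ndarray:
    """Additive softmax bias p on the previously chosen first-step action.

    The bias enters only the choice rule, never the value updates.
    """
    if p < 0:
        raise ValueError("perseveration strength must be >= 0")
    bonus = np.zeros(n_actions)
    if last_choice1 is not None and p != 0.0:
        bonus[last_choice1] = p
    return bonus


def latent_state_update(posterior: float, ev: TrialEvents,
                        p_good: float, p_bad: float, omega: float) -> float:
    """One Bayesian update of P(state a is the good state).

    The evidence step uses only the outcome likelihood given the reached
    second-step state (the transition is independent of the latent state
    and cancels); the reversal step then mixes the posterior with its
    complement at rate omega.
    """
    if not 0.0 <= posterior <= 1.0:
        raise ValueError("posterior must lie in [0, 1]")
    if ev.second_state == 0:
        like_a_good = p_good if ev.outcome else 1.0 - p_good
        like_b_good = p_bad if ev.outcome else 1.0 - p_bad
    else:
        like_a_good = p_bad if ev.outcome else 1.0 - p_bad
        like_b_good = p_good if ev.outcome else 1.0 - p_good
    denom = posterior * like_a_good + (1.0 - posterior) * like_b_good
    if denom > 0.0:
        posterior = posterior * like_a_good / denom
    return (1.0 - omega) * posterior + omega * (1.0 - posterior)


def latent_state_choice_probs(posterior: float, epsilon: float) -> np.ndarray:
    """First-step choice probabilities of the latent-state policy.

    The action whose common transition leads to the more probable good
    state is chosen with probability 1 - epsilon; exact posterior ties
    give 0.5 for each action.
    """
    if not 0.0 <= posterior <= 1.0:
        raise ValueError("posterior must lie in [0, 1]")
    if posterior > 0.5:
        p_a = 1.0 - epsilon
    elif posterior < 0.5:
        p_a = epsilon
    else:
        p_a = 0.5
    return np.array([p_a, 1.0 - p_a])


# ----------------------------------------------------------------------
# Agent classes
# ----------------------------------------------------------------------

class Agent:
    """Common interface: choice probabilities given internal state, and a
    state update given the observable events of one trial."""

    name: str = "agent"
    kernel_family: str = ""

    def reset(self, config: TaskConfig) -> None:
        raise NotImplementedError

    def first_step_probs(self) -> np.ndarray:
        raise NotImplementedError

    def second_step_probs(self, second_state: int) -> np.ndarray:
        """Choice probabilities over second-step actions (original task)."""
        return np.array([1.0])

    def update(self, ev: TrialEvents) -> None:
        raise NotImplementedError

    def first_step_values(self) -> np.ndarray:
        """Action values entering the first-step choice rule (pre-choice)."""
        return np.zeros(2)

    def kernel_params(self) -> np.ndarray:
        """Parameter vector in the layout expected by twostep._kernels."""
        raise NotImplementedError

    @property
    def params(self) -> Dict[str, float]:
        raise NotImplementedError


class QLambdaAgent(Agent):
    """Model-free Q(lambda) agent.

    Updates, applied sequentially at trial end (the first-step update
    uses the pre-update second-step value):

        Q(s1,a1) <- (1-alpha) Q(s1,a1) + alpha (Q(s2,a2) + lambda (r - Q(s2,a2)))
        Q(s2,a2) <- (1-alpha) Q(s2,a2) + alpha r

    lambda = 1 uses only the trial outcome; lambda = 0 uses only the
    second-step value.  An optional perseveration bias biases the choice
    rule towards the previous first-step action.
    """

    name = "q_lambda"
    kernel_family = "q_lambda"

    def __init__(self, alpha: float, T: float, lam: float = 1.0,
                 perseveration: float = 0.0):
        if not 0.0 <= alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if not 0.0 <= lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")
        if T < 0:
            raise ValueError("T must be >= 0")
        if perseveration < 0:
            raise ValueError("perseveration must be >= 0")
        self.alpha, self.T, self.lam = alpha, T, lam
        self.perseveration = perseveration
        self.reset(TaskConfig.reduced())

    def reset(self, config: TaskConfig) -> None:
        self.config = config
        self.q1 = np.full(2, Q_INIT)
        self.q2 = np.full((2, 2), Q_INIT)
        self.last_choice1: Optional[int] = None

    def first_step_values(self) -> np.ndarray:
        return self.q1.copy()

    def first_step_probs(self) -> np.ndarray:
        bonus = perseveration_bonus(self.last_choice1, self.perseveration)
        return softmax_choice_probs(self.q1, self.T, bonus)

    def second_step_probs(self, second_state: int) -> np.ndarray:
        if self.config.n_second_actions == 1:
            return np.array([1.0])
        return softmax_choice_probs(self.q2[second_state], self.T)

    def update(self, ev: TrialEvents) -> None:
        a, lam = self.alpha, self.lam
        q2_pre = self.q2[ev.second_state, ev.choice2]
        self.q1[ev.choice1] = (1 - a) * self.q1[ev.choice1] + a * (
            q2_pre + lam * (ev.outcome - q2_pre))
        self.q2[ev.second_state, ev.choice2] = (1 - a) * q2_pre + a * ev.outcome
        self.last_choice1 = ev.choice1

    def kernel_params(self) -> np.ndarray:
        v = np.zeros(8)
        v[:4] = self.alpha, self.T, self.lam, self.perseveration
        return v

    @property
    def params(self) -> Dict[str, float]:
        return {"alpha": self.alpha, "T": self.T, "lam": self.lam,
                "perseveration": self.perseveration}


class ModelBasedAgent(Agent):
    """Model-based agent: Q(s1, a_i) = sum_j P(s_j | a_i) V(s_j).

    On the original task V(s_j) is the maximum of the two second-step
    action values in state j; on the reduced task it is the value of the
    single action.  With ``eta=None`` the true transition matrix is
    used; otherwise the estimate is learned online,
    P(x | a1) <- (1 - eta) P(x | a1) + eta X, initialised uniform.
    """

    name = "model_based"
    kernel_family = "model_based"

    def __init__(self, alpha: float, T: float, eta: Optional[float] = None,
                 perseveration: float = 0.0):
        if not 0.0 <= alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if eta is not None and not 0.0 <= eta <= 1.0:
            raise ValueError("eta must lie in [0, 1]")
        if T < 0:
            raise ValueError("T must be >= 0")
        if perseveration < 0:
            raise ValueError("perseveration must be >= 0")
        self.alpha, self.T, self.eta = alpha, T, eta
        self.perseveration = perseveration
        self.reset(TaskConfig.reduced())

    def reset(self, config: TaskConfig) -> None:
        self.config = config
        self.q2 = np.full((2, 2), Q_INIT)
        if self.eta is None:
            p = config.p_common
            self.t_hat = np.array([[p, 1 - p], [1 - p, p]])
        else:
            self.t_hat = np.full((2, 2), 0.5)
        self.last_choice1: Optional[int] = None

    def _state_values(self) -> np.ndarray:
        if self.config.n_second_actions == 1:
            return self.q2[:, 0]
        return self.q2.max(axis=1)

    def first_step_values(self) -> np.ndarray:
        return self.t_hat @ self._state_values()

    def first_step_probs(self) -> np.ndarray:
        bonus = perseveration_bonus(self.last_choice1, self.perseveration)
        return softmax_choice_probs(self.first_step_values(), self.T, bonus)

    def second_step_probs(self, second_state: int) -> np.ndarray:
        if self.config.n_second_actions == 1:
            return np.array([1.0])
        return softmax_choice_probs(self.q2[second_state], self.T)

    def update(self, ev: TrialEvents) -> None:
        if self.eta is not None:
            x = np.array([1.0 - ev.second_state, float(ev.second_state)])
            self.t_hat[ev.choice1] = (
                (1 - self.eta) * self.t_hat[ev.choice1] + self.eta * x)
        a = self.alpha
        self.q2[ev.second_state, ev.choice2] = (
            (1 - a) * self.q2[ev.second_state, ev.choice2] + a * ev.outcome)
        self.last_choice1 = ev.choice1

    def kernel_params(self) -> np.ndarray:
        v = np.zeros(8)
        v[:5] = (self.alpha, self.T,
                 self.eta if self.eta is not None else 0.0,
                 self.perseveration,
                 0.0 if self.eta is None else 1.0)
        return v

    @property
    def params(self) -> Dict[str, float]:
        out = {"alpha": self.alpha, "T": self.T,
               "perseveration": self.perseveration}
        if self.eta is not None:
            out["eta"] = self.eta
        return out


def cue_index(outcome: int, second_state: int) -> int:
    """Cue state defined by the previous trial's outcome and second-step
    state: index = 2 * outcome + second_state."""
    return 2 * int(outcome) + int(second_state)


class RewardAsCueAgent(Agent):
    """Model-free agent in an extended state space.

    The first-step choice is treated as occurring in one of four states
    defined by the previous trial's (outcome, second-step state) pair.
    Values of actions A/B are learned independently in each cue state
    with the outcome-driven update (1 - alpha) Q + alpha r.  On trial 1
    no cue exists: the choice is uniform random and no first-step update
    is made for that trial.  On the original task second-step values are
    learned with separate (alpha, T).
    """

    name = "reward_as_cue"
    kernel_family = "reward_as_cue"

    def __init__(self, alpha: float, T: float,
                 alpha_second: Optional[float] = None,
                 T_second: Optional[float] = None):
        if not 0.0 <= alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if T < 0:
            raise ValueError("T must be >= 0")
        self.alpha, self.T = alpha, T
        self.alpha_second = alpha if alpha_second is None else alpha_second
        self.T_second = T if T_second is None else T_second
        self.reset(TaskConfig.reduced())

    def reset(self, config: TaskConfig) -> None:
        self.config = config
        self.q1 = np.full((4, 2), Q_INIT)
        self.q2 = np.full((2, 2), Q_INIT)
        self.cue: Optional[int] = None

    def first_step_values(self) -> np.ndarray:
        if self.cue is None:
            return np.full(2, Q_INIT)
        return self.q1[self.cue].copy()

    def first_step_probs(self) -> np.ndarray:
        if self.cue is None:
            return np.array([0.5, 0.5])
        return softmax_choice_probs(self.q1[self.cue], self.T)

    def second_step_probs(self, second_state: int) -> np.ndarray:
        if self.config.n_second_actions == 1:
            return np.array([1.0])
        return softmax_choice_probs(self.q2[second_state], self.T_second)

    def update(self, ev: TrialEvents) -> None:
        if self.cue is not None:
            a = self.alpha
            self.q1[self.cue, ev.choice1] = (
                (1 - a) * self.q1[self.cue, ev.choice1] + a * ev.outcome)
        if self.config.n_second_actions == 2:
            a2 = self.alpha_second
            self.q2[ev.second_state, ev.choice2] = (
                (1 - a2) * self.q2[ev.second_state, ev.choice2]
                + a2 * ev.outcome)
        self.cue = cue_index(ev.outcome, ev.second_state)

    def kernel_params(self) -> np.ndarray:
        v = np.zeros(8)
        v[:4] = self.alpha, self.T, self.alpha_second, self.T_second
        return v

    @property
    def params(self) -> Dict[str, float]:
        return {"alpha": self.alpha, "T": self.T,
                "alpha_second": self.alpha_second,
                "T_second": self.T_second}


class LatentStateAgent(Agent):
    """Bayesian latent-state inference agent.

    Believes the world is in one of two states — reward probability
    p_good in state a and p_bad in state b, or vice versa — with a
    per-trial reversal probability omega.  The posterior that state a is
    good is updated after each trial (evidence step, then reversal
    mixing).  Choice follows the inferred state with lapse rate epsilon.
    On the original task second-step choices use softmax Q-learning with
    (alpha, T); believed probabilities default to 0.8/0.2 on the reduced
    task and 0.625/0.375 on the original task (the 75th/25th percentiles
    of the walk range).
    """

    name = "latent_state"
    kernel_family = "latent_state"

    def __init__(self, omega: float, epsilon: float,
                 p_good: Optional[float] = None,
                 p_bad: Optional[float] = None,
                 alpha: float = 0.5, T: float = 5.0):
        if not 0.0 <= omega <= 1.0 or not 0.0 <= epsilon <= 1.0:
            raise ValueError("omega and epsilon must lie in [0, 1]")
        self.omega, self.epsilon = omega, epsilon
        self._p_good, self._p_bad = p_good, p_bad
        self.alpha, self.T = alpha, T
        self.reset(TaskConfig.reduced())

    def reset(self, config: TaskConfig) -> None:
        self.config = config
        default = (0.8, 0.2) if config.variant == "reduced" else (0.625, 0.375)
        self.p_good = default[0] if self._p_good is None else self._p_good
        self.p_bad = default[1] if self._p_bad is None else self._p_bad
        if not self.p_good > self.p_bad:
            raise ValueError("require p_good > p_bad")
        self.posterior = 0.5
        self.q2 = np.full((2, 2), Q_INIT)

    def first_step_probs(self) -> np.ndarray:
        return latent_state_choice_probs(self.posterior, self.epsilon)

    def second_step_probs(self, second_state: int) -> np.ndarray:
        if self.config.n_second_actions == 1:
            return np.array([1.0])
        return softmax_choice_probs(self.q2[second_state], self.T)

    def update(self, ev: TrialEvents) -> None:
        self.posterior = latent_state_update(
            self.posterior, ev, self.p_good, self.p_bad, self.omega)
        if self.config.n_second_actions == 2:
            a = self.alpha
            self.q2[ev.second_state, ev.choice2] = (
                (1 - a) * self.q2[ev.second_state, ev.choice2] + a * ev.outcome)

    def kernel_params(self) -> np.ndarray:
        v = np.zeros(8)
        v[:6] = (self.omega, self.epsilon, self.p_good, self.p_bad,
                 self.alpha, self.T)
        return v

    @property
    def params(self) -> Dict[str, float]:
        return {"omega": self.omega, "epsilon": self.epsilon,
                "p_good": self.p_good, "p_bad": self.p_bad,
                "alpha": self.alpha, "T": self.T}


#: fixed cue -> action mapping: reward in a -> A, reward in b -> B,
#: non-reward in a -> B, non-reward in b -> A.  Indexed by cue_index.
DETERMINISTIC_RC_POLICY = {0: 1, 1: 0, 2: 0, 3: 1}


class DeterministicRewardAsCueAgent(Agent):
    """Fixed reward-as-cue policy used for performance evaluation.

    Deterministic, so it is used only for simulation, never for
    likelihood evaluation.  The first trial (no cue) is a uniform random
    choice, as is the second step on the original task (the strategy
    specifies only the first-step mapping).
    """

    name = "deterministic_reward_as_cue"
    kernel_family = "deterministic_reward_as_cue"

    def __init__(self):
        self.reset(TaskConfig.reduced())

    def reset(self, config: TaskConfig) -> None:
        self.config = config
        self.cue: Optional[int] = None

    def first_step_probs(self) -> np.ndarray:
        if self.cue is None:
            return np.array([0.5, 0.5])
        a = DETERMINISTIC_RC_POLICY[self.cue]
        p = np.zeros(2)
        p[a] = 1.0
        return p

    def second_step_probs(self, second_state: int) -> np.ndarray:
        if self.config.n_second_actions == 1:
            return np.array([1.0])
        return np.array([0.5, 0.5])

    def update(self, ev: TrialEvents) -> None:
        self.cue = cue_index(ev.outcome, ev.second_state)

    def kernel_params(self) -> np.ndarray:
        return np.zeros(8)

    @property
    def params(self) -> Dict[str, float]:
        return {}


class RandomFirstStepAgent(Agent):
    """Uniform random first-step choice with Q-learning at the second step.

    Used on the original task as a performance reference: it shows how
    much reward first-step control adds over exploiting the second-step
    contingencies alone.
    """

    name = "random_first_step"
    kernel_family = "random_first_step"

    def __init__(self, alpha: float, T: float):
        if not 0.0 <= alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if T < 0:
            raise ValueError("T must be >= 0")
        self.alpha, self.T = alpha, T
        self.reset(TaskConfig.original())

    def reset(self, config: TaskConfig) -> None:
        self.config = config
        self.q2 = np.full((2, 2), Q_INIT)

    def first_step_probs(self) -> np.ndarray:
        return np.array([0.5, 0.5])

    def second_step_probs(self, second_state: int) -> np.ndarray:
        if self.config.n_second_actions == 1:
            return np.array([1.0])
        return softmax_choice_probs(self.q2[second_state], self.T)

    def update(self, ev: TrialEvents) -> None:
        a = self.alpha
        self.q2[ev.second_state, ev.choice2] = (
            (1 - a) * self.q2[ev.second_state, ev.choice2] + a * ev.outcome)

    def kernel_params(self) -> np.ndarray:
        v = np.zeros(8)
        v[:2] = self.alpha, self.T
        return v

    @property
    def params(self) -> Dict[str, float]:
        return {"alpha": self.alpha, "T": self.T}


# ----------------------------------------------------------------------
# Registry
# ----------------------------------------------------------------------

AGENT_CLASSES = {
    "q_lambda": QLambdaAgent,
    "model_based": ModelBasedAgent,
    "reward_as_cue": RewardAsCueAgent,
    "latent_state": LatentStateAgent,
    "deterministic_reward_as_cue": DeterministicRewardAsCueAgent,
    "random_first_step": RandomFirstStepAgent,
}


def make_agent(name: str, **params) -> Agent:
    """Construct an agent by family name; convenience aliases ``q0`` and
    ``q1`` fix lambda at 0 and 1."""
    if name in ("q0", "q1"):
        lam = 0.0 if name == "q0" else 1.0
        return QLambdaAgent(lam=lam, **params)
    try:
        cls = AGENT_CLASSES[name]
    except KeyError:
        raise ValueError(f"unknown agent family {name!r}; "
                         f"known: {sorted(AGENT_CLASSES)}")
    return cls(**params)
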