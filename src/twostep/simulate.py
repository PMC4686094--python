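"""Running agents on tasks and storing the resulting sessions.

A :class:`Session` holds aligned per-trial records (first-step choice,
transition type, second-step state, second-step choice, outcome, the
true reward probabilities in force on each trial, and the agent's choice
probabilities) together with metadata identifying the agent, task and
seed.  Sessions round-trip losslessly through a tab-separated text
format so externally recorded data can be analysed with the same tools.

The default batch scale is 10 sessions of 10000 trials.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .agents import Agent, make_agent
from .task_env import (FIRST_STEP_ACTIONS, SECOND_STEP_STATES, TaskConfig,
                       TrialEvents)

MAX_SEED = 2 ** 31 - 1


@dataclass
class Session:
    """Per-trial record of one simulated (or recorded) session.

    All event arrays use integer coding (see :mod:`twostep.task_env`);
    ``reward_probs`` has shape (n_trials, 2, 2) indexed [trial,
    second-step state, second-step action]; ``p_choice_a`` is the
    agent's probability of choosing action A on each trial and
    ``p_choice2_0`` its probability of choosing second-step action 0 in
    the reached state (1.0 on the reduced task); ``q1_pre`` holds the
    first-step action values entering the choice rule (zeros for
    policies without first-step values).
    """

    choice1: np.ndarray
    common: np.ndarray
    second_state: np.ndarray
    choice2: np.ndarray
    outcome: np.ndarray
    p_choice_a: np.ndarray
    p_choice2_0: np.ndarray
    q1_pre: np.ndarray
    reward_probs: np.ndarray
    meta: Dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.choice1)
        for name in ("common", "second_state", "choice2", "outcome",
                     "p_choice_a", "p_choice2_0"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"per-trial sequence {name!r} has length "
                                 f"{len(getattr(self, name))}, expected {n}")
        if self.q1_pre.shape != (n, 2) or self.reward_probs.shape != (n, 2, 2):
            raise ValueError("q1_pre must be (n, 2) and reward_probs (n, 2, 2)")
        if not np.isin(self.outcome, (0, 1)).all():
            raise ValueError("outcomes must be 0 or 1")
        consistent = (self.choice1 == self.second_state) == (self.common == 1)
        if not consistent.all():
            bad = int(np.flatnonzero(~consistent)[0])
            raise ValueError(
                f"trial {bad}: transition type inconsistent with choice1 and "
                "second_state")

    @property
    def n_trials(self) -> int:
        return len(self.choice1)

    @property
    def task_config(self) -> TaskConfig:
        return TaskConfig(**self.meta["task_config"])

    @property
    def stay(self) -> np.ndarray:
        """stay[t] = 1 if choice1 on trial t+1 repeats trial t (length n-1)."""
        return (self.choice1[1:] == self.choice1[:-1]).astype(int)

    def reward_fraction(self) -> float:
        return float(self.outcome.mean())

    def events(self, t: int) -> TrialEvents:
        return TrialEvents(choice1=int(self.choice1[t]),
                           common=bool(self.common[t]),
                           second_state=int(self.second_state[t]),
                           choice2=int(self.choice2[t]),
                           outcome=int(self.outcome[t]))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "choice1": self.choice1,
            "common": self.common,
            "second_state": self.second_state,
            "choice2": self.choice2,
            "outcome": self.outcome,
            "p_choice_a": self.p_choice_a,
            "p_choice2_0": self.p_choice2_0,
            "q1_a": self.q1_pre[:, 0],
            "q1_b": self.q1_pre[:, 1],
            "prob_a0": self.reward_probs[:, 0, 0],
            "prob_a1": self.reward_probs[:, 0, 1],
            "prob_b0": self.reward_probs[:, 1, 0],
            "prob_b1": self.reward_probs[:, 1, 1],
        })


def run_session(agent: Agent, task_config: TaskConfig, n_trials: int,
                seed: int) -> Session:
    """Simulate one session; bit-identical output for identical inputs."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    seed = int(seed)
    if not 0 <= seed <= MAX_SEED:
        raise ValueError(f"seed must lie in [0, {MAX_SEED}]")
    agent.reset(task_config)
    family = _kernels.FAMILY_CODES[agent.kernel_family]
    params = agent.kernel_params()
    out = _kernels.simulate_session(family, params,
                                    *_kernels.task_args(task_config),
                                    n_trials, seed)
    (choice1, common, second_state, choice2, outcome,
     p_choice_a, p_choice2_0, q1_pre, reward_probs) = out
    # JSON round-trip normalises tuples to lists so metadata compares
    # equal after a file round-trip
    meta = json.loads(json.dumps({
        "agent": agent.name,
        "agent_params": dict(agent.params),
        "task_config": dataclasses.asdict(task_config),
        "seed": seed,
        "n_trials": n_trials}))
    return Session(choice1, common, second_state, choice2, outcome,
                   p_choice_a, p_choice2_0, q1_pre, reward_probs, meta)


def spawn_seeds(master_seed: int, n: int) -> List[int]:
    """Derive n distinct per-session seeds from a master seed."""
    ss = np.random.SeedSequence(int(master_seed))
    seeds = [int(s) % MAX_SEED for s in ss.generate_state(n, dtype=np.uint64)]
    if len(set(seeds)) != n:  # astronomically unlikely
        raise RuntimeError("seed collision while spawning session seeds")
    return seeds


def run_batch(agent: Agent, task_config: TaskConfig, n_sessions: int = 10,
              n_trials: int = 10000, seed: Optional[int] = None,
              seed_list: Optional[Sequence[int]] = None) -> List[Session]:
    """Simulate a batch of sessions with distinct per-session seeds.

    Either a master ``seed`` (from which per-session seeds are spawned
    deterministically) or an explicit ``seed_list`` must be given.
    """
    if seed_list is not None:
        seed_list = [int(s) for s in seed_list]
        if len(seed_list) != n_sessions:
            raise ValueError("seed_list length must equal n_sessions")
        if len(set(seed_list)) != n_sessions:
            raise ValueError("duplicate seeds in seed_list")
    elif seed is not None:
        seed_list = spawn_seeds(seed, n_sessions)
    else:
        raise ValueError("provide either seed or seed_list")
    return [run_session(agent, task_config, n_trials, s) for s in seed_list]


def replay_choice_probabilities(session: Session):
    """Re-derive the agent's choice probabilities by replaying its updates
    on the recorded events through the pure-Python agent classes.

    Returns (p_choice_a, p_choice2_0, q1_pre) arrays; these match the
    values stored at simulation time (up to floating-point rounding of
    the compiled path).
    """
    agent = make_agent(session.meta["agent"], **session.meta["agent_params"])
    config = session.task_config
    agent.reset(config)
    n = session.n_trials
    p1 = np.empty(n)
    p2 = np.empty(n)
    q1 = np.empty((n, 2))
    for t in range(n):
        p1[t] = agent.first_step_probs()[0]
        q1[t] = agent.first_step_values()
        if config.n_second_actions == 2:
            p2[t] = agent.second_step_probs(int(session.second_state[t]))[0]
        else:
            p2[t] = 1.0
        agent.update(session.events(t))
    return p1, p2, q1


# ----------------------------------------------------------------------
# Tab-separated session files
# ----------------------------------------------------------------------

_COLUMNS = ["trial", "choice1", "transition", "second_state", "choice2",
            "outcome", "p_choice_a", "p_choice2_0", "q1_a", "q1_b",
            "prob_a0", "prob_a1", "prob_b0", "prob_b1"]


def write_sessions(sessions: Sequence[Session], path) -> None:
    """Write sessions to a tab-separated file.

    Each session is preceded by a ``# session`` comment line carrying
    its metadata as JSON, followed by a header line and one row per
    trial.  Enumerations are spelled out (A/B, common/rare, a/b); floats
    are written with full precision so the round-trip is lossless.
    """
    with open(path, "w") as fh:
        for sess in sessions:
            fh.write("# session\t" + json.dumps(sess.meta) + "\n")
            fh.write("\t".join(_COLUMNS) + "\n")
            for t in range(sess.n_trials):
                row = [
                    str(t),
                    FIRST_STEP_ACTIONS[sess.choice1[t]],
                    "common" if sess.common[t] else "rare",
                    SECOND_STEP_STATES[sess.second_state[t]],
                    str(int(sess.choice2[t])),
                    str(int(sess.outcome[t])),
                    repr(float(sess.p_choice_a[t])),
                    repr(float(sess.p_choice2_0[t])),
                    repr(float(sess.q1_pre[t, 0])),
                    repr(float(sess.q1_pre[t, 1])),
                    repr(float(sess.reward_probs[t, 0, 0])),
                    repr(float(sess.reward_probs[t, 0, 1])),
                    repr(float(sess.reward_probs[t, 1, 0])),
                    repr(float(sess.reward_probs[t, 1, 1])),
                ]
                fh.write("\t".join(row) + "\n")


def _parse_row(fields: List[str], lineno: int) -> tuple:
    if len(fields) != len(_COLUMNS):
        raise ValueError(f"line {lineno}: expected {len(_COLUMNS)} fields, "
                         f"got {len(fields)}")
    try:
        choice1 = FIRST_STEP_ACTIONS.index(fields[1])
        transition = fields[2]
        if transition not in ("common", "rare"):
            raise ValueError(f"bad transition label {transition!r}")
        second_state = SECOND_STEP_STATES.index(fields[3])
        choice2 = int(fields[4])
        outcome = int(fields[5])
        floats = [float(x) for x in fields[6:]]
    except ValueError as err:
        raise ValueError(f"line {lineno}: malformed row ({err})") from err
    common = transition == "common"
    if (choice1 == second_state) != common:
        raise ValueError(
            f"line {lineno}: transition type inconsistent with choice and "
            "second-step state")
    return choice1, common, second_state, choice2, outcome, floats


def read_sessions(path) -> List[Session]:
    """Read sessions written by :func:`write_sessions`.

    Malformed or inconsistent rows are rejected with the offending line
    number.
    """
    sessions: List[Session] = []
    meta: Optional[Dict] = None
    rows: List[tuple] = []

    def _flush():
        if meta is None:
            return
        if not rows:
            raise ValueError("session block with no trial rows")
        n = len(rows)
        choice1 = np.array([r[0] for r in rows], dtype=np.int64)
        common = np.array([1 if r[1] else 0 for r in rows], dtype=np.int64)
        second_state = np.array([r[2] for r in rows], dtype=np.int64)
        choice2 = np.array([r[3] for r in rows], dtype=np.int64)
        outcome = np.array([r[4] for r in rows], dtype=np.int64)
        f = np.array([r[5] for r in rows])
        sessions.append(Session(
            choice1, common, second_state, choice2, outcome,
            p_choice_a=f[:, 0], p_choice2_0=f[:, 1],
            q1_pre=f[:, 2:4].copy(),
            reward_probs=f[:, 4:8].reshape(n, 2, 2).copy(),
            meta=meta))

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("# session"):
                _flush()
                rows = []
                try:
                    meta = json.loads(line.split("\t", 1)[1])
                except (IndexError, json.JSONDecodeError) as err:
                    raise ValueError(
                        f"line {lineno}: bad session metadata ({err})") from err
            elif line.startswith("#"):
                continue
            elif line.startswith("trial\t"):
                continue  # header
            else:
                if meta is None:
                    raise ValueError(
                        f"line {lineno}: trial row before any session header")
                rows.append(_parse_row(line.split("\t"), lineno))
    _flush()
    if not sessions:
        raise ValueError(f"no sessions found in {path}")
    return sessions
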