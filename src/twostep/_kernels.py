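"""Numba-compiled engine for session simulation and likelihood replay.

Heavy computations (reward-rate optimisation, maximum-likelihood
fitting) evaluate millions of trials, so the per-trial agent step is
compiled.  The same step functions (`_first_probs`, `_second_probs`,
`_update`) drive both :func:`simulate_session` and
:func:`session_loglik`, so the probabilities recorded during simulation
and the probabilities entering a likelihood are produced by one code
path.  The pure-Python agent classes in :mod:`twostep.agents` implement
the identical arithmetic and are checked against these kernels in the
test suite.

Agent families are dispatched on integer codes (``FAMILY_CODES``) with a
fixed-length parameter vector whose layout per family is::

    q_lambda:                   [alpha, T, lambda, perseveration]
    model_based:                [alpha, T, eta, perseveration, learn_flag]
    reward_as_cue:              [alpha1, T1, alpha2, T2]
    latent_state:               [omega, epsilon, p_good, p_bad, alpha2, T2]
    deterministic_reward_as_cue: []
    random_first_step:          [alpha, T]

Mutable agent state is carried in four arrays: ``q1`` (4 x 2; cue-state
rows for reward-as-cue, row 0 for plain Q agents), ``q2`` (2 x 2),
``t_hat`` (2 x 2 transition estimate) and ``scal`` = [latent-state
posterior, last first-step choice (-1 = none), cue index (-1 = none)].
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .task_env import TaskConfig

FAMILY_CODES = {
    "q_lambda": 0,
    "model_based": 1,
    "reward_as_cue": 2,
    "latent_state": 3,
    "deterministic_reward_as_cue": 4,
    "random_first_step": 5,
}

VARIANT_CODES = {"original": 0, "reduced": 1}
PROCESS_CODES = {"blocks": 0, "random_walk": 1, "fixed": 2}

_LOG_TINY = math.log(1e-300)


def task_args(config: TaskConfig):
    """Flatten a TaskConfig into the scalar arguments the kernels take."""
    return (VARIANT_CODES[config.variant],
            float(config.p_common),
            PROCESS_CODES[config.reward_process],
            int(config.block_length),
            float(config.block_probs[0]), float(config.block_probs[1]),
            float(config.walk_bounds[0]), float(config.walk_bounds[1]),
            float(config.walk_sd),
            float(config.fixed_probs[0]), float(config.fixed_probs[1]))


@njit(cache=True)
def _softmax2(v0, v1, T):
    m = v0 if v0 > v1 else v1
    e0 = math.exp(T * (v0 - m))
    e1 = math.exp(T * (v1 - m))
    return e0 / (e0 + e1)


@njit(cache=True)
def _reflect(x, lo, hi):
    while x < lo or x > hi:
        if x > hi:
            x = 2.0 * hi - x
        elif x < lo:
            x = 2.0 * lo - x
    return x


@njit(cache=True)
def _first_probs(family, params, q1, q2, t_hat, scal, n2):
    """Probability of first-step action A plus the recorded pre-choice
    first-step values (zeros for policies without first-step values)."""
    if family == 0:  # q_lambda
        v0 = q1[0, 0]
        v1 = q1[0, 1]
        b0 = 0.0
        b1 = 0.0
        p = params[3]
        lc = scal[1]
        if p != 0.0 and lc >= 0.0:
            if lc == 0.0:
                b0 = p
            else:
                b1 = p
        return _softmax2(v0 + b0, v1 + b1, params[1]), v0, v1
    elif family == 1:  # model_based
        if n2 == 1:
            V0 = q2[0, 0]
            V1 = q2[1, 0]
        else:
            V0 = q2[0, 0] if q2[0, 0] > q2[0, 1] else q2[0, 1]
            V1 = q2[1, 0] if q2[1, 0] > q2[1, 1] else q2[1, 1]
        v0 = t_hat[0, 0] * V0 + t_hat[0, 1] * V1
        v1 = t_hat[1, 0] * V0 + t_hat[1, 1] * V1
        b0 = 0.0
        b1 = 0.0
        p = params[3]
        lc = scal[1]
        if p != 0.0 and lc >= 0.0:
            if lc == 0.0:
                b0 = p
            else:
                b1 = p
        return _softmax2(v0 + b0, v1 + b1, params[1]), v0, v1
    elif family == 2:  # reward_as_cue
        cue = scal[2]
        if cue < 0.0:
            return 0.5, 0.5, 0.5
        c = int(cue)
        v0 = q1[c, 0]
        v1 = q1[c, 1]
        return _softmax2(v0, v1, params[1]), v0, v1
    elif family == 3:  # latent_state
        post = scal[0]
        eps = params[1]
        if post > 0.5:
            pA = 1.0 - eps
        elif post < 0.5:
            pA = eps
        else:
            pA = 0.5
        return pA, 0.0, 0.0
    elif family == 4:  # deterministic reward-as-cue
        cue = scal[2]
        if cue < 0.0:
            return 0.5, 0.0, 0.0
        c = int(cue)
        # policy: cue (r, s2): (1,a)->A, (1,b)->B, (0,a)->B, (0,b)->A
        if c == 2 or c == 1:
            return 1.0, 0.0, 0.0  # chooses A
        else:
            return 0.0, 0.0, 0.0  # chooses B
    else:  # random first step
        return 0.5, 0.0, 0.0


@njit(cache=True)
def _second_probs(family, params, q2, s2):
    """Probability of second-step action 0 in the reached state
    (original task only)."""
    if family == 0 or family == 1:
        return _softmax2(q2[s2, 0], q2[s2, 1], params[1])
    elif family == 2:
        return _softmax2(q2[s2, 0], q2[s2, 1], params[3])
    elif family == 3:
        return _softmax2(q2[s2, 0], q2[s2, 1], params[5])
    elif family == 5:
        return _softmax2(q2[s2, 0], q2[s2, 1], params[1])
    else:  # deterministic reward-as-cue: unspecified, random
        return 0.5


@njit(cache=True)
def _update(family, params, q1, q2, t_hat, scal, c1, s2, c2, r, n2):
    """State update at trial end, given the trial's observable events."""
    if family == 0:  # q_lambda: first-step update uses pre-update Q(s2,a2)
        a = params[0]
        lam = params[2]
        q2_pre = q2[s2, c2]
        q1[0, c1] = (1 - a) * q1[0, c1] + a * (q2_pre + lam * (r - q2_pre))
        q2[s2, c2] = (1 - a) * q2_pre + a * r
        scal[1] = c1
    elif family == 1:  # model_based
        if params[4] == 1.0:  # learned transition estimate
            eta = params[2]
            x1 = float(s2)
            t_hat[c1, 0] = (1 - eta) * t_hat[c1, 0] + eta * (1.0 - x1)
            t_hat[c1, 1] = (1 - eta) * t_hat[c1, 1] + eta * x1
        a = params[0]
        q2[s2, c2] = (1 - a) * q2[s2, c2] + a * r
        scal[1] = c1
    elif family == 2:  # reward_as_cue
        cue = scal[2]
        if cue >= 0.0:
            c = int(cue)
            a = params[0]
            q1[c, c1] = (1 - a) * q1[c, c1] + a * r
        if n2 == 2:
            a2 = params[2]
            q2[s2, c2] = (1 - a2) * q2[s2, c2] + a2 * r
        scal[2] = 2 * r + s2
    elif family == 3:  # latent_state
        omega = params[0]
        pg = params[2]
        pb = params[3]
        post = scal[0]
        if s2 == 0:
            la = pg if r == 1 else 1.0 - pg
            lb = pb if r == 1 else 1.0 - pb
        else:
            la = pb if r == 1 else 1.0 - pb
            lb = pg if r == 1 else 1.0 - pg
        denom = post * la + (1.0 - post) * lb
        if denom > 0.0:
            post = post * la / denom
        scal[0] = (1.0 - omega) * post + omega * (1.0 - post)
        if n2 == 2:
            a = params[4]
            q2[s2, c2] = (1 - a) * q2[s2, c2] + a * r
    elif family == 4:  # deterministic reward-as-cue
        scal[2] = 2 * r + s2
    else:  # random first step: second-step Q-learning only
        a = params[0]
        q2[s2, c2] = (1 - a) * q2[s2, c2] + a * r


@njit(cache=True)
def simulate_session(family, params, variant, p_common, process,
                     block_length, block_good, block_bad,
                     walk_lo, walk_hi, walk_sd, fixed0, fixed1,
                     n_trials, seed):
    """Simulate one session; all randomness comes from ``seed``.

    Returns per-trial arrays: choice1, common(0/1), second_state,
    choice2, outcome, P(choice1 = A), P(choice2 = action 0), pre-choice
    first-step values (n x 2) and the true reward probabilities in force
    on each trial (n x 2 x 2).  Reward probabilities advance at trial
    end, after the outcome draw.
    """
    np.random.seed(seed)
    n2 = 2 if variant == 0 else 1

    # --- initial reward probabilities
    rp = np.full((2, 2), 0.5)
    block_phase = 0
    if process == 0:  # blocks: first good state drawn at random
        if np.random.random() < 0.5:
            rp[0, 0] = block_good
            rp[0, 1] = block_good
            rp[1, 0] = block_bad
            rp[1, 1] = block_bad
        else:
            rp[0, 0] = block_bad
            rp[0, 1] = block_bad
            rp[1, 0] = block_good
            rp[1, 1] = block_good
    elif process == 1:  # random walk: uniform start within bounds
        for s in range(2):
            for a in range(n2):
                rp[s, a] = walk_lo + (walk_hi - walk_lo) * np.random.random()
        if n2 == 1:
            rp[0, 1] = rp[0, 0]
            rp[1, 1] = rp[1, 0]
    else:  # fixed
        rp[0, 0] = fixed0
        rp[0, 1] = fixed0
        rp[1, 0] = fixed1
        rp[1, 1] = fixed1

    # --- agent state
    q1 = np.full((4, 2), 0.5)
    q2 = np.full((2, 2), 0.5)
    t_hat = np.full((2, 2), 0.5)
    if family == 1 and params[4] == 0.0:  # true transition matrix
        t_hat[0, 0] = p_common
        t_hat[0, 1] = 1.0 - p_common
        t_hat[1, 0] = 1.0 - p_common
        t_hat[1, 1] = p_common
    scal = np.zeros(3)
    scal[0] = 0.5   # latent-state posterior
    scal[1] = -1.0  # last first-step choice (none)
    scal[2] = -1.0  # cue (none)

    # --- outputs
    choice1 = np.empty(n_trials, dtype=np.int64)
    common = np.empty(n_trials, dtype=np.int64)
    second_state = np.empty(n_trials, dtype=np.int64)
    choice2 = np.empty(n_trials, dtype=np.int64)
    outcome = np.empty(n_trials, dtype=np.int64)
    p_choice_a = np.empty(n_trials)
    p_choice2_0 = np.empty(n_trials)
    q1_pre = np.empty((n_trials, 2))
    reward_probs = np.empty((n_trials, 2, 2))

    for t in range(n_trials):
        reward_probs[t, :, :] = rp

        pA, v0, v1 = _first_probs(family, params, q1, q2, t_hat, scal, n2)
        c1 = 0 if np.random.random() < pA else 1
        is_common = np.random.random() < p_common
        s2 = c1 if is_common else 1 - c1
        if n2 == 2:
            p20 = _second_probs(family, params, q2, s2)
            c2 = 0 if np.random.random() < p20 else 1
        else:
            p20 = 1.0
            c2 = 0
        r = 1 if np.random.random() < rp[s2, c2] else 0

        choice1[t] = c1
        common[t] = 1 if is_common else 0
        second_state[t] = s2
        choice2[t] = c2
        outcome[t] = r
        p_choice_a[t] = pA
        p_choice2_0[t] = p20
        q1_pre[t, 0] = v0
        q1_pre[t, 1] = v1

        _update(family, params, q1, q2, t_hat, scal, c1, s2, c2, r, n2)

        # advance the reward-probability process (trial t used rp as-is)
        if process == 0:
            block_phase += 1
            if block_phase >= block_length:
                tmp0 = rp[0, 0]
                tmp1 = rp[0, 1]
                rp[0, 0] = rp[1, 0]
                rp[0, 1] = rp[1, 1]
                rp[1, 0] = tmp0
                rp[1, 1] = tmp1
                block_phase = 0
        elif process == 1:
            for s in range(2):
                for a in range(n2):
                    step = np.random.normal(0.0, walk_sd)
                    rp[s, a] = _reflect(rp[s, a] + step, walk_lo, walk_hi)
            if n2 == 1:
                rp[0, 1] = rp[0, 0]
                rp[1, 1] = rp[1, 0]

    return (choice1, common, second_state, choice2, outcome,
            p_choice_a, p_choice2_0, q1_pre, reward_probs)


@njit(cache=True)
def simulate_reward_fraction(family, params, variant, p_common, process,
                             block_length, block_good, block_bad,
                             walk_lo, walk_hi, walk_sd, fixed0, fixed1,
                             n_trials, seed):
    """Reward fraction of one simulated session.

    Identical dynamics and random-number sequence to
    :func:`simulate_session` (same step functions, same draw order) but
    without per-trial outputs; used as the reward-rate optimisation
    objective where millions of trials are simulated per fit.
    """
    np.random.seed(seed)
    n2 = 2 if variant == 0 else 1

    rp = np.full((2, 2), 0.5)
    block_phase = 0
    if process == 0:
        if np.random.random() < 0.5:
            rp[0, 0] = block_good
            rp[0, 1] = block_good
            rp[1, 0] = block_bad
            rp[1, 1] = block_bad
        else:
            rp[0, 0] = block_bad
            rp[0, 1] = block_bad
            rp[1, 0] = block_good
            rp[1, 1] = block_good
    elif process == 1:
        for s in range(2):
            for a in range(n2):
                rp[s, a] = walk_lo + (walk_hi - walk_lo) * np.random.random()
        if n2 == 1:
            rp[0, 1] = rp[0, 0]
            rp[1, 1] = rp[1, 0]
    else:
        rp[0, 0] = fixed0
        rp[0, 1] = fixed0
        rp[1, 0] = fixed1
        rp[1, 1] = fixed1

    q1 = np.full((4, 2), 0.5)
    q2 = np.full((2, 2), 0.5)
    t_hat = np.full((2, 2), 0.5)
    if family == 1 and params[4] == 0.0:
        t_hat[0, 0] = p_common
        t_hat[0, 1] = 1.0 - p_common
        t_hat[1, 0] = 1.0 - p_common
        t_hat[1, 1] = p_common
    scal = np.zeros(3)
    scal[0] = 0.5
    scal[1] = -1.0
    scal[2] = -1.0

    total_reward = 0
    for t in range(n_trials):
        pA, v0, v1 = _first_probs(family, params, q1, q2, t_hat, scal, n2)
        c1 = 0 if np.random.random() < pA else 1
        is_common = np.random.random() < p_common
        s2 = c1 if is_common else 1 - c1
        if n2 == 2:
            p20 = _second_probs(family, params, q2, s2)
            c2 = 0 if np.random.random() < p20 else 1
        else:
            c2 = 0
        r = 1 if np.random.random() < rp[s2, c2] else 0
        total_reward += r

        _update(family, params, q1, q2, t_hat, scal, c1, s2, c2, r, n2)

        if process == 0:
            block_phase += 1
            if block_phase >= block_length:
                tmp0 = rp[0, 0]
                tmp1 = rp[0, 1]
                rp[0, 0] = rp[1, 0]
                rp[0, 1] = rp[1, 1]
                rp[1, 0] = tmp0
                rp[1, 1] = tmp1
                block_phase = 0
        elif process == 1:
            for s in range(2):
                for a in range(n2):
                    step = np.random.normal(0.0, walk_sd)
                    rp[s, a] = _reflect(rp[s, a] + step, walk_lo, walk_hi)
            if n2 == 1:
                rp[0, 1] = rp[0, 0]
                rp[1, 1] = rp[1, 0]

    return total_reward / n_trials


@njit(cache=True)
def session_loglik(family, params, variant, p_common,
                   choice1, second_state, choice2, outcome):
    """Log-likelihood of recorded choices under an agent.

    The agent's state evolves on the recorded events.  On the original
    task both first- and second-step choices are modelled; the reduced
    task has no second-step choice.  Returns (log-likelihood,
    n_modelled_choices, n_zero_probability_choices); zero-probability
    choices contribute log(1e-300) each.
    """
    n2 = 2 if variant == 0 else 1
    n_trials = choice1.shape[0]

    q1 = np.full((4, 2), 0.5)
    q2 = np.full((2, 2), 0.5)
    t_hat = np.full((2, 2), 0.5)
    if family == 1 and params[4] == 0.0:
        t_hat[0, 0] = p_common
        t_hat[0, 1] = 1.0 - p_common
        t_hat[1, 0] = 1.0 - p_common
        t_hat[1, 1] = p_common
    scal = np.zeros(3)
    scal[0] = 0.5
    scal[1] = -1.0
    scal[2] = -1.0

    total = 0.0
    n_obs = 0
    n_zero = 0
    for t in range(n_trials):
        c1 = choice1[t]
        s2 = second_state[t]
        c2 = choice2[t]
        r = outcome[t]

        pA, v0, v1 = _first_probs(family, params, q1, q2, t_hat, scal, n2)
        p = pA if c1 == 0 else 1.0 - pA
        if p <= 0.0:
            total += _LOG_TINY
            n_zero += 1
        else:
            total += math.log(p)
        n_obs += 1

        if n2 == 2:
            p20 = _second_probs(family, params, q2, s2)
            p = p20 if c2 == 0 else 1.0 - p20
            if p <= 0.0:
                total += _LOG_TINY
                n_zero += 1
            else:
                total += math.log(p)
            n_obs += 1

        _update(family, params, q1, q2, t_hat, scal, c1, s2, c2, r, n2)

    return total, n_obs, n_zero
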