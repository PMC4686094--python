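"""Maximum-likelihood fitting of agents to session data.

Any agent family can be fitted to any session set: the agent's state is
evolved along the *recorded* events and the log-likelihood is the sum of
log choice probabilities of the recorded choices (both steps on the
original task; only the first step on the reduced task, which has no
second-step choice).  Optimisation runs over unconstrained transformed
parameters (logit for unit-interval parameters, log for inverse
temperatures) with multiple random restarts.

On the reduced task every fitted family has two free parameters, so raw
likelihoods are directly comparable; BIC = k ln(n) - 2 LL is also
reported for the original task.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

from . import _kernels
from .agents import Agent, make_agent
from .simulate import Session

#: agent families fitted in the reduced-task model comparison
REDUCED_FITTERS = ("q0", "q1", "model_based", "reward_as_cue", "latent_state")


# ----------------------------------------------------------------------
# Likelihood evaluation
# ----------------------------------------------------------------------

def _session_arrays(sessions: Sequence[Session]):
    return [(s.choice1, s.second_state, s.choice2, s.outcome)
            for s in sessions]


def session_log_likelihoods(agent: Agent, sessions: Sequence[Session],
                            ) -> np.ndarray:
    """Per-session log-likelihood of the recorded choices under an agent.

    The agent is reset per session and its state evolves on the recorded
    events.  Recorded choices assigned zero probability (possible only
    for deterministic policies) contribute log(1e-300) each.
    """
    out = np.empty(len(sessions))
    for i, sess in enumerate(sessions):
        config = sess.task_config
        agent.reset(config)
        family = _kernels.FAMILY_CODES[agent.kernel_family]
        variant = _kernels.VARIANT_CODES[config.variant]
        ll, n_obs, n_zero = _kernels.session_loglik(
            family, agent.kernel_params(), variant, config.p_common,
            sess.choice1, sess.second_state, sess.choice2, sess.outcome)
        out[i] = ll
    return out


def session_log_likelihood(agent: Agent, sessions: Sequence[Session]) -> float:
    """Total log-likelihood summed over sessions."""
    return float(session_log_likelihoods(agent, sessions).sum())


def n_modelled_choices(sessions: Sequence[Session]) -> int:
    """Number of modelled choices: both steps per trial on the original
    task, the first step only on the reduced task."""
    total = 0
    for s in sessions:
        per_trial = 2 if s.task_config.n_second_actions == 2 else 1
        total += per_trial * s.n_trials
    return total


# ----------------------------------------------------------------------
# Parameterisation for unconstrained optimisation
# ----------------------------------------------------------------------

#: transform codes: 'unit' <-> logit/expit, 'pos' <-> log/exp
_UNIT, _POS = "unit", "pos"


def _to_unconstrained(value: float, kind: str) -> float:
    return float(logit(value)) if kind == _UNIT else float(np.log(value))


def _from_unconstrained(x: float, kind: str) -> float:
    return float(expit(x)) if kind == _UNIT else float(np.exp(x))


@dataclass(frozen=True)
class FamilySpec:
    """Free parameters of a fitted family and its agent constructor."""

    family: str
    param_names: Tuple[str, ...]
    transforms: Tuple[str, ...]
    build: Callable[..., Agent]


def family_spec(name: str, variant: str,
                lam: Optional[float] = None) -> FamilySpec:
    """Free-parameter specification for a fitted agent family.

    The eligibility trace of Q(lambda) families is fixed, not estimated
    ('q0' and 'q1' fix it at 0 and 1; pass ``lam`` for intermediate
    values), so every reduced-task family keeps two parameters.
    """
    if name in ("q0", "q1") or name == "q_lambda":
        lam_fixed = {"q0": 0.0, "q1": 1.0}.get(name, lam)
        if lam_fixed is None:
            raise ValueError("q_lambda fits require a fixed lam")
        return FamilySpec(
            name, ("alpha", "T"), (_UNIT, _POS),
            lambda alpha, T: make_agent("q_lambda", alpha=alpha, T=T,
                                        lam=lam_fixed))
    if name == "model_based":
        return FamilySpec(
            name, ("alpha", "T"), (_UNIT, _POS),
            lambda alpha, T: make_agent("model_based", alpha=alpha, T=T))
    if name == "reward_as_cue":
        if variant == "original":
            return FamilySpec(
                name, ("alpha", "T", "alpha_second", "T_second"),
                (_UNIT, _POS, _UNIT, _POS),
                lambda alpha, T, alpha_second, T_second: make_agent(
                    "reward_as_cue", alpha=alpha, T=T,
                    alpha_second=alpha_second, T_second=T_second))
        return FamilySpec(
            name, ("alpha", "T"), (_UNIT, _POS),
            lambda alpha, T: make_agent("reward_as_cue", alpha=alpha, T=T))
    if name == "latent_state":
        if variant == "original":
            return FamilySpec(
                name, ("omega", "epsilon", "alpha", "T"),
                (_UNIT, _UNIT, _UNIT, _POS),
                lambda omega, epsilon, alpha, T: make_agent(
                    "latent_state", omega=omega, epsilon=epsilon,
                    alpha=alpha, T=T))
        return FamilySpec(
            name, ("omega", "epsilon"), (_UNIT, _UNIT),
            lambda omega, epsilon: make_agent("latent_state", omega=omega,
                                              epsilon=epsilon))
    raise ValueError(f"no fit specification for agent family {name!r}")


def _random_start(spec: FamilySpec, rng: np.random.Generator) -> np.ndarray:
    """Random initial point, drawn on the natural scale then transformed.

    Start ranges reflect the plausible scale of each parameter: reversal
    probabilities are of order the inverse mean block length, so omega
    starts log-uniform over (1e-3, 0.5); lapse rates start below 0.5
    (above 0.5 the policy is inverted, a mirror-image likelihood basin);
    learning rates start anywhere in the unit interval.  The optimiser
    itself is unconstrained beyond the parameter transforms.
    """
    x = np.empty(len(spec.param_names))
    for i, (name, kind) in enumerate(zip(spec.param_names, spec.transforms)):
        if name == "omega":
            v = np.exp(rng.uniform(np.log(1e-3), np.log(0.5)))
        elif name == "epsilon":
            v = rng.uniform(0.02, 0.45)
        elif kind == _UNIT:
            v = rng.uniform(0.05, 0.95)
        else:
            v = rng.uniform(0.5, 10.0)
        x[i] = _to_unconstrained(v, kind)
    return x


# ----------------------------------------------------------------------
# Fitting
# ----------------------------------------------------------------------

@dataclass
class FitResult:
    """Outcome of a maximum-likelihood fit.

    BIC = n_params * ln(n_observations) - 2 * log_likelihood, with
    n_observations the number of modelled choices.  The best restart is
    reported; per-restart log-likelihoods are kept as a diagnostic.
    """

    agent: str
    params: Dict[str, float]
    log_likelihood: float
    n_observations: int
    n_params: int
    bic: float
    restart_logliks: List[float]
    converged: bool
    per_session_loglik: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def loglik_per_choice(self) -> float:
        """Mean log-likelihood per modelled choice (log of the per-choice
        geometric-mean likelihood)."""
        return self.log_likelihood / self.n_observations


def fit_ml(agent_type: str, sessions: Sequence[Session],
           n_restarts: int = 10, seed: int = 0,
           lam: Optional[float] = None) -> FitResult:
    """Fit an agent family to sessions by maximum likelihood.

    Powell's method on the transformed unconstrained parameters, best of
    ``n_restarts`` random restarts.
    """
    if not sessions:
        raise ValueError("need at least one session")
    variant = sessions[0].task_config.variant
    spec = family_spec(agent_type, variant, lam=lam)
    rng = np.random.default_rng(seed)

    def neg_loglik(x: np.ndarray) -> float:
        natural = {name: _from_unconstrained(xi, kind)
                   for name, xi, kind in zip(spec.param_names, x,
                                             spec.transforms)}
        agent = spec.build(**natural)
        return -session_log_likelihood(agent, sessions)

    best = None
    restart_lls: List[float] = []
    any_converged = False
    for _ in range(n_restarts):
        x0 = _random_start(spec, rng)
        res = optimize.minimize(neg_loglik, x0, method="Powell")
        restart_lls.append(-res.fun)
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if not any_converged:
        raise RuntimeError(
            f"no restart converged fitting {agent_type}: {best.message}")

    params = {name: _from_unconstrained(xi, kind)
              for name, xi, kind in zip(spec.param_names, best.x,
                                        spec.transforms)}
    agent = spec.build(**params)
    per_session = session_log_likelihoods(agent, sessions)
    ll = float(per_session.sum())
    n_obs = n_modelled_choices(sessions)
    k = len(spec.param_names)
    return FitResult(agent=agent_type, params=params, log_likelihood=ll,
                     n_observations=n_obs, n_params=k,
                     bic=k * np.log(n_obs) - 2.0 * ll,
                     restart_logliks=restart_lls, converged=any_converged,
                     per_session_loglik=per_session)


# ----------------------------------------------------------------------
# Cross-fitting
# ----------------------------------------------------------------------

@dataclass
class CrossFitResult:
    """Likelihood matrix of fitted families across generating agents.

    ``mean_loglik[fitter][generator]`` is the mean per-session fitted
    log-likelihood; ``sem_loglik`` its SEM across sessions; ``bic`` the
    total-dataset BIC.  ``fits`` holds the underlying FitResults.
    """

    generators: List[str]
    fitters: List[str]
    mean_loglik: pd.DataFrame
    sem_loglik: pd.DataFrame
    bic: pd.DataFrame
    fits: Dict[Tuple[str, str], FitResult]

    def pairwise_pvalues(self, generator: str) -> pd.DataFrame:
        """Paired t-tests between fitters' per-session log-likelihoods on
        the same generator's data."""
        out = pd.DataFrame(np.nan, index=self.fitters, columns=self.fitters)
        for f1 in self.fitters:
            for f2 in self.fitters:
                if f1 == f2:
                    continue
                a = self.fits[(generator, f1)].per_session_loglik
                b = self.fits[(generator, f2)].per_session_loglik
                out.loc[f1, f2] = stats.ttest_rel(a, b).pvalue
        return out

    def best_fitter(self, generator: str) -> str:
        return self.mean_loglik.loc[generator].idxmax()


def cross_fit_matrix(datasets: Dict[str, Sequence[Session]],
                     fitters: Sequence[str] = REDUCED_FITTERS,
                     n_restarts: int = 10, seed: int = 0) -> CrossFitResult:
    """Fit every family to every labelled dataset.

    ``datasets`` maps generating-agent names to session lists.  Each
    (generator, fitter) cell reports the mean and SEM across sessions of
    the per-session log-likelihood at the jointly fitted parameters.
    """
    generators = list(datasets)
    fitters = list(fitters)
    mean = pd.DataFrame(index=generators, columns=fitters, dtype=float)
    sem = pd.DataFrame(index=generators, columns=fitters, dtype=float)
    bic = pd.DataFrame(index=generators, columns=fitters, dtype=float)
    fits: Dict[Tuple[str, str], FitResult] = {}
    rng = np.random.default_rng(seed)
    for gen in generators:
        sessions = datasets[gen]
        for fitter in fitters:
            fit = fit_ml(fitter, sessions, n_restarts=n_restarts,
                         seed=int(rng.integers(2 ** 31)))
            fits[(gen, fitter)] = fit
            per = fit.per_session_loglik
            mean.loc[gen, fitter] = per.mean()
            sem.loc[gen, fitter] = per.std(ddof=1) / np.sqrt(len(per))
            bic.loc[gen, fitter] = fit.bic
    return CrossFitResult(generators, fitters, mean, sem, bic, fits)
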