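"""Trial-by-trial behavioural analyses of two-step sessions.

Implements the three analyses used to characterise agent strategies:

* **Stay-probability tables** — the fraction of trials on which the
  first-step choice is repeated, split by the previous trial's
  transition (common/rare) and outcome (rewarded/not).
* **One-trial-back logistic regression** of stay vs switch on the
  previous trial's events, optionally extended with a 'correct'
  predictor (binary or continuous) that absorbs the confounding
  influence of action values at trial start.
* **Lagged logistic regression** of choice on event types at multiple
  lags, separating strategies whose influence is confined to the
  previous trial from those with smoothly decaying influence.

All regressions are fitted per session by maximum likelihood
(statsmodels Logit); loadings are aggregated across sessions with mean,
SEM and a two-sided one-sample t-test against zero.  Sessions whose fit
is degenerate (perfect separation) fall back to a lightly
ridge-stabilised fit and are flagged in the result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .simulate import Session

ONE_BACK_PREDICTORS = ("stay", "outcome", "transition", "interaction",
                       "correct_binary", "correct_continuous")
EVENT_PREDICTORS = ("rewarded_common", "rewarded_rare",
                    "nonrewarded_common", "nonrewarded_rare")

#: the four predictors of the basic (uncorrected) one-trial-back model
BASIC_PREDICTORS = ("stay", "outcome", "transition", "interaction")

STAY_CELLS = (("common", "rewarded"), ("common", "non-rewarded"),
              ("rare", "rewarded"), ("rare", "non-rewarded"))


# ----------------------------------------------------------------------
# Stay probabilities
# ----------------------------------------------------------------------

@dataclass
class StayTable:
    """Stay probability per {common, rare} x {rewarded, non-rewarded} cell.

    ``per_session`` is a (n_sessions x 4) DataFrame whose columns follow
    ``STAY_CELLS``; ``mean`` and ``sem`` aggregate across sessions.
    """

    per_session: pd.DataFrame
    mean: pd.Series
    sem: pd.Series

    def interaction(self) -> pd.Series:
        """Per-session transition x outcome interaction:
        (stay | common, rewarded) - (stay | rare, rewarded)
        + (stay | rare, non-rewarded) - (stay | common, non-rewarded)."""
        p = self.per_session
        return (p[("common", "rewarded")] - p[("rare", "rewarded")]
                + p[("rare", "non-rewarded")] - p[("common", "non-rewarded")])


def stay_table(sessions: Sequence[Session]) -> StayTable:
    """Stay probabilities conditioned on the previous trial's transition
    and outcome, with mean and SEM across sessions.

    A session with an empty cell contributes NaN to that cell (excluded
    from the cross-session aggregate) and triggers a warning.
    """
    rows = []
    for i, sess in enumerate(sessions):
        if sess.n_trials < 2:
            raise ValueError("stay probabilities need at least 2 trials")
        stay = sess.stay
        prev_common = sess.common[:-1] == 1
        prev_rew = sess.outcome[:-1] == 1
        row = {}
        for cell in STAY_CELLS:
            mask = (prev_common if cell[0] == "common" else ~prev_common) & \
                   (prev_rew if cell[1] == "rewarded" else ~prev_rew)
            if mask.sum() == 0:
                warnings.warn(f"session {i}: no trials in stay cell {cell}; "
                              "session excluded from that cell")
                row[cell] = np.nan
            else:
                row[cell] = stay[mask].mean()
        rows.append(row)
    per_session = pd.DataFrame(rows, columns=pd.MultiIndex.from_tuples(STAY_CELLS))
    mean = per_session.mean(axis=0, skipna=True)
    n = per_session.notna().sum(axis=0)
    sem = per_session.std(axis=0, ddof=1, skipna=True) / np.sqrt(n)
    return StayTable(per_session, mean, sem)


# ----------------------------------------------------------------------
# Design matrices
# ----------------------------------------------------------------------

def _state_reward_probs(session: Session) -> np.ndarray:
    """Reward probability of each second-step state per trial (n x 2).

    On the original task the higher of the two action probabilities in a
    state is taken as the state's reward probability.
    """
    if session.task_config.n_second_actions == 1:
        return session.reward_probs[:, :, 0]
    return session.reward_probs.max(axis=2)


def build_design(session: Session,
                 predictors: Sequence[str] = BASIC_PREDICTORS,
                 ) -> Tuple[pd.DataFrame, np.ndarray]:
    """One-trial-back design matrix and stay/switch response.

    One row per trial from trial 2; predictor values are functions of
    trial t-1's events, coded as:

    * stay: +1 (overall staying tendency; acts as the intercept)
    * outcome: +0.5 rewarded / -0.5 non-rewarded
    * transition: +0.5 common / -0.5 rare
    * interaction: +0.5 for common-rewarded and rare-non-rewarded,
      -0.5 otherwise
    * correct_binary: +0.5 if the chosen action commonly led to the
      state with the higher reward probability, -0.5 if to the lower
      (0 at a tie)
    * correct_continuous: reward probability of the state commonly
      reached from the chosen action minus that of the state commonly
      reached from the not-chosen action
    * rewarded_common / rewarded_rare / nonrewarded_common /
      nonrewarded_rare: +0.5 when that event occurred, 0 otherwise
    """
    prev = slice(0, session.n_trials - 1)
    common = session.common[prev] == 1
    rew = session.outcome[prev] == 1
    y = sess_stay = session.stay

    need_probs = any(p.startswith("correct") for p in predictors)
    if need_probs:
        state_p = _state_reward_probs(session)[prev]
        chosen = session.choice1[prev]
        # common transition maps action i to state i
        p_chosen = state_p[np.arange(len(chosen)), chosen]
        p_other = state_p[np.arange(len(chosen)), 1 - chosen]

    cols: Dict[str, np.ndarray] = {}
    for name in predictors:
        if name == "stay":
            cols[name] = np.ones(len(y))
        elif name == "outcome":
            cols[name] = np.where(rew, 0.5, -0.5)
        elif name == "transition":
            cols[name] = np.where(common, 0.5, -0.5)
        elif name == "interaction":
            cols[name] = np.where(common == rew, 0.5, -0.5)
        elif name == "correct_binary":
            cols[name] = 0.5 * np.sign(p_chosen - p_other)
        elif name == "correct_continuous":
            cols[name] = p_chosen - p_other
        elif name == "rewarded_common":
            cols[name] = np.where(rew & common, 0.5, 0.0)
        elif name == "rewarded_rare":
            cols[name] = np.where(rew & ~common, 0.5, 0.0)
        elif name == "nonrewarded_common":
            cols[name] = np.where(~rew & common, 0.5, 0.0)
        elif name == "nonrewarded_rare":
            cols[name] = np.where(~rew & ~common, 0.5, 0.0)
        else:
            raise ValueError(f"unknown predictor {name!r}")
    return pd.DataFrame(cols), sess_stay.astype(float)


def build_lagged_design(session: Session, n_lags: int,
                        ) -> Tuple[pd.DataFrame, np.ndarray]:
    """Lagged design matrix and choice-identity response.

    The response is the first-step choice (1 = action A).  The predictor
    for event type e at lag k is the event indicator at trial t-k (coded
    +0.5/0) multiplied by the sign of the choice at t-k (A -> +1,
    B -> -1), so a positive loading means the event predicts repeating
    the choice made k trials earlier.  An intercept absorbs overall side
    bias.  Trials without a full lag history are dropped.
    """
    if n_lags < 1:
        raise ValueError("n_lags must be >= 1")
    n = session.n_trials
    if n <= n_lags:
        raise ValueError("session shorter than the requested lag depth")
    common = session.common == 1
    rew = session.outcome == 1
    choice_sign = np.where(session.choice1 == 0, 1.0, -1.0)
    events = {
        "rewarded_common": np.where(rew & common, 0.5, 0.0),
        "rewarded_rare": np.where(rew & ~common, 0.5, 0.0),
        "nonrewarded_common": np.where(~rew & common, 0.5, 0.0),
        "nonrewarded_rare": np.where(~rew & ~common, 0.5, 0.0),
    }
    t = np.arange(n_lags, n)
    cols: Dict[str, np.ndarray] = {"intercept": np.ones(len(t))}
    for k in range(1, n_lags + 1):
        for name in EVENT_PREDICTORS:
            cols[f"{name}_lag{k}"] = events[name][t - k] * choice_sign[t - k]
    y = (session.choice1[t] == 0).astype(float)
    return pd.DataFrame(cols), y


# ----------------------------------------------------------------------
# Logistic regression fitting
# ----------------------------------------------------------------------

RIDGE_PENALTY = 1e-4  # applied only when plain maximum likelihood degenerates


@dataclass
class RegressionResult:
    """Cross-session summary of per-session logistic regressions.

    ``loadings`` is (n_sessions x n_predictors); ``pvalues`` are
    two-sided one-sample t-tests of the per-session loadings against
    zero.  ``ridged_sessions`` lists sessions whose maximum-likelihood
    fit was degenerate and was ridge-stabilised.
    """

    predictors: List[str]
    loadings: pd.DataFrame
    mean: pd.Series
    sem: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    ridged_sessions: List[int] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "sem": self.sem,
                             "t": self.tvalues, "p": self.pvalues})


def _fit_logit(X: pd.DataFrame, y: np.ndarray) -> Tuple[np.ndarray, bool]:
    """Maximum-likelihood logistic fit; returns (coefs, ridged_flag).

    Falls back to a small L2 penalty when the ML fit separates or fails
    to converge (unbounded coefficients).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            if res.mle_retvals.get("converged", False) and \
                    np.all(np.abs(res.params) < 30):
                return np.asarray(res.params), False
        except Exception:
            pass
        # ridge-stabilised fallback
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit_regularized(
            alpha=RIDGE_PENALTY, L1_wt=0.0)
        return np.asarray(res.params), True


def _aggregate(loadings: np.ndarray, names: List[str],
               ridged: List[int]) -> RegressionResult:
    df = pd.DataFrame(loadings, columns=names)
    mean = df.mean(axis=0)
    sem = df.sem(axis=0, ddof=1)
    if len(df) > 1:
        t, p = stats.ttest_1samp(df.values, 0.0, axis=0)
    else:
        t = np.full(len(names), np.nan)
        p = np.full(len(names), np.nan)
    return RegressionResult(names, df, mean, sem,
                            pd.Series(t, index=names),
                            pd.Series(p, index=names), ridged)


def fit_choice_regression(sessions: Sequence[Session],
                          predictors: Sequence[str] = BASIC_PREDICTORS,
                          ) -> RegressionResult:
    """Per-session one-trial-back logistic regression of stay vs switch,
    aggregated across sessions."""
    names = list(predictors)
    loadings = np.empty((len(sessions), len(names)))
    ridged: List[int] = []
    for i, sess in enumerate(sessions):
        X, y = build_design(sess, names)
        coefs, was_ridged = _fit_logit(X, y)
        loadings[i] = coefs
        if was_ridged:
            ridged.append(i)
    if ridged:
        warnings.warn(f"ridge-stabilised fits used for sessions {ridged}")
    return _aggregate(loadings, names, ridged)


def fit_lagged_regression(sessions: Sequence[Session], n_lags: int = 12,
                          ) -> RegressionResult:
    """Per-session lagged logistic regression (4 event predictors per lag
    plus an intercept), aggregated across sessions."""
    names: Optional[List[str]] = None
    rows = []
    ridged: List[int] = []
    for i, sess in enumerate(sessions):
        X, y = build_lagged_design(sess, n_lags)
        if names is None:
            names = list(X.columns)
        coefs, was_ridged = _fit_logit(X, y)
        rows.append(coefs)
        if was_ridged:
            ridged.append(i)
    if ridged:
        warnings.warn(f"ridge-stabilised fits used for sessions {ridged}")
    return _aggregate(np.asarray(rows), names, ridged)


def lagged_loading_matrix(result: RegressionResult) -> pd.DataFrame:
    """Reshape a lagged-regression result to (lag x event type) means."""
    lags = sorted({int(name.rsplit("_lag", 1)[1])
                   for name in result.predictors if "_lag" in name})
    data = {ev: [result.mean[f"{ev}_lag{k}"] for k in lags]
            for ev in EVENT_PREDICTORS}
    return pd.DataFrame(data, index=pd.Index(lags, name="lag"))


# ----------------------------------------------------------------------
# Diagnostics
# ----------------------------------------------------------------------

@dataclass
class ValueTable:
    """Mean first-step action values at trial start for the chosen and
    not-chosen action, split by the trial's transition and outcome."""

    chosen: pd.DataFrame       # sessions x 4 cells
    not_chosen: pd.DataFrame
    mean: pd.DataFrame         # rows: cells; columns: chosen/not_chosen/diff
    sem: pd.DataFrame

    def per_session_diff(self) -> pd.DataFrame:
        return self.chosen - self.not_chosen


_Q_AGENTS = ("q_lambda", "model_based")


def trial_start_value_table(sessions: Sequence[Session]) -> ValueTable:
    """Mean Q(chosen) and Q(not chosen) at trial start per
    {transition x outcome} cell, with cross-session SEM.

    Requires sessions simulated from an agent with first-step action
    values (Q(lambda) or model-based).
    """
    chosen_rows, not_chosen_rows = [], []
    for sess in sessions:
        if sess.meta.get("agent") not in _Q_AGENTS:
            raise ValueError(
                "trial-start value table requires sessions from an agent "
                f"with first-step action values {_Q_AGENTS}, got "
                f"{sess.meta.get('agent')!r}")
        q_chosen = sess.q1_pre[np.arange(sess.n_trials), sess.choice1]
        q_other = sess.q1_pre[np.arange(sess.n_trials), 1 - sess.choice1]
        common = sess.common == 1
        rew = sess.outcome == 1
        c_row, n_row = {}, {}
        for cell in STAY_CELLS:
            mask = (common if cell[0] == "common" else ~common) & \
                   (rew if cell[1] == "rewarded" else ~rew)
            c_row[cell] = q_chosen[mask].mean() if mask.any() else np.nan
            n_row[cell] = q_other[mask].mean() if mask.any() else np.nan
        chosen_rows.append(c_row)
        not_chosen_rows.append(n_row)
    cols = pd.MultiIndex.from_tuples(STAY_CELLS)
    chosen = pd.DataFrame(chosen_rows, columns=cols)
    not_chosen = pd.DataFrame(not_chosen_rows, columns=cols)
    diff = chosen - not_chosen
    mean = pd.DataFrame({"chosen": chosen.mean(), "not_chosen": not_chosen.mean(),
                         "diff": diff.mean()})
    sem = pd.DataFrame({"chosen": chosen.sem(), "not_chosen": not_chosen.sem(),
                        "diff": diff.sem()})
    return ValueTable(chosen, not_chosen, mean, sem)


def predictor_correlation(sessions: Sequence[Session],
                          predictors: Sequence[str],
                          pooled: bool = True) -> pd.DataFrame:
    """Pearson correlation between predictors across trials.

    With ``pooled=True`` trials from all sessions are concatenated;
    otherwise per-session correlation matrices are averaged.  Constant
    predictors yield NaN correlations (reported with a warning).
    """
    designs = [build_design(s, predictors)[0] for s in sessions]
    names = list(predictors)

    def _corr(X: pd.DataFrame) -> np.ndarray:
        values = X.values
        sd = values.std(axis=0)
        if np.any(sd == 0):
            constant = [names[j] for j in np.flatnonzero(sd == 0)]
            warnings.warn(f"constant predictor(s) {constant}: correlation "
                          "undefined, reported as NaN")
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.corrcoef(values, rowvar=False)

    if pooled:
        corr = _corr(pd.concat(designs, axis=0, ignore_index=True))
    else:
        corr = np.nanmean([_corr(X) for X in designs], axis=0)
    return pd.DataFrame(corr, index=names, columns=names)
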