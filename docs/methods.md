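# Methods

## Task models

Both task variants share the transition structure: first-step action
i ∈ {A, B} leads to second-step state i ("common", probability
p_common) or to the other state ("rare", 1 − p_common).

* **Original task** — p_common = 0.7; two actions per second-step
  state; the four reward probabilities evolve as independent reflecting
  Gaussian random walks on [0.25, 0.75] with per-trial step SD 0.025.
* **Reduced task** — p_common = 0.8; one action per second-step state;
  reward probabilities 0.8/0.2 in states a/b, reversing every 50 trials.
  Variants: reflecting walks on [0, 1] with step SD 0.1, or static
  probabilities (0.8/0.2 or 0.5/0.5).

Reflection folds an overshooting proposal back into the interval
(x → 2·hi − x or 2·lo − x, applied repeatedly); the stationary
distribution of the walk is uniform on its bounds, which the tests
check against the folded free-walk construction. Walk steps for the
different second-step actions are mutually independent. Reward
probabilities advance at trial end: trial t's outcome uses the
probabilities in force at trial t. At session start, block tasks draw
the identity of the first good state at random (so sessions are
exchangeable) and walk tasks draw each probability uniformly within its
bounds.

## Agents

All value updates are convex combinations of quantities in [0, 1], so
values initialised at 0.5 (the chance reward rate, unbiased between
actions) remain in [0, 1]. Choice is softmax with inverse temperature
T, computed overflow-safely; T = 0 gives uniform choice. Updates are
applied sequentially at trial end.

* **Q(λ)**: Q(s1,a1) ← (1−α) Q(s1,a1) + α (Q(s2,a2) + λ (r − Q(s2,a2))),
  then Q(s2,a2) ← (1−α) Q(s2,a2) + α r. The first-step update uses the
  pre-update second-step value. λ = 1 and λ = 0 give the outcome-driven
  and value-driven endpoints. On the original task a single (α, T)
  serves both steps.
* **Model-based**: Q(s1,a_i) = Σ_j P(s_j|a_i) V(s_j), recomputed at
  each trial start; V is the single second-step action value (reduced)
  or the maximum of the two (original). P is the true transition matrix,
  or learned online, P̂(x|a1) ← (1−η) P̂(x|a1) + η X, initialised
  uniform (0.5/0.5) — only the chosen action's row updates.
* **Perseveration**: an additive bias p on the previously chosen
  first-step action, applied inside the softmax only; it never enters
  value updates.
* **Reward-as-cue**: the first-step choice is made in one of four cue
  states given by the previous trial's (outcome, second-step state);
  values per cue state update by (1−α) Q + α r. Trial 1 has no cue: the
  choice is uniform and no first-step update is made for that trial.
  On the original task, second-step values learn with separate
  (α₂, T₂).
* **Latent-state**: posterior P(a is the good state) starts at 0.5.
  After each trial, a Bayesian evidence step uses the outcome likelihood
  given the reached state (P(r | s2 = a, a-good) = p_good, etc.; the
  transition probability is independent of the latent state and
  cancels), followed by reversal mixing
  posterior ← (1−ω) posterior + ω (1−posterior) — in that order.
  Believed probabilities are 0.8/0.2 on the reduced task and
  0.625/0.375 (the walk range's 75th/25th percentiles) on the original
  task. Choice: the action favoured by the more probable state with
  probability 1 − ε; exact posterior ties give 0.5. On the original
  task second-step choices use softmax Q-learning with (α, T).

## Engine

Per-trial dynamics are compiled with numba; the same step functions
drive session simulation, the reward-rate objective and likelihood
replay, so recorded choice probabilities, objective values and
likelihoods come from one code path. The pure-Python agent classes
implement the identical arithmetic and are verified against the kernels
by replaying recorded sessions (agreement within 1e-9; the compiled and
interpreted exponentials may differ in the last ulp). All randomness
flows through a single per-session stream seeded explicitly; batch
runs derive distinct per-session seeds from a master seed.

## Analyses

One-trial-back logistic regression predicts stay (= repeating the
first-step choice) from the previous trial's events, coded: stay +1
(intercept), outcome ±0.5, transition ±0.5, interaction ±0.5
(+ for common-rewarded and rare-non-rewarded), correct-binary ±0.5
(sign of the difference between the reward probability of the state
commonly reached from the chosen action and that of the other state;
0 at a tie), correct-continuous (that difference itself), and the four
event indicators (+0.5 / 0). On the original task a state's reward
probability is the higher of its two action probabilities. Fits are
per-session maximum likelihood (statsmodels Logit); aggregation across
sessions uses mean, SEM and a two-sided one-sample t-test. A session
whose ML fit separates or diverges is ridge-stabilised (L2 penalty
1e-4) and flagged in the result.

The lagged regression predicts choice identity (A vs B). The predictor
for event type e at lag k is the event indicator at t−k (coded +0.5/0)
times the sign of the choice at t−k (A → +1, B → −1), with an intercept
absorbing side bias, so a positive loading means the event predicts
repeating the choice made k trials earlier. Trials without a full lag
history are dropped. The default lag depth is 12 (configurable); the
acceptance checks use 5 lags, which suffices to expose the decay
patterns. This encoding is one natural reading of the lagged analysis;
it is not claimed to be bit-identical to any other implementation.

## Model fitting

The likelihood of a session under an agent evolves the agent's state
along the recorded events and sums log probabilities of the recorded
choices — both steps per trial on the original task, the first step
only on the reduced task. Optimisation is Powell's method over
transformed parameters (logit for unit-interval parameters, log for
inverse temperatures), best of 10 random restarts. Restart initial
points are drawn on the natural scale: learning rates uniform on
(0.05, 0.95), temperatures uniform on (0.5, 10), reversal rates ω
log-uniform on (1e-3, 0.5) and lapse rates ε uniform on (0.02, 0.45) —
the latent-state likelihood has a mirror basin at ε > 0.5 (inverted
policy) that traps local optimisers started there. λ is fixed per
Q-family, not estimated, so every reduced-task family has two free
parameters and raw likelihoods are directly comparable; BIC
(k ln n − 2 LL, n = number of modelled choices) is also reported.
Cross-fitting fits each family jointly to all sessions of each
generator and compares fitters by paired t-tests on per-session
log-likelihoods.

## Reward-rate optimisation

Protocol per evaluation session (10 per agent): Powell optimisation of
the reward fraction of a simulation whose seed is fixed within the run
(common random numbers), 10 random restarts; the chosen parameters are
then evaluated once on a fresh seed, and the mean ± SEM over the 10
fresh-seed sessions of 10000 trials is reported. Two numerical choices
matter because the objective is a noisy function of the parameters:
the optimisation simulation is 30000 trials (3× an evaluation session),
and the best restart is selected by re-evaluating each restart's
solution on a separate validation seed rather than by its
optimisation-seed value. Without these, the search selects spurious
noise peaks of one event sequence (a winner's curse over thousands of
objective evaluations) and fresh-seed performance drops by ~0.005.
Powell runs with xtol 1e-2 / ftol 1e-3, matching the objective's
resolution (1/n_trials). Optimisation bounds are enforced by
transforms: unit-interval parameters via logit, temperatures as
T = 50·sigmoid(x). A brute-force grid search over the two natural
parameters provides an independent cross-check for two-parameter
agents. The deterministic reward-as-cue strategy is evaluated directly
(no parameters); its expected reward on fixed-probability tasks has a
closed form via the stationary distribution of the 4-state cue chain,
used as a test oracle.

## Problem sizes

Simulated experiments use 10 sessions of 10000 trials per agent and
condition; all trials enter the analyses. The acceptance script runs
the four performance optimisations, one regression comparison and two
maximum-likelihood fits at this scale (a few minutes on one CPU).

## What the synthetic data does and does not capture

Sessions are generated by the same stationary processes the agents are
analysed against: no satiety or motivation drift, no reaction times, no
session boundaries within a batch, no forgetting between sessions, and
subjects are single agents rather than mixtures of strategies. Passing
tests therefore demonstrate properties of the analysis pipeline and of
the agent models — e.g. that the corrected regression removes the
trial-start value confound for data generated by these agents — not
that real subjects' strategies are identifiable under the same
conditions.

## Known limitations

* The optimised reduced-task model-based reward fraction plateaus at
  ~0.638 ± 0.002 over a dense (α, T) scan (T up to 1000). This is an
  inherent ceiling of the exponential-moving-average value update: the
  Bayes-updating latent-state agent reaches ~0.646 on the same
  environment, and diagnostic variants with counterfactual or
  forgetting updates fall in between. Published figures for this
  quantity that exceed the ceiling are not reproducible from the update
  equations implemented here.
* Relatedly, the reversal rate ω recovered by fitting the latent-state
  agent to model-based data is ~0.037, slightly above the environment's
  true 0.02-per-trial scale and sensitive to the exact switching noise
  of the generating agent.
* The reward-as-cue likelihood is nearly flat along (α, T) ridges when
  the fitted α is very small (the policy depends mainly on their
  product), so those two parameters are individually poorly identified
  even though the fitted likelihood is stable.
* Lagged-regression loadings at different lags are correlated
  predictors of the same choices; their SEMs are cross-session only and
  should not be read as independent errors.
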