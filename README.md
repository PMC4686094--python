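# twostep

Simulation and analysis of the **two-step decision task**, the
behavioural paradigm used to dissociate model-based from model-free
reinforcement learning. The package is aimed at computational and
behavioural neuroscientists who design two-step task variants (in
particular high-contrast versions for animal subjects) and need to know
when their analyses can be fooled.

On each trial a first-step choice between actions A and B leads
probabilistically to one of two second-step states a or b (action A
commonly leads to state a, action B to state b; rare transitions invert
the mapping), where reward is delivered with slowly changing
probability. A model-free learner updates the chosen action's value
from the trial outcome, so reward promotes staying regardless of the
transition. A model-based learner evaluates first-step actions
prospectively,

    Q(s1, a_i) = Σ_j P(s_j | a_i) V(s_j),

so a reward obtained after a *rare* transition makes it *switch* — the
classic transition × outcome interaction read out from stay
probabilities, trial-by-trial logistic regression, or likelihood-based
model comparison.

The package implements two task variants (the original walk-based task,
p_common = 0.7, and a reduced high-contrast variant, p_common = 0.8,
one second-step action per state, reward probabilities 0.8/0.2
alternating in 50-trial blocks) and five agent families:

| agent | policy / update |
|---|---|
| `q_lambda` (`q0`, `q1`) | softmax on learned first-step values; eligibility trace λ interpolates between outcome-driven (λ=1) and second-step-value-driven (λ=0) updates |
| `model_based` | prospective evaluation with the true (or η-learned) transition matrix |
| `reward_as_cue` | model-free learning in an extended state space where the previous trial's (outcome, second-step state) pair is the decision state |
| `latent_state` | Bayesian inference of which state currently has high reward probability (reversal rate ω), fixed belief-to-action mapping with lapse ε |
| `deterministic_reward_as_cue` | the fixed cue-response mapping (reward in a → A, reward in b → B, non-reward in a → B, non-reward in b → A) |

With these it reproduces, from a single command each, the package's
headline results: the spurious transition-outcome interaction shown by
the purely model-free Q(1) agent on the reduced task, its correction by
a "correct" regression predictor, the signatures by which lagged
regression and likelihood cross-fitting separate the strategies, and
reward-rate optimisation showing which strategies are worth their
computational cost on each task variant.

## Worked example

Simulate the Q(1) agent at the reference parameters on the reduced task
and run the one-trial-back logistic regression of stay vs switch:

```bash
twostep simulate --agent q1 -p alpha=0.334 -p T=3.22 --task reduced \
    --n-sessions 10 --n-trials 10000 --seed 0 --out q1_sessions.tsv
twostep analyse --input q1_sessions.tsv --analysis regression
```

```
        mean      sem        t        p
stay         0.615    0.011    57.1   7.7e-13
outcome      0.917    0.014    66.6   2.0e-13
transition   0.026    0.011     2.5   3.6e-02
interaction  0.563    0.016    35.5   5.6e-11
```

Although this agent ignores transitions by construction, its
interaction loading (0.56) is massively significant — correlations
between trial-start action values and subsequent trial events masquerade
as model-based behaviour. Adding the binary correct predictor
(`--analysis regression-corrected`) absorbs the confound:

```
        mean      sem        t        p
stay         0.511    0.008    67.8   1.7e-13
outcome      0.948    0.014    66.6   2.0e-13
transition   0.016    0.012     1.3   2.1e-01
interaction -0.004    0.016    -0.2   8.2e-01
correct_binary 1.020  0.025    41.1   1.5e-11
```

The interaction collapses to −0.004 (p = 0.82), correctly revealing a
purely outcome-driven strategy. The same sessions' stay probabilities
(`--analysis stay`: 0.797 / 0.472 / 0.685 / 0.604 for common-rewarded /
common-non-rewarded / rare-rewarded / rare-non-rewarded) show the
interaction pattern that would classically be read as model-based.

The same analyses are available as library functions
(`twostep.fit_choice_regression`, `twostep.stay_table`,
`twostep.fit_lagged_regression`, `twostep.fit_ml`,
`twostep.cross_fit_matrix`, `twostep.optimise_performance`), and named
end-to-end recipes regenerate whole result tables:

```bash
twostep reproduce confound_correction --seed 0 --out-dir results/
```

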