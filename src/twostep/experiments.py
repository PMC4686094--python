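"""Named experiment recipes regenerating the package's headline results.

Each experiment is a self-contained pipeline — simulate the relevant
agents, run the analyses, write tab-separated tables — addressable by
name from the command line (``twostep reproduce <name>``).  Outputs are
accompanied by a provenance manifest (config hash, seeds, problem sizes)
sufficient to re-derive any number in the tables.

Default problem sizes follow the study conditions (10 sessions of 10000
trials per agent); ``n_sessions``/``n_trials`` can be scaled down for
quick runs, which is recorded in the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Callable, Dict, List

import numpy as np
import pandas as pd

from .agents import make_agent
from .choice_analysis import (BASIC_PREDICTORS, fit_choice_regression,
                              fit_lagged_regression, predictor_correlation,
                              stay_table, trial_start_value_table)
from .model_fitting import REDUCED_FITTERS, cross_fit_matrix, fit_ml
from .performance_opt import (deterministic_reward_as_cue_performance,
                              optimise_performance)
from .simulate import run_batch
from .task_env import TaskConfig

logger = logging.getLogger("twostep")

#: generating parameters of the model-based reference agent
MB_PARAMS = {"alpha": 0.5, "T": 5.0}

CORRECTED_PREDICTORS = list(BASIC_PREDICTORS) + ["correct_binary"]
CONTINUOUS_PREDICTORS = list(BASIC_PREDICTORS) + ["correct_continuous"]


def _write(df: pd.DataFrame, out_dir: Path, name: str) -> str:
    path = out_dir / f"{name}.tsv"
    df.to_csv(path, sep="\t")
    logger.info("wrote %s", path)
    return path.name


def _stay_frame(table) -> pd.DataFrame:
    return pd.DataFrame({"stay_prob": table.mean, "sem": table.sem})


def _mb_reference_sessions(task: TaskConfig, n_sessions, n_trials, seed):
    agent = make_agent("model_based", **MB_PARAMS)
    return run_batch(agent, task, n_sessions, n_trials, seed=seed)


def _fitted_agents(task: TaskConfig, n_sessions, n_trials, seed,
                   n_restarts=10):
    """The five agent families with parameters set, as in the reference
    protocol, by maximum-likelihood fit to model-based-agent data."""
    mb_sessions = _mb_reference_sessions(task, n_sessions, n_trials, seed)
    agents = {"model_based": make_agent("model_based", **MB_PARAMS)}
    rng = np.random.default_rng(seed + 1)
    for name in ("q0", "q1", "reward_as_cue", "latent_state"):
        fit = fit_ml(name, mb_sessions, n_restarts=n_restarts,
                     seed=int(rng.integers(2 ** 31)))
        agents[name] = make_agent(name, **fit.params)
        logger.info("fitted %s: %s", name,
                    {k: round(v, 4) for k, v in fit.params.items()})
    return agents


# ----------------------------------------------------------------------
# Experiment implementations
# ----------------------------------------------------------------------

def exp_stay_probability(out_dir: Path, seed: int, n_sessions: int,
                         n_trials: int, **_) -> List[str]:
    """Stay-probability tables for Q(1) and model-based agents on both
    task variants (the classic dissociation and its failure on the
    reduced task)."""
    outputs = []
    combos = [
        ("q1_original", make_agent("q1", alpha=0.5, T=5.0),
         TaskConfig.original()),
        ("mb_original", make_agent("model_based", **MB_PARAMS),
         TaskConfig.original()),
        ("q1_reduced", make_agent("q1", alpha=0.334, T=3.22),
         TaskConfig.reduced()),
        ("mb_reduced", make_agent("model_based", **MB_PARAMS),
         TaskConfig.reduced()),
    ]
    for label, agent, task in combos:
        sessions = run_batch(agent, task, n_sessions, n_trials, seed=seed)
        outputs.append(_write(_stay_frame(stay_table(sessions)), out_dir,
                              f"stay_{label}"))
    return outputs


def exp_confound_correction(out_dir: Path, seed: int, n_sessions: int,
                            n_trials: int, **_) -> List[str]:
    """The trial-start action-value confound and its regression
    correction for the Q(1) agent on the reduced task."""
    agent = make_agent("q1", alpha=0.334, T=3.22)
    sessions = run_batch(agent, TaskConfig.reduced(), n_sessions, n_trials,
                         seed=seed)
    outputs = [
        _write(fit_choice_regression(sessions).to_frame(), out_dir,
               "q1_regression_basic"),
        _write(fit_choice_regression(sessions, CORRECTED_PREDICTORS
                                     ).to_frame(),
               out_dir, "q1_regression_corrected"),
        _write(trial_start_value_table(sessions).mean, out_dir,
               "q1_trial_start_values"),
        _write(predictor_correlation(sessions,
                                     CORRECTED_PREDICTORS[1:]),
               out_dir, "q1_predictor_correlation"),
    ]
    return outputs


def exp_walk_correction(out_dir: Path, seed: int, n_sessions: int,
                        n_trials: int, **_) -> List[str]:
    """Residual confound under random-walk reward probabilities: the
    binary correct predictor under-corrects, the continuous one does
    not."""
    agent = make_agent("q1", alpha=0.334, T=3.22)
    sessions = run_batch(agent, TaskConfig.reduced_walk(), n_sessions,
                         n_trials, seed=seed)
    return [
        _write(fit_choice_regression(sessions).to_frame(), out_dir,
               "walk_regression_basic"),
        _write(fit_choice_regression(sessions, CORRECTED_PREDICTORS
                                     ).to_frame(),
               out_dir, "walk_regression_binary"),
        _write(fit_choice_regression(sessions, CONTINUOUS_PREDICTORS
                                     ).to_frame(),
               out_dir, "walk_regression_continuous"),
    ]


def exp_agent_comparison(out_dir: Path, seed: int, n_sessions: int,
                         n_trials: int, task: str = "reduced",
                         n_lags: int = 12, n_restarts: int = 10,
                         **_) -> List[str]:
    """Five agents x four analyses (stay table, basic and corrected
    regression, lagged regression), with non-reference agents'
    parameters fitted to model-based data."""
    task_config = (TaskConfig.reduced() if task == "reduced"
                   else TaskConfig.original())
    agents = _fitted_agents(task_config, n_sessions, n_trials, seed,
                            n_restarts)
    outputs = []
    for i, (name, agent) in enumerate(agents.items()):
        sessions = run_batch(agent, task_config, n_sessions, n_trials,
                             seed=seed + 101 + i)
        outputs.append(_write(_stay_frame(stay_table(sessions)), out_dir,
                              f"{name}_stay"))
        outputs.append(_write(fit_choice_regression(sessions).to_frame(),
                              out_dir, f"{name}_regression_basic"))
        outputs.append(_write(
            fit_choice_regression(sessions, CORRECTED_PREDICTORS).to_frame(),
            out_dir, f"{name}_regression_corrected"))
        outputs.append(_write(
            fit_lagged_regression(sessions, n_lags=n_lags).to_frame(),
            out_dir, f"{name}_regression_lagged"))
    return outputs


def exp_performance(out_dir: Path, seed: int, n_sessions: int,
                    n_trials: int, n_restarts: int = 10, **_) -> List[str]:
    """Optimised reward rates for all agents on both task variants."""
    outputs = []
    for task_name, task in [("original", TaskConfig.original()),
                            ("reduced", TaskConfig.reduced())]:
        rows = []
        agent_names = ["q0", "q1", "model_based", "latent_state"]
        if task_name == "original":
            agent_names.append("random_first_step")
        for name in agent_names:
            res = optimise_performance(name, task, n_restarts=n_restarts,
                                       n_sessions=n_sessions,
                                       n_trials=n_trials, seed=seed)
            rows.append({"agent": name, "reward_fraction": res.mean,
                         "sem": res.sem})
            logger.info("%s %s: %.4f +- %.4f", task_name, name, res.mean,
                        res.sem)
        det = deterministic_reward_as_cue_performance(
            task, n_sessions=n_sessions, n_trials=n_trials, seed=seed)
        rows.append({"agent": det.agent, "reward_fraction": det.mean,
                     "sem": det.sem})
        outputs.append(_write(pd.DataFrame(rows).set_index("agent"), out_dir,
                              f"performance_{task_name}"))
    return outputs


def exp_crossfit(out_dir: Path, seed: int, n_sessions: int, n_trials: int,
                 task: str = "reduced", n_restarts: int = 10,
                 **_) -> List[str]:
    """Likelihood matrix: every family fitted to data simulated from
    every family (parameters of generators fitted to model-based data
    first, as in the reference protocol)."""
    task_config = (TaskConfig.reduced() if task == "reduced"
                   else TaskConfig.original())
    agents = _fitted_agents(task_config, n_sessions, n_trials, seed,
                            n_restarts)
    datasets = {name: run_batch(agent, task_config, n_sessions, n_trials,
                                seed=seed + 13 + i)
                for i, (name, agent) in enumerate(agents.items())}
    result = cross_fit_matrix(datasets, REDUCED_FITTERS,
                              n_restarts=n_restarts, seed=seed)
    return [
        _write(result.mean_loglik, out_dir, f"crossfit_loglik_{task}"),
        _write(result.sem_loglik, out_dir, f"crossfit_loglik_sem_{task}"),
        _write(result.bic, out_dir, f"crossfit_bic_{task}"),
    ]


def exp_parameter_table(out_dir: Path, seed: int, n_sessions: int,
                        n_trials: int, n_restarts: int = 10,
                        **_) -> List[str]:
    """Maximum-likelihood parameters of each family fitted to
    model-based-agent data on both task variants."""
    outputs = []
    for task_name, task in [("reduced", TaskConfig.reduced()),
                            ("original", TaskConfig.original())]:
        mb_sessions = _mb_reference_sessions(task, n_sessions, n_trials,
                                             seed)
        rows = []
        rng = np.random.default_rng(seed)
        for name in ("q0", "q1", "reward_as_cue", "latent_state"):
            fit = fit_ml(name, mb_sessions, n_restarts=n_restarts,
                         seed=int(rng.integers(2 ** 31)))
            row = {"agent": name, "loglik": fit.log_likelihood,
                   "bic": fit.bic}
            row.update(fit.params)
            rows.append(row)
        outputs.append(_write(pd.DataFrame(rows).set_index("agent"), out_dir,
                              f"ml_parameters_{task_name}"))
    return outputs


EXPERIMENTS: Dict[str, Callable] = {
    "stay_probability": exp_stay_probability,
    "confound_correction": exp_confound_correction,
    "walk_correction": exp_walk_correction,
    "agent_comparison_reduced": exp_agent_comparison,
    "performance": exp_performance,
    "crossfit_reduced": exp_crossfit,
    "parameter_table": exp_parameter_table,
}


def run_experiment(name: str, out_dir, seed: int = 0, n_sessions: int = 10,
                   n_trials: int = 10000, **options) -> Dict:
    """Run a named experiment and write its tables plus a provenance
    manifest to ``out_dir``.  Re-running with the same seed reproduces
    identical tables."""
    if name not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {name!r}; "
                         f"known: {sorted(EXPERIMENTS)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = {"experiment": name, "seed": seed, "n_sessions": n_sessions,
              "n_trials": n_trials, **options}
    config_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]
    logger.info("running experiment %s (config hash %s)", name, config_hash)
    outputs = EXPERIMENTS[name](out_dir=out_dir, seed=seed,
                                n_sessions=n_sessions, n_trials=n_trials,
                                **options)
    manifest = {**config, "config_hash": config_hash, "outputs": outputs}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
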