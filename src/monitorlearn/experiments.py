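"""Simulation harnesses for the model-level results.

Regenerates, as tidy summary tables: the three-variant learning-curve
comparison, the confidence-calibration sweep, the confidence-conditional
coupling between predicted and actual outcomes, and the Shannon-surprise
grid over sensory prediction error and predictive precision.

Variant and calibration comparisons run under common random numbers: agent
``k`` uses the same seed (hence the same response-noise, noise-level,
efference-copy and calibration streams) in every arm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from monitorlearn.bayes_learner import (
    VARIANTS,
    AgentConfig,
    run_agent,
    trajectory_frame,
)
from monitorlearn.task_model import TaskConfig

__all__ = [
    "SimulationSummary",
    "SurpriseGrid",
    "run_model_comparison",
    "run_cc_sweep",
    "prediction_feedback_coupling",
    "shannon_surprise_grid",
]


@dataclass
class SimulationSummary:
    """Trial-wise error summary plus the pooled trial-level trajectories.

    ``curves`` has one row per (arm, trial) with mean/SEM of target and
    scale error across agents; ``trajectories`` holds every simulated trial
    (columns from :func:`monitorlearn.bayes_learner.trajectory_frame` plus
    ``agent`` and the arm label).
    """

    curves: pd.DataFrame
    trajectories: pd.DataFrame
    arm: str  # name of the arm column: "variant" or "cc"


def _agent_seeds(n_agents: int, seed: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n_agents)


def _summarize(traj: pd.DataFrame, arm: str) -> pd.DataFrame:
    grouped = traj.groupby([arm, "trial"])
    curves = grouped.agg(
        target_error_mean=("target_error", "mean"),
        scale_error_mean=("scale_error", "mean"),
        n_agents=("target_error", "size"),
    ).reset_index()
    if traj["agent"].nunique() >= 2:
        sems = grouped.agg(
            target_error_sem=("target_error", "sem"),
            scale_error_sem=("scale_error", "sem"),
        ).reset_index(drop=True)
        curves = pd.concat([curves, sems], axis=1)
    else:
        warnings.warn("single agent: SEM undefined, omitted", stacklevel=3)
    return curves


def _run_arms(
    arms: dict[str, AgentConfig], n_agents: int, task: TaskConfig, seed: int, arm: str
) -> SimulationSummary:
    seeds = _agent_seeds(n_agents, seed)
    frames = []
    for label, base in arms.items():
        for k in range(n_agents):
            agent = replace(base, rng_seed=int(seeds[k]))
            frames.append(
                trajectory_frame(run_agent(agent, task), agent=k, **{arm: label})
            )
    traj = pd.concat(frames, ignore_index=True)
    return SimulationSummary(_summarize(traj, arm), traj, arm)


def run_model_comparison(
    n_agents: int = 200,
    task: TaskConfig | None = None,
    seed: int = 0,
    cc: float = 1.0,
) -> SimulationSummary:
    """Run the three model variants under common random numbers.

    The full variant uses calibration ``cc`` (default perfectly
    calibrated); the reduced variants have no calibration parameter.
    """
    if n_agents < 1:
        raise ValueError("n_agents must be >= 1")
    task = task or TaskConfig()
    arms = {v: AgentConfig(variant=v, cc=cc) for v in VARIANTS}
    return _run_arms(arms, n_agents, task, seed, "variant")


def run_cc_sweep(
    cc_levels: tuple[float, ...] = (0.0, 0.75, 1.0),
    n_agents: int = 200,
    task: TaskConfig | None = None,
    seed: int = 0,
) -> SimulationSummary:
    """Full-variant runs at each calibration level, common random numbers."""
    if n_agents < 1:
        raise ValueError("n_agents must be >= 1")
    task = task or TaskConfig()
    arms = {f"{cc:g}": AgentConfig(variant="full", cc=cc) for cc in cc_levels}
    summary = _run_arms(arms, n_agents, task, seed, "cc")
    summary.trajectories["cc"] = summary.trajectories["cc"].astype(float)
    summary.curves["cc"] = summary.curves["cc"].astype(float)
    return summary


def prediction_feedback_coupling(
    trajectories: pd.DataFrame, min_trials: int = 3
) -> pd.DataFrame:
    """OLS slope of feedback on predicted outcome per confidence stratum.

    Returns one row per confidence level with ``slope``, ``stderr`` and
    ``n``.  Strata with fewer than ``min_trials`` trials are omitted with a
    warning.
    """
    required = {"po", "f", "co"}
    missing = required - set(trajectories.columns)
    if missing:
        raise ValueError(f"trajectories missing columns: {sorted(missing)}")
    rows = []
    valid = trajectories.dropna(subset=["po", "f", "co"])
    for co, sub in valid.groupby("co"):
        if len(sub) < min_trials:
            warnings.warn(
                f"confidence stratum co={co}: only {len(sub)} trials, slope omitted",
                stacklevel=2,
            )
            continue
        res = stats.linregress(sub["po"], sub["f"])
        rows.append(
            {"co": co, "slope": res.slope, "stderr": res.stderr, "n": len(sub)}
        )
    return pd.DataFrame(rows)


@dataclass
class SurpriseGrid:
    """Shannon information of outcomes under Gaussian predictive beliefs.

    ``surprise[j, k]`` is the surprise of a sensory prediction error
    ``spe_values[j]`` under a zero-mean Gaussian predictive distribution
    with SD ``sigma_values[k]``.  Marginals are means along each axis.
    """

    spe_values: np.ndarray
    sigma_values: np.ndarray
    surprise: np.ndarray
    spe_marginal: np.ndarray  # mean over sigma, per spe
    sigma_marginal: np.ndarray  # mean over spe, per sigma


def shannon_surprise_grid(
    spe_values: np.ndarray | None = None,
    sigma_values: np.ndarray | None = None,
) -> SurpriseGrid:
    """Surprise(-log predictive density) over an SPE x precision grid.

    Defaults: SPE from 0 to 500 and SDs matching the agent's three
    efference-copy noise levels projected on the feedback scale.
    """
    if spe_values is None:
        spe_values = np.linspace(0.0, 500.0, 101)
    if sigma_values is None:
        sigma_values = np.array([5.0, 10.0, 20.0]) * 9.0
    spe_values = np.asarray(spe_values, dtype=float)
    sigma_values = np.asarray(sigma_values, dtype=float)
    if np.any(sigma_values <= 0):
        raise ValueError("predictive SDs must be > 0")
    surprise = -stats.norm.logpdf(
        spe_values[:, None], loc=0.0, scale=sigma_values[None, :]
    )
    return SurpriseGrid(
        spe_values=spe_values,
        sigma_values=sigma_values,
        surprise=surprise,
        spe_marginal=surprise.mean(axis=1),
        sigma_marginal=surprise.mean(axis=0),
    )
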