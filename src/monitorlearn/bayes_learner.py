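"""Bayesian learner with performance monitoring and its reduced variants.

The agent infers the hidden target interval ``t`` and feedback scale ``s``
by grid approximation.  Each trial it forms an intended response from its
current belief, executes it with motor noise, observes a noisy efference
copy, reports an outcome prediction and a confidence level, and updates its
belief from the feedback.  The update fuses the intended response and the
efference copy by precision weighting; how well the agent knows the
trial-wise efference-copy precision is governed by its confidence
calibration ``cc`` and by the model variant:

``full``
    uses the (possibly miscalibrated) trial-wise noise level,
``average_confidence``
    always assumes the average noise level (no trial-wise insight),
``feedback_only``
    ignores the efference copy entirely and learns from feedback given the
    intended response alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from monitorlearn.task_model import (
    TaskConfig,
    generate_feedback,
    sample_efference_copy,
    sample_response,
    sample_sigma_c_level,
)

__all__ = [
    "VARIANTS",
    "PosteriorGrid",
    "AgentConfig",
    "TrialOutput",
    "DegenerateUpdateError",
    "init_prior",
    "intended_response",
    "expected_scale",
    "subjective_sigma_c",
    "confidence_report",
    "predicted_outcome",
    "fuse",
    "likelihood_over_grid",
    "update_posterior",
    "run_trial",
    "run_agent",
    "trajectory_frame",
]

VARIANTS = ("full", "average_confidence", "feedback_only")

_NORM_TOL = 1e-9


class DegenerateUpdateError(RuntimeError):
    """Raised when a posterior update underflows to an all-zero grid."""


@dataclass
class PosteriorGrid:
    """Joint belief over (target interval t, feedback scale s) on a grid.

    ``prob`` holds nonnegative cell weights of shape
    ``(len(t_values), len(s_values))`` summing to 1.
    """

    t_values: np.ndarray
    s_values: np.ndarray
    prob: np.ndarray

    def __post_init__(self) -> None:
        self.t_values = np.asarray(self.t_values, dtype=float)
        self.s_values = np.asarray(self.s_values, dtype=float)
        self.prob = np.asarray(self.prob, dtype=float)
        if self.prob.shape != (self.t_values.size, self.s_values.size):
            raise ValueError(
                f"prob shape {self.prob.shape} does not match grids "
                f"({self.t_values.size}, {self.s_values.size})"
            )
        for name, g in (("t_values", self.t_values), ("s_values", self.s_values)):
            if g.size > 1 and not np.all(np.diff(g) > 0):
                raise ValueError(f"{name} must be strictly increasing")

    @property
    def is_normalized(self) -> bool:
        return abs(float(self.prob.sum()) - 1.0) <= _NORM_TOL

    def t_marginal(self) -> np.ndarray:
        return self.prob.sum(axis=1)

    def s_marginal(self) -> np.ndarray:
        return self.prob.sum(axis=0)

    def copy(self) -> "PosteriorGrid":
        return PosteriorGrid(self.t_values, self.s_values, self.prob.copy())


@dataclass(frozen=True)
class AgentConfig:
    """Agent variant, calibration and noise parameters.

    ``cc`` is the probability that the agent assumes the correct
    efference-copy noise level on a trial; with probability ``1 - cc`` it
    assumes one of the incorrect levels, uniformly.  ``sigma_r`` and
    ``sigma_c_levels`` default to the task's values when left ``None``.
    ``use_rounded_average`` switches the ``average_confidence`` variant's
    fixed assumed noise SD from the exact level mean (35/3 for the default
    levels) to the rounded value 12.
    """

    variant: str = "full"
    cc: float = 1.0
    sigma_r: float | None = None
    sigma_c_levels: tuple[float, ...] | None = None
    rng_seed: int = 0
    use_rounded_average: bool = False
    t_range: tuple[float, float] = (0.0, 100.0)
    s_range: tuple[float, float] = (0.1, 100.0)
    n_t: int = 100
    n_s: int = 50

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(
                f"variant must be one of {VARIANTS}, got {self.variant!r}"
            )
        if not 0.0 <= self.cc <= 1.0:
            raise ValueError(f"cc must be in [0, 1], got {self.cc}")
        if self.sigma_c_levels is not None:
            object.__setattr__(
                self, "sigma_c_levels", tuple(float(x) for x in self.sigma_c_levels)
            )


@dataclass(frozen=True)
class TrialOutput:
    """Full record of one simulated trial."""

    trial: int
    i: float  # intended response
    r: float  # executed response
    c: float  # efference copy
    sigma_c_true: float
    sigma_c_subjective: float  # nan for feedback_only
    co: float  # confidence report in {1,2,3}; nan without trial-wise confidence
    po: float  # predicted outcome on the feedback scale; nan for feedback_only
    f: float  # feedback
    t_hat: float  # posterior mean of t after the update
    s_hat: float  # posterior mean of s after the update
    target_error: float
    scale_error: float
    degenerate_update: bool = False


def init_prior(
    t_range: tuple[float, float] = (0.0, 100.0),
    s_range: tuple[float, float] = (0.1, 100.0),
    n_t: int = 100,
    n_s: int = 50,
) -> PosteriorGrid:
    """Uniform joint prior on an evenly spaced (t, s) grid.

    Defaults give the 100 x 50 grid over t in [0, 100], s in [0.1, 100]
    with cell weight 1/5000.
    """
    t_values = np.linspace(t_range[0], t_range[1], n_t)
    s_values = np.linspace(s_range[0], s_range[1], n_s)
    prob = np.full((n_t, n_s), 1.0 / (n_t * n_s))
    return PosteriorGrid(t_values, s_values, prob)


def _require_normalized(grid: PosteriorGrid) -> None:
    if not grid.is_normalized:
        raise ValueError(
            f"grid is not normalized (sum = {grid.prob.sum():.6g})"
        )


def intended_response(grid: PosteriorGrid) -> float:
    """Expected target interval under the t marginal."""
    _require_normalized(grid)
    return float(grid.t_marginal() @ grid.t_values)


def expected_scale(grid: PosteriorGrid) -> float:
    """Expected feedback scale under the s marginal."""
    _require_normalized(grid)
    return float(grid.s_marginal() @ grid.s_values)


def subjective_sigma_c(
    sigma_c_true: float,
    cc: float,
    levels: Sequence[float],
    rng: np.random.Generator,
) -> float:
    """Noise level the agent assumes for this trial.

    Returns the true level with probability ``cc``; otherwise a uniform
    draw from the incorrect levels.
    """
    levels = tuple(levels)
    if sigma_c_true not in levels:
        raise ValueError(f"sigma_c_true {sigma_c_true} not in levels {levels}")
    if not 0.0 <= cc <= 1.0:
        raise ValueError(f"cc must be in [0, 1], got {cc}")
    if cc < 1.0 and len(levels) < 2:
        raise ValueError("cc < 1 requires at least two levels to err towards")
    if cc >= 1.0 or rng.random() < cc:
        return float(sigma_c_true)
    wrong = [x for x in levels if x != sigma_c_true]
    return float(wrong[rng.integers(len(wrong))])


def confidence_report(
    sigma_c_subjective: float, levels: Sequence[float] = (5.0, 10.0, 20.0)
) -> int:
    """Map the assumed noise level to a discrete confidence rating.

    The smallest level (most precise efference copy) maps to the highest
    rating: for the default levels 5 -> 3, 10 -> 2, 20 -> 1.
    """
    levels = sorted(levels)
    for rank, level in enumerate(levels):
        if sigma_c_subjective == level:
            return len(levels) - rank
    raise ValueError(
        f"sigma_c {sigma_c_subjective} not in level set {tuple(levels)}; "
        "confidence mapping undefined"
    )


def predicted_outcome(c: float, i: float, grid: PosteriorGrid) -> float:
    """Predicted feedback: (c - i) projected on the expected scale.

    Uses the pre-update belief for the current trial.
    """
    return (c - i) * expected_scale(grid)


def fuse(c: float, i: float, sigma_c: float, sigma_r: float) -> tuple[float, float]:
    """Precision-weighted fusion of efference copy and intended response.

    Returns ``(m, v)``: the expected feedback-generating response and its
    variance, ``v = 1 / (1/sigma_c^2 + 1/sigma_r^2)`` and
    ``m = v * (c / sigma_c^2 + i / sigma_r^2)``.
    """
    if not sigma_c > 0 or not sigma_r > 0:
        raise ValueError(
            f"noise SDs must be > 0, got sigma_c={sigma_c}, sigma_r={sigma_r}"
        )
    v = 1.0 / (1.0 / sigma_c**2 + 1.0 / sigma_r**2)
    m = v * (c / sigma_c**2 + i / sigma_r**2)
    return m, v


def _log_likelihood_over_grid(
    f: float, m: float, v: float, grid: PosteriorGrid
) -> np.ndarray:
    if not v > 0:
        raise ValueError(f"expected response variance must be > 0, got {v}")
    t = grid.t_values[:, None]
    s = grid.s_values[None, :]
    mean = (m - t) * s
    var = v * s**2
    return -0.5 * (np.log(2.0 * np.pi * var) + (f - mean) ** 2 / var)


def likelihood_over_grid(
    f: float, m: float, v: float, grid: PosteriorGrid
) -> np.ndarray:
    """Gaussian likelihood of feedback ``f`` at every grid cell.

    Cell (t, s) predicts feedback with mean ``(m - t) * s`` and variance
    ``v * s**2`` (feedback is the response error times the scale, so the
    response variance is scaled by s^2).
    """
    return np.exp(_log_likelihood_over_grid(f, m, v, grid))


def update_posterior(
    prior: PosteriorGrid, likelihood: np.ndarray
) -> PosteriorGrid:
    """Cellwise product of prior and likelihood, renormalized.

    Raises :class:`DegenerateUpdateError` if every cell underflows to zero.
    """
    likelihood = np.asarray(likelihood, dtype=float)
    if likelihood.shape != prior.prob.shape:
        raise ValueError(
            f"likelihood shape {likelihood.shape} != grid {prior.prob.shape}"
        )
    if np.any(likelihood < 0) or not np.all(np.isfinite(likelihood)):
        raise ValueError("likelihood weights must be finite and nonnegative")
    post = prior.prob * likelihood
    total = post.sum()
    if not np.isfinite(total) or total <= 0.0:
        raise DegenerateUpdateError(
            "posterior update underflowed: all cell products are zero"
        )
    return PosteriorGrid(prior.t_values, prior.s_values, post / total)


@dataclass
class _Streams:
    """Named random streams so variants share common random numbers."""

    response: np.random.Generator
    level: np.random.Generator
    copy: np.random.Generator
    calibration: np.random.Generator

    @classmethod
    def from_seed(cls, seed: int) -> "_Streams":
        keys = ("response", "level", "copy", "calibration")
        return cls(
            **{k: np.random.default_rng([j, seed]) for j, k in enumerate(keys)}
        )


def _effective_sigma(agent: AgentConfig, task: TaskConfig) -> tuple[float, tuple[float, ...]]:
    sigma_r = task.sigma_r if agent.sigma_r is None else agent.sigma_r
    levels = (
        task.sigma_c_levels if agent.sigma_c_levels is None else agent.sigma_c_levels
    )
    return sigma_r, levels


def run_trial(
    grid: PosteriorGrid,
    agent: AgentConfig,
    task: TaskConfig,
    streams: _Streams,
    trial: int = 0,
) -> tuple[TrialOutput, PosteriorGrid]:
    """Simulate one trial and return its record and the updated belief.

    The outcome prediction is formed from the pre-update belief; only then
    is feedback observed and the posterior updated.  An underflowing update
    retains the prior and flags the trial.
    """
    _require_normalized(grid)
    sigma_r, levels = _effective_sigma(agent, task)

    i = intended_response(grid)
    r = sample_response(i, sigma_r, streams.response)
    sigma_c_true = sample_sigma_c_level(levels, streams.level)
    c = sample_efference_copy(r, sigma_c_true, streams.copy)

    if agent.variant == "full":
        sigma_c_subj = subjective_sigma_c(
            sigma_c_true, agent.cc, levels, streams.calibration
        )
        co: float = float(confidence_report(sigma_c_subj, levels))
        po = predicted_outcome(c, i, grid)
        m, v = fuse(c, i, sigma_c_subj, sigma_r)
    elif agent.variant == "average_confidence":
        sigma_c_subj = 12.0 if agent.use_rounded_average else float(np.mean(levels))
        co = float("nan")  # no trial-wise confidence
        po = predicted_outcome(c, i, grid)
        m, v = fuse(c, i, sigma_c_subj, sigma_r)
    else:  # feedback_only: the efference copy is never consulted
        sigma_c_subj = float("nan")
        co = float("nan")
        po = float("nan")
        m, v = i, sigma_r**2

    f = generate_feedback(r, task.t_true, task.s_true)

    loglik = _log_likelihood_over_grid(f, m, v, grid)
    degenerate = False
    try:
        new_grid = update_posterior(grid, np.exp(loglik - loglik.max()))
    except DegenerateUpdateError:
        new_grid = grid.copy()
        degenerate = True

    t_hat = intended_response(new_grid)
    s_hat = expected_scale(new_grid)
    out = TrialOutput(
        trial=trial,
        i=i,
        r=r,
        c=c,
        sigma_c_true=sigma_c_true,
        sigma_c_subjective=sigma_c_subj,
        co=co,
        po=po,
        f=f,
        t_hat=t_hat,
        s_hat=s_hat,
        target_error=abs(t_hat - task.t_true),
        scale_error=abs(s_hat - task.s_true),
        degenerate_update=degenerate,
    )
    return out, new_grid


def run_agent(agent: AgentConfig, task: TaskConfig) -> list[TrialOutput]:
    """Run ``task.n_trials`` sequential trials from the uniform prior."""
    grid = init_prior(agent.t_range, agent.s_range, agent.n_t, agent.n_s)
    streams = _Streams.from_seed(agent.rng_seed)
    trajectory: list[TrialOutput] = []
    for trial in range(1, task.n_trials + 1):
        out, grid = run_trial(grid, agent, task, streams, trial=trial)
        trajectory.append(out)
    return trajectory


def trajectory_frame(trajectory: Sequence[TrialOutput], **extra) -> pd.DataFrame:
    """Tidy one-row-per-trial frame of a trajectory; ``extra`` columns are
    broadcast (e.g. agent id, variant, cc)."""
    df = pd.DataFrame([vars(t) for t in trajectory])
    for key, value in extra.items():
        df[key] = value
    return df


def save_belief_snapshots(path, grids: Sequence[PosteriorGrid]) -> None:
    """Write per-trial belief grids to HDF5 (t_values, s_values, prob)."""
    import h5py

    with h5py.File(path, "w") as h5:
        h5.create_dataset("t_values", data=grids[0].t_values)
        h5.create_dataset("s_values", data=grids[0].s_values)
        h5.create_dataset("prob", data=np.stack([g.prob for g in grids]))
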