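"""Simulated time-estimation environment.

The environment hides a target interval ``t`` and a feedback scale ``s``.
On each trial the agent executes a response ``r`` (its intention plus motor
noise) and receives feedback ``f = (r - t) * s``: negative values signal
undershoots, positive values overshoots.  The agent additionally observes a
noisy efference copy of its executed response whose noise level varies from
trial to trial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TaskConfig",
    "generate_feedback",
    "sample_response",
    "sample_efference_copy",
    "sample_sigma_c_level",
]


@dataclass(frozen=True)
class TaskConfig:
    """True task parameters and noise levels for an agent run.

    Attributes
    ----------
    t_true : float
        Hidden target interval, model units.
    s_true : float
        Hidden feedback scale (> 0).
    sigma_r : float
        Response-noise standard deviation (> 0).
    sigma_c_levels : tuple of float
        Strictly increasing efference-copy noise SDs; one is drawn
        uniformly per trial.
    n_trials : int
        Trials per agent run.
    rng_seed : int
        Base seed for the run's random streams.
    """

    t_true: float = 19.0
    s_true: float = 90.0
    sigma_r: float = 10.0
    sigma_c_levels: tuple[float, ...] = (5.0, 10.0, 20.0)
    n_trials: int = 250
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.s_true > 0:
            raise ValueError(f"s_true must be > 0, got {self.s_true}")
        if not self.sigma_r > 0:
            raise ValueError(f"sigma_r must be > 0, got {self.sigma_r}")
        levels = tuple(float(x) for x in self.sigma_c_levels)
        if len(levels) == 0:
            raise ValueError("sigma_c_levels must be non-empty")
        if any(x <= 0 for x in levels):
            raise ValueError(f"sigma_c_levels must all be > 0, got {levels}")
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ValueError(
                f"sigma_c_levels must be strictly increasing, got {levels}"
            )
        object.__setattr__(self, "sigma_c_levels", levels)
        if self.n_trials < 1:
            raise ValueError(f"n_trials must be >= 1, got {self.n_trials}")


def generate_feedback(r: float, t: float, s: float) -> float:
    """Feedback shown for executed response ``r``: ``(r - t) * s``.

    Exactly linear in ``r`` and antisymmetric around ``t``.  Negative
    feedback encodes an undershoot, positive an overshoot.
    """
    if not (math.isfinite(r) and math.isfinite(t) and math.isfinite(s)):
        raise ValueError(f"non-finite trial inputs: r={r}, t={t}, s={s}")
    if not s > 0:
        raise ValueError(f"feedback scale must be > 0, got {s}")
    return (r - t) * s


def sample_response(i: float, sigma_r: float, rng: np.random.Generator) -> float:
    """Draw one executed response from Normal(i, sigma_r**2)."""
    if not sigma_r > 0:
        raise ValueError(f"sigma_r must be > 0, got {sigma_r}")
    return float(rng.normal(i, sigma_r))


def sample_efference_copy(
    r: float, sigma_c: float, rng: np.random.Generator
) -> float:
    """Draw one efference copy from Normal(r, sigma_c**2)."""
    if not sigma_c > 0:
        raise ValueError(f"sigma_c must be > 0, got {sigma_c}")
    return float(rng.normal(r, sigma_c))


def sample_sigma_c_level(
    levels: tuple[float, ...], rng: np.random.Generator
) -> float:
    """Uniform categorical draw of the trial's efference-copy noise SD."""
    levels = tuple(levels)
    if len(levels) == 0:
        raise ValueError("level set must be non-empty")
    return float(levels[rng.integers(len(levels))])
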