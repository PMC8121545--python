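"""Synthetic behavioral tables and EEG epochs for pipeline testing.

``generate_behavior`` simulates each participant as a full-variant agent
re-parameterized in milliseconds (target 1504 ms), with a per-participant
confidence calibration drawn from a configurable range, and emits a trial
table in the behavioral pipeline's schema.  ``generate_epochs`` builds
feedback-locked epochs as autocorrelated band-limited noise plus ERP
component templates whose amplitudes carry the configured trial-level
effects (FRN ~ RPE, P3a ~ SPE and confidence, P3b ~ SPE, -EM, -RPE), with
optional injected amplitude/gradient artifacts.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import signal

from monitorlearn.bayes_learner import AgentConfig, run_agent
from monitorlearn.behavior_metrics import REQUIRED_COLUMNS
from monitorlearn.erp_features import P3A_ROI, P3B_ROI, EpochArray, write_epochs
from monitorlearn.task_model import TaskConfig

__all__ = [
    "BehaviorGenConfig",
    "ErpGenConfig",
    "ComponentTemplate",
    "generate_behavior",
    "generate_epochs",
    "write_fixture_bundle",
    "SYNTH_CHANNELS",
]

#: channels of the synthetic montage: both analysis ROIs (FCz and Pz included)
SYNTH_CHANNELS: tuple[str, ...] = tuple(P3A_ROI) + tuple(P3B_ROI)

_CONFIDENCE_ANCHORS = {1: 0.17, 2: 0.5, 3: 0.83}


@dataclass(frozen=True)
class BehaviorGenConfig:
    """Configuration of the synthetic behavioral experiment."""

    n_participants: int = 40
    blocks: int = 5
    trials_per_block: int = 50
    target_ms: float = 1504.0
    sigma_r_ms: float = 150.0
    sigma_c_levels_ms: tuple[float, ...] = (75.0, 150.0, 300.0)
    cc_range: tuple[float, float] = (0.0, 1.0)
    confidence_jitter_sd: float = 0.05
    rt_log_mean: float = -0.2  # lognormal parameters of response time, s
    rt_log_sd: float = 0.35
    slow_trial_rate: float = 0.004  # rare > 6 s contaminants
    t_grid_range: tuple[float, float] = (500.0, 3500.0)
    s_grid_range: tuple[float, float] = (0.1, 5.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_r_ms <= 0 or any(x <= 0 for x in self.sigma_c_levels_ms):
            raise ValueError("noise SDs must be > 0")
        lo, hi = self.cc_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"cc_range must lie in [0, 1], got {self.cc_range}")
        if self.n_participants < 1 or self.blocks < 1 or self.trials_per_block < 1:
            raise ValueError("counts must be >= 1")


def generate_behavior(config: BehaviorGenConfig) -> pd.DataFrame:
    """Simulate the behavioral experiment; returns a tidy trial table.

    Columns follow :data:`monitorlearn.behavior_metrics.REQUIRED_COLUMNS`,
    plus ``cc_true`` and ``co`` for recovery checks.  Feedback is the
    signed error in ms (the scale seen by the learner is unknown to it).
    """
    root = np.random.SeedSequence(config.rng_seed)
    agent_seeds = root.generate_state(config.n_participants)
    aux = np.random.default_rng(root.spawn(1)[0])

    cc_lo, cc_hi = config.cc_range
    cc_true = aux.uniform(cc_lo, cc_hi, size=config.n_participants)

    n_trials = config.blocks * config.trials_per_block
    task = TaskConfig(
        t_true=config.target_ms,
        s_true=1.0,
        sigma_r=config.sigma_r_ms,
        sigma_c_levels=config.sigma_c_levels_ms,
        n_trials=n_trials,
    )
    frames = []
    for p in range(config.n_participants):
        agent = AgentConfig(
            variant="full",
            cc=float(cc_true[p]),
            rng_seed=int(agent_seeds[p]),
            t_range=config.t_grid_range,
            s_range=config.s_grid_range,
        )
        traj = run_agent(agent, task)
        co = np.array([t.co for t in traj])
        confidence = np.clip(
            np.array([_CONFIDENCE_ANCHORS[int(c)] for c in co])
            + aux.normal(0.0, config.confidence_jitter_sd, n_trials),
            0.0,
            1.0,
        )
        rt = np.exp(aux.normal(config.rt_log_mean, config.rt_log_sd, n_trials))
        slow = aux.random(n_trials) < config.slow_trial_rate
        rt[slow] = aux.uniform(6.2, 9.0, size=int(slow.sum()))
        frames.append(
            pd.DataFrame(
                {
                    "participant": p + 1,
                    "block": np.repeat(
                        np.arange(1, config.blocks + 1), config.trials_per_block
                    ),
                    "trial": np.tile(
                        np.arange(1, config.trials_per_block + 1), config.blocks
                    ),
                    "produced_interval": [t.r for t in traj],
                    "response_time": rt,
                    "prediction": [t.po for t in traj],
                    "confidence": confidence,
                    "feedback": [t.f for t in traj],
                    "co": co.astype(int),
                    "cc_true": cc_true[p],
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    assert set(REQUIRED_COLUMNS) <= set(table.columns)
    return table


@dataclass(frozen=True)
class ComponentTemplate:
    """A Gaussian-in-time ERP component with a channel topography."""

    latency_ms: float
    width_ms: float
    topography: dict[str, float]  # channel -> weight

    def waveform(self, times_ms: np.ndarray) -> np.ndarray:
        return np.exp(-0.5 * ((times_ms - self.latency_ms) / self.width_ms) ** 2)


def _roi_topo(channels: tuple[str, ...], focus: str) -> dict[str, float]:
    return {ch: (1.0 if ch == focus else 0.8) for ch in channels}


@dataclass(frozen=True)
class ErpGenConfig:
    """Templates, effect coefficients and noise model for synthetic epochs.

    Effect coefficients are in microvolts per unit of the *scaled*
    predictor (errors in seconds, confidence mapped to [-1, 1]).
    """

    srate: float = 500.0
    t0_ms: float = -200.0
    n_samples: int = 500
    channels: tuple[str, ...] = SYNTH_CHANNELS
    p2: ComponentTemplate = field(
        default_factory=lambda: ComponentTemplate(
            180.0, 25.0, _roi_topo(P3A_ROI, "FCz")
        )
    )
    frn: ComponentTemplate = field(
        default_factory=lambda: ComponentTemplate(
            250.0, 30.0, _roi_topo(P3A_ROI, "FCz")
        )
    )
    p3a: ComponentTemplate = field(
        default_factory=lambda: ComponentTemplate(
            380.0, 40.0, _roi_topo(P3A_ROI, "FCz")
        )
    )
    p3b: ComponentTemplate = field(
        default_factory=lambda: ComponentTemplate(
            466.0, 45.0, _roi_topo(P3B_ROI, "Pz")
        )
    )
    p2_amp: float = 5.0
    frn_base: float = -8.0
    frn_rpe: float = 10.0  # positive: better-than-expected -> shallower FRN
    p3a_base: float = 6.0
    p3a_spe: float = 5.0
    p3a_confidence: float = 2.0
    p3b_base: float = 5.0
    p3b_spe: float = 4.0
    p3b_em: float = -4.0
    p3b_rpe: float = -2.5
    noise_sd: float = 6.0
    noise_ar: float = 0.95
    band_hz: tuple[float, float] = (0.5, 40.0)
    artifact_rate: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ValueError("artifact_rate must be in [0, 1]")

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + (1000.0 / self.srate) * np.arange(self.n_samples)


def component_amplitudes(trials: pd.DataFrame, config: ErpGenConfig) -> pd.DataFrame:
    """Per-trial injected component amplitudes implied by the trial table.

    Expects error-signal columns in ms and confidence in [0, 1]; applies
    the same predictor scaling as the analysis pipeline (ms -> s,
    confidence -> [-1, 1]) before the linear effect model.
    """
    needed = ("rpe", "spe", "error_magnitude", "confidence")
    missing = [c for c in needed if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing error-signal columns: {missing}")
    rpe_s = trials["rpe"].to_numpy() / 1000.0
    spe_s = trials["spe"].to_numpy() / 1000.0
    em_s = trials["error_magnitude"].to_numpy() / 1000.0
    conf = trials["confidence"].to_numpy() * 2.0 - 1.0
    return pd.DataFrame(
        {
            "p2_amp": np.full(len(trials), config.p2_amp),
            "frn_amp": config.frn_base + config.frn_rpe * rpe_s,
            "p3a_amp": config.p3a_base
            + config.p3a_spe * spe_s
            + config.p3a_confidence * conf,
            "p3b_amp": config.p3b_base
            + config.p3b_spe * spe_s
            + config.p3b_em * em_s
            + config.p3b_rpe * rpe_s,
        }
    )


def _band_limited_noise(
    rng: np.random.Generator, shape: tuple[int, ...], config: ErpGenConfig
) -> np.ndarray:
    """AR(1)-like noise band-limited to the configured range.

    Shaped in the frequency domain (AR(1) power spectrum times the
    squared magnitude response of a 2nd-order Butterworth band-pass), so
    generating many epochs stays a single FFT round trip.  Scaled to
    ``noise_sd`` overall standard deviation.
    """
    n = shape[-1]
    white = rng.standard_normal(shape)
    spectrum = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / config.srate)
    # AR(1) magnitude response
    a = config.noise_ar
    ar_gain = 1.0 / np.sqrt(1.0 - 2.0 * a * np.cos(2.0 * np.pi * freqs / config.srate) + a**2)
    sos = signal.butter(
        2, config.band_hz, btype="bandpass", fs=config.srate, output="sos"
    )
    _, band_gain = signal.sosfreqz(sos, worN=2.0 * np.pi * freqs / config.srate)
    gain = ar_gain * np.abs(band_gain) ** 2  # filtfilt-style squared magnitude
    filtered = np.fft.irfft(spectrum * gain, n=n, axis=-1)
    std = filtered.std()
    if std > 0:
        filtered = filtered / std
    return config.noise_sd * filtered


def generate_epochs(
    trials: pd.DataFrame, config: ErpGenConfig
) -> tuple[EpochArray, pd.DataFrame]:
    """Build one synthetic epoch per trial row.

    Returns the epoch array and a ground-truth frame with the injected
    component amplitudes and an ``artifact_injected`` flag per epoch.
    """
    rng = np.random.default_rng(config.rng_seed)
    n_epochs = len(trials)
    if n_epochs == 0:
        raise ValueError("empty trial table: no epochs to generate")
    times = config.times_ms
    n_ch = len(config.channels)
    ch_index = {ch: j for j, ch in enumerate(config.channels)}

    amps = component_amplitudes(trials, config)
    data = np.zeros((n_epochs, n_ch, config.n_samples))
    if config.noise_sd > 0:
        data += _band_limited_noise(rng, data.shape, config)

    components = (
        (config.p2, amps["p2_amp"].to_numpy()),
        (config.frn, amps["frn_amp"].to_numpy()),
        (config.p3a, amps["p3a_amp"].to_numpy()),
        (config.p3b, amps["p3b_amp"].to_numpy()),
    )
    for template, amp in components:
        wave = template.waveform(times)  # (samples,)
        topo = np.zeros(n_ch)
        for ch, w in template.topography.items():
            if ch in ch_index:
                topo[ch_index[ch]] = w
        data += amp[:, None, None] * topo[None, :, None] * wave[None, None, :]

    injected = rng.random(n_epochs) < config.artifact_rate
    post_onset = np.flatnonzero(times > 0)
    for e in np.flatnonzero(injected):
        ch = int(rng.integers(n_ch))
        at = int(rng.choice(post_onset))
        if rng.random() < 0.5:
            data[e, ch, at] += 400.0  # amplitude artifact
        else:
            data[e, ch, at:] += 80.0  # gradient (step) artifact

    epochs = EpochArray(data, config.channels, config.srate, config.t0_ms)
    truth = amps.copy()
    truth["artifact_injected"] = injected
    return epochs, truth


def write_fixture_bundle(
    behavior_config: BehaviorGenConfig,
    erp_config: ErpGenConfig,
    out_dir,
    target_ms: float | None = None,
) -> dict[str, Path]:
    """Write a coherent trials CSV + epochs HDF5/JSON + config bundle.

    The epochs are generated from the error signals of the generated
    behavior, so behavioral and electrophysiological effects agree.
    Deterministic for fixed config seeds.
    """
    from monitorlearn.behavior_metrics import compute_error_signals

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    trials = generate_behavior(behavior_config)
    signals = compute_error_signals(
        trials, target=target_ms or behavior_config.target_ms
    )
    epochs, truth = generate_epochs(signals, erp_config)

    paths = {
        "trials": out_dir / "trials.csv",
        "epochs": out_dir / "epochs.h5",
        "truth": out_dir / "epoch_truth.csv",
        "config": out_dir / "config.yaml",
    }
    trials.to_csv(paths["trials"], index=False)
    write_epochs(paths["epochs"], epochs, metadata=signals)
    truth.to_csv(paths["truth"], index=False)
    paths["config"].write_text(
        yaml.safe_dump(
            {
                "behavior": asdict(behavior_config),
                "erp": _erp_config_dict(erp_config),
            },
            sort_keys=False,
        )
    )
    return paths


def _erp_config_dict(config: ErpGenConfig) -> dict:
    d = asdict(config)
    for key in ("p2", "frn", "p3a", "p3b"):
        d[key] = asdict(getattr(config, key))
    return d
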