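"""Single-trial ERP feature extraction on feedback-locked epochs.

Epochs are sampled at 500 Hz from -200 to 800 ms around feedback onset
(500 samples, 2 ms steps).  Features:

* FRN: peak-to-peak at FCz — the minimum in 200..300 ms minus the maximum
  in the 100 ms preceding that trough (negative-going by convention).
* P3a: mean voltage 330..430 ms over a fronto-central ROI.
* P3b: mean voltage 416..516 ms over a parietal ROI.

Artifact rejection flags epochs with any |sample| > 150 uV or any
adjacent-sample jump > 50 uV; baselines subtract the mean of the 200 ms
pre-stimulus interval.  Mean windows are closed on the left and open on
the right in sample space; peak-search windows include both endpoints.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "P3A_ROI",
    "P3B_ROI",
    "P3A_WINDOW_MS",
    "P3B_WINDOW_MS",
    "EpochArray",
    "RoiSpec",
    "baseline_correct",
    "reject_artifacts",
    "frn_peak_to_peak",
    "window_mean",
    "subject_window",
    "extract_features",
    "read_epochs",
    "write_epochs",
]

P3A_ROI = ("F1", "Fz", "F2", "FC1", "FCz", "FC2", "C1", "Cz", "C2")
P3B_ROI = ("CP1", "CPz", "CP2", "P1", "Pz", "P2", "PO3", "POz", "PO4")

P3A_WINDOW_MS = (330.0, 430.0)
P3B_WINDOW_MS = (416.0, 516.0)
FRN_TROUGH_WINDOW_MS = (200.0, 300.0)

AMPLITUDE_THRESHOLD_UV = 150.0
GRADIENT_THRESHOLD_UV = 50.0


@dataclass
class EpochArray:
    """Epoched voltage data: epochs x channels x samples, in microvolts."""

    data: np.ndarray
    channel_names: tuple[str, ...]
    srate: float = 500.0
    t0: float = -200.0  # ms of the first sample relative to feedback onset

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_names = tuple(str(c) for c in self.channel_names)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3-D, got shape {self.data.shape}")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError(
                f"{self.data.shape[1]} channels in data but "
                f"{len(self.channel_names)} names"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms relative to feedback onset."""
        step = 1000.0 / self.srate
        return self.t0 + step * np.arange(self.data.shape[2])

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not present; have {self.channel_names}"
            ) from None

    def copy(self) -> "EpochArray":
        return EpochArray(self.data.copy(), self.channel_names, self.srate, self.t0)


@dataclass(frozen=True)
class RoiSpec:
    name: str
    channels: tuple[str, ...]

    def indices(self, epochs: EpochArray) -> list[int]:
        return [epochs.channel_index(ch) for ch in self.channels]


def _sample_slice(epochs: EpochArray, window_ms: tuple[float, float],
                  closed: str = "left") -> np.ndarray:
    """Boolean sample mask for a time window.

    ``closed='left'`` gives [lo, hi); ``closed='both'`` gives [lo, hi]
    (used for peak searches so the printed window edges participate).
    """
    t = epochs.times
    lo, hi = window_ms
    eps = 1e-9
    if closed == "both":
        mask = (t >= lo - eps) & (t <= hi + eps)
    else:
        mask = (t >= lo - eps) & (t < hi - eps)
    if not mask.any():
        raise ValueError(f"window {window_ms} ms contains no samples")
    return mask


def baseline_correct(epochs: EpochArray) -> EpochArray:
    """Subtract the mean over [-200, 0) ms per epoch and channel."""
    if epochs.t0 > -200.0 + 1e-9:
        raise ValueError(
            f"epochs start at {epochs.t0} ms; need the full -200..0 baseline"
        )
    mask = _sample_slice(epochs, (-200.0, 0.0), closed="left")
    baseline = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return EpochArray(
        epochs.data - baseline, epochs.channel_names, epochs.srate, epochs.t0
    )


def reject_artifacts(
    epochs: EpochArray,
    amplitude_uv: float = AMPLITUDE_THRESHOLD_UV,
    gradient_uv: float = GRADIENT_THRESHOLD_UV,
) -> np.ndarray:
    """Boolean mask of rejected epochs (True = rejected).

    An epoch is rejected if any channel sample exceeds +/-150 uV in
    absolute value or any adjacent-sample difference exceeds 50 uV.
    Applied to all channels present.
    """
    amp_bad = np.abs(epochs.data) > amplitude_uv
    grad_bad = np.abs(np.diff(epochs.data, axis=2)) > gradient_uv
    return amp_bad.any(axis=(1, 2)) | grad_bad.any(axis=(1, 2))


def frn_peak_to_peak(
    epochs: EpochArray,
    channel: str = "FCz",
    trough_window_ms: tuple[float, float] = FRN_TROUGH_WINDOW_MS,
    preceding_ms: float = 100.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-epoch peak-to-peak FRN amplitude and trough latency at FCz.

    Finds the minimum voltage in the trough window, then the maximum in
    the ``preceding_ms`` window ending at the trough; returns
    ``(v_min - v_max, trough latency in ms)``.  Both searches include
    their window endpoints; ties take the earliest sample.
    """
    ch = epochs.channel_index(channel)
    t = epochs.times
    trough_mask = _sample_slice(epochs, trough_window_ms, closed="both")
    trough_idx = np.flatnonzero(trough_mask)
    x = epochs.data[:, ch, :]
    rel_min = x[:, trough_mask].argmin(axis=1)
    trough_samples = trough_idx[rel_min]
    trough_lat = t[trough_samples]

    frn = np.empty(epochs.n_epochs)
    for e in range(epochs.n_epochs):
        pre = (t >= trough_lat[e] - preceding_ms - 1e-9) & (
            t <= trough_lat[e] + 1e-9
        )
        v_max = x[e, pre].max()
        frn[e] = x[e, trough_samples[e]] - v_max
    return frn, trough_lat


def window_mean(
    epochs: EpochArray, roi: RoiSpec, window_ms: tuple[float, float]
) -> np.ndarray:
    """Per-epoch mean voltage over the ROI channels and window samples."""
    t = epochs.times
    if window_ms[0] < t[0] - 1e-9 or window_ms[1] > t[-1] + (1000.0 / epochs.srate):
        raise ValueError(f"window {window_ms} ms outside epoch span")
    mask = _sample_slice(epochs, window_ms, closed="left")
    idx = roi.indices(epochs)
    return epochs.data[:, idx, :][:, :, mask].mean(axis=(1, 2))


def subject_window(
    epochs: EpochArray,
    channel: str,
    search_span_ms: tuple[float, float],
    width_ms: float = 100.0,
    rejected: np.ndarray | None = None,
) -> tuple[float, float]:
    """Subject-wise quantification window from the average waveform.

    Averages the subject's surviving epochs, finds the positive-peak
    latency on ``channel`` within the search span (endpoints included,
    earliest sample on ties) and returns the ``width_ms`` window centered
    on it.
    """
    keep = np.ones(epochs.n_epochs, dtype=bool) if rejected is None else ~np.asarray(rejected)
    if not keep.any():
        raise ValueError("no surviving epochs to average")
    avg = epochs.data[keep, epochs.channel_index(channel), :].mean(axis=0)
    mask = _sample_slice(epochs, search_span_ms, closed="both")
    idx = np.flatnonzero(mask)
    seg = avg[mask]
    peak = idx[seg.argmax()]
    if (seg == seg.max()).sum() > 1:
        warnings.warn("tied peak maxima; earliest latency taken", stacklevel=2)
    lat = epochs.times[peak]
    return (lat - width_ms / 2.0, lat + width_ms / 2.0)


def extract_features(
    epochs: EpochArray,
    p3a_window_ms: tuple[float, float] = P3A_WINDOW_MS,
    p3b_window_ms: tuple[float, float] = P3B_WINDOW_MS,
    baseline: bool = True,
) -> pd.DataFrame:
    """Run the full single-trial feature pipeline on an epoch array.

    Baseline-corrects, rejects artifacts, and computes FRN, P3a and P3b
    per epoch.  Features of rejected epochs are NaN.
    """
    if baseline:
        epochs = baseline_correct(epochs)
    rejected = reject_artifacts(epochs)
    frn, lat = frn_peak_to_peak(epochs)
    p3a = window_mean(epochs, RoiSpec("P3a", P3A_ROI), p3a_window_ms)
    p3b = window_mean(epochs, RoiSpec("P3b", P3B_ROI), p3b_window_ms)
    df = pd.DataFrame(
        {
            "epoch": np.arange(epochs.n_epochs),
            "rejected": rejected,
            "frn": frn,
            "frn_neg_peak_latency": lat,
            "p3a": p3a,
            "p3b": p3b,
        }
    )
    df.loc[rejected, ["frn", "frn_neg_peak_latency", "p3a", "p3b"]] = np.nan
    return df


def write_epochs(path, epochs: EpochArray, metadata: pd.DataFrame | None = None) -> None:
    """Write epochs to HDF5 with an optional JSON trial-metadata sidecar."""
    path = Path(path)
    with h5py.File(path, "w") as h5:
        h5.create_dataset("data", data=epochs.data)
        h5.create_dataset(
            "channel_names",
            data=np.array(epochs.channel_names, dtype=h5py.string_dtype()),
        )
        h5.attrs["srate"] = epochs.srate
        h5.attrs["t0"] = epochs.t0
    if metadata is not None:
        sidecar = path.with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {
                    "n_epochs": int(epochs.n_epochs),
                    "trials": metadata.to_dict(orient="records"),
                },
                indent=1,
                default=float,
            )
        )


def read_epochs(path) -> tuple[EpochArray, pd.DataFrame | None]:
    """Read epochs written by :func:`write_epochs`."""
    path = Path(path)
    with h5py.File(path, "r") as h5:
        epochs = EpochArray(
            data=h5["data"][()],
            channel_names=tuple(s.decode() for s in h5["channel_names"][()]),
            srate=float(h5.attrs["srate"]),
            t0=float(h5.attrs["t0"]),
        )
    sidecar = path.with_suffix(".json")
    metadata = None
    if sidecar.exists():
        payload = json.loads(sidecar.read_text())
        metadata = pd.DataFrame(payload["trials"])
    return epochs, metadata
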