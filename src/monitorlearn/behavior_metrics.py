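"""Trial-level behavioral pipeline.

Operates on tidy trial tables with columns ``participant``, ``block``
(1..5), ``trial`` (within block), ``produced_interval`` (ms),
``response_time`` (s), ``prediction`` (signed ms on the feedback axis),
``confidence`` (in [0, 1]) and ``feedback`` (signed ms).

Error signals per trial:

* signed error  = produced interval - target
* error magnitude (EM) = |signed error|
* SPE = |prediction - feedback|   (sensory prediction error)
* RPE = |prediction| - |feedback| (reward prediction error; positive when
  the outcome is better than predicted)
* improvement = EM(previous trial) - EM(current trial), within block

The confidence-calibration index is the sign-reversed partial correlation
of confidence and SPE, controlling for block-wise mean error magnitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

DEFAULT_TARGET_MS = 1504.0

#: display mapping of the rating scale: +/-125 px correspond to +/-1 s
PX_PER_MS = 125.0 / 1000.0

REQUIRED_COLUMNS = (
    "participant",
    "block",
    "trial",
    "produced_interval",
    "response_time",
    "prediction",
    "confidence",
    "feedback",
)

__all__ = [
    "DEFAULT_TARGET_MS",
    "REQUIRED_COLUMNS",
    "CalibrationIndex",
    "filter_outliers",
    "compute_error_signals",
    "improvement",
    "confidence_calibration",
    "scale_predictors",
    "log_error_magnitude",
    "fit_trial_model",
    "prediction_px_to_ms",
]


def _check_columns(table: pd.DataFrame, needed) -> None:
    missing = [c for c in needed if c not in table.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")


def prediction_px_to_ms(px: pd.Series | np.ndarray) -> np.ndarray:
    """Convert raw pixel prediction ratings to ms via the scale anchors."""
    return np.asarray(px, dtype=float) / PX_PER_MS


def filter_outliers(
    records: pd.DataFrame,
    participant_mean_rt_max: float = 10.0,
    trial_rt_max: float = 6.0,
) -> tuple[pd.DataFrame, dict]:
    """Drop slow participants, then slow trials.

    A participant whose mean response time exceeds 10 s loses all trials;
    remaining trials with response time above 6 s are dropped.  Returns the
    kept records and an exclusion log with both counts.
    """
    _check_columns(records, ("participant", "response_time"))
    if records.empty:
        warnings.warn("empty trial table passed to filter_outliers", stacklevel=2)
        return records.copy(), {
            "excluded_participants": [],
            "n_participant_trials_removed": 0,
            "n_slow_trials_removed": 0,
        }
    mean_rt = records.groupby("participant")["response_time"].mean()
    bad_participants = mean_rt.index[mean_rt > participant_mean_rt_max].tolist()
    kept = records[~records["participant"].isin(bad_participants)]
    n_participant_trials = len(records) - len(kept)
    slow = kept["response_time"] > trial_rt_max
    log = {
        "excluded_participants": bad_participants,
        "n_participant_trials_removed": int(n_participant_trials),
        "n_slow_trials_removed": int(slow.sum()),
    }
    return kept[~slow].reset_index(drop=True), log


def compute_error_signals(
    records: pd.DataFrame, target: float = DEFAULT_TARGET_MS
) -> pd.DataFrame:
    """Append signed_error, error_magnitude, spe, rpe and improvement.

    Rows with missing predictions get NaN for prediction-based signals and
    are flagged in ``missing_prediction``.  Improvement is undefined on the
    first trial of each participant x block run.
    """
    _check_columns(records, ("produced_interval", "prediction", "feedback"))
    out = records.copy()
    out["signed_error"] = out["produced_interval"] - target
    out["error_magnitude"] = out["signed_error"].abs()
    out["missing_prediction"] = out["prediction"].isna()
    out["spe"] = (out["prediction"] - out["feedback"]).abs()
    out["rpe"] = out["prediction"].abs() - out["feedback"].abs()
    if {"participant", "block"}.issubset(out.columns):
        em_prev = out.groupby(["participant", "block"])["error_magnitude"].shift(1)
        out["improvement"] = em_prev - out["error_magnitude"]
    return out


def improvement(em_prev: float, em_curr: float) -> float:
    """Previous minus current error magnitude; positive = improved."""
    return em_prev - em_curr


@dataclass(frozen=True)
class CalibrationIndex:
    """Per-participant confidence-calibration index.

    Sign-reversed partial correlation of confidence with SPE so that
    higher values mean better calibration.
    """

    participant: object
    index: float
    n_trials: int


def confidence_calibration(
    trials: pd.DataFrame, min_trials: int = 10
) -> CalibrationIndex:
    """Calibration index for one participant's trials.

    Confidence and SPE are each residualized on the participant's
    block-wise mean error magnitude (expanded to trials); the index is the
    negated Pearson correlation of the residuals.
    """
    _check_columns(trials, ("participant", "block", "confidence", "spe",
                           "error_magnitude"))
    participants = trials["participant"].unique()
    if len(participants) != 1:
        raise ValueError(f"expected one participant, got {len(participants)}")
    data = trials.dropna(subset=["confidence", "spe"])
    if len(data) < min_trials:
        raise ValueError(
            f"need >= {min_trials} trials with confidence and spe, got {len(data)}"
        )
    if data["confidence"].nunique() < 2 or data["spe"].nunique() < 2:
        warnings.warn("zero variance in confidence or spe; index undefined",
                      stacklevel=2)
        return CalibrationIndex(participants[0], float("nan"), len(data))
    block_em = data.groupby("block")["error_magnitude"].transform("mean")
    conf_res = _residualize(data["confidence"].to_numpy(), block_em.to_numpy())
    spe_res = _residualize(data["spe"].to_numpy(), block_em.to_numpy())
    r = float(np.corrcoef(conf_res, spe_res)[0, 1])
    return CalibrationIndex(participants[0], -r, len(data))


def _residualize(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def scale_predictors(table: pd.DataFrame) -> pd.DataFrame:
    """Rescale and center predictors for trial-level regressions.

    Error magnitude, RPE and SPE go from ms to s; confidence (in [0, 1])
    and block (1..5) are mapped onto [-1, 1].  Block, error magnitude,
    confidence and SPE are then median-centered; RPE is left uncentered
    because zero is meaningful (outcome exactly as predicted).
    """
    _check_columns(table, ("error_magnitude", "rpe", "spe", "confidence", "block"))
    out = table.copy()
    for col in ("error_magnitude", "rpe", "spe"):
        out[col] = out[col] / 1000.0
    out["confidence"] = out["confidence"] * 2.0 - 1.0
    out["block"] = (out["block"] - 3.0) / 2.0
    for col in ("block", "error_magnitude", "confidence", "spe"):
        out[col] = out[col] - out[col].median()
    return out


def log_error_magnitude(em: pd.Series | np.ndarray) -> np.ndarray:
    """Natural log of error magnitude with a zero guard.

    Zeros are replaced by half the smallest positive value before taking
    the log (a log of zero would be -inf and break the regressions).
    """
    em = np.asarray(em, dtype=float)
    if np.any(em < 0):
        raise ValueError("error magnitude must be nonnegative")
    positive = em[em > 0]
    if positive.size == 0:
        raise ValueError("error magnitude is identically zero")
    floor = positive.min() / 2.0
    return np.log(np.where(em > 0, em, floor))


def fit_trial_model(
    table: pd.DataFrame,
    outcome: str,
    terms: str,
    group: str | None = None,
) -> pd.DataFrame:
    """Fixed-effects least-squares fit of ``outcome ~ terms``.

    ``terms`` is a patsy-style right-hand side (e.g.
    ``"prediction * block * confidence"``).  With ``group`` set, that
    column is added as a categorical covariate absorbing per-group
    intercepts.  Returns a coefficient table with estimate, standard
    error, t statistic and two-sided p value, plus the model R^2 in
    ``attrs``.  Rank-deficient designs raise, naming the collinear terms.
    """
    rhs = terms if group is None else f"{terms} + C({group})"
    model = smf.ols(f"{outcome} ~ {rhs}", data=table)
    rank = np.linalg.matrix_rank(model.exog)
    if rank < model.exog.shape[1]:
        names = model.exog_names
        # identify columns whose removal restores full column rank
        collinear = [
            names[j]
            for j in range(model.exog.shape[1])
            if np.linalg.matrix_rank(np.delete(model.exog, j, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient design; collinear terms: {collinear}")
    res = model.fit()
    coefs = pd.DataFrame(
        {
            "estimate": res.params,
            "se": res.bse,
            "t": res.tvalues,
            "p": res.pvalues,
        }
    )
    coefs.attrs["r_squared"] = float(res.rsquared)
    coefs.attrs["nobs"] = int(res.nobs)
    return coefs
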