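"""Handcrafted per-segment features for classical baselines.

One row per ω-second segment, computed from the *raw* (unstandardized)
channels:

* accelerometry — per axis and for the magnitude: mean, SD, min, max, energy
  (mean squared amplitude) and entropy (Shannon entropy, in nats, of a
  16-bin value histogram);
* electrodermal activity — tonic/phasic split by a zero-phase low-pass at
  0.05 Hz: mean and SD of each component, plus the count of phasic peaks
  above 0.01 µS prominence;
* heart-rate variability, from interbeat events falling inside the segment
  window — mean NN, SDNN, RMSSD, pNN50 (50 ms threshold);
* temperature — mean and SD.

Features that cannot be computed (e.g. fewer than two interbeat intervals in
the window) are flagged missing and later mean-imputed from training rows
only, so no statistic leaks across splits.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import signal as sg

from .preprocess import Segment
from .session import IBISeries

__all__ = ["FEATURE_NAMES", "extract_features", "extract_matrix", "impute_missing",
           "missingness_report"]

_ACC_STATS = ("mean", "sd", "min", "max", "energy", "entropy")
_ACC_SOURCES = ("acc_x", "acc_y", "acc_z", "acc_mag")

FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"{src}_{stat}" for src in _ACC_SOURCES for stat in _ACC_STATS]
    + ["eda_tonic_mean", "eda_tonic_sd", "eda_phasic_mean", "eda_phasic_sd",
       "eda_phasic_peaks"]
    + ["hrv_mean_nn", "hrv_sdnn", "hrv_rmssd", "hrv_pnn50"]
    + ["temp_mean", "temp_sd"]
)

ENTROPY_BINS = 16
EDA_LOWPASS_HZ = 0.05
PEAK_PROMINENCE_US = 0.01
PNN_THRESHOLD_S = 0.050


def signal_energy(x: np.ndarray) -> float:
    """Mean squared amplitude."""
    return float(np.mean(np.square(x)))


def signal_entropy(x: np.ndarray, bins: int = ENTROPY_BINS) -> float:
    """Shannon entropy (nats) of the value histogram; 0 for a constant signal."""
    if np.ptp(x) == 0:
        return 0.0
    counts, _ = np.histogram(x, bins=bins)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def _acc_stats(x: np.ndarray) -> list[float]:
    return [
        float(np.mean(x)), float(np.std(x)), float(np.min(x)), float(np.max(x)),
        signal_energy(x), signal_entropy(x),
    ]


def _eda_features(eda: np.ndarray, fs: float) -> list[float]:
    nyq = fs / 2.0
    if EDA_LOWPASS_HZ >= nyq or len(eda) < 13:  # filtfilt needs padding room
        tonic = np.full_like(eda, np.mean(eda))
    else:
        b, a = sg.butter(2, EDA_LOWPASS_HZ / nyq)
        tonic = sg.filtfilt(b, a, eda)
    phasic = eda - tonic
    peaks, _ = sg.find_peaks(phasic, prominence=PEAK_PROMINENCE_US)
    return [
        float(np.mean(tonic)), float(np.std(tonic)),
        float(np.mean(phasic)), float(np.std(phasic)),
        float(len(peaks)),
    ]


def _hrv_features(ibi: IBISeries | None, t_start: float, t_end: float) -> list[float]:
    if ibi is None:
        return [math.nan] * 4
    inside = (ibi.event_times >= t_start) & (ibi.event_times < t_end)
    nn = ibi.intervals[inside]
    if len(nn) < 2:
        return [math.nan] * 4
    dnn = np.diff(nn)
    return [
        float(np.mean(nn)),
        float(np.std(nn)),  # SDNN
        float(np.sqrt(np.mean(dnn**2))),  # RMSSD
        float(np.mean(np.abs(dnn) > PNN_THRESHOLD_S)),  # pNN50
    ]


def extract_features(segment: Segment, ibi: IBISeries | None = None) -> pd.Series:
    """One named feature row for a raw segment; NaN marks missing features."""
    values: list[float] = []
    axes = {name: segment.channels[name] for name in ("acc_x", "acc_y", "acc_z")}
    mag = np.sqrt(sum(np.square(v) for v in axes.values()))
    for src in _ACC_SOURCES:
        x = mag if src == "acc_mag" else axes[src]
        values.extend(_acc_stats(x))
    values.extend(_eda_features(segment.channels["eda"], segment.fs["eda"]))
    values.extend(_hrv_features(ibi, segment.start_offset, segment.start_offset + segment.omega))
    temp = segment.channels["temp"]
    values.extend([float(np.mean(temp)), float(np.std(temp))])
    return pd.Series(values, index=list(FEATURE_NAMES))


def extract_matrix(
    segments: list[Segment], ibi_by_session: dict[str, IBISeries] | None = None,
) -> pd.DataFrame:
    """Feature matrix with segment metadata columns prepended."""
    ibi_by_session = ibi_by_session or {}
    rows = []
    for seg in segments:
        row = extract_features(seg, ibi_by_session.get(seg.session_id))
        row["session_id"] = seg.session_id
        row["subject_id"] = seg.subject_id
        row["start_offset"] = seg.start_offset
        row["label"] = seg.label
        rows.append(row)
    frame = pd.DataFrame(rows).reset_index(drop=True)
    meta = ["session_id", "subject_id", "start_offset", "label"]
    return frame[meta + list(FEATURE_NAMES)]


def impute_missing(matrix: pd.DataFrame, fit_rows: np.ndarray | list[int]) -> pd.DataFrame:
    """Mean-impute missing cells using column means over ``fit_rows`` only.

    A column entirely missing within the fitting rows is imputed with 0 and a
    warning is raised.  Rows outside ``fit_rows`` never influence the means.
    """
    import warnings

    out = matrix.copy()
    fit_idx = np.asarray(fit_rows)
    cols = [c for c in FEATURE_NAMES if c in out.columns]
    for col in cols:
        fit_values = out.loc[out.index[fit_idx], col].astype(float)
        mean = fit_values.mean()
        if math.isnan(mean):
            warnings.warn(f"feature {col!r} entirely missing in fitting rows; imputing 0")
            mean = 0.0
        out[col] = out[col].astype(float).fillna(mean)
    return out


def missingness_report(matrix: pd.DataFrame) -> pd.Series:
    """Per-feature percentage of missing values (descriptive)."""
    cols = [c for c in FEATURE_NAMES if c in matrix.columns]
    return matrix[cols].isna().mean() * 100.0
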