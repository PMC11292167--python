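"""Turn raw sessions into analysis-ready wake, on-body recording segments.

Pipeline order: off-body detection (EDA/TEMP threshold rules) -> minimum
wear-run enforcement (5 min) -> sleep/wake detection (arm-angle stillness
heuristic) -> sliding-window segmentation of wake spans -> channel-wise
standardization.

Statuses are decided at 1-second resolution and broadcast to all channels by
time interval, since the threshold rules live on the EDA/TEMP clock while the
other channels run at their own rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .session import ChannelSeries, SessionRecord, REQUIRED_CHANNELS

__all__ = [
    "OFF_BODY",
    "SLEEP",
    "WAKE",
    "StatusTimeline",
    "Segment",
    "NormalizationStats",
    "detect_off_body",
    "enforce_min_wear_run",
    "compute_arm_angle",
    "detect_sleep_wake",
    "segment_wake_spans",
    "fit_normalization",
    "standardize",
    "preprocess_session",
]

OFF_BODY, SLEEP, WAKE = 0, 1, 2
_STATUS_NAMES = {OFF_BODY: "off_body", SLEEP: "sleep", WAKE: "wake"}

# threshold rules for wear detection
EDA_MIN_US = 0.05  # below this the electrode has lost skin contact
EDA_MAX_US = 100.0  # sensor range ceiling
TEMP_MIN_C = 30.0
TEMP_MAX_C = 40.0

EPOCH_S = 5  # arm-angle epoch length
ANGLE_DELTA_DEG = 5.0  # stillness threshold on successive epoch angles
MIN_SLEEP_S = 300  # a still run must last at least this long to count as sleep


@dataclass
class StatusTimeline:
    """Per-second classification of a session into off_body / sleep / wake."""

    statuses: np.ndarray  # int8 array of OFF_BODY/SLEEP/WAKE

    def __post_init__(self) -> None:
        self.statuses = np.asarray(self.statuses, dtype=np.int8)

    def __len__(self) -> int:
        return len(self.statuses)

    def seconds_in(self, status: int) -> int:
        return int(np.sum(self.statuses == status))

    def as_labels(self) -> list[str]:
        return [_STATUS_NAMES[int(s)] for s in self.statuses]


@dataclass
class Segment:
    """One ω-second multichannel window of wake, on-body recording."""

    session_id: str
    subject_id: str
    start_offset: int  # seconds since session start
    channels: dict[str, np.ndarray]  # name -> array of length ω * f_c
    fs: dict[str, float]  # name -> sampling rate
    label: str | None = None
    dataset_id: str = "default"

    @property
    def omega(self) -> int:
        name = next(iter(self.channels))
        return int(round(len(self.channels[name]) / self.fs[name]))

    def copy(self) -> "Segment":
        return Segment(
            session_id=self.session_id,
            subject_id=self.subject_id,
            start_offset=self.start_offset,
            channels={k: v.copy() for k, v in self.channels.items()},
            fs=dict(self.fs),
            label=self.label,
            dataset_id=self.dataset_id,
        )


@dataclass
class NormalizationStats:
    """Per-channel mean/SD, learned only from designated fitting data.

    SD is the population SD (divide by n).  Channels whose SD is zero are
    listed in ``degenerate``; :func:`standardize` guards them with ε.
    """

    mean: dict[str, float]
    sd: dict[str, float]
    scope: str = "train"
    degenerate: tuple[str, ...] = field(default_factory=tuple)


def _per_second_any(values: np.ndarray, fs: float, n_seconds: int, predicate) -> np.ndarray:
    """True for seconds where ``predicate`` holds for any sample in [s, s+1)."""
    out = np.zeros(n_seconds, dtype=bool)
    for s in range(n_seconds):
        lo = int(round(s * fs))
        hi = int(round((s + 1) * fs))
        chunk = values[lo:hi]
        if chunk.size:
            out[s] = bool(np.any(predicate(chunk)))
    return out


def detect_off_body(eda: ChannelSeries, temp: ChannelSeries) -> np.ndarray:
    """Per-second off-body flags from the electrodermal and temperature rules.

    A second is off-body iff any EDA sample in it is < 0.05 µS or exceeds the
    100 µS sensor range, or any skin-temperature sample falls outside the
    physiological 30-40 °C band.  Flagged-missing (NaN) samples also mark the
    second off-body: a sample we cannot trust cannot prove skin contact.

    Returns a boolean array (True = off-body) over whole seconds covered by
    both channels.
    """
    if eda is None:
        raise ValueError("off-body detection requires the EDA channel")
    if temp is None:
        raise ValueError("off-body detection requires the TEMP channel")
    n_seconds = int(min(eda.duration, temp.duration))
    eda_bad = _per_second_any(
        eda.values, eda.fs, n_seconds,
        lambda x: ~np.isfinite(x) | (x < EDA_MIN_US) | (x > EDA_MAX_US),
    )
    temp_bad = _per_second_any(
        temp.values, temp.fs, n_seconds,
        lambda x: ~np.isfinite(x) | (x < TEMP_MIN_C) | (x > TEMP_MAX_C),
    )
    return eda_bad | temp_bad


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open [start, end) index pairs."""
    out = []
    n = len(mask)
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def enforce_min_wear_run(off_flags: np.ndarray, min_run_s: int = 300) -> np.ndarray:
    """Relabel on-body runs shorter than ``min_run_s`` seconds as off-body.

    Runs of exactly ``min_run_s`` are kept ("at least" 5 minutes).  The
    operation is idempotent.
    """
    off = np.asarray(off_flags, dtype=bool).copy()
    for start, end in _runs(~off):
        if end - start < min_run_s:
            off[start:end] = True
    return off


def compute_arm_angle(
    acc_x: np.ndarray, acc_y: np.ndarray, acc_z: np.ndarray,
    fs: float, epoch_s: int = EPOCH_S,
) -> np.ndarray:
    """Arm angle per 5-s epoch: atan(z̄ / sqrt(x̄² + ȳ²)) in degrees.

    Each axis is summarized by its median over the epoch.  An epoch with zero
    gravity norm has an undefined angle and is reported as 0° (flat).
    """
    n = min(len(acc_x), len(acc_y), len(acc_z))
    per_epoch = int(round(epoch_s * fs))
    n_epochs = n // per_epoch
    angles = np.zeros(n_epochs)
    for e in range(n_epochs):
        sl = slice(e * per_epoch, (e + 1) * per_epoch)
        mx = np.nanmedian(acc_x[sl])
        my = np.nanmedian(acc_y[sl])
        mz = np.nanmedian(acc_z[sl])
        horiz = np.hypot(mx, my)
        if horiz == 0.0 and mz == 0.0:
            angles[e] = 0.0
        else:
            angles[e] = np.degrees(np.arctan2(mz, horiz))
    return angles


def detect_sleep_wake(
    angle_epochs: np.ndarray,
    off_flags: np.ndarray,
    epoch_s: int = EPOCH_S,
    angle_delta_deg: float = ANGLE_DELTA_DEG,
    min_sleep_s: int = MIN_SLEEP_S,
) -> StatusTimeline:
    """Score sleep vs wake on on-body seconds from arm-angle stillness.

    An on-body stretch is sleep iff it lies inside a maximal run, at least
    ``min_sleep_s`` long, in which no successive-epoch angle change exceeds
    ``angle_delta_deg``.  Runs never bridge off-body gaps: an epoch containing
    any off-body second breaks the run.  Off-body seconds keep their status;
    everything else is wake (including trailing partial epochs).
    """
    off = np.asarray(off_flags, dtype=bool)
    n_seconds = len(off)
    statuses = np.full(n_seconds, WAKE, dtype=np.int8)
    statuses[off] = OFF_BODY

    n_epochs = min(len(angle_epochs), n_seconds // epoch_s)
    if n_epochs == 0:
        return StatusTimeline(statuses)

    # epoch usable iff fully on-body
    epoch_on = np.array([
        not np.any(off[e * epoch_s:(e + 1) * epoch_s]) for e in range(n_epochs)
    ])
    # still[e] true iff the change from epoch e-1 to e is small; the first
    # epoch of an on-body run has no predecessor within the run and starts one
    min_epochs = int(np.ceil(min_sleep_s / epoch_s))
    e = 0
    while e < n_epochs:
        if not epoch_on[e]:
            e += 1
            continue
        # maximal on-body epoch run [e, j)
        j = e
        while j < n_epochs and epoch_on[j]:
            j += 1
        # within it, split into maximal still runs
        k = e
        while k < j:
            m = k + 1
            while m < j and abs(angle_epochs[m] - angle_epochs[m - 1]) <= angle_delta_deg:
                m += 1
            if (m - k) * epoch_s >= min_sleep_s and (m - k) >= min_epochs:
                statuses[k * epoch_s:m * epoch_s] = SLEEP
            k = m
        e = j
    return StatusTimeline(statuses)


def segment_wake_spans(
    session: SessionRecord,
    timeline: StatusTimeline,
    omega: int = 512,
    step: int = 128,
) -> list[Segment]:
    """Slice every maximal contiguous wake span into overlapping windows.

    Within a wake span of length L ≥ ω, windows start at span_start + k·Δω for
    k = 0 .. floor((L − ω)/Δω), giving floor((L − ω)/Δω) + 1 segments.  Spans
    shorter than ω yield none.  Segments never straddle non-wake seconds and
    inherit the session label.
    """
    wake = timeline.statuses == WAKE
    segments: list[Segment] = []
    deep = {name: session.channels[name] for name in REQUIRED_CHANNELS
            if name in session.channels}
    for span_start, span_end in _runs(wake):
        L = span_end - span_start
        if L < omega:
            continue
        n_windows = (L - omega) // step + 1
        for k in range(n_windows):
            start = span_start + k * step
            chans = {}
            ok = True
            for name, ch in deep.items():
                lo = int(round(start * ch.fs))
                hi = lo + int(round(omega * ch.fs))
                if hi > len(ch.values):
                    ok = False
                    break
                chans[name] = ch.values[lo:hi].copy()
            if not ok:
                continue
            segments.append(Segment(
                session_id=session.session_id,
                subject_id=session.subject_id,
                start_offset=start,
                channels=chans,
                fs={name: deep[name].fs for name in chans},
                label=session.label,
                dataset_id=session.dataset_id,
            ))
    return segments


def fit_normalization(segments: list[Segment], scope: str = "train") -> NormalizationStats:
    """Per-channel mean and population SD over all samples of ``segments``."""
    if not segments:
        raise ValueError("cannot fit normalization statistics on an empty collection")
    names = list(segments[0].channels)
    mean, sd, degenerate = {}, {}, []
    for name in names:
        pooled = np.concatenate([s.channels[name] for s in segments])
        pooled = pooled[np.isfinite(pooled)]
        mean[name] = float(np.mean(pooled))
        sd[name] = float(np.std(pooled))  # population SD
        if sd[name] == 0.0:
            degenerate.append(name)
    return NormalizationStats(mean=mean, sd=sd, scope=scope, degenerate=tuple(degenerate))


def standardize(segment: Segment, stats: NormalizationStats, eps: float = 1e-8) -> Segment:
    """Return a copy with each channel mapped to (x − mean)/max(SD, ε)."""
    out = segment.copy()
    for name, values in out.channels.items():
        denom = max(stats.sd[name], eps)
        out.channels[name] = (values - stats.mean[name]) / denom
    return out


def preprocess_session(
    session: SessionRecord, omega: int = 512, step: int = 128,
) -> tuple[StatusTimeline, list[Segment]]:
    """Full pipeline: off-body → min-wear-run → sleep/wake → segmentation."""
    off = detect_off_body(session.channels["eda"], session.channels["temp"])
    off = enforce_min_wear_run(off)
    acc_fs = session.channels["acc_x"].fs
    angles = compute_arm_angle(
        session.channels["acc_x"].values,
        session.channels["acc_y"].values,
        session.channels["acc_z"].values,
        fs=acc_fs,
    )
    timeline = detect_sleep_wake(angles, off)
    segments = segment_wake_spans(session, timeline, omega=omega, step=step)
    return timeline, segments
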