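"""Synthetic E4-style cohorts with controlled wear, sleep and class structure.

The generator emulates the wristband export well enough to exercise every
downstream stage: native sampling rates (32 Hz triaxial acceleration, 64 Hz
blood volume pulse, 4 Hz electrodermal activity and skin temperature, 1 Hz
heart rate, event-based interbeat intervals), hour-level wear/nonwear bouts,
sleep bouts with a near-constant arm angle, and a tunable two-class
physiological effect (acute episode vs euthymia).

Physiology model per channel: baseline + circadian sinusoid + AR(1) noise.
The pulse signal is an amplitude-modulated oscillation at the instantaneous
heart rate; interbeat intervals are derived from the same rate trace.

Subjects share channel baselines by default (``subject_jitter=0``): under a
zero class effect the labels are then exchangeable, which is what calibration
tests of the end-to-end classifier require.  Real cohorts have stable
inter-individual offsets; switch them on via ``subject_jitter`` when that
realism matters more than null calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .session import ChannelSeries, IBISeries, SessionRecord

__all__ = ["SynthConfig", "generate_session", "generate_session_with_truth", "generate_cohort"]

_DEFAULT_EFFECT = {"eda_mean": 1.0, "activity_scale": 1.5, "hr_mean": 5.0}
_DEFAULT_NOISE = {"acc": 0.03, "bvp": 0.15, "eda": 0.03, "temp": 0.05, "hr": 1.0}

FS = {"acc": 32.0, "bvp": 64.0, "eda": 4.0, "temp": 4.0, "hr": 1.0}


@dataclass
class SynthConfig:
    """Conditions under which a synthetic cohort is generated.

    ``effect`` holds per-channel class offsets applied to the acute class:
    ``eda_mean`` (µS shift), ``activity_scale`` (multiplier on wake movement
    bursts), ``hr_mean`` (bpm shift).  ``seed`` fully determines the output.
    """

    n_subjects: int = 8
    class_ratio: float = 0.5  # fraction of subjects labeled acute
    session_hours: float = 2.0
    wear_prob: float = 0.9  # per-hour probability the device is worn
    sleep_window: tuple[float, float] | None = None  # hours since session start
    nonwear_bouts: tuple[tuple[float, float], ...] = ()  # explicit (start_s, end_s)
    effect: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_EFFECT))
    noise_sd: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_NOISE))
    subject_jitter: float = 0.0  # SD of per-subject baseline offsets, in channel units
    start_hour: float = 12.0  # clock hour of session start (sets circadian phase)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.class_ratio <= 1.0:
            raise ValueError("class_ratio must lie in [0, 1]")
        if self.session_hours <= 0:
            raise ValueError("session_hours must be positive")


def _ar1(rng: np.random.Generator, n: int, sd: float, phi: float = 0.95) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sd``."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    from scipy.signal import lfilter

    innov_sd = sd * np.sqrt(1.0 - phi**2)
    eps = rng.normal(0.0, innov_sd, size=n)
    x0 = rng.normal(0.0, sd)
    # y[i] = eps[i] + phi * y[i-1], seeded with a stationary draw y[-1] = x0
    out, _ = lfilter([1.0], [1.0, -phi], eps, zi=np.array([phi * x0]))
    return out


def _circadian(hours_of_day: np.ndarray, amplitude: float, peak_hour: float) -> np.ndarray:
    return amplitude * np.cos(2 * np.pi * (hours_of_day - peak_hour) / 24.0)


def _status_truth(cfg: SynthConfig, rng: np.random.Generator, n_seconds: int) -> np.ndarray:
    """Ground-truth per-second status: 0 off-body, 1 sleep, 2 wake."""
    status = np.full(n_seconds, 2, dtype=np.int8)
    if cfg.sleep_window is not None:
        lo = int(cfg.sleep_window[0] * 3600)
        hi = int(cfg.sleep_window[1] * 3600)
        status[max(lo, 0):min(hi, n_seconds)] = 1
    # hour-level wear decisions
    n_hours = int(np.ceil(n_seconds / 3600))
    for h in range(n_hours):
        if rng.random() >= cfg.wear_prob:
            status[h * 3600:(h + 1) * 3600] = 0
    for start_s, end_s in cfg.nonwear_bouts:
        status[int(start_s):int(end_s)] = 0
    return status


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([0.0, 0.0, 1.0])


def generate_session_with_truth(
    cfg: SynthConfig, subject_index: int, label: str | None,
) -> tuple[SessionRecord, np.ndarray]:
    """Generate one session plus its ground-truth per-second status array."""
    rng = np.random.default_rng([cfg.seed, subject_index])
    n_seconds = int(round(cfg.session_hours * 3600))
    t0 = 1_600_000_000.0 + 86_400.0 * subject_index
    status = _status_truth(cfg, rng, n_seconds)
    is_acute = label == "acute"
    eff = {**{k: 0.0 for k in _DEFAULT_EFFECT}, **(cfg.effect if is_acute else {})}
    if not is_acute:
        eff["activity_scale"] = 1.0
    elif "activity_scale" not in cfg.effect:
        eff["activity_scale"] = 1.0

    jit = {
        name: rng.normal(0.0, cfg.subject_jitter) if cfg.subject_jitter > 0 else 0.0
        for name in ("eda", "temp", "hr")
    }

    sec = np.arange(n_seconds)
    hours_of_day = (cfg.start_hour + sec / 3600.0) % 24.0
    sleep_sec = status == 1
    off_sec = status == 0

    def upsample(per_second: np.ndarray, fs: float) -> np.ndarray:
        return np.repeat(per_second, int(fs))

    # ---- heart rate (1 Hz), shared driver for BVP and IBI -------------------
    hr_base = 70.0 + jit["hr"] + eff["hr_mean"]
    hr = hr_base + _circadian(hours_of_day, 4.0, peak_hour=16.0)
    hr = hr - 10.0 * sleep_sec
    hr = hr + _ar1(rng, n_seconds, cfg.noise_sd["hr"])
    hr = np.clip(hr, 40.0, 180.0)

    # ---- EDA (4 Hz) ---------------------------------------------------------
    n_eda = int(n_seconds * FS["eda"])
    eda_sec = 0.4 + jit["eda"] + eff["eda_mean"] + _circadian(hours_of_day, 0.1, 15.0)
    eda_sec = eda_sec - 0.1 * sleep_sec
    eda = upsample(eda_sec, FS["eda"]) + _ar1(rng, n_eda, cfg.noise_sd["eda"])
    eda = np.clip(eda, 0.06, None)
    off_eda = upsample(off_sec.astype(float), FS["eda"]).astype(bool)
    eda[off_eda] = np.clip(0.005 + rng.normal(0.0, 0.005, size=off_eda.sum()), 0.0, 0.04)

    # ---- TEMP (4 Hz) --------------------------------------------------------
    n_temp = int(n_seconds * FS["temp"])
    temp_sec = 33.5 + jit["temp"] + _circadian(hours_of_day, 0.4, 3.0) + 0.3 * sleep_sec
    temp = upsample(temp_sec, FS["temp"]) + _ar1(rng, n_temp, cfg.noise_sd["temp"])
    temp = np.clip(temp, 30.5, 39.5)
    off_temp = upsample(off_sec.astype(float), FS["temp"]).astype(bool)
    temp[off_temp] = 26.0 + rng.normal(0.0, 0.5, size=off_temp.sum())

    # ---- ACC (32 Hz): gravity orientation + wake movement bursts ------------
    n_acc = int(n_seconds * FS["acc"])
    orient = np.empty((n_seconds, 3))
    current = _random_unit_vector(rng)
    for s in range(n_seconds):
        if status[s] == 2 and rng.random() < 1.0 / 30.0:  # posture change ~every 30 s awake
            current = _random_unit_vector(rng)
        elif status[s] == 0 and s > 0 and status[s - 1] != 0:
            current = np.array([0.0, 0.0, 1.0])  # device set down flat
        orient[s] = current
    gravity = np.repeat(orient, int(FS["acc"]), axis=0)
    activity_amp = 0.1 * eff["activity_scale"]
    burst = upsample((status == 2).astype(float), FS["acc"]) * activity_amp
    acc = gravity + rng.normal(0.0, 1.0, size=(n_acc, 3)) * burst[:, None]
    acc += np.stack([_ar1(rng, n_acc, cfg.noise_sd["acc"]) for _ in range(3)], axis=1)

    # ---- BVP (64 Hz): amplitude-modulated pulse oscillation ------------------
    n_bvp = int(n_seconds * FS["bvp"])
    hr_bvp = np.repeat(hr, int(FS["bvp"]))
    phase = 2 * np.pi * np.cumsum(hr_bvp / 60.0) / FS["bvp"]
    resp = 1.0 + 0.2 * np.sin(2 * np.pi * 0.25 * np.arange(n_bvp) / FS["bvp"])
    bvp = resp * np.sin(phase) + _ar1(rng, n_bvp, cfg.noise_sd["bvp"])
    off_bvp = upsample(off_sec.astype(float), FS["bvp"]).astype(bool)
    bvp[off_bvp] = rng.normal(0.0, 0.02, size=off_bvp.sum())

    # ---- IBI events from the heart-rate trace -------------------------------
    beat_times = []
    t = 0.0
    while t < n_seconds:
        beat_times.append(t)
        rate = hr[min(int(t), n_seconds - 1)]
        t += 60.0 / rate
    beat_times = np.asarray(beat_times)
    ibi = None
    if len(beat_times) > 1:
        ibi = IBISeries(event_times=beat_times[1:], intervals=np.diff(beat_times))

    subject_id = f"subj{subject_index:03d}"
    session = SessionRecord(
        session_id=f"{subject_id}_s0",
        subject_id=subject_id,
        dataset_id="synthetic",
        label=label,
        channels={
            "acc_x": ChannelSeries("acc_x", acc[:, 0], FS["acc"], t0),
            "acc_y": ChannelSeries("acc_y", acc[:, 1], FS["acc"], t0),
            "acc_z": ChannelSeries("acc_z", acc[:, 2], FS["acc"], t0),
            "bvp": ChannelSeries("bvp", bvp, FS["bvp"], t0),
            "eda": ChannelSeries("eda", eda, FS["eda"], t0),
            "temp": ChannelSeries("temp", temp, FS["temp"], t0),
            "hr": ChannelSeries("hr", hr, FS["hr"], t0),
        },
        ibi=ibi,
    )
    return session, status


def generate_session(cfg: SynthConfig, subject_index: int, label: str | None) -> SessionRecord:
    """Generate one subject's session; deterministic in (cfg, subject_index)."""
    return generate_session_with_truth(cfg, subject_index, label)[0]


def generate_cohort(cfg: SynthConfig) -> list[SessionRecord]:
    """Generate ``cfg.n_subjects`` sessions with labels set by ``class_ratio``.

    The first ``round(n_subjects * class_ratio)`` subjects are acute, the rest
    euthymia; subject ids are unique and the whole cohort is reproducible
    under ``cfg.seed``.
    """
    n_acute = int(round(cfg.n_subjects * cfg.class_ratio))
    n_euth = cfg.n_subjects - n_acute
    if cfg.n_subjects < 2 and n_acute > 0 and n_euth > 0:
        raise ValueError("need at least 2 subjects to represent both classes")
    labels = ["acute"] * n_acute + ["euthymia"] * n_euth
    return [generate_session(cfg, i, labels[i]) for i in range(cfg.n_subjects)]
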