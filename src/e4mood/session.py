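"""Reading, writing and validating Empatica-E4-style session exports.

A session is a directory with one CSV per sensor stream, following the
de-facto device export dialect:

* ``EDA.csv`` / ``TEMP.csv`` / ``BVP.csv`` / ``HR.csv`` — first row is the
  UNIX start time of the recording (epoch seconds), second row is the
  sampling rate in Hz, then one sample per line.
* ``ACC.csv`` — same layout but with three comma-separated columns (x, y, z).
* ``IBI.csv`` — first row ``<start>, IBI``; then one ``offset,interval`` pair
  per line (both in seconds, offsets relative to the start time).
* ``session.json`` — a sidecar carrying session/subject/dataset identifiers
  and the optional binary label.  This file is a package extension: the raw
  device export has no such metadata, but the data model downstream needs it.

Missing or corrupt samples are represented as NaN ("flagged missing") rather
than dropped, so sample indices stay aligned to time.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "ChannelSeries",
    "IBISeries",
    "SessionRecord",
    "DialectError",
    "SessionValidationError",
    "REQUIRED_CHANNELS",
    "read_session",
    "write_session",
    "validate_session",
]

#: channels every deep-learning segment must provide
REQUIRED_CHANNELS = ("acc_x", "acc_y", "acc_z", "bvp", "eda", "temp")

#: mapping from export file stem to the channel names it contributes
_FILE_CHANNELS = {
    "ACC": ("acc_x", "acc_y", "acc_z"),
    "BVP": ("bvp",),
    "EDA": ("eda",),
    "TEMP": ("temp",),
    "HR": ("hr",),
}


class DialectError(ValueError):
    """The on-disk export does not follow the expected CSV dialect."""


class SessionValidationError(ValueError):
    """Session content violates a hard invariant (e.g. non-monotone IBI)."""


@dataclass
class ChannelSeries:
    """One uniformly sampled sensor stream.

    Parameters
    ----------
    name:
        Channel identifier (``acc_x``, ``acc_y``, ``acc_z``, ``bvp``, ``eda``,
        ``temp`` or ``hr``).
    values:
        Samples as a float array; NaN marks flagged-missing values.
    fs:
        Sampling rate in Hz; must be positive.
    t0:
        Session start time, UNIX epoch seconds.  All channels of one session
        share the same ``t0``.
    """

    name: str
    values: np.ndarray
    fs: float
    t0: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def duration(self) -> float:
        """Length of the stream in seconds."""
        return len(self.values) / self.fs if self.fs > 0 else math.nan


@dataclass
class IBISeries:
    """Interbeat intervals: times between consecutive ventricular contractions.

    ``event_times`` are seconds since the session start (strictly increasing);
    ``intervals[i]`` is the interval, in seconds, ending at ``event_times[i]``.
    """

    event_times: np.ndarray
    intervals: np.ndarray

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        self.intervals = np.asarray(self.intervals, dtype=float)
        if len(self.event_times) != len(self.intervals):
            raise SessionValidationError("IBI event_times and intervals differ in length")
        if np.any(np.diff(self.event_times) <= 0):
            raise SessionValidationError("IBI event times must be strictly increasing")
        if np.any(self.intervals <= 0):
            raise SessionValidationError("IBI intervals must be positive")


@dataclass
class SessionRecord:
    """One subject-device recording: multirate channels plus optional IBI."""

    session_id: str
    subject_id: str
    dataset_id: str = "default"
    label: str | None = None  # "acute" | "euthymia" | None
    channels: dict[str, ChannelSeries] = field(default_factory=dict)
    ibi: IBISeries | None = None

    @property
    def t0(self) -> float:
        if not self.channels:
            raise SessionValidationError("session has no channels")
        return next(iter(self.channels.values())).t0

    @property
    def duration(self) -> float:
        """Session duration in seconds: the shortest channel duration."""
        return min(ch.duration for ch in self.channels.values())

    def copy(self) -> "SessionRecord":
        return SessionRecord(
            session_id=self.session_id,
            subject_id=self.subject_id,
            dataset_id=self.dataset_id,
            label=self.label,
            channels={
                k: replace(v, values=v.values.copy()) for k, v in self.channels.items()
            },
            ibi=None
            if self.ibi is None
            else IBISeries(self.ibi.event_times.copy(), self.ibi.intervals.copy()),
        )


def _parse_header_row(line: str, path: Path) -> list[float]:
    try:
        return [float(tok) for tok in line.strip().split(",") if tok.strip() != ""]
    except ValueError as exc:
        raise DialectError(f"{path.name}: malformed header row {line!r}") from exc


def _read_channel_file(path: Path) -> tuple[float, float, np.ndarray]:
    """Return (t0, fs, samples) from a single-stream export file."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 2:
        raise DialectError(f"{path.name}: expected start-time and sampling-rate rows")
    t0_row = _parse_header_row(lines[0], path)
    fs_row = _parse_header_row(lines[1], path)
    if not t0_row or not fs_row:
        raise DialectError(f"{path.name}: empty header row")
    n_cols = len(t0_row)
    if len(fs_row) != n_cols:
        raise DialectError(f"{path.name}: start-time and rate rows disagree on columns")
    body = []
    for line in lines[2:]:
        if not line.strip():
            continue
        toks = line.split(",")
        if len(toks) != n_cols:
            raise DialectError(f"{path.name}: row with {len(toks)} columns, expected {n_cols}")
        body.append([_to_float(tok) for tok in toks])
    data = np.asarray(body, dtype=float).reshape(-1, n_cols)
    return t0_row[0], fs_row[0], data


def _to_float(tok: str) -> float:
    tok = tok.strip()
    if tok in ("", "nan", "NaN", "NA"):
        return math.nan
    return float(tok)


def read_session(directory_path: str | Path) -> SessionRecord:
    """Read an E4-style export directory into a :class:`SessionRecord`.

    EDA, TEMP, ACC and BVP files are required; HR and IBI are optional.
    Sampling rates and the start time are taken from file headers, never
    assumed.
    """
    directory = Path(directory_path)
    if not directory.is_dir():
        raise FileNotFoundError(f"no such session directory: {directory}")

    channels: dict[str, ChannelSeries] = {}
    t0: float | None = None
    for stem in ("EDA", "TEMP", "ACC", "BVP", "HR"):
        path = directory / f"{stem}.csv"
        if not path.exists():
            if stem == "HR":
                continue
            raise DialectError(f"missing required export file {stem}.csv in {directory}")
        file_t0, fs, data = _read_channel_file(path)
        if t0 is None:
            t0 = file_t0
        names = _FILE_CHANNELS[stem]
        if data.shape[1] != len(names):
            raise DialectError(f"{stem}.csv: expected {len(names)} columns, got {data.shape[1]}")
        for j, name in enumerate(names):
            channels[name] = ChannelSeries(name=name, values=data[:, j], fs=fs, t0=file_t0)

    ibi = None
    ibi_path = directory / "IBI.csv"
    if ibi_path.exists():
        with open(ibi_path) as fh:
            lines = [ln for ln in fh.read().splitlines() if ln.strip()]
        if not lines:
            raise DialectError("IBI.csv: empty file")
        # header: "<t0>, IBI"
        try:
            float(lines[0].split(",")[0])
        except ValueError as exc:
            raise DialectError("IBI.csv: malformed header") from exc
        pairs = []
        for line in lines[1:]:
            toks = line.split(",")
            if len(toks) != 2:
                raise DialectError(f"IBI.csv: malformed row {line!r}")
            pairs.append((float(toks[0]), float(toks[1])))
        if pairs:
            arr = np.asarray(pairs)
            ibi = IBISeries(event_times=arr[:, 0], intervals=arr[:, 1])

    meta_path = directory / "session.json"
    meta = {}
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    return SessionRecord(
        session_id=meta.get("session_id", directory.name),
        subject_id=meta.get("subject_id", directory.name),
        dataset_id=meta.get("dataset_id", "default"),
        label=meta.get("label"),
        channels=channels,
        ibi=ibi,
    )


def _fmt(x: float) -> str:
    return "nan" if math.isnan(x) else repr(float(x))


def write_session(session: SessionRecord, directory_path: str | Path) -> Path:
    """Write a session in the export dialect; inverse of :func:`read_session`.

    Round-trips losslessly (``repr`` float formatting preserves the value
    exactly, so write -> read -> write is byte-identical).
    """
    if not session.channels:
        raise SessionValidationError("cannot write a session with no channels")
    directory = Path(directory_path)
    directory.mkdir(parents=True, exist_ok=True)

    for stem, names in _FILE_CHANNELS.items():
        present = [n for n in names if n in session.channels]
        if not present:
            continue
        if len(present) != len(names):
            raise SessionValidationError(f"partial channel group for {stem}.csv: {present}")
        series = [session.channels[n] for n in names]
        fs = series[0].fs
        t0 = series[0].t0
        lines = [
            ",".join(_fmt(t0) for _ in names),
            ",".join(_fmt(fs) for _ in names),
        ]
        cols = [s.values for s in series]
        n = len(cols[0])
        for i in range(n):
            lines.append(",".join(_fmt(c[i]) for c in cols))
        (directory / f"{stem}.csv").write_text("\n".join(lines) + "\n")

    if session.ibi is not None:
        lines = [f"{_fmt(session.t0)}, IBI"]
        for t, iv in zip(session.ibi.event_times, session.ibi.intervals):
            lines.append(f"{_fmt(t)},{_fmt(iv)}")
        (directory / "IBI.csv").write_text("\n".join(lines) + "\n")

    meta = {
        "session_id": session.session_id,
        "subject_id": session.subject_id,
        "dataset_id": session.dataset_id,
        "label": session.label,
    }
    (directory / "session.json").write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")
    return directory


def validate_session(session: SessionRecord) -> list[str]:
    """Check session invariants; return a list of findings (never raises).

    Findings cover: nonpositive sampling rates, missing required channels,
    start-time disagreement, and channel durations that differ by more than
    one sample period of the slowest channel.
    """
    findings: list[str] = []
    if not session.channels:
        return ["session has no channels"]

    for name, ch in session.channels.items():
        if not ch.fs > 0:
            findings.append(f"{name}: nonpositive sampling rate ({ch.fs})")

    for name in REQUIRED_CHANNELS:
        if name not in session.channels:
            findings.append(f"missing required channel {name}")

    t0s = {ch.t0 for ch in session.channels.values()}
    if len(t0s) > 1:
        findings.append(f"channels disagree on start time: {sorted(t0s)}")

    rated = [ch for ch in session.channels.values() if ch.fs > 0]
    if len(rated) > 1:
        slowest = min(ch.fs for ch in rated)
        tol = 1.0 / slowest
        durations = {ch.name: ch.duration for ch in rated}
        dmin, dmax = min(durations.values()), max(durations.values())
        if dmax - dmin > tol:
            findings.append(
                "channel durations mismatch beyond one slow-channel sample period: "
                + ", ".join(f"{k}={v:.2f}s" for k, v in sorted(durations.items()))
            )
    return findings
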