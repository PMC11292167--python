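"""Self-supervision schemes: masked prediction and transformation prediction.

Masked prediction (MP) corrupts each channel with a Boolean mask whose
masked / unmasked run lengths follow geometric distributions with means
``l0`` and ``l1 = l0 * (1 - r) / r`` (``r`` the masking ratio), zeroes the
masked positions, and scores a reconstruction by the RMSE over masked
positions only.

Transformation prediction (TP) draws one of six augmentations per channel —
identity, Gaussian noise, magnitude warping, permutation, time warping,
cropping — applies it, and scores a per-channel 6-way classifier by the
channel-average categorical cross-entropy.

``l0`` is specified in seconds and converted per channel through its sampling
rate, so a 3-second run is 96 samples at 32 Hz but 192 at 64 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .preprocess import Segment

__all__ = [
    "MaskSpec",
    "TRANSFORM_KINDS",
    "TransformAssignment",
    "sample_mask",
    "sample_segment_masks",
    "apply_mask",
    "mp_loss",
    "sample_transforms",
    "apply_transform",
    "apply_assignment",
    "tp_loss",
]

TRANSFORM_KINDS = (
    "identity",
    "gaussian_noise",
    "magnitude_warp",
    "permutation",
    "time_warp",
    "crop",
)

DEFAULT_TRANSFORM_PARAMS = {
    "gaussian_noise": {"sigma": 0.1},
    "magnitude_warp": {"n_knots": 4, "knot_sd": 0.2},
    "permutation": {"n_blocks": 4},
    "time_warp": {"n_knots": 4, "knot_sd": 0.2},
    "crop": {"fraction": 0.5},
}


@dataclass(frozen=True)
class MaskSpec:
    """Geometric-run masking configuration.

    ``r`` is the masking ratio; ``l0_seconds`` the mean masked-run length.
    The mean unmasked-run length is derived, never set independently:
    ``l1 = l0 * (1 - r) / r``.
    """

    r: float = 0.15
    l0_seconds: float = 3.0

    def __post_init__(self) -> None:
        if not 0.0 < self.r < 1.0:
            raise ValueError("masking ratio r must lie strictly between 0 and 1")
        if self.l0_seconds <= 0:
            raise ValueError("mean masked-run length must be positive")

    def l0_samples(self, fs: float) -> int:
        return max(1, int(round(self.l0_seconds * fs)))

    def l1_samples(self, fs: float) -> float:
        l0 = self.l0_samples(fs)
        return l0 * (1.0 - self.r) / self.r


def sample_mask(
    n_samples: int, spec: MaskSpec, rng: np.random.Generator, fs: float = 32.0,
) -> np.ndarray:
    """Sample a Boolean mask of alternating geometric runs (True = masked).

    Masked-run lengths are Geometric with mean ``l0``; unmasked runs have
    mean ``l1``; the first run is masked with probability ``r``; the final
    run is truncated at the sequence end.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    l0 = spec.l0_samples(fs)
    l1 = spec.l1_samples(fs)
    p0 = 1.0 / l0
    p1 = 1.0 / l1
    mask = np.zeros(n_samples, dtype=bool)
    pos = 0
    state_masked = bool(rng.random() < spec.r)
    while pos < n_samples:
        run = int(rng.geometric(p0 if state_masked else p1))
        end = min(pos + run, n_samples)
        if state_masked:
            mask[pos:end] = True
        pos = end
        state_masked = not state_masked
    return mask


def sample_segment_masks(
    segment: Segment, spec: MaskSpec, rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Independent per-channel masks, run lengths scaled by each channel's fs."""
    return {
        name: sample_mask(len(values), spec, rng, fs=segment.fs[name])
        for name, values in segment.channels.items()
    }


def apply_mask(segment: Segment, masks: dict[str, np.ndarray]) -> Segment:
    """Zero masked positions (multiplication by the 0/1 mask); rest untouched."""
    out = segment.copy()
    for name, values in out.channels.items():
        m = np.asarray(masks[name], dtype=bool)
        if len(m) != len(values):
            raise ValueError(f"mask length mismatch on channel {name}")
        values[m] = 0.0
    return out


def mp_loss(
    original: dict[str, np.ndarray],
    reconstruction: dict[str, np.ndarray],
    masks: dict[str, np.ndarray],
) -> float:
    """Masked RMSE: sqrt of the mean squared error over masked positions only."""
    sse = 0.0
    count = 0
    for name, x in original.items():
        m = np.asarray(masks[name], dtype=bool)
        xh = reconstruction[name]
        if len(xh) != len(x) or len(m) != len(x):
            raise ValueError(f"length mismatch on channel {name}")
        diff = np.asarray(x)[m] - np.asarray(xh)[m]
        sse += float(np.sum(diff**2))
        count += int(m.sum())
    if count == 0:
        raise ValueError("mask cardinality |M| is zero; masked RMSE is undefined")
    return float(np.sqrt(sse / count))


@dataclass
class TransformAssignment:
    """One transformation per channel, with its parameters."""

    kinds: tuple[str, ...]
    params: dict[str, dict] = field(default_factory=dict)

    @property
    def indices(self) -> np.ndarray:
        return np.array([TRANSFORM_KINDS.index(k) for k in self.kinds])


def sample_transforms(n_channels: int, rng: np.random.Generator) -> TransformAssignment:
    """Draw one of the six transformation kinds iid uniform per channel."""
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    idx = rng.integers(0, len(TRANSFORM_KINDS), size=n_channels)
    return TransformAssignment(
        kinds=tuple(TRANSFORM_KINDS[i] for i in idx),
        params=dict(DEFAULT_TRANSFORM_PARAMS),
    )


def _spline_envelope(n: int, n_knots: int, knot_sd: float, rng: np.random.Generator) -> np.ndarray:
    # knots at the ends plus n_knots interior positions
    xs = np.linspace(0, n - 1, n_knots + 2)
    ys = rng.normal(1.0, knot_sd, size=n_knots + 2)
    return CubicSpline(xs, ys)(np.arange(n))


def apply_transform(
    x: np.ndarray, kind: str, params: dict | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Apply one augmentation to a (standardized) channel; length-preserving.

    ``identity`` is an exact pass-through; every other kind measurably alters
    the signal under default parameters.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    p = {**DEFAULT_TRANSFORM_PARAMS.get(kind, {}), **(params or {})}
    if kind == "identity":
        return x.copy()
    if rng is None:
        raise ValueError(f"transformation {kind!r} needs a random generator")
    if kind == "gaussian_noise":
        return x + rng.normal(0.0, p["sigma"], size=n)
    if kind == "magnitude_warp":
        return x * _spline_envelope(n, p["n_knots"], p["knot_sd"], rng)
    if kind == "permutation":
        blocks = np.array_split(x, p["n_blocks"])
        order = rng.permutation(len(blocks))
        return np.concatenate([blocks[i] for i in order])
    if kind == "time_warp":
        # distort the time axis with a smooth monotone-ish remap, then resample
        warp = np.cumsum(np.clip(_spline_envelope(n, p["n_knots"], p["knot_sd"], rng), 0.05, None))
        warp = (warp - warp[0]) / (warp[-1] - warp[0]) * (n - 1)
        return np.interp(np.arange(n), warp, x)
    if kind == "crop":
        width = max(2, int(round(n * p["fraction"])))
        start = int(rng.integers(0, n - width + 1))
        window = x[start:start + width]
        return np.interp(np.linspace(0, width - 1, n), np.arange(width), window)
    raise ValueError(f"unknown transformation kind {kind!r}")


def apply_assignment(
    segment: Segment, assignment: TransformAssignment, rng: np.random.Generator,
    channel_order: tuple[str, ...] | None = None,
) -> Segment:
    """Apply one sampled transformation to each channel of a segment."""
    order = channel_order or tuple(segment.channels)
    if len(order) != len(assignment.kinds):
        raise ValueError("assignment length does not match channel count")
    out = segment.copy()
    for name, kind in zip(order, assignment.kinds):
        out.channels[name] = apply_transform(
            out.channels[name], kind, assignment.params.get(kind), rng
        )
    return out


def tp_loss(per_channel_logits: np.ndarray, assignment: TransformAssignment | np.ndarray) -> float:
    """Channel-average categorical cross-entropy of transformation predictions.

    ``per_channel_logits`` has shape (channels, 6) or (batch, channels, 6);
    probabilities come from a softmax over the last axis.
    """
    logits = np.asarray(per_channel_logits, dtype=float)
    targets = assignment.indices if isinstance(assignment, TransformAssignment) else np.asarray(assignment)
    if logits.ndim == 2:
        logits = logits[None]
        targets = np.asarray(targets)[None]
    if logits.shape[:2] != np.asarray(targets).shape[:2] or logits.shape[-1] != len(TRANSFORM_KINDS):
        raise ValueError("logits shape does not match the assignment")
    z = logits - logits.max(axis=-1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=-1, keepdims=True))
    b_idx, c_idx = np.indices(targets.shape)
    nll = -logp[b_idx, c_idx, targets]
    return float(nll.mean())
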