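"""The two self-supervision schemes, worked on arrays.

Masked prediction samples geometric-run Boolean masks (mean masked run 3 s,
masking ratio 0.15), zeroes the masked positions and scores reconstructions
by RMSE over masked positions only.  Transformation prediction draws one of
six augmentations per channel and scores a 6-way per-channel classifier by
channel-average categorical cross-entropy.
"""

import math

import numpy as np

from e4mood.pretext import (
    MaskSpec, TRANSFORM_KINDS, TransformAssignment,
    apply_transform, mp_loss, sample_mask, tp_loss,
)

rng = np.random.default_rng(0)
spec = MaskSpec()  # r = 0.15, l0 = 3 s
mask = sample_mask(1_000_000, spec, rng, fs=32.0)
print(f"masked fraction over 1e6 samples: {mask.mean():.4f}  (target r = {spec.r})")
print(f"derived mean unmasked run: {spec.l1_samples(32):.0f} samples "
      f"(= 96 x 0.85 / 0.15)")

n = 32_768  # one 512 s window of 64 Hz signal
x = {"bvp": rng.normal(size=n)}
m = {"bvp": sample_mask(n, spec, rng, fs=64.0)}
print(f"masked RMSE of a zero reconstruction: "
      f"{mp_loss(x, {'bvp': np.zeros(n)}, m):.3f}  (~1.0 for unit-variance input)")
print(f"masked RMSE of a perfect reconstruction: {mp_loss(x, x, m):.3f}")

assign = TransformAssignment(kinds=TRANSFORM_KINDS)
transformed = [apply_transform(rng.normal(size=256), k, None, rng)
               for k in assign.kinds]
uniform = np.zeros((6, 6))
print(f"transformation CCE under uniform predictions: {tp_loss(uniform, assign):.4f} "
      f"(= ln 6 = {math.log(6):.4f})")

# The masked fraction matches the configured ratio, the unmasked-run mean is
# pinned by l1 = l0 (1-r)/r, and the cross-entropy of an uninformed 6-way
# guess is exactly ln 6 — the closed forms the training losses are built on.
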