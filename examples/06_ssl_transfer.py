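"""Self-supervised pretraining and transfer: linear readout vs fine-tuning.

Pretrains the encoder with masked prediction on all training segments, then
solves the target task from a quarter of the labeled segments under the two
transfer modes.  Linear readout freezes the encoder (its outputs stay
bit-identical); fine-tuning retrains everything from the pretrained
initialization.
"""

import numpy as np

from e4mood import (
    E4mer, ModelConfig, SynthConfig, TrainConfig, evaluate, fit_normalization,
    generate_cohort, predict_segments, preprocess_session, standardize,
    time_split_target, train, transfer,
)
from e4mood.train import LABEL_TO_INT

cfg = SynthConfig(n_subjects=6, session_hours=1.0, wear_prob=1.0,
                  sleep_window=None, seed=7)
segments = []
for session in generate_cohort(cfg):
    _, segs = preprocess_session(session, omega=64, step=32)
    segments.extend(segs)
split = time_split_target(segments)
parts = {k: split.segments(segments, k) for k in ("train", "val", "test")}
stats = fit_normalization(parts["train"])
parts = {k: [standardize(s, stats) for s in v] for k, v in parts.items()}

fs = {k: int(v) for k, v in parts["train"][0].fs.items()}
mcfg = ModelConfig(channel_fs=fs, n_filters=4, d_model=32, n_heads=4,
                   n_layers=2, mlp_hidden=32, dropout=0.1, omega=64, seed=0)

encoder = E4mer(mcfg)
mp = train(encoder, parts["train"], parts["val"],
           TrainConfig(task="mp", lr=3e-3, batch_size=32, max_epochs=4, seed=0))
print(f"masked RMSE: epoch 1 = {mp.history[0]['val_loss']:.3f}, "
      f"best = {mp.best_val:.3f}")

labeled = parts["train"][::4]


def target_accuracy(model):
    probs = predict_segments(model, parts["test"])
    labels = np.array([LABEL_TO_INT[s.label] for s in parts["test"]])
    return evaluate(probs, labels, [s.subject_id for s in parts["test"]]).acc_segment


for mode in ("LR", "FT"):
    clf = transfer(encoder, mode, head_seed=1)
    train(clf, labeled, parts["val"],
          TrainConfig(task="classify", batch_size=32, max_epochs=8, seed=0))
    print(f"{mode}: ACC_segment = {target_accuracy(clf):.3f}")

# Masked RMSE falls as the encoder learns the signal structure.  Both
# transfer modes then solve the (easy, synthetic) target task from a small
# labeled budget; on real data fine-tuning is the stronger of the two.
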