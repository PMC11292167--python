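"""Multirate transformer: token invariants, heads, transfer contracts."""

import numpy as np
import pytest

from e4mood.model import (
    CHANNEL_ORDER,
    E4mer,
    ModelConfig,
    load_checkpoint,
    save_checkpoint,
    segments_to_batch,
    transfer,
)
from e4mood.train import TrainConfig, train

from conftest import TINY_FS, make_segment

OMEGA = 8


def tiny_config(seed=0, dropout=0.0):
    return ModelConfig(channel_fs=dict(TINY_FS), n_filters=2, d_model=8, n_heads=2,
                       n_layers=1, mlp_hidden=8, dropout=dropout, omega=OMEGA, seed=seed)


@pytest.fixture
def model():
    m = E4mer(tiny_config())
    m.eval()
    return m


@pytest.fixture
def batch():
    rng = np.random.default_rng(0)
    return segments_to_batch([make_segment(omega=OMEGA, rng=rng) for _ in range(3)])


def test_every_channel_embeds_to_omega_tokens():
    """One token per second regardless of sampling rate (fs ∈ {1,4,32,64})."""
    rng = np.random.default_rng(1)
    fs = {"acc_x": 32, "acc_y": 32, "acc_z": 32, "bvp": 64, "eda": 4, "temp": 1}
    cfg = ModelConfig(channel_fs=fs, n_filters=2, d_model=8, n_heads=2, n_layers=1,
                      mlp_hidden=8, dropout=0.0, omega=4, seed=0)
    m = E4mer(cfg)
    m.eval()
    b = segments_to_batch([make_segment(omega=4, fs=fs, rng=rng)])
    tokens = m.channel_embed(b)
    assert tokens.shape == (1, 4, 2 * len(CHANNEL_ORDER))  # N=ω, features 6F


def test_indivisible_channel_length_rejected(model):
    bad = {name: np.zeros((1, 7)) for name in CHANNEL_ORDER}
    with pytest.raises(ValueError):
        model.channel_embed(bad)


def test_encode_preserves_token_axis(model, batch):
    reps = model.representations(batch)
    assert reps.shape == (3, OMEGA, model.cfg.d_model)


def test_eval_forward_is_deterministic(model, batch):
    a = model.representations(batch).data
    b = model.representations(batch).data
    np.testing.assert_array_equal(a, b)


def test_batch_order_equivariance(model, batch):
    reps = model.representations(batch).data
    flipped = {k: v[::-1].copy() for k, v in batch.items()}
    reps_flipped = model.representations(flipped).data
    np.testing.assert_allclose(reps_flipped, reps[::-1], atol=1e-10)


def test_classification_probabilities_normalized(model, batch):
    probs = model.classify(model.representations(batch)).data
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
    assert (probs >= 0).all()


def test_untrained_probabilities_center_near_half():
    rng = np.random.default_rng(2)
    vals = []
    for seed in range(8):
        m = E4mer(tiny_config(seed=seed))
        m.eval()
        b = segments_to_batch([make_segment(omega=OMEGA, rng=rng) for _ in range(4)])
        vals.append(m.classify(m.representations(b)).data[:, 1].mean())
    assert np.mean(vals) == pytest.approx(0.5, abs=0.15)


def test_reconstruction_lengths_are_native(model, batch):
    recon = model.reconstruct(model.representations(batch))
    for name in CHANNEL_ORDER:
        assert recon[name].shape == (3, OMEGA * TINY_FS[name])


def test_transform_logits_shape(model, batch):
    logits = model.predict_transforms(model.representations(batch))
    assert logits.shape == (3, 6, 6)


def test_checkpoint_round_trip(tmp_path, model, batch):
    path = save_checkpoint(model, tmp_path / "ckpt.npz")
    again = load_checkpoint(path)
    again.eval()
    np.testing.assert_array_equal(
        again.representations(batch).data, model.representations(batch).data
    )


class TestTransfer:
    def _data(self):
        rng = np.random.default_rng(3)
        segs = []
        for i in range(8):
            label = "acute" if i % 2 else "euthymia"
            seg = make_segment(omega=OMEGA, rng=rng, label=label,
                               subject=f"s{i}", session=f"s{i}_r0")
            segs.append(seg)
        return segs

    def test_lr_freezes_encoder_outputs(self, batch):
        pretrained = E4mer(tiny_config())
        clf = transfer(pretrained, "LR", head_seed=5)
        clf.set_mode(False)
        before = clf.representations(batch).data.copy()
        segs = self._data()
        train(clf, segs, segs, TrainConfig(task="classify", max_epochs=2,
                                           batch_size=4, seed=0))
        clf.set_mode(False)
        after = clf.representations(batch).data
        np.testing.assert_array_equal(before, after)  # bit-identical

    def test_ft_encoder_moves_after_one_step(self):
        pretrained = E4mer(tiny_config())
        clf = transfer(pretrained, "FT", head_seed=5)
        w0 = clf.embed_bvp.conv.weight.data.copy()
        segs = self._data()
        train(clf, segs, segs, TrainConfig(task="classify", max_epochs=1,
                                           batch_size=4, seed=0))
        assert not np.array_equal(clf.embed_bvp.conv.weight.data, w0)

    def test_fresh_head_differs_from_pretraining_head(self):
        pretrained = E4mer(tiny_config())
        clf = transfer(pretrained, "FT", head_seed=5)
        assert not np.array_equal(clf.cls_fc1.weight.data, pretrained.cls_fc1.weight.data)
        # encoder weights are copied over exactly
        np.testing.assert_array_equal(
            clf.embed_eda.conv.weight.data, pretrained.embed_eda.conv.weight.data
        )

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            transfer(E4mer(tiny_config()), "XX")
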