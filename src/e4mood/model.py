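"""The multirate channel-embedding transformer classifier.

Each wristband channel runs at its own sampling rate, so each gets its own
convolutional channel embedding: a 1D convolution with kernel size equal to
the channel's sampling frequency, GELU, 1D BatchNorm, then 1D max pooling
with the sampling frequency as both kernel and stride.  Every channel thus
lands on exactly one token per second (N = ω tokens), and the per-channel
features are concatenated along the feature axis before a linear projection
(plus a learned positional encoding) into the transformer representation
module.  Interchangeable heads sit on top: a classification MLP (softmax over
acute / euthymia), a per-channel reconstruction head for masked prediction,
and a per-channel 6-way head for transformation prediction.

Transfer from a pretrained encoder supports linear readout (LR: encoder
frozen, BatchNorm statistics included) and fine-tuning (FT: everything
trainable from the pretrained initialization); the pretext head is discarded
either way.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor
from .preprocess import Segment

__all__ = ["ModelConfig", "E4mer", "segments_to_batch", "transfer",
           "save_checkpoint", "load_checkpoint"]

CHANNEL_ORDER = ("acc_x", "acc_y", "acc_z", "bvp", "eda", "temp")

DEFAULT_FS = {"acc_x": 32, "acc_y": 32, "acc_z": 32, "bvp": 64, "eda": 4, "temp": 4}

_ENCODER_PREFIXES = ("embed_", "input_proj", "pos_embedding", "encoder_layers")


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``channel_fs`` maps each raw channel to its sampling rate (samples per
    second; the convolution kernel and pooling width).  ``omega`` is the
    segment length in seconds and hence the token count N.
    """

    channel_fs: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_FS))
    n_filters: int = 8
    d_model: int = 64
    n_heads: int = 4
    n_layers: int = 2
    mlp_hidden: int = 64
    dropout: float = 0.1
    omega: int = 512
    n_classes: int = 2
    n_transforms: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")

    def to_json(self) -> str:
        return json.dumps({k: v for k, v in self.__dict__.items()}, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        payload = json.loads(text)
        payload["channel_fs"] = {k: int(v) for k, v in payload["channel_fs"].items()}
        return cls(**payload)


def segments_to_batch(segments: list[Segment]) -> dict[str, np.ndarray]:
    """Stack segments into per-channel (B, L_c) arrays in canonical order."""
    return {
        name: np.stack([s.channels[name] for s in segments])
        for name in CHANNEL_ORDER
    }


class _ChannelEmbed(nn.Module):
    """conv(k=fs) -> GELU -> BatchNorm -> maxpool(k=stride=fs): one token/second."""

    def __init__(self, fs: int, n_filters: int, rng: np.random.Generator):
        super().__init__()
        self.fs = fs
        self.conv = nn.Conv1d(1, n_filters, fs, rng)
        self.bn = nn.BatchNorm1d(n_filters)

    def forward(self, x: Tensor) -> Tensor:  # x: (B, 1, L)
        h = self.conv(x).gelu()
        h = self.bn(h)
        return nn.maxpool1d(h, self.fs)  # (B, F, N)


class E4mer(nn.Module):
    """Channel embeddings + transformer representation module + heads."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        for name in CHANNEL_ORDER:
            setattr(self, f"embed_{name}", _ChannelEmbed(cfg.channel_fs[name], cfg.n_filters, rng))
        d_in = cfg.n_filters * len(CHANNEL_ORDER)
        self.input_proj = nn.Linear(d_in, cfg.d_model, rng)
        self.pos_embedding = nn.Parameter(rng.normal(0.0, 0.02, size=(cfg.omega, cfg.d_model)))
        self.encoder_layers = [
            nn.TransformerEncoderLayer(cfg.d_model, cfg.n_heads, 2 * cfg.d_model,
                                       cfg.dropout, rng)
            for _ in range(cfg.n_layers)
        ]
        # heads
        self.cls_fc1 = nn.Linear(cfg.d_model, cfg.mlp_hidden, rng)
        self.cls_fc2 = nn.Linear(cfg.mlp_hidden, cfg.n_classes, rng)
        for name in CHANNEL_ORDER:
            setattr(self, f"recon_{name}", nn.Linear(cfg.d_model, cfg.channel_fs[name], rng))
        self.tp_fc = nn.Linear(cfg.d_model, len(CHANNEL_ORDER) * cfg.n_transforms, rng)
        self.freeze_encoder = False

    # -- encoder -----------------------------------------------------------
    def channel_embed(self, batch: dict[str, np.ndarray]) -> Tensor:
        """Embed each channel and concatenate: (B, N, 6F)."""
        outs = []
        for name in CHANNEL_ORDER:
            x = np.asarray(batch[name], dtype=float)
            fs = self.cfg.channel_fs[name]
            if x.shape[1] % fs != 0:
                raise ValueError(
                    f"channel {name} length {x.shape[1]} not divisible by fs={fs}"
                )
            emb = getattr(self, f"embed_{name}")(Tensor(x[:, None, :]))
            outs.append(emb.transpose(0, 2, 1))  # (B, N, F)
        return nn.concatenate(outs, axis=-1)

    def encode(self, tokens: Tensor) -> Tensor:
        """Project tokens to d_model, add positions, run the transformer."""
        n = tokens.shape[1]
        h = self.input_proj(tokens) + self.pos_embedding[:n]
        for layer in self.encoder_layers:
            h = layer(h)
        return h  # (B, N, d_model)

    def representations(self, batch: dict[str, np.ndarray]) -> Tensor:
        return self.encode(self.channel_embed(batch))

    # -- heads --------------------------------------------------------------
    def classify_logits(self, reps: Tensor) -> Tensor:
        pooled = reps.mean(axis=1)  # mean over tokens
        return self.cls_fc2(self.cls_fc1(pooled).gelu())

    def classify(self, reps: Tensor) -> Tensor:
        """Probabilities over (euthymia, acute); rows sum to 1."""
        return nn.softmax(self.classify_logits(reps), axis=-1)

    def reconstruct(self, reps: Tensor) -> dict[str, Tensor]:
        """Per-channel reconstructions at native lengths (B, ω·f_c)."""
        out = {}
        B, n_tokens, _ = reps.shape
        for name in CHANNEL_ORDER:
            fs = self.cfg.channel_fs[name]
            y = getattr(self, f"recon_{name}")(reps)  # (B, N, fs)
            out[name] = y.reshape(B, n_tokens * fs)
        return out

    def predict_transforms(self, reps: Tensor) -> Tensor:
        """Per-channel 6-way logits of shape (B, 6 channels, 6 kinds)."""
        pooled = reps.mean(axis=1)
        logits = self.tp_fc(pooled)
        B = logits.shape[0]
        return logits.reshape(B, len(CHANNEL_ORDER), self.cfg.n_transforms)

    # -- parameter groups ----------------------------------------------------
    def encoder_parameter_names(self) -> list[str]:
        return [n for n, _ in self.named_parameters() if n.startswith(_ENCODER_PREFIXES)]

    def encoder_parameters(self):
        names = set(self.encoder_parameter_names())
        return [p for n, p in self.named_parameters() if n in names]

    def head_parameters(self):
        names = set(self.encoder_parameter_names())
        return [p for n, p in self.named_parameters() if n not in names]

    def trainable_parameters(self):
        return self.head_parameters() if self.freeze_encoder else self.parameters()

    def _encoder_modules(self):
        mods = [getattr(self, f"embed_{n}") for n in CHANNEL_ORDER]
        mods += [self.input_proj] + list(self.encoder_layers)
        return mods

    def set_mode(self, training: bool) -> None:
        """Set train/eval, keeping a frozen encoder in eval (BN stats fixed)."""
        self.train(training)
        if self.freeze_encoder:
            for mod in self._encoder_modules():
                mod.eval()

    def encoder_state(self) -> dict[str, np.ndarray]:
        full = self.state_dict()
        keep = {}
        for key, value in full.items():
            name = key[len("buffer:"):] if key.startswith("buffer:") else key
            if name.startswith(_ENCODER_PREFIXES):
                keep[key] = value
        return keep

    def load_encoder_state(self, state: dict[str, np.ndarray]) -> None:
        self.load_state_dict(state)


def transfer(pretrained: "E4mer", mode: str, head_seed: int = 1) -> "E4mer":
    """Build a target-task model from a pretrained encoder.

    ``mode="LR"``: linear readout — encoder parameters frozen (their outputs
    are bit-identical before and after target training; BatchNorm statistics
    are frozen too).  ``mode="FT"``: fine-tuning — all parameters trainable,
    encoder initialized from pretraining.  The pretext head is discarded and
    a fresh classification head is drawn from ``head_seed``.
    """
    if mode not in ("LR", "FT"):
        raise ValueError("mode must be 'LR' or 'FT'")
    cfg = ModelConfig(**{**pretrained.cfg.__dict__})
    cfg.seed = head_seed
    model = E4mer(cfg)
    model.load_encoder_state(pretrained.encoder_state())
    model.freeze_encoder = mode == "LR"
    return model


def save_checkpoint(model: E4mer, path: str | Path) -> Path:
    """Flat named-parameter archive (.npz) with the config stored alongside."""
    path = Path(path)
    state = model.state_dict()
    state["__config__"] = np.frombuffer(model.cfg.to_json().encode(), dtype=np.uint8)
    np.savez(path, **state)
    return path if path.suffix == ".npz" else Path(str(path) + ".npz")


def load_checkpoint(path: str | Path) -> E4mer:
    with np.load(path) as archive:
        state = {k: archive[k] for k in archive.files}
    cfg = ModelConfig.from_json(bytes(state.pop("__config__")).decode())
    model = E4mer(cfg)
    model.load_state_dict(state)
    return model
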