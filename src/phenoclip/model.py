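"""The phenotyping network.

One shared CNN encodes every channel's (marker image, self-mask,
neighbor-mask) triplet into a d_model vector; each channel's image embedding
is added to the projected text embedding of its marker name; a channel-wise
transformer with a learnable [CLS] token and no positional encoding fuses
the channel tokens (making the model invariant to channel count and order);
the final-layer [CLS]-to-channel attention yields marker positivity scores;
and a gradient-reversed MLP head predicts imaging modality so the trunk
unlearns platform-specific signal.

Cell-type classification is contrastive: the [CLS] embedding is compared by
cosine similarity to projected cell-type name embeddings, so the candidate
label set can be chosen freely at inference time.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .autodiff import Tensor, as_tensor, concat
from .data import PATCH_SIZE, DEFAULT_C_MAX
from .text import DEFAULT_D_RAW

__all__ = ["ModelConfig", "ModelOutput", "PhenotypeModel", "tiny_config",
           "save_checkpoint", "load_checkpoint"]


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    The default configuration matches the full-scale recipe (11-layer CNN
    with interleaved strides 1 and 2, five 256-wide transformer layers,
    C_max = 75); tests and the desk-scale benchmark use :func:`tiny_config`.
    """

    d_model: int = 256
    n_transformer_layers: int = 5
    ff_dim: int = 512
    n_heads: int = 8
    cnn_widths: tuple = (16, 16, 32, 32, 64, 64, 128, 128, 256, 256, 256)
    cnn_strides: tuple = (1, 2, 1, 2, 1, 2, 1, 2, 1, 2, 1)
    cnn_kernel: int = 3
    cnn_padding: int = 1
    c_max: int = DEFAULT_C_MAX
    d_raw: int = DEFAULT_D_RAW
    n_modalities: int = 2
    temperature_init: float = 0.07
    grl_lambda: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        if len(self.cnn_widths) != len(self.cnn_strides):
            raise ValueError("cnn_widths and cnn_strides must have equal length")
        if self.n_modalities < 2:
            raise ValueError("adversarial head needs at least 2 modalities")
        if min(self.d_model, self.ff_dim, self.c_max, self.d_raw) < 1:
            raise ValueError("all dimensions must be positive")

    def hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True,
                                         default=list).encode()).hexdigest()[:16]


def tiny_config(**overrides) -> ModelConfig:
    """Desk-scale configuration: 5-layer CNN, 2 transformer layers, d_model 64."""
    base = dict(d_model=64, n_transformer_layers=2, ff_dim=128, n_heads=4,
                cnn_widths=(8, 16, 32, 32, 32), cnn_strides=(4, 2, 2, 2, 1),
                c_max=16, d_raw=DEFAULT_D_RAW)
    base.update(overrides)
    return ModelConfig(**base)


@dataclass
class ModelOutput:
    cls_embedding: Tensor            # (B, d_model)
    channel_embeddings: Tensor       # (B, C, d_model)
    positivity_scores: Tensor        # (B, C) in [0, 1]; padded slots are 0
    modality_logits: Tensor | None   # (B, n_modalities)
    temperature: Tensor              # positive scalar
    attention: Tensor                # (B, heads, T, T) final layer


class CNNEncoder(nn.Module):
    """Shared per-channel image encoder: conv -> SiLU -> batchnorm stacks,
    global average pooling, and a linear projection to d_model."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.convs, self.bns = [], []
        cin = 3
        for width, stride in zip(cfg.cnn_widths, cfg.cnn_strides):
            self.convs.append(nn.Conv2d(cin, width, rng, kernel=cfg.cnn_kernel,
                                        stride=stride, padding=cfg.cnn_padding))
            self.bns.append(nn.BatchNorm2d(width))
            cin = width
        self.proj = nn.Linear(cin, cfg.d_model, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        for conv, bn in zip(self.convs, self.bns):
            x = bn(conv(x).silu())
        pooled = x.mean(axis=(2, 3))
        return self.proj(pooled)

    def feature_map_size(self, size: int, kernel: int, padding: int) -> int:
        for conv in self.convs:
            size = nn.Conv2d.output_size(size, kernel, conv.stride, padding)
        return size


class PhenotypeModel(nn.Module):
    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.cnn = CNNEncoder(config, rng)
        self.text_proj = nn.Linear(config.d_raw, config.d_model, rng)
        self.cls_token = nn.Parameter(rng.normal(0.0, 0.02, size=(1, 1, config.d_model)))
        self.layers = [nn.TransformerEncoderLayer(config.d_model, config.n_heads,
                                                  config.ff_dim, rng)
                       for _ in range(config.n_transformer_layers)]
        self.final_ln = nn.LayerNorm(config.d_model)
        d = config.d_model
        self.adv1 = nn.Linear(d, d, rng)
        self.adv2 = nn.Linear(d, d, rng)
        self.adv3 = nn.Linear(d, config.n_modalities, rng)
        self.log_tau = nn.Parameter(np.log(config.temperature_init))

    # -- components ----------------------------------------------------------
    def encode_images(self, batch: Tensor | np.ndarray) -> Tensor:
        """(B, C, 3, 64, 64) -> (B, C, d_model) with one shared CNN."""
        batch = as_tensor(batch)
        b, c, planes, h, w = batch.shape
        if (h, w) != (PATCH_SIZE, PATCH_SIZE) or planes != 3:
            raise ValueError(f"expected (*, *, 3, {PATCH_SIZE}, {PATCH_SIZE}) input, "
                             f"got {batch.shape}")
        flat = batch.reshape(b * c, planes, h, w)
        emb = self.cnn(flat)
        return emb.reshape(b, c, self.config.d_model)

    def project_text(self, raw: Tensor | np.ndarray) -> Tensor:
        """Linear map from provider space (D_raw) to model space (d_model)."""
        raw = as_tensor(raw)
        if raw.shape[-1] != self.config.d_raw:
            raise ValueError(f"raw embedding dimension {raw.shape[-1]} != "
                             f"configured D_raw = {self.config.d_raw}")
        shape = raw.shape
        out = self.text_proj(raw.reshape(int(np.prod(shape[:-1])), shape[-1]))
        return out.reshape(*shape[:-1], self.config.d_model)

    def fuse_channels(self, image_embs: Tensor, marker_text_embs: Tensor,
                      padding_mask: np.ndarray):
        """Run the channel-wise transformer over [CLS] + (image + text) tokens.

        Returns (cls_embedding, channel_embeddings, final-layer attention).
        No positional encoding is used; padded slots are excluded from
        attention via the key mask.
        """
        padding_mask = np.asarray(padding_mask, dtype=np.float32)
        if padding_mask.ndim != 2:
            raise ValueError("padding_mask must be (B, C)")
        if np.any(padding_mask.sum(axis=1) == 0):
            raise ValueError("every cell must have at least one real channel")
        b, c, d = image_embs.shape
        tokens = image_embs + marker_text_embs
        cls = self.cls_token.broadcast_to((b, 1, d))
        x = concat([cls, tokens], axis=1)
        key_mask = np.concatenate([np.ones((b, 1), dtype=np.float32), padding_mask], axis=1)
        attn = None
        for layer in self.layers:
            x, attn = layer(x, key_mask)
        x = self.final_ln(x)
        return x[:, 0], x[:, 1:], attn

    def marker_positivity(self, attention: Tensor, padding_mask: np.ndarray) -> Tensor:
        """[CLS]-to-channel attention -> per-marker positivity scores in [0, 1].

        Head-averaged [CLS] attention is renormalized over real channels and
        rescaled by the per-cell maximum so the top marker scores 1; padded
        slots are masked to 0.
        """
        mask = np.asarray(padding_mask, dtype=np.float32)
        w = attention[:, :, 0, 1:].mean(axis=1)      # (B, C) head-averaged
        w = w * mask
        w = w / (w.sum(axis=1, keepdims=True) + 1e-12)
        scores = w / (w.max(axis=1, keepdims=True) + 1e-12)
        return scores * mask

    def modality_logits(self, cls_embedding: Tensor, reverse: bool = True) -> Tensor:
        """3-layer MLP modality head behind a gradient-reversal layer."""
        x = nn.grad_reverse(cls_embedding, self.config.grl_lambda) if reverse \
            else cls_embedding
        x = self.adv1(x).silu()
        x = self.adv2(x).silu()
        return self.adv3(x)

    @property
    def temperature(self) -> Tensor:
        return self.log_tau.exp()

    # -- full forward ---------------------------------------------------------
    def forward(self, batch: Tensor | np.ndarray, marker_text_raw: Tensor | np.ndarray,
                padding_mask: np.ndarray, with_adversary: bool = True) -> ModelOutput:
        """End-to-end forward pass.

        ``marker_text_raw`` is the (B, C, D_raw) stack of raw marker-name
        embeddings aligned with the channel axis of ``batch``.
        """
        image_embs = self.encode_images(batch)
        text_embs = self.project_text(marker_text_raw)
        cls, channels, attn = self.fuse_channels(image_embs, text_embs, padding_mask)
        scores = self.marker_positivity(attn, padding_mask)
        logits = self.modality_logits(cls) if with_adversary else None
        return ModelOutput(cls_embedding=cls, channel_embeddings=channels,
                           positivity_scores=scores, modality_logits=logits,
                           temperature=self.temperature, attention=attn)

    __call__ = forward


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(model: PhenotypeModel, path: str, provider_id: str = "") -> None:
    """Single-file archive of parameters + config + embedding-provider id."""
    state = model.state_dict()
    meta = {"config": asdict(model.config), "config_hash": model.config.hash(),
            "provider_id": provider_id}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta, default=list).encode(),
                                          dtype=np.uint8), **state)


def load_checkpoint(path: str, expected_provider_id: str | None = None):
    """Rebuild a model from an archive; verifies config hash and provider id."""
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]))
        state = {k: archive[k] for k in archive.files if k != "__meta__"}
    cfg_dict = meta["config"]
    for key in ("cnn_widths", "cnn_strides"):
        cfg_dict[key] = tuple(cfg_dict[key])
    config = ModelConfig(**cfg_dict)
    if config.hash() != meta["config_hash"]:
        raise ValueError("checkpoint config hash mismatch")
    if expected_provider_id is not None and meta["provider_id"] != expected_provider_id:
        raise ValueError(f"checkpoint was built with provider "
                         f"{meta['provider_id']!r}, got {expected_provider_id!r}")
    model = PhenotypeModel(config)
    model.load_state_dict(state)
    return model, meta
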