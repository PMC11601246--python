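"""Training loop: augmentation, loss scheduling, optimization, validation.

Each batch is drawn from a single dataset (so the channel axis is that
dataset's panel), spatially augmented (flips, right-angle rotations, random
resize) identically across the three planes of every channel, and has a few
marker channels dropped to force robustness to panel composition. Marker
and cell-type name embeddings receive per-draw Gaussian noise. The three
loss terms are combined with constant weights for classification and
positivity and a quartic-root epoch ramp for the adversary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import f1_score

from .losses import (LossWeights, focal_clip_loss, modality_loss,
                     positivity_loss, total_loss)
from .model import PhenotypeModel
from .optim import RAdam
from .synthetic import Corpus
from .text import embed_terms, EmbeddingCache

__all__ = ["TrainConfig", "augment", "fit", "stratified_split", "cls_embeddings"]


@dataclass
class TrainConfig:
    lr: float = 1e-4
    epochs: int = 20
    batch_size: int = 32
    channel_dropout_k: int = 8
    embed_noise_sigma: float = 0.005
    label_smoothing_pos: float = 0.2
    label_smoothing_mod: float = 0.01
    gamma: float = 2.0
    val_fraction: float = 0.1
    resize_range: tuple = (0.9, 1.1)
    flip: bool = True
    rotate: bool = True
    adversary: bool = True
    train_datasets: list | None = None   # dataset indices; None = all
    seed: int = 0


def _resize_map(size: int, zoom: float) -> np.ndarray:
    center = (size - 1) / 2.0
    src = np.floor(center + (np.arange(size) - center) / zoom + 0.5).astype(np.intp)
    return np.clip(src, 0, size - 1)


def augment(batch: np.ndarray, padding_mask: np.ndarray,
            rng: np.random.Generator, config: TrainConfig):
    """Spatial + channel-dropout augmentation of a (B, C, 3, H, W) batch.

    Spatial ops apply identically to all three planes of every channel;
    channel dropout zeroes k randomly chosen real channels and clears their
    padding-mask bits, never dropping all channels. Returns new arrays.
    """
    x = batch.copy()
    mask = padding_mask.copy()
    b, c = mask.shape
    size = x.shape[-1]
    for i in range(b):
        if config.flip:
            if rng.random() < 0.5:
                x[i] = x[i, :, :, ::-1, :]
            if rng.random() < 0.5:
                x[i] = x[i, :, :, :, ::-1]
        if config.rotate:
            k = int(rng.integers(0, 4))
            if k:
                x[i] = np.rot90(x[i], k=k, axes=(-2, -1))
        lo, hi = config.resize_range
        if hi > lo or lo != 1.0:
            zoom = rng.uniform(lo, hi)
            if abs(zoom - 1.0) > 1e-9:
                idx = _resize_map(size, zoom)
                x[i] = x[i][:, :, idx[:, None], idx[None, :]]
        if config.channel_dropout_k > 0:
            real = np.flatnonzero(mask[i] > 0)
            k_eff = min(config.channel_dropout_k, len(real) - 1)
            if k_eff > 0:
                drop = rng.choice(real, size=k_eff, replace=False)
                x[i, drop] = 0.0
                mask[i, drop] = 0.0
    return x, mask


def stratified_split(labels: np.ndarray, val_fraction: float,
                     rng: np.random.Generator):
    """Per-class split into train/validation index arrays."""
    train_idx, val_idx = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        n_val = max(1, int(round(val_fraction * len(idx))))
        val_idx.append(idx[:n_val])
        train_idx.append(idx[n_val:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(val_idx))


def cls_embeddings(model: PhenotypeModel, patches: np.ndarray,
                   marker_raw: np.ndarray, batch_size: int = 256) -> np.ndarray:
    """Eval-mode [CLS] embeddings for a stack of same-panel patches."""
    was_training = model.training
    model.eval()
    out = []
    n, c = patches.shape[0], patches.shape[1]
    for start in range(0, n, batch_size):
        chunk = patches[start:start + batch_size]
        b = chunk.shape[0]
        mask = np.ones((b, c), dtype=np.float32)
        raw = np.broadcast_to(marker_raw, (b,) + marker_raw.shape)
        result = model.forward(chunk, raw, mask, with_adversary=False)
        out.append(result.cls_embedding.data.copy())
    if was_training:
        model.train()
    return np.concatenate(out)


def _predict_types(model, patches, marker_raw, type_raw, type_names):
    cls = cls_embeddings(model, patches, marker_raw)
    model.eval()
    proj = model.project_text(type_raw).data
    cls_n = cls / (np.linalg.norm(cls, axis=1, keepdims=True) + 1e-12)
    proj_n = proj / (np.linalg.norm(proj, axis=1, keepdims=True) + 1e-12)
    sims = cls_n @ proj_n.T
    return np.asarray(type_names)[np.argmax(sims, axis=1)]


def fit(model: PhenotypeModel, corpus: Corpus, config: TrainConfig,
        weights: LossWeights | None = None, provider=None,
        cache: EmbeddingCache | None = None, metrics_path: str | None = None):
    """Train a model on a corpus; returns ``(model, history)``.

    The model is checkpointed (in memory) at the best validation macro-F1
    epoch and restored before returning. History records per-epoch means of
    every loss term plus validation macro-F1, and is fully determined by
    ``config.seed``.
    """
    from .text import HashProvider

    weights = weights or LossWeights(epochs_total=config.epochs)
    provider = provider or HashProvider(d_raw=model.config.d_raw)
    cache = cache if cache is not None else EmbeddingCache()
    ds_indices = config.train_datasets
    if ds_indices is None:
        ds_indices = list(range(len(corpus.datasets)))
    datasets = [corpus.datasets[i] for i in ds_indices]
    if any(ds.n_cells == 0 for ds in datasets) or not datasets:
        raise ValueError("training requires a non-empty corpus")
    type_names = corpus.cell_types
    label_to_idx = {name: i for i, name in enumerate(type_names)}
    for ds in datasets:
        unknown = set(ds.labels) - set(type_names)
        if unknown:
            raise ValueError(f"labels {unknown} missing from cell-type set")
    modality_names = sorted({ds.modality_id for ds in datasets})
    n_mod = len(modality_names)
    if config.adversary and n_mod < 2:
        raise ValueError("adversarial training needs >= 2 modalities")

    seed_seq = np.random.SeedSequence(config.seed)
    split_rng, train_rng = [np.random.default_rng(s) for s in seed_seq.spawn(2)]

    marker_raw = [embed_terms(ds.channel_names, "marker", provider, cache)
                  .astype(np.float32) for ds in datasets]
    type_raw = embed_terms(type_names, "cell_type", provider, cache).astype(np.float32)

    splits = [stratified_split(ds.labels, config.val_fraction, split_rng)
              for ds in datasets]
    optimizer = RAdam(list(model.parameters()), lr=config.lr)
    history = {k: [] for k in ("epoch", "loss_cls", "loss_pos", "loss_adv",
                               "loss_total", "w_adv", "val_macro_f1")}
    best = (-1.0, None)

    # pool cells across datasets so each batch mixes panels and modalities;
    # batches are zero-padded to the largest panel present in the batch.
    # (per-dataset batches would let batchnorm normalize away modality
    # differences per batch, hiding them from the adversary at train time)
    pool = np.array([(d, i) for d, (_, (tr_idx, _)) in
                     enumerate(zip(datasets, splits)) for i in tr_idx])
    d_raw_dim = model.config.d_raw

    for epoch in range(1, config.epochs + 1):
        model.train()
        order = train_rng.permutation(len(pool))
        sums = {"loss_cls": 0.0, "loss_pos": 0.0, "loss_adv": 0.0, "loss_total": 0.0}
        for start in range(0, len(order), config.batch_size):
            chunk = pool[order[start:start + config.batch_size]]
            b = len(chunk)
            c_b = max(len(datasets[d].channel_names) for d, _ in chunk)
            x = np.zeros((b, c_b, 3, 64, 64), dtype=np.float32)
            mask = np.zeros((b, c_b), dtype=np.float32)
            m_raw = np.zeros((b, c_b, d_raw_dim), dtype=np.float32)
            pos = np.zeros((b, c_b), dtype=np.float32)
            y = np.empty(b, dtype=int)
            mod_targets = np.empty(b, dtype=int)
            for j, (d, i) in enumerate(chunk):
                ds = datasets[d]
                c = len(ds.channel_names)
                x[j, :c] = ds.patches[i]
                mask[j, :c] = 1.0
                m_raw[j, :c] = marker_raw[d]
                pos[j, :c] = ds.positivity[i]
                y[j] = label_to_idx[ds.labels[i]]
                mod_targets[j] = modality_names.index(ds.modality_id)
            x, mask = augment(x, mask, train_rng, config)
            m_raw += train_rng.normal(0.0, config.embed_noise_sigma,
                                      size=m_raw.shape).astype(np.float32)
            t_raw = type_raw[y] + train_rng.normal(
                0.0, config.embed_noise_sigma, size=(b, d_raw_dim)
            ).astype(np.float32)

            out = model.forward(x, m_raw, mask, with_adversary=config.adversary)
            t_proj = model.project_text(t_raw)
            loss_cls = focal_clip_loss(out.cls_embedding, t_proj,
                                       gamma=config.gamma, tau=model.temperature)
            loss_pos = positivity_loss(out.positivity_scores, pos,
                                       mask, smoothing=config.label_smoothing_pos)
            loss_adv = None
            if config.adversary:
                loss_adv = modality_loss(out.modality_logits, mod_targets,
                                         smoothing=config.label_smoothing_mod)
            loss, breakdown = total_loss(loss_cls, loss_pos, loss_adv, weights, epoch)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            for k in sums:
                sums[k] += breakdown.get(k, 0.0)

        n_batches = int(np.ceil(len(pool) / config.batch_size))
        val_true, val_pred = [], []
        for d, (ds, (_, va_idx)) in enumerate(zip(datasets, splits)):
            pred = _predict_types(model, ds.patches[va_idx], marker_raw[d],
                                  type_raw, type_names)
            val_pred.extend(pred)
            val_true.extend(ds.labels[va_idx])
        val_f1 = float(f1_score(val_true, val_pred, average="macro",
                                labels=type_names, zero_division=0))
        history["epoch"].append(epoch)
        for k in sums:
            history[k].append(sums[k] / n_batches)
        history["w_adv"].append(breakdown["w_adv"])
        history["val_macro_f1"].append(val_f1)
        if val_f1 > best[0]:
            best = (val_f1, model.state_dict())
        if metrics_path is not None:
            with open(metrics_path, "a") as fh:
                fh.write(json.dumps({k: history[k][-1] for k in history}) + "\n")

    if best[1] is not None:
        model.load_state_dict(best[1])
    model.eval()
    return model, history
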