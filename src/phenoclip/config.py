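"""YAML run configuration with sections data / model / train / losses / provider.

A run config fully determines a training run; :func:`resolve_config` fills
defaults so the resolved copy written next to every run is self-contained.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from .losses import LossWeights
from .model import ModelConfig, tiny_config
from .synthetic import ModalityEffect, SyntheticSpec, default_benchmark_spec
from .text import DEFAULT_D_RAW, HashProvider, HTTPProvider
from .train import TrainConfig

__all__ = ["load_config", "resolve_config", "save_resolved_config",
           "build_provider", "spec_from_dict", "spec_to_dict"]


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def spec_from_dict(d: dict) -> SyntheticSpec:
    d = dict(d)
    d["profile_matrix"] = np.asarray(d["profile_matrix"], dtype=np.float64)
    d["modalities"] = [ModalityEffect(**m) for m in d["modalities"]]
    d["cell_radius_range"] = tuple(d.get("cell_radius_range", (4.0, 8.0)))
    d["spillover_pairs"] = [tuple(p) for p in d.get("spillover_pairs", [])]
    return SyntheticSpec(**d)


def spec_to_dict(spec: SyntheticSpec) -> dict:
    d = asdict(spec)
    d["profile_matrix"] = spec.profile_matrix.tolist()
    d["cell_radius_range"] = list(spec.cell_radius_range)
    d["spillover_pairs"] = [list(p) for p in spec.spillover_pairs]
    return d


def build_provider(section: dict | None):
    section = section or {}
    kind = section.get("kind", "offline-hash")
    if kind == "offline-hash":
        return HashProvider(d_raw=section.get("d_raw", DEFAULT_D_RAW))
    if kind == "http":
        return HTTPProvider(base_url=section["url"], d_raw=section["d_raw"],
                            explainer_model=section.get("explainer_model", ""),
                            embedder_model=section.get("embedder_model", ""))
    raise ValueError(f"unknown provider kind {kind!r}")


def resolve_config(raw: dict):
    """Build (spec, model_config, train_config, loss_weights, provider)."""
    data = raw.get("data", {})
    if "spec" in data:
        spec = spec_from_dict(data["spec"])
    else:
        spec = default_benchmark_spec(seed=data.get("seed", 0))
    model_section = dict(raw.get("model", {}))
    preset = model_section.pop("preset", "tiny")
    for key in ("cnn_widths", "cnn_strides"):
        if key in model_section:
            model_section[key] = tuple(model_section[key])
    n_mod = len({spec.modalities[m].name for m in spec.dataset_modalities})
    model_section.setdefault("n_modalities", max(n_mod, 2))
    model_cfg = tiny_config(**model_section) if preset == "tiny" \
        else ModelConfig(**model_section)
    train_section = dict(raw.get("train", {}))
    if "resize_range" in train_section:
        train_section["resize_range"] = tuple(train_section["resize_range"])
    train_cfg = TrainConfig(**train_section)
    weights = LossWeights(**raw.get("losses", {}))
    provider = build_provider(raw.get("provider"))
    return spec, model_cfg, train_cfg, weights, provider


def save_resolved_config(path: str | Path, spec, model_cfg, train_cfg, weights,
                         provider) -> None:
    resolved = {
        "data": {"spec": spec_to_dict(spec)},
        "model": {k: (list(v) if isinstance(v, tuple) else v)
                  for k, v in asdict(model_cfg).items()},
        "train": {k: (list(v) if isinstance(v, tuple) else v)
                  for k, v in asdict(train_cfg).items()},
        "losses": asdict(weights),
        "provider": {"kind": "offline-hash" if isinstance(provider, HashProvider)
                     else "http", "id": provider.provider_id,
                     "d_raw": provider.d_raw},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(resolved, fh, sort_keys=False)
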