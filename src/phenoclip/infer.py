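"""Zero-shot inference with dynamic candidate sets.

Because the classifier is similarity-based, the set of candidate cell types
is chosen at inference time: any list of names is embedded with the same
provider and projection used in training, and each cell is assigned the
candidate whose name embedding has the highest cosine similarity with the
cell's [CLS] embedding. Candidate sets can be bound per tissue via a
tissue -> cell-types map to suppress cross-tissue errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import PhenotypeModel
from .text import EmbeddingCache, embed_terms

logger = logging.getLogger(__name__)

__all__ = ["CandidateSet", "PredictionResult", "build_candidate_set",
           "bind_by_tissue", "predict", "export_embeddings"]


@dataclass
class CandidateSet:
    cell_type_names: list[str]
    embeddings: np.ndarray        # (K, d_model), projected with the trained map
    provider_id: str = ""

    def __post_init__(self):
        if len(self.cell_type_names) == 0:
            raise ValueError("candidate set must be non-empty")
        if len(set(self.cell_type_names)) != len(self.cell_type_names):
            raise ValueError("candidate names must be unique")
        if self.embeddings.shape[0] != len(self.cell_type_names):
            raise ValueError("one embedding row per candidate required")


@dataclass
class PredictionResult:
    cell_id: int
    predicted_type: str
    similarity: np.ndarray        # (K,) cosine similarities in [-1, 1]
    positivity_scores: dict       # marker name -> score in [0, 1]


def build_candidate_set(names: list[str], model: PhenotypeModel, provider,
                        cache: EmbeddingCache | None = None) -> CandidateSet:
    """Embed candidate cell-type names with the trained projection."""
    raw = embed_terms(list(names), "cell_type", provider, cache).astype(np.float32)
    model.eval()
    projected = model.project_text(raw).data
    return CandidateSet(cell_type_names=list(names), embeddings=projected,
                        provider_id=provider.provider_id)


def bind_by_tissue(tissue_id: str, tissue_map: dict, model: PhenotypeModel,
                   provider, full_set: list[str] | None = None,
                   cache: EmbeddingCache | None = None) -> CandidateSet:
    """Candidate set for a tissue; unknown tissues fall back to the full set."""
    if tissue_id in tissue_map:
        names = list(tissue_map[tissue_id])
        logger.info("tissue %r bound to %d candidate types", tissue_id, len(names))
    else:
        if full_set is None:
            full_set = sorted({t for types in tissue_map.values() for t in types})
        names = list(full_set)
        logger.warning("unknown tissue %r; falling back to the full label set",
                       tissue_id)
    return build_candidate_set(names, model, provider, cache)


def predict(model: PhenotypeModel, patches: np.ndarray, marker_raw: np.ndarray,
            candidates: CandidateSet, channel_names: list[str] | None = None,
            cell_ids: np.ndarray | None = None,
            provider_id: str | None = None) -> list[PredictionResult]:
    """Assign each cell the candidate type with maximal cosine similarity.

    ``patches``: (N, C, 3, 64, 64) same-panel patches; ``marker_raw``:
    (C, D_raw) raw marker-name embeddings for that panel. Ties break to the
    lowest candidate index (np.argmax convention).
    """
    if provider_id is not None and candidates.provider_id \
            and provider_id != candidates.provider_id:
        raise ValueError(f"candidate embeddings come from provider "
                         f"{candidates.provider_id!r}, model expects {provider_id!r}")
    model.eval()
    n, c = patches.shape[0], patches.shape[1]
    if cell_ids is None:
        cell_ids = np.arange(n)
    cand_n = candidates.embeddings / (
        np.linalg.norm(candidates.embeddings, axis=1, keepdims=True) + 1e-12)
    results = []
    for start in range(0, n, 256):
        chunk = patches[start:start + 256]
        b = chunk.shape[0]
        mask = np.ones((b, c), dtype=np.float32)
        raw = np.broadcast_to(marker_raw, (b,) + marker_raw.shape)
        out = model.forward(chunk, raw, mask, with_adversary=False)
        cls = out.cls_embedding.data
        cls_n = cls / (np.linalg.norm(cls, axis=1, keepdims=True) + 1e-12)
        sims = cls_n @ cand_n.T
        scores = out.positivity_scores.data
        for i in range(b):
            pos = {}
            if channel_names is not None:
                pos = {name: float(scores[i, j])
                       for j, name in enumerate(channel_names)}
            results.append(PredictionResult(
                cell_id=int(cell_ids[start + i]),
                predicted_type=candidates.cell_type_names[int(np.argmax(sims[i]))],
                similarity=sims[i].copy(), positivity_scores=pos))
    return results


def export_embeddings(model: PhenotypeModel, patches: np.ndarray,
                      marker_raw: np.ndarray, cell_ids: np.ndarray | None = None,
                      metadata: dict | None = None) -> pd.DataFrame:
    """Per-cell [CLS] embeddings as a table for external visualization."""
    from .train import cls_embeddings

    cls = cls_embeddings(model, patches, marker_raw)
    n = cls.shape[0]
    if cell_ids is None:
        cell_ids = np.arange(n)
    df = pd.DataFrame({"cell_id": cell_ids})
    for key, value in (metadata or {}).items():
        df[key] = value
    for j in range(cls.shape[1]):
        df[f"emb_{j}"] = cls[:, j]
    return df
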