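"""Marker and cell-type name embeddings via a pluggable provider.

A provider turns a canonical term into a free-text description (an "expert
explainer" step) and the description into a fixed-length vector (an
"embedder" step). The default provider is fully offline and deterministic:
descriptions are templated, and embedding vectors are seeded pseudo-random
unit vectors derived from a cryptographic hash of the text, so distinct
terms receive near-orthogonal embeddings of configurable dimension. A
generic HTTP adapter is provided for hosted explainer/embedder endpoints.

Vectors are cached per (term, role, provider) so a corpus run never invokes
the provider twice for the same term; caches can be persisted as JSON lines.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "TermDescription", "TermEmbedding", "HashProvider", "HTTPProvider",
    "EmbeddingCache", "describe_term", "embed_description", "embed_terms",
    "perturb_embedding", "DEFAULT_D_RAW",
]

DEFAULT_D_RAW = 256

MARKER_TEMPLATE = (
    "{term}: protein marker used in multiplexed tissue imaging. Describe its "
    "general function, alternative names, and the cell types that express it."
)
CELL_TYPE_TEMPLATE = (
    "{term}: cell type found in human tissue. Describe its lineage, function, "
    "alternative names, and the protein markers that identify it."
)
ROLES = ("marker", "cell_type")


@dataclass
class TermDescription:
    term: str
    role: str
    description: str
    provider_id: str

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}")
        if not self.description:
            raise ValueError("description must be non-empty")


@dataclass
class TermEmbedding:
    term: str
    role: str
    raw_vector: np.ndarray
    projected_vector: np.ndarray | None = None


class HashProvider:
    """Offline fallback provider: templated text, hash-seeded unit vectors."""

    def __init__(self, d_raw: int = DEFAULT_D_RAW, provider_id: str = "offline-hash-v1",
                 marker_template: str = MARKER_TEMPLATE,
                 cell_type_template: str = CELL_TYPE_TEMPLATE):
        if d_raw < 1:
            raise ValueError("d_raw must be positive")
        self.d_raw = d_raw
        self.provider_id = provider_id
        self.templates = {"marker": marker_template, "cell_type": cell_type_template}

    def describe(self, term: str, role: str) -> str:
        if role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}")
        return self.templates[role].format(term=term)

    def embed(self, text: str) -> np.ndarray:
        if not text:
            raise ValueError("cannot embed an empty description")
        digest = hashlib.sha256(text.encode("utf-8")).digest()
        seed = int.from_bytes(digest[:8], "big") % (2 ** 31)
        vec = np.random.default_rng(seed).standard_normal(self.d_raw)
        return (vec / np.linalg.norm(vec)).astype(np.float32)


class HTTPProvider:
    """Adapter for a hosted explainer/embedder endpoint (OpenAI-style JSON).

    Configured with a base URL, model names, and the embedding dimension the
    endpoint returns; any transport failure raises with the term identified
    so callers can retry.
    """

    def __init__(self, base_url: str, d_raw: int, explainer_model: str = "",
                 embedder_model: str = "", provider_id: str | None = None,
                 timeout: float = 30.0):
        self.base_url = base_url.rstrip("/")
        self.d_raw = d_raw
        self.explainer_model = explainer_model
        self.embedder_model = embedder_model
        self.provider_id = provider_id or f"http:{self.base_url}"
        self.timeout = timeout

    def _post(self, route: str, payload: dict) -> dict:
        import urllib.request

        req = urllib.request.Request(
            f"{self.base_url}/{route}", data=json.dumps(payload).encode(),
            headers={"Content-Type": "application/json"})
        with urllib.request.urlopen(req, timeout=self.timeout) as resp:
            return json.loads(resp.read())

    def describe(self, term: str, role: str) -> str:
        template = MARKER_TEMPLATE if role == "marker" else CELL_TYPE_TEMPLATE
        try:
            out = self._post("chat/completions", {
                "model": self.explainer_model,
                "messages": [{"role": "user", "content": template.format(term=term)}]})
            return out["choices"][0]["message"]["content"]
        except Exception as exc:  # pragma: no cover - network path
            raise RuntimeError(f"explainer failed for term {term!r}: {exc}") from exc

    def embed(self, text: str) -> np.ndarray:  # pragma: no cover - network path
        try:
            out = self._post("embeddings", {"model": self.embedder_model, "input": text})
            vec = np.asarray(out["data"][0]["embedding"], dtype=np.float32)
        except Exception as exc:
            raise RuntimeError(f"embedder failed: {exc}") from exc
        if vec.shape != (self.d_raw,):
            raise ValueError(f"provider returned dimension {vec.shape[0]}, "
                             f"configured D_raw = {self.d_raw}")
        return vec


@dataclass
class EmbeddingCache:
    """In-memory (term, role, provider_id) -> raw vector cache with JSONL I/O."""

    entries: dict = field(default_factory=dict)
    hits: int = 0
    misses: int = 0

    def get_or_compute(self, term: str, role: str, provider) -> np.ndarray:
        key = (term, role, provider.provider_id)
        if key in self.entries:
            self.hits += 1
            return self.entries[key]
        self.misses += 1
        vec = provider.embed(provider.describe(term, role))
        self.entries[key] = vec
        return vec

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for (term, role, pid), vec in self.entries.items():
                fh.write(json.dumps({"term": term, "role": role, "provider_id": pid,
                                     "vector": np.asarray(vec).tolist()}) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddingCache":
        cache = cls()
        with open(path) as fh:
            for line in fh:
                rec = json.loads(line)
                cache.entries[(rec["term"], rec["role"], rec["provider_id"])] = \
                    np.asarray(rec["vector"], dtype=np.float32)
        return cache


def describe_term(term: str, role: str, provider) -> TermDescription:
    return TermDescription(term=term, role=role,
                           description=provider.describe(term, role),
                           provider_id=provider.provider_id)


def embed_description(desc: TermDescription, provider) -> np.ndarray:
    vec = provider.embed(desc.description)
    if vec.shape != (provider.d_raw,):
        raise ValueError(f"embedding dimension {vec.shape[0]} != configured "
                         f"D_raw = {provider.d_raw}")
    return vec


def embed_terms(terms: list[str], role: str, provider,
                cache: EmbeddingCache | None = None) -> np.ndarray:
    """Raw embeddings for a list of terms, stacked as (len(terms), D_raw)."""
    cache = cache if cache is not None else EmbeddingCache()
    return np.stack([cache.get_or_compute(t, role, provider) for t in terms])


def perturb_embedding(vec: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Additive elementwise Gaussian noise, used as a training-time regularizer."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return vec
    return vec + rng.normal(0.0, sigma, size=vec.shape).astype(vec.dtype)
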