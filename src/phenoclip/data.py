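"""Canonical data types, preprocessing, and per-cell patch extraction.

Multiplexed images arrive as (C, H, W) stacks with one channel per protein
marker, a microns-per-pixel resolution, and a whole-cell segmentation label
mask. Preprocessing resamples everything to a common 0.5 mpp grid,
normalizes each channel to [0, 1] by clipping at the 99th percentile of its
non-zero pixels, and cuts a 64x64 patch per cell consisting of (marker
image, self-mask, neighbor-mask) triplets.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PATCH_SIZE = 64
HALF = PATCH_SIZE // 2
DEFAULT_C_MAX = 75
TARGET_MPP = 0.5

__all__ = [
    "MarkerPanel", "FOVImage", "SegmentationMask", "CellPatch", "PaddedBatch",
    "resample_to_mpp", "normalize_channel", "normalize_fov", "extract_patch",
    "pad_batch", "standardize_names", "load_alias_map",
    "read_fov_tiff", "read_mask_tiff", "write_fov_tiff",
    "write_corpus_store", "read_corpus_store",
    "PATCH_SIZE", "DEFAULT_C_MAX", "TARGET_MPP",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class MarkerPanel:
    """Ordered marker names for one dataset plus raw-name aliases."""

    canonical_names: list[str]
    alias_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.canonical_names)) != len(self.canonical_names):
            raise ValueError("canonical marker names must be unique")

    def __len__(self) -> int:
        return len(self.canonical_names)


@dataclass
class FOVImage:
    """One field of view: a (C, H, W) non-negative intensity stack."""

    pixels: np.ndarray
    mpp: float
    panel: MarkerPanel
    modality_id: str = "unknown"
    tissue_id: str = "unknown"
    dataset_id: str = "unknown"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3:
            raise ValueError("pixels must be (C, H, W)")
        if self.pixels.shape[0] != len(self.panel):
            raise ValueError(
                f"channel count {self.pixels.shape[0]} != panel size {len(self.panel)}")
        if self.mpp <= 0:
            raise ValueError("mpp must be positive")


@dataclass
class SegmentationMask:
    """Whole-cell label image: 0 = background, k > 0 = cell k."""

    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2-D")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative integers")

    def cell_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


@dataclass
class CellPatch:
    """Per-cell (C, 3, 64, 64) stack: marker image, self-mask, neighbor-mask."""

    tensor: np.ndarray
    channel_names: list[str]
    cell_id: int
    centroid: tuple[int, int]
    dataset_id: str = "unknown"
    modality_id: str = "unknown"
    tissue_id: str = "unknown"
    label: str | None = None
    positivity: np.ndarray | None = None


@dataclass
class PaddedBatch:
    """A batch of patches zero-padded along the channel axis to C_max."""

    tensor: np.ndarray          # (B, C_max, 3, 64, 64)
    padding_mask: np.ndarray    # (B, C_max), 1 = real channel
    channel_names: list[list[str]]
    labels: list[str | None] | None = None
    positivity: np.ndarray | None = None   # (B, C_max)
    modality_ids: list[str] | None = None


# ---------------------------------------------------------------------------
# preprocessing operations
# ---------------------------------------------------------------------------

def _nearest_index_map(n_in: int, zoom: float) -> np.ndarray:
    """Output-index -> source-index map for nearest-neighbor resampling.

    Output length is ``floor(n_in * zoom + 0.5)``; output pixel centers are
    mapped back to source coordinates and rounded down to the nearest pixel.
    """
    n_out = max(1, int(np.floor(n_in * zoom + 0.5)))
    src = np.floor((np.arange(n_out) + 0.5) / zoom).astype(np.intp)
    return np.clip(src, 0, n_in - 1)


def resample_to_mpp(image: FOVImage, mask: SegmentationMask | None = None,
                    target_mpp: float = TARGET_MPP):
    """Resample an FOV (and optionally its mask) to ``target_mpp``.

    Nearest-neighbor, no anti-aliasing, label-preserving for masks. Returns
    the image alone, or an (image, mask) pair when a mask is given.
    """
    if target_mpp <= 0:
        raise ValueError("target_mpp must be positive")
    if image.mpp <= 0:
        raise ValueError("image mpp must be positive")
    zoom = image.mpp / target_mpp
    _, h, w = image.pixels.shape
    rows = _nearest_index_map(h, zoom)
    cols = _nearest_index_map(w, zoom)
    pixels = image.pixels[:, rows[:, None], cols[None, :]]
    out = FOVImage(pixels=pixels, mpp=target_mpp, panel=image.panel,
                   modality_id=image.modality_id, tissue_id=image.tissue_id,
                   dataset_id=image.dataset_id)
    if mask is None:
        return out
    if mask.labels.shape != (h, w):
        raise ValueError("mask shape does not match image")
    out_mask = SegmentationMask(mask.labels[rows[:, None], cols[None, :]])
    return out, out_mask


def normalize_channel(channel: np.ndarray) -> np.ndarray:
    """Clip at the 99th percentile of non-zero values, then min-max to [0, 1].

    Degenerate inputs: an all-zero channel passes through unchanged; a
    constant non-zero channel maps to all zeros (min == max convention).
    """
    channel = np.asarray(channel, dtype=np.float64)
    if np.any(channel < 0) or not np.all(np.isfinite(channel)):
        raise ValueError("channel values must be finite and non-negative")
    nonzero = channel[channel > 0]
    if nonzero.size == 0:
        return np.zeros_like(channel)
    p99 = np.percentile(nonzero, 99)  # linear-interpolation percentile
    clipped = np.minimum(channel, p99)
    lo, hi = clipped.min(), clipped.max()
    if hi == lo:
        return np.zeros_like(channel)
    return (clipped - lo) / (hi - lo)


def normalize_fov(image: FOVImage) -> FOVImage:
    """Apply :func:`normalize_channel` to every channel of an FOV."""
    pixels = np.stack([normalize_channel(c) for c in image.pixels])
    return FOVImage(pixels=pixels.astype(np.float32), mpp=image.mpp, panel=image.panel,
                    modality_id=image.modality_id, tissue_id=image.tissue_id,
                    dataset_id=image.dataset_id)


def mask_centroid(labels: np.ndarray, cell_id: int) -> tuple[int, int]:
    """Integer-rounded centroid of a cell's pixels (row, col)."""
    rows, cols = np.nonzero(labels == cell_id)
    if rows.size == 0:
        raise KeyError(f"cell id {cell_id} not present in mask")
    return int(np.floor(rows.mean() + 0.5)), int(np.floor(cols.mean() + 0.5))


def extract_patch(image: FOVImage, mask: SegmentationMask, cell_id: int,
                  label: str | None = None,
                  positivity: np.ndarray | None = None) -> CellPatch:
    """Cut a 64x64 patch centered on a cell with self- and neighbor-masks.

    The window is the half-open block [r-32, r+32) x [c-32, c+32) around the
    integer-rounded mask centroid (r, c); out-of-image regions are zero in
    all three planes.
    """
    labels = mask.labels
    if labels.shape != image.pixels.shape[1:]:
        raise ValueError("mask shape does not match image")
    r, c = mask_centroid(labels, cell_id)
    h, w = labels.shape
    r0, r1 = r - HALF, r + HALF
    c0, c1 = c - HALF, c + HALF
    sr0, sr1 = max(r0, 0), min(r1, h)
    sc0, sc1 = max(c0, 0), min(c1, w)
    dr0, dc0 = sr0 - r0, sc0 - c0

    n_ch = image.pixels.shape[0]
    tensor = np.zeros((n_ch, 3, PATCH_SIZE, PATCH_SIZE), dtype=np.float32)
    img_win = image.pixels[:, sr0:sr1, sc0:sc1]
    lab_win = labels[sr0:sr1, sc0:sc1]
    self_mask = (lab_win == cell_id).astype(np.float32)
    neighbor_mask = ((lab_win > 0) & (lab_win != cell_id)).astype(np.float32)
    hh, ww = lab_win.shape
    tensor[:, 0, dr0:dr0 + hh, dc0:dc0 + ww] = img_win
    tensor[:, 1, dr0:dr0 + hh, dc0:dc0 + ww] = self_mask
    tensor[:, 2, dr0:dr0 + hh, dc0:dc0 + ww] = neighbor_mask
    return CellPatch(tensor=tensor, channel_names=list(image.panel.canonical_names),
                     cell_id=int(cell_id), centroid=(r, c), dataset_id=image.dataset_id,
                     modality_id=image.modality_id, tissue_id=image.tissue_id,
                     label=label, positivity=positivity)


def pad_batch(patches: list[CellPatch], c_max: int = DEFAULT_C_MAX) -> PaddedBatch:
    """Zero-pad patches along the channel axis and build the padding mask."""
    b = len(patches)
    tensor = np.zeros((b, c_max, 3, PATCH_SIZE, PATCH_SIZE), dtype=np.float32)
    padding_mask = np.zeros((b, c_max), dtype=np.float32)
    positivity = np.zeros((b, c_max), dtype=np.float32)
    has_pos = False
    names, labels, modalities = [], [], []
    for i, p in enumerate(patches):
        c = p.tensor.shape[0]
        if c > c_max:
            raise ValueError(
                f"dataset {p.dataset_id!r}: {c} channels exceed C_max = {c_max}")
        tensor[i, :c] = p.tensor
        padding_mask[i, :c] = 1.0
        if p.positivity is not None:
            positivity[i, :c] = p.positivity
            has_pos = True
        names.append(list(p.channel_names))
        labels.append(p.label)
        modalities.append(p.modality_id)
    return PaddedBatch(tensor=tensor, padding_mask=padding_mask, channel_names=names,
                       labels=labels, positivity=positivity if has_pos else None,
                       modality_ids=modalities)


def standardize_names(raw_names: list[str], alias_map: dict[str, str],
                      strict: bool = True) -> list[str]:
    """Map raw marker / cell-type names to canonical names.

    Canonical names pass through unchanged (idempotent). Unknown names raise
    in strict mode and pass through with a warning otherwise.
    """
    canonical = set(alias_map.values())
    out = []
    for name in raw_names:
        if name in canonical:
            out.append(name)
        elif name in alias_map:
            out.append(alias_map[name])
        elif strict:
            raise KeyError(f"unmapped name: {name!r}")
        else:
            logger.warning("unmapped name %r passed through", name)
            out.append(name)
    return out


def load_alias_map(path: str | Path) -> dict[str, str]:
    """Load an alias map from CSV (raw_name, canonical_name) or a JSON object."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            mapping = json.load(fh)
        return {str(k): str(v) for k, v in mapping.items()}
    df = pd.read_csv(path)
    return dict(zip(df["raw_name"].astype(str), df["canonical_name"].astype(str)))


# ---------------------------------------------------------------------------
# TIFF interfaces
# ---------------------------------------------------------------------------

def read_fov_tiff(image_path: str | Path, channels: list[str] | str | Path,
                  mpp: float, alias_map: dict[str, str] | None = None,
                  strict: bool = False, **meta) -> FOVImage:
    """Read a multi-channel TIFF with channel names from a list or sidecar CSV.

    A sidecar CSV must have columns ``channel_index`` and ``raw_name``.
    """
    import tifffile

    pixels = tifffile.imread(str(image_path))
    if pixels.ndim == 2:
        pixels = pixels[None]
    if isinstance(channels, (str, Path)):
        df = pd.read_csv(channels).sort_values("channel_index")
        names = df["raw_name"].astype(str).tolist()
    else:
        names = list(channels)
    if alias_map:
        names = standardize_names(names, alias_map, strict=strict)
    panel = MarkerPanel(canonical_names=names, alias_map=alias_map or {})
    return FOVImage(pixels=np.asarray(pixels, dtype=np.float32), mpp=mpp,
                    panel=panel, **meta)


def read_mask_tiff(path: str | Path) -> SegmentationMask:
    import tifffile

    return SegmentationMask(np.asarray(tifffile.imread(str(path))).astype(np.int32))


def write_fov_tiff(image: FOVImage, image_path: str | Path,
                   channels_path: str | Path | None = None) -> None:
    import tifffile

    tifffile.imwrite(str(image_path), image.pixels.astype(np.float32),
                     photometric="minisblack",
                     metadata={"axes": "CYX",
                               "Channel": {"Name": image.panel.canonical_names}})
    if channels_path is not None:
        pd.DataFrame({"channel_index": np.arange(len(image.panel)),
                      "raw_name": image.panel.canonical_names}).to_csv(
            channels_path, index=False)


# ---------------------------------------------------------------------------
# chunked store (zarr layout: /datasets/<id>/{patches, padding_mask, ...})
# ---------------------------------------------------------------------------

def write_corpus_store(path: str | Path, datasets: list[dict]) -> None:
    """Write processed per-dataset tensors to a zarr hierarchy.

    Each entry needs keys: ``dataset_id``, ``patches`` (N, C, 3, 64, 64),
    ``padding_mask`` (N, C), ``channel_names``, and optionally ``labels``
    (list of str), ``positivity`` (N, C), and ``meta`` (JSON-able dict).
    """
    import zarr

    root = zarr.open_group(str(path), mode="w")
    grp = root.create_group("datasets")
    for ds in datasets:
        g = grp.create_group(str(ds["dataset_id"]))
        for key in ("patches", "padding_mask", "positivity"):
            if ds.get(key) is not None:
                arr = np.asarray(ds[key])
                g.create_array(key, shape=arr.shape, dtype=arr.dtype,
                               chunks=_chunks_for(arr.shape))[:] = arr
        if ds.get("labels") is not None:
            labels = list(ds["labels"])
            vocab = sorted(set(labels))
            codes = np.array([vocab.index(x) for x in labels], dtype=np.int32)
            g.create_array("labels", shape=codes.shape, dtype=codes.dtype)[:] = codes
            g.attrs["label_vocab"] = vocab
        g.attrs["channel_names"] = list(ds["channel_names"])
        g.attrs["meta"] = ds.get("meta", {})


def _chunks_for(shape: tuple) -> tuple:
    if len(shape) >= 3:
        return (min(shape[0], 64),) + shape[1:]
    return shape


def read_corpus_store(path: str | Path) -> list[dict]:
    """Read back a corpus store written by :func:`write_corpus_store`."""
    import zarr

    root = zarr.open_group(str(path), mode="r")
    out = []
    for name in sorted(root["datasets"].keys()):
        g = root["datasets"][name]
        ds = {"dataset_id": name,
              "channel_names": list(g.attrs["channel_names"]),
              "meta": dict(g.attrs.get("meta", {}))}
        for key in ("patches", "padding_mask", "positivity"):
            if key in g:
                ds[key] = g[key][:]
        if "labels" in g:
            vocab = list(g.attrs["label_vocab"])
            ds["labels"] = [vocab[i] for i in g["labels"][:]]
        out.append(ds)
    return out
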