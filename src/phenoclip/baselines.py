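"""Mean-intensity baselines, classification metrics, and the modality probe.

The classical phenotyping input is a per-cell feature table of mean marker
intensities. Across datasets with different panels, features are aligned to
the union of all markers, with missing markers filled by a placeholder
(NaN for tree models with native missing-value routing, 0 for MLPs), plus a
cell-size column. A cross-validated linear probe on frozen [CLS] embeddings
measures how much imaging-modality information survives in the learned
representation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold, cross_val_score

__all__ = ["extract_feature_table", "feature_matrix", "XGBoostBaseline",
           "MLPBaseline", "evaluate_classification", "modality_probe"]

META_COLUMNS = ("cell_id", "dataset_id", "modality_id", "label")


def extract_feature_table(fovs, master_panel: list[str]) -> pd.DataFrame:
    """Per-cell mean marker intensities aligned to a universal marker list.

    ``fovs`` is an iterable of ``(FOVImage, SegmentationMask, truth)``
    triplets (the layout produced by the simulator; truth needs cell_id and
    cell_type columns). Markers absent from an FOV's panel are NaN; a
    ``cell_size`` column (pixel count) is appended. Cells with zero pixels
    are excluded with a warning.
    """
    rows = []
    for fov, mask, truth in fovs:
        labels = mask.labels
        n_max = int(labels.max())
        counts = np.bincount(labels.ravel(), minlength=n_max + 1)
        means = {}
        for name, channel in zip(fov.panel.canonical_names, fov.pixels):
            sums = np.bincount(labels.ravel(), weights=channel.ravel().astype(np.float64),
                               minlength=n_max + 1)
            with np.errstate(invalid="ignore"):
                means[name] = sums / counts
        for _, rec in truth.iterrows():
            cid = int(rec["cell_id"])
            if cid > n_max or counts[cid] == 0:
                import warnings

                warnings.warn(f"cell {cid} has zero pixels; excluded")
                continue
            row = {"cell_id": cid, "dataset_id": fov.dataset_id,
                   "modality_id": fov.modality_id, "label": rec["cell_type"],
                   "cell_size": int(counts[cid])}
            for marker in master_panel:
                row[marker] = means[marker][cid] if marker in means else np.nan
            rows.append(row)
    columns = list(META_COLUMNS) + list(master_panel) + ["cell_size"]
    return pd.DataFrame(rows)[columns]


def feature_matrix(table: pd.DataFrame, placeholder: float | None = None):
    """(X, y) from a feature table; ``placeholder`` fills missing markers
    (None keeps NaN for models with native missing-value handling)."""
    feats = table.drop(columns=list(META_COLUMNS))
    if placeholder is not None:
        feats = feats.fillna(placeholder)
    return feats.to_numpy(dtype=np.float64), table["label"].to_numpy()


class XGBoostBaseline:
    """Gradient-boosted trees on mean intensities; NaN marks missing markers."""

    def __init__(self, n_estimators: int = 160, seed: int = 0, **params):
        self.n_estimators = n_estimators
        self.seed = seed
        self.params = params
        self.model = None
        self.classes_: np.ndarray | None = None

    def fit(self, table: pd.DataFrame):
        import xgboost as xgb

        x, y = feature_matrix(table, placeholder=None)
        self.classes_, y_codes = np.unique(y, return_inverse=True)
        self.model = xgb.XGBClassifier(n_estimators=self.n_estimators,
                                       random_state=self.seed, **self.params)
        self.model.fit(x, y_codes)
        return self

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        x, _ = feature_matrix(table, placeholder=None)
        return self.classes_[self.model.predict(x)]


class MLPBaseline:
    """Feed-forward net on mean intensities; missing markers are set to 0."""

    def __init__(self, hidden=(64, 64), max_iter: int = 500, seed: int = 0):
        from sklearn.neural_network import MLPClassifier

        self.model = MLPClassifier(hidden_layer_sizes=hidden, max_iter=max_iter,
                                   random_state=seed)

    def fit(self, table: pd.DataFrame):
        x, y = feature_matrix(table, placeholder=0.0)
        self.model.fit(x, y)
        return self

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        x, _ = feature_matrix(table, placeholder=0.0)
        return self.model.predict(x)


def evaluate_classification(predictions, truth, min_support: int = 0):
    """Per-class F1 for classes with support >= min_support, macro average
    over the retained classes, and a confusion matrix."""
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.shape != truth.shape:
        raise ValueError("predictions and truth must align")
    classes = np.unique(np.concatenate([truth, predictions]))
    _, _, f1, support = precision_recall_fscore_support(
        truth, predictions, labels=classes, zero_division=0)
    truth_support = np.array([(truth == c).sum() for c in classes])
    retained = truth_support >= min_support
    if not retained.any():
        raise ValueError(f"no class has support >= {min_support}")
    per_class = {c: float(f) for c, f, keep in zip(classes, f1, retained) if keep}
    report = {
        "per_class_f1": per_class,
        "support": {c: int(s) for c, s, keep in zip(classes, truth_support, retained)
                    if keep},
        "macro_f1": float(np.mean(list(per_class.values()))),
        "confusion_matrix": pd.DataFrame(
            confusion_matrix(truth, predictions, labels=classes),
            index=classes, columns=classes),
    }
    return report


def modality_probe(embeddings: np.ndarray, modality_labels, n_folds: int = 5,
                   seed: int = 0):
    """Cross-validated linear-probe accuracy for imaging modality.

    Returns ``(accuracy, chance)`` where chance is the majority-class rate.
    Raises if only one modality is present.
    """
    labels = np.asarray(modality_labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("modality probe needs at least two modalities")
    clf = LogisticRegression(max_iter=2000)
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = cross_val_score(clf, np.asarray(embeddings), labels, cv=cv,
                             scoring="accuracy")
    return float(scores.mean()), float(counts.max() / counts.sum())
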