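"""Shared fixtures: a micro simulation spec for fast unit tests and the
session-wide benchmark corpus used by the acceptance suite."""

from __future__ import annotations

import numpy as np
import pytest

from phenoclip.synthetic import (ModalityEffect, SyntheticSpec,
                                 default_benchmark_spec, make_corpus)


def micro_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """A miniature corpus spec: 2 datasets, 5 markers, 3 types, ~40 cells each."""
    markers = ["DAPI", "CD45", "CD3", "CD20", "PanCK"]
    types = ["T cell", "B cell", "Epithelial cell"]
    on, off = np.log(60.0), np.log(2.0)
    profiles = np.full((3, 5), off)
    profiles[0, [0, 1, 2]] = on     # T cell
    profiles[1, [0, 1, 3]] = on     # B cell
    profiles[2, [0, 4]] = on        # Epithelial
    base = dict(
        master_panel=markers, cell_types=types, profile_matrix=profiles,
        panels=[markers, ["DAPI", "CD45", "CD3", "CD20"]],
        modalities=[ModalityEffect("modA", 1.0, 0.0, 0.0),
                    ModalityEffect("modB", 2.0, 1.0, 0.8)],
        dataset_modalities=[0, 1],
        cells_per_fov=40, fovs_per_dataset=1, fov_size=160,
        cell_radius_range=(4.0, 7.0), jitter_sigma=0.2, noise_sigma=1.0,
        spillover_sigma=0.1, spillover_pairs=[("CD45", "CD3")],
        positivity_threshold=float((on + off) / 2), seed=seed)
    base.update(overrides)
    return SyntheticSpec(**base)


@pytest.fixture(scope="session")
def micro_corpus():
    return make_corpus(micro_spec())


@pytest.fixture(scope="session")
def bench_corpus():
    """The canonical benchmark corpus (3 datasets, 12/9/7-marker panels)."""
    return make_corpus(default_benchmark_spec(seed=0))
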