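# phenoclip

Language-informed cell phenotyping for multiplexed spatial proteomics.

Multiplexed imaging platforms (CODEX, MIBI, IMC, CycIF, ...) produce
images with one channel per protein marker, and every experiment uses a
different marker panel. After segmentation, each cell must be assigned a
cell type from its marker expression — but a classifier with a fixed
feature vector cannot transfer to a dataset whose panel it has never seen.
`phenoclip` is for computational biologists who need one phenotyping model
that trains across heterogeneous datasets and predicts on new panels,
zero-shot.

## The model

Each marker channel of a segmented cell becomes a token: a shared CNN
encodes the channel's (image, self-mask, neighbor-mask) triplet
(C, 3, 64, 64), and the projected embedding of the marker's *name* —
produced by a pluggable text provider with a deterministic offline
fallback — is added to it. A transformer with a learnable [CLS] token and
no positional encoding applies self-attention across channels, so the
model is invariant to channel order and panel size. Classification is
contrastive: with normalized [CLS] embedding `z` and cell-type name
embeddings `t_k`, the prediction is `argmax_k cos(z, t_k)` over *any*
candidate set chosen at inference time. Training minimizes

    L = L_CLIP^focal(γ=2, τ) + L_BCE^pos(s=0.2) + w·e^{1/4} · L_CE^mod(s=0.01)

— a focal symmetric CLIP loss aligning cells with their type names, a
label-smoothed BCE tying the [CLS]-to-channel attention weights to marker
positivity, and a modality cross-entropy behind a gradient-reversal layer
whose weight ramps with the quartic root of the epoch, teaching the trunk
to unlearn platform-specific signal. See `docs/methods.md` for the full
treatment.

The package also ships a synthetic multiplexed-image simulator (elliptical
cells, log-normal marker profiles, per-dataset panels, modality
gain/offset/blur, background noise, channel spillover) with exact ground
truth, a mean-intensity XGBoost/MLP baseline, evaluation metrics, and a
modality linear probe — everything needed to exercise the pipeline without
any downloads.

## Worked example

Train the desk-scale configuration on the built-in benchmark corpus
(3 synthetic datasets with 12/9/7-marker panels across 2 modalities,
~550 cells each; dataset 2's panel is never seen in training):

```python
from phenoclip.benchmarks import benchmark_corpus, run_benchmark

corpus = benchmark_corpus()          # renders + preprocesses all datasets
result = run_benchmark(seed=1, corpus=corpus)
print(f"validation macro-F1: {result.val_macro_f1:.3f}")
print(f"zero-shot macro-F1 (unseen 7-marker panel): {result.zeroshot_macro_f1:.3f}")
print(f"XGBoost mean-intensity baseline, same split: {result.baseline_zeroshot_f1:.3f}")
print(f"marker-positivity AUC (attention vs truth): {result.positivity_auc:.3f}")
print(f"modality probe accuracy: {result.probe_accuracy:.3f}")
```

prints (about 2 minutes on one CPU):

```
validation macro-F1: 1.000
zero-shot macro-F1 (unseen 7-marker panel): 0.863
XGBoost mean-intensity baseline, same split: 0.660
marker-positivity AUC (attention vs truth): 1.000
modality probe accuracy: 0.706
```

The held-out validation cells are classified perfectly; on the never-seen
7-marker panel — which omits both myeloid markers, so macrophages must be
recognized by lineage exclusion — the model keeps macro-F1 0.86 while the
mean-intensity tree baseline, whose missing-marker features have no
meaningful routing, drops to 0.66. The positivity AUC of 1.0 means the
[CLS] attention weights separate expressed from unexpressed markers
essentially perfectly, and the probe accuracy of 0.71 (vs ~0.83 for a
model trained without the adversary; chance 0.5) shows the
gradient-reversal head removed a substantial part of the platform signal
from the cell embeddings.

The `examples/` directory holds short narrative scripts, one per
capability: simulation, preprocessing/patching, training, zero-shot
prediction with tissue binding, marker positivity, and the
modality-invariance probe. A thin CLI covers the shell workflows:

```bash
phenoclip simulate --out corpus/                    # OME-TIFFs + masks + truth CSVs
phenoclip train --config run.yaml --out run/        # checkpoint + metrics.jsonl
phenoclip predict --checkpoint run/model.npz --images corpus/dataset-2 \
    --masks corpus/dataset-2 --channels corpus/dataset-2/fov-0.channels.csv \
    --candidates types.csv --out predictions.csv
phenoclip evaluate --pred predictions.csv --truth truth.csv --out report.json
```

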