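# Methods

## The phenotyping problem

Multiplexed tissue imaging (CODEX, MIBI, IMC, CycIF, ...) measures tens of
protein markers per pixel over intact tissue. After whole-cell
segmentation, each cell must be assigned a cell type from its marker
expression pattern ("phenotyping"). The obstacle to a general model is
heterogeneity: every experiment images a different marker panel, with
different marker identities, counts, and platform-specific intensity
characteristics. A classifier with a fixed input feature vector cannot be
applied to a dataset whose panel it has never seen.

`phenoclip` treats each marker **channel** as a token. A cell is the *set*
of its channels, and the model's core is self-attention over that set:

1. **Image encoder.** Every channel contributes a (marker image,
   self-mask, neighbor-mask) triplet of shape (3, 64, 64), cut from the
   normalized field of view around the cell centroid. One shared CNN (conv
   3x3 -> SiLU -> batchnorm stacks, strided downsampling, global average
   pooling, linear head) maps each triplet to a `d_model` vector. Because
   the same CNN processes every channel slot, the encoder is agnostic to
   which marker a channel carries.
2. **Language encoder.** Each marker *name* (and each candidate cell-type
   name) is described and embedded by a pluggable text provider; the raw
   `D_raw` vector is mapped into model space by a linear projection trained
   jointly with the rest of the network. The default provider is fully
   offline: the description is templated, and the embedding is a seeded
   pseudo-random unit vector derived from a SHA-256 hash of the text, so
   distinct terms get near-orthogonal, reproducible vectors. A generic
   HTTP adapter can substitute a hosted explainer/embedder; swapping
   providers changes vectors but no tensor shapes.
3. **Channel-wise transformer.** Each channel token is the *sum* of its
   image embedding and projected name embedding. A learnable [CLS] token
   is prepended and the sequence passes through pre-norm transformer
   encoder layers with **no positional encoding**; a key padding mask
   excludes unused channel slots. The model is therefore invariant to
   channel order and to the amount of padding (verified to < 1e-4 in
   single precision).
4. **Heads.** The final-layer [CLS]-to-channel attention, averaged over
   heads, renormalized over real channels, and rescaled by the per-cell
   maximum, is read out as a marker-positivity score in [0, 1]. The [CLS]
   embedding itself is the cell representation: cell-type classification
   is the cosine similarity between it and projected cell-type name
   embeddings, so the candidate label set is chosen at inference time
   ("prediction-set binding", optionally restricted per tissue). A 3-layer
   MLP behind a gradient-reversal layer predicts the imaging modality; its
   reversed gradients push the trunk toward platform-invariant features.

## Losses and training

Three terms are combined per batch:

- **Focal contrastive (CLIP) loss** between L2-normalized [CLS] rows `I`
  and matched cell-type-name rows `T`: `S = I Tᵀ/τ` is softmaxed along
  rows (image view) and along rows of `Sᵀ` (text view); each view
  contributes `mean((1 - p_t)^γ · (-log p_t))` on the diagonal targets,
  and the views are averaged. γ = 2 focuses capacity on hard cells; τ is
  learnable, parameterized as `exp(log τ)` with init 0.07 (the common
  contrastive default; the positivity constraint motivates the log
  parameterization).
- **Positivity BCE** between attention-derived scores and gated
  positivity labels, with label smoothing 0.2 applied as
  `t -> t(1-s) + s/2`; averaged over real, labeled channels only.
- **Adversarial modality cross-entropy** (label smoothing 0.01,
  uniformly redistributed) behind the gradient-reversal layer. Its weight
  ramps as `w_adv · epoch^(1/4)` with the 1-based current epoch index
  (a constant would not ramp), so the model first learns type-discriminative
  features and only later unlearns platform signal. `w_cls = w_pos = 1`,
  `w_adv = 0.1` by default.

Optimization uses RAdam. Batches pool cells across all training datasets
and are zero-padded to the largest panel in the batch; this matters beyond
convenience: if batches were drawn from a single dataset at a time,
train-mode batchnorm would normalize each batch by its own dataset's
statistics and strip modality differences from the very activations the
adversary head sees, silently disabling domain-adversarial training (the
head's cross-entropy then sits at chance for the whole run).
Augmentation: random horizontal/vertical flips,
right-angle rotations, and random resize (zoom 0.9-1.1, nearest), applied
identically to all three planes of every channel; channel dropout zeroes
`k` randomly chosen real channels per cell and clears their mask bits
(never dropping the last channel), with the dropped channels' name
embeddings excluded via the mask. Marker- and type-name embeddings receive
fresh Gaussian noise (sigma 0.005) at every batch draw as a regularizer.
Validation is a stratified 90/10 split per dataset with a fixed seed; the
best-validation-macro-F1 parameters are restored after training.

## Preprocessing conventions

- Resampling to 0.5 microns/pixel uses nearest-neighbor interpolation
  without anti-aliasing; output length is `floor(n·zoom + 0.5)` and output
  pixel centers map back via `floor((i + 0.5)/zoom)`. Masks use the same
  index map, which keeps image/mask registration exact and is
  label-preserving.
- Per channel per FOV, intensities are clipped at the 99th percentile
  (linear interpolation) of the channel's *non-zero* pixels, then min-max
  scaled to [0, 1]. Degenerate cases: an all-zero channel passes through;
  a constant non-zero channel maps to zeros. Note the operation is not
  exactly idempotent: re-normalizing an already-normalized channel clips
  again at the new 99th percentile, a visible effect when a channel has
  few non-zero pixels.
- Resampling precedes normalization (the order is fixed in config).
- The patch window is the half-open 64x64 block `[r-32, r+32) x [c-32,
  c+32)` around the integer-rounded mask centroid, 0-based (row, col);
  out-of-image regions are zero in all three planes. Fragmented or
  multi-nucleated labels are centered on their overall mask centroid.
- Channel order inside a patch follows the dataset's panel order; the
  model's order invariance makes a global sort unnecessary.
- Batches are zero-padded along the channel axis to `C_max` (75 for the
  full-scale configuration) with a binary padding mask.

## Architecture defaults and the desk-scale configuration

The full-scale configuration mirrors the published recipe: an 11-layer CNN
(kernel 3, padding 1, strides interleaved 1 and 2, ending at a 2x2
feature map), five transformer layers with `d_model` 256, feed-forward 512,
and `C_max` 75. Unstated details fixed here: channel widths double from a
base of 16 (capped at 256); 8 attention heads of dimension 32; [CLS] is
prepended and may attend to itself; pre-norm blocks for small-scale
stability; batchnorm statistics are shared across channel slots (a
consequence of the `(B·C, 3, 64, 64)` reshape) and frozen at eval.

All tests and the benchmark run a `tiny` configuration chosen for
single-CPU wall time: 5 CNN layers (widths 8-16-32-32-32, strides
4-2-2-2-1), 2 transformer layers, `d_model` 64, feed-forward 128, 4 heads,
`D_raw` 256. The attention-normalization recipe for positivity
(head-average, renormalize over real channels, rescale by per-cell max so
the top marker scores exactly 1) is a documented choice; the underlying
normalization is ambiguous in the source description, and both steps are
config options.

## The synthetic corpus

The simulator emulates the features of real multiplexed data that the
model and baselines are sensitive to, with exact ground truth:

- **Cell geometry.** Non-overlapping ellipses (random radii 4-8 px,
  random orientation) placed by Poisson-disk rejection; cells may touch
  the field border (boundary-adjacent cells exercise patch padding) and
  sit within 1 px of each other (neighbor context and spillover).
- **Expression.** Per-type mean log-intensities ("on" = ln 60, "off" =
  ln 2) with per-cell log-normal jitter (sigma 0.25) — strictly positive
  and heavy-tailed like staining data. Positivity truth is the profile
  thresholded at the on/off midpoint.
- **Panels.** Per-dataset marker subsets of a master panel.
- **Modality effects.** Per-modality gain/offset/Gaussian blur.
- **Noise.** Additive Gaussian background noise (clipped at zero) and
  channel spillover: a Gaussian-blurred fraction of designated source
  channels leaks into their partners.

The canonical benchmark spec: 12 markers, 4 cell types (T cell, B cell,
Macrophage, Epithelial cell), 3 datasets of ~550 cells (5 FOVs of ~110
cells at 256x256), 2 modalities (identity vs gain 2.5 / offset 3 / blur
1.2). Datasets 0 and 1 (12- and 9-marker panels) train; dataset 2's
7-marker panel is the zero-shot hold-out and deliberately omits both
myeloid-defining markers (CD68, CD11c), so macrophages are only
recognizable by lineage exclusion (CD45+ CD3- CD20-). This is the regime
that defeats per-marker tabular baselines — a tree trained where CD68 was
always observed has no meaningful routing for its missing value — while a
panel-invariant model trained with channel dropout handles it.

What the simulator does **not** emulate: real tissue architecture,
autofluorescence, segmentation errors beyond boundary adjacency,
cell-shape/type correlations, and realistic class imbalance. Passing the
benchmark therefore demonstrates that the machinery (losses, invariances,
adversary, zero-shot binding) works as specified, not that the tiny model
would reach any particular accuracy on real consortium data.

## Benchmark training recipe and problem sizes

The benchmark trains the tiny configuration for 20 epochs with RAdam at
learning rate 3e-3, batch size 16, channel dropout k = 2, on ~990 training
cells (90% of datasets 0-1). Batch size 16 (~1,100 optimizer steps) and
the raised learning rate (full-scale default 1e-4) address the long
initial plateau of the contrastive objective at this data scale: with half
as many steps, or the full-scale rate, some initializations do not leave
the plateau within the 20-epoch budget. Evaluation: macro-F1 on
the held-out validation cells and on the never-seen dataset 2; the
mean-intensity XGBoost baseline (union feature table, NaN placeholders,
160 rounds, cell-size column) is trained on exactly the same training
rows. The modality probe is a 5-fold cross-validated logistic regression
on eval-mode [CLS] embeddings of all dataset-0/1 cells.

## Numerical and engineering choices

The network and training loop run on a small reverse-mode autodiff engine
over NumPy arrays written for this package (tensor-level operations:
im2col convolution, batchnorm, layer norm, masked multi-head attention,
gradient reversal, reductions). Analytic gradients of every operation and
of all three losses are validated against central finite differences in
float64. Models run in float32; probability clamps use 1e-6 (float32-safe)
inside BCE and 1e-8 elsewhere; masked attention uses additive -inf bias,
which zeroes excluded keys exactly. Ties in `argmax` (prediction) break to
the lowest candidate index. Degenerate inputs (empty channel set, empty
candidate set, single modality for the probe, infeasible cell packing)
raise informative errors rather than propagating NaNs.
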