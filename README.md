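# dcetensor

Tensor-based multichannel reconstruction and hybrid fuzzy segmentation of
dynamic contrast-enhanced (DCE) MRI tumour studies, with a synthetic
phantom generator and self-referencing reconstruction-quality metrics.

## The problem

A breast DCE-MRI study is one pre-contrast baseline volume plus a short
series of post-contrast volumes (canonically n = 6 at 60 s intervals).
Tumours reveal themselves by their enhancement kinetics — malignant
tissue typically shows rapid wash-in followed by wash-out, benign tissue
a persistent rise — but frame-by-frame intensity segmentation (e.g.
fuzzy C-means on each enhancement image) is fragile: intra-scan
inhomogeneity, moderately enhancing fat and skin, and noise produce
ragged boundaries and disconnected false-positive voxels.

`dcetensor` implements a reconstruction that pools all frames before
segmenting. Writing `X_τ` for the enhancement (post-minus-baseline)
volume at frame τ restricted to a region of interest:

1. **Per-frame HOSVD.** Each `X_τ` is factorized by higher-order SVD
   (Tucker form) into orthonormal mode bases `A_τ^(i)`, i = 1,2,3, and an
   all-orthogonal core `C_τ`:  `X_τ = C_τ ×₁ A_τ^(1) ×₂ A_τ^(2) ×₃ A_τ^(3)`.
2. **Temporal PCA over basis images.** For each mode, entry `j` of the
   basis matrix traces a state vector `u_j ∈ R^n` over the frames. With
   `ū` the mean state vector and ε the entry count, the ensemble
   covariance `Δ = (1/ε) Σ_j (u_j − ū)(u_j − ū)ᵀ` is eigendecomposed;
   the leading eigenvector `e₁` is the dominant temporal enhancement
   channel. The channel-1 basis image is the per-entry projection
   `s_j = u_jᵀ e₁`, matricised back to the basis shape.
3. **Channel reconstruction.** With `C_A` the core averaged over the
   early frames (default τ = 1..3),
   `Γ₁ = C_A ×₁ A₁^(1) ×₂ A₁^(2) ×₃ A₁^(3)` is a single volume that
   concentrates the dominant enhancement dynamic and depresses tissue
   (fat, skin) whose time course differs from it.
4. **Hybrid segmentation.** Fuzzy C-means on `Γ₁` inside the ROI, keeping
   the highest-center class, yields the tumour mask.

The ROI itself comes from a mask pipeline on the enhancement series:
FCM binarization of the peak-enhancement frame (default frame 4),
morphological dilation by a discrete ball (so no boundary tumour voxel
is lost), and subtraction of the enhancing skin shell.

Reconstruction quality is quantified without ground truth by comparing
the hybrid mask against the per-frame FCM masks using five ratios
(reported in percent): `NcReR = NCD/REC`, `OvReR = OVL/REC`,
`DiReR = DIF/REC`, `NoReR = NOI/REC` and `NoEsR = NOI/ESI`, where REC and
ESI are the hybrid and per-frame mask sizes, NCD/OVL/DIF count
non-covered/overlapping/differing voxels, and NOI counts mask voxels not
connected to the largest component — the noise the reconstruction is
supposed to suppress.

## Worked example

The package ships a phantom generator (64×64×32 grid, n = 6 frames: a
washout tumour peaking at frame 4, a plateau fatty confounder, an
enhancing skin shell, a 10% bias field, noise at 5% of the tumour peak),
so the whole pipeline runs without patient data:

```bash
dcetensor run-all --seed 1 -o demo/
```

prints

```
pipeline complete; report written to demo/
Dice vs phantom tumour truth: 0.9989
hybrid NoReR: 0.00%
mean ES NoEsR: 8.07%
```

meaning: the hybrid mask recovers the known tumour almost voxel-exactly
(Dice 0.9989); the hybrid segmentation contains no disconnected noise
voxels (NoReR 0%), whereas the frame-by-frame FCM masks carry on average
8% noise voxels relative to their size — the fatty confounder and noise
spikes appear there as components disconnected from the tumour.
`demo/report.csv` lists the per-frame ratios (one row per enhancement
frame plus a final hybrid row, the layout used for reporting case
studies); `demo/` also holds every intermediate as NIfTI (enhancement
series, ROI mask, reconstruction `gamma`, masks, truth) plus a
`provenance.json` sidecar with all parameters and the seed.

The same stages are available individually (`simulate`, `preprocess`,
`reconstruct`, `segment`, `evaluate`) over NIfTI files, and as a library
API (`dcetensor.run_pipeline`, `FuzzyCMeans`, `TemporalPCA`,
`hosvd_decompose`, ...). Real studies are loaded from one 4D NIfTI or
per-frame 3D NIfTI files (baseline first); inputs are assumed rigidly
co-registered.

## Layout

```
src/dcetensor/
  core.py            data model (volumes, studies, enhancement series, masks)
  io.py              NIfTI I/O + provenance sidecars
  phantom.py         synthetic studies with ground truth
  preprocess.py      ROI mask pipeline (FCM binarization, dilation, skin shell)
  fcm.py             fuzzy C-means estimator (scikit-learn conventions)
  tensor.py          unfold / fold / mode products / HOSVD
  reconstruction.py  sign alignment, temporal PCA, channel reconstruction,
                     hybrid segmentation
  metrics.py         overlap labeling, noise voxels, the five ratios
  pipeline.py        orchestration
  cli.py             command-line interface
docs/methods.md      models, parameters, numerical choices, limitations
```
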