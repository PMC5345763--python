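# Methods

This note documents the models implemented in `dcetensor`, the
parameters that matter, the numerical conventions, and the limitations a
user should know before applying the pipeline to real data.

## Data model

A dynamic study is a baseline volume plus n ≥ 1 post-contrast volumes on
one voxel grid (n = 6 at 60 s spacing is the canonical protocol).  The
enhancement series (ES) is the voxelwise difference `post_τ − baseline`.
Negative enhancement is retained: clipping would bias every covariance
computed downstream.  Arrays are indexed `(x, y, z)`, 0-based; NIfTI
affines are carried through unchanged.  Inputs are assumed rigidly
co-registered; the package performs no registration.  An optional crop
box (`PipelineConfig.crop_box`) restricts a study to one breast side; it
is never inferred automatically.

## ROI mask pipeline

Stages, in order, with defaults:

| parameter | default | meaning |
|---|---|---|
| `peak_frame` | 4 | 1-based frame used for binarization; `"auto"` = argmax of mean enhancement, ties to the lowest index |
| binarization FCM | 3 classes, top 1 | intensity classes of the peak ES frame |
| `dilation_radius` | 2 voxels | discrete Euclidean ball; guards against losing weakly enhancing boundary voxels |
| `skin_thickness` | 2 voxels | shell subtracted from the mask; shell = Otsu body support minus its erosion |

Masking means voxelwise multiplication of every ES frame by the binary
mask — a mask application, not a linear convolution, which would smear
intensity across the ROI edge.

**Why three binarization classes.** On an ES difference image most
voxels are pure noise centred at 0.  A two-class fuzzy C-means fit (m=2)
on such zero-inflated data places both centres near the noise mode
(measured on the default phantom: centres −2.1 and 16.1, class boundary
≈ 1σ of the noise), so the "enhancing" class absorbs the upper noise
tail and, after dilation, floods most of the grid.  With three classes
(background noise / moderate enhancement / strong enhancement, keeping
the top class) the boundary sits at ≈ 3.4σ and the mask stays compact
(≈ 20% of the default phantom grid, the residual dominated by the
dilated enhancing-skin band).  The standalone `binarize_enhancement`
function keeps the plain two-class default; the three-class default
applies to the pipeline's `MaskPipelineParams`.

The skin shell is reconstructed from the baseline (Otsu threshold →
hole-filled body support → body minus its erosion); its thickness is
configurable because real skin extraction depends on resolution.  A
shell of thickness t removes skin detections but not the part of the
dilated mask that protrudes inward past t; users who want the band gone
should set `skin_thickness ≥ skin depth + dilation_radius`.

## Fuzzy C-means

Standard alternating updates on scalar intensities:
`v_k = Σ u_ik^m x_i / Σ u_ik^m`, `u_ik = 1/Σ_j (d_ik/d_ij)^(2/(m−1))`.
Defaults: m = 2, tol = 1e−5 on centre movement, max 300 iterations,
deterministic quantile-centre initialization (random membership
initialization available behind a seed).  A sample exactly on a centre
receives membership 1 there.  The objective is non-increasing and
memberships sum to 1 per sample; both are asserted in tests, and hard
labels at m → 1⁺ agree with k-means on separated data.  Clustering is
intensity-only — no spatial regularization.

## Tensor algebra

Mode-i unfolding moves axis i first and flattens the remaining axes in
C order; `fold` is its exact inverse and the mode product is
`fold(M · unfold(X, i))`.  HOSVD takes the leading left singular vectors
of each unfolding as the mode basis and contracts the transposed bases
onto the tensor for the core.  Each singular vector is oriented so its
largest-magnitude entry is positive, making the factorization
deterministic.  At full ranks the reconstruction is exact (asserted at
< 1e−10 relative error); truncation is exposed but the canonical
pipeline does not truncate.  The decomposition runs on the ROI bounding
box, not the full grid — the mask exists precisely to make the spatial
voxel count commensurate with the six-frame temporal dimension.

## Temporal PCA and channel reconstruction

Per-frame SVD column signs are arbitrary, so bases are first aligned
columnwise to frame 1, flipping the matching core slices in compensation
(per-frame reconstructions are unchanged; the operation is idempotent).

For each mode, the state vector of basis entry j is its time course
`u_j ∈ R^n`.  The model uses the ensemble covariance
`Δ = (1/ε) Σ_j (u_j − ū)(u_j − ū)ᵀ` (divisor ε = entry count), its
eigenvalues sorted descending, eigenvector signs fixed as above.  Two
consequences worth stating explicitly:

* A time-constant stack is a rank-1 stack along the flat direction
  `1/√n`, so Δ = var(v)·𝟙𝟙ᵀ with a single non-zero eigenvalue — *not*
  the zero matrix.  This is the desirable behaviour: when all temporal
  structure sits in the cores (e.g. a separable `X_τ = f(τ)·S`), the
  flat channel still reproduces the spatial pattern.  An expectation
  that "no temporal variation ⇒ Δ = 0" would require per-pixel temporal
  centring, which is a different model.
* The channel-s basis image is the raw projection `s_j = u_jᵀ e_s`
  matricised back to the basis shape.  Raw (uncentred) projection is the
  default because it preserves the mean intensity scale; centred
  projection (`center=True`) is available.

The reconstruction is `Γ_s = C_A ×₁ A_s^(1) ×₂ A_s^(2) ×₃ A_s^(3)` with
`C_A` the mean core over `core_frames` (default frames 1–3; an
all-frames option exists — the early-frame average is kept as default
because the first frames carry the wash-in dynamic the first channel
represents).  Channel s = 1 is the default; higher channels are
computed on demand but not fused.  Because eigenvector signs are
conventional, the overall sign of Γ is fixed by orienting it to have
non-negative inner product with the peak-frame masked ES inside the ROI
box.

Measured on single-washout-tumour phantoms, the first channel is
strictly dominant but not overwhelming: λ₁/Σλ per mode is ≈ 0.65–0.87 at
1% noise and ≈ 0.54–0.69 at 5% noise.  The spectrum is flattened by the
many noise-dominated columns that full-rank bases carry; tests therefore
assert strict dominance (λ₁ = max, λ₁ ≥ 2λ₂) rather than a fixed energy
fraction.

Hybrid segmentation clusters Γ inside the ROI (FCM, default 2 classes,
keeping the top class; a 5-class variant is configuration) and applies
no connected-component pruning — disconnected voxels are measured by the
metrics, not silently removed.

## Quality metrics

The overlay labels each voxel 1 (per-frame FCM ES mask only), 2 (hybrid
only) or 3 (both); counts NCD = TuRI = |1|, TuOI = |2|, OVL = |3|,
REC = |2|+|3|, ESI = |1|+|3|, DIF = TuRI + TuOI.  Ratios are reported in
percent: NcReR = NCD/REC, OvReR = OVL/REC, DiReR = DIF/REC,
NoReR = NOI/REC (hybrid, once), NoEsR = NOI/ESI (per frame).  NOI counts
voxels outside the largest connected component (default 26-connectivity;
ties go to the component containing the lexicographically smallest
voxel).  By default the overlap ratios compare main components only —
disconnected voxels are zeroed before labeling — while the noise ratios
always use raw mask counts; `main_components_only=False` compares raw
masks.  NoEsR is reported as `Inf` when an ES mask is empty.  The exact
identities `OvReR + TuOI/REC·100 = 100` and
`DiReR = NcReR + TuOI/REC·100` hold by construction and are asserted.
NoReR is defined uniformly as NOI/REC·100.

## Phantom generator

The generator emulates the structure the pipeline must handle, not MR
physics.  Defaults (all configurable): 64×64×32 grid, n = 6 frames at
60 s; body ellipsoid of constant tissue intensity 100 in air; one
washout tumour (linear rise to peak 100 at frame 4, 30% washout by
frame 6); one plateau fatty confounder at amplitude 25; a 2-voxel skin
shell with persistent enhancement to amplitude 30; a smooth low-order
multiplicative bias field of ±10% on the baseline tissue; i.i.d.
Gaussian noise of σ = 5 (5% of tumour peak) added to each post-contrast
frame.  Kinetic curves are piecewise linear — the simplest family
showing the three clinical patterns (washout / plateau / persistent); no
pharmacokinetic (Tofts-type) model is implied.  Enhancement is added on
top of the biased baseline, so at σ = 0 the ES is exactly piecewise
constant per region — every downstream stage has closed-form
expectations.  Truth masks (tumour, fat, skin) are pairwise disjoint and
reproducible from the spec alone; identical seeds give bit-identical
studies.

What the phantom does **not** emulate — and hence what passing tests do
not establish about real data: Rician noise statistics, coil
sensitivity, partial-volume boundaries, motion/misregistration,
heterogeneous intra-tumour kinetics, and anatomically realistic skin or
glandular structure.  The clinical 448×288×160 grid is supported but not
used in routine tests; phantom studies use the desk-scale grid so the
full ten-seed end-to-end suite completes in well under a minute.

## Numerical choices and degenerate inputs

* SVD/eigenvector sign convention: largest-magnitude entry positive;
  ties in FCM tumour-cluster selection and peak-frame selection break
  toward the lower index; main-component ties toward the
  lexicographically smallest voxel.
* Constant volumes are rejected by binarization and hybrid segmentation
  (`DegenerateInputError`); an empty final ROI mask aborts the pipeline
  (`PipelineError`); an empty body support yields an empty skin shell
  with a warning.
* FCM quantile initialization separates coincident initial centres by a
  relative epsilon so clusters can split even on heavily tied data.
* All stochastic stages draw from `numpy.random.default_rng` seeded from
  one configuration seed; fixed seed ⇒ bit-identical masks and reports.

## Known limitations

* The temporal channel model inherits the arbitrariness of SVD null
  spaces: on exactly rank-deficient inputs (e.g. noise-free phantoms)
  basis columns beyond the signal rank are numerically arbitrary, and
  properties such as exact scale equivariance hold only where singular
  values are distinct.
* Reported patient-data ratios depend on FCM settings (fuzzifier,
  tolerance, initialization) that are not uniquely determined; on
  phantoms the pipeline's behaviour is asserted through properties
  (Dice against truth, noise suppression) rather than fixed ratio
  values.
* Very large tumours relative to the six-frame temporal dimension are
  hard to reconstruct from one channel; the package computes higher
  channels but does not fuse them.
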