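"""Temporal PCA over per-frame HOSVD bases and multichannel reconstruction.

Given the masked enhancement series restricted to its ROI bounding box,
each frame tau = 1..n is HOSVD-factorized into mode bases A_tau^i and a
core C_tau.  Entry j of a mode-i basis then traces an n-vector over time
(its "state vector" u_j); PCA of the covariance of these state vectors —
averaged over all basis-matrix entries, divisor = entry count — yields
temporal channels per mode.  The channel-s basis image is the per-entry
projection of the state vectors onto eigenvector s, matricised back to
the basis-matrix shape.  The channel reconstruction is

    Gamma_s = C_A x_1 A_s^1 x_2 A_s^2 x_3 A_s^3,

with C_A the core averaged over the early frames (default frames 1-3)
and s = 1 the dominant enhancement channel.  Fuzzy C-means on Gamma
restricted to the ROI mask gives the hybrid tumour segmentation.

Per-frame SVDs carry arbitrary column signs, so before any temporal
statistics the bases are aligned to the first frame columnwise, with the
matching core slices flipped in compensation — every per-frame
reconstruction is unchanged by the alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .core import BinaryMask
from .errors import DegenerateInputError, DimensionError, ParameterError
from .fcm import FCMParams, assign_tumour_cluster, fcm_cluster
from .tensor import HOSVDFactors, mode_multiply

__all__ = [
    "TemporalBasisStack",
    "TemporalPCAModel",
    "ChannelReconstruction",
    "align_signs",
    "build_temporal_stack",
    "TemporalPCA",
    "fit_temporal_pca",
    "project_channel_basis",
    "reconstruct_channel",
    "hybrid_segment",
]


@dataclass
class TemporalBasisStack:
    """Per-frame basis matrices of one tensor mode, ordered by frame."""

    mode: int
    matrices: list[np.ndarray]  # n matrices, common shape (N, M)
    sign_aligned: bool = False

    def __post_init__(self) -> None:
        if not self.matrices:
            raise ParameterError("stack needs at least one frame")
        shape = self.matrices[0].shape
        for k, m in enumerate(self.matrices):
            if m.shape != shape:
                raise DimensionError(f"frame {k} basis shape {m.shape} != {shape}")

    @property
    def n(self) -> int:
        return len(self.matrices)

    @property
    def basis_shape(self) -> tuple[int, int]:
        return self.matrices[0].shape

    def state_vectors(self) -> np.ndarray:
        """(epsilon, n) array: row j is the time course of basis entry j
        (C-order flattening of the basis matrix)."""
        return np.stack([m.ravel() for m in self.matrices], axis=1)


def align_signs(factors: Sequence[HOSVDFactors], reference: int = 0) -> list[HOSVDFactors]:
    """Align per-frame basis column signs to a reference frame.

    For every non-reference frame and mode, a basis column is flipped when
    its inner product with the corresponding reference column is negative;
    the matching core slice is flipped in compensation, leaving each
    per-frame reconstruction bit-identical.  Idempotent.
    """
    ref = factors[reference].mode_bases
    out: list[HOSVDFactors] = []
    for k, fac in enumerate(factors):
        if k == reference:
            out.append(
                HOSVDFactors(
                    tuple(b.copy() for b in fac.mode_bases),
                    fac.core.copy(),
                    frame_index=fac.frame_index,
                )
            )
            continue
        bases = []
        core = fac.core.copy()
        for mode in range(3):
            B = fac.mode_bases[mode]
            R = ref[mode]
            if B.shape != R.shape:
                raise DimensionError(
                    f"frame {k} mode {mode} basis shape {B.shape} != reference {R.shape}"
                )
            flips = np.sign(np.sum(B * R, axis=0))
            flips[flips == 0] = 1.0
            bases.append(B * flips)
            core = mode_multiply(core, np.diag(flips), mode)
        out.append(HOSVDFactors(tuple(bases), core, frame_index=fac.frame_index))
    return out


def build_temporal_stack(factors: Sequence[HOSVDFactors], mode: int) -> TemporalBasisStack:
    """Collect the mode-``mode`` bases of sign-aligned per-frame factors."""
    return TemporalBasisStack(
        mode=mode, matrices=[f.mode_bases[mode] for f in factors], sign_aligned=True
    )


class TemporalPCA(TransformerMixin, BaseEstimator):
    """PCA of per-entry temporal state vectors.

    Input to :meth:`fit` is an (epsilon, n) array whose rows are the
    n-frame time courses of the basis-matrix entries.  The covariance is
    the first-order (biased, divisor epsilon) covariance of the rows; its
    eigenpairs are sorted by descending eigenvalue and each eigenvector is
    oriented so its largest-magnitude entry is positive.

    Parameters
    ----------
    center : bool, default False
        If True, :meth:`transform` projects mean-removed state vectors;
        the default projects raw state vectors, preserving the mean
        intensity scale of the basis images.

    Attributes
    ----------
    mean_ : (n,) per-frame mean state vector.
    covariance_ : (n, n) symmetric PSD matrix.
    eigenvalues_ : (n,) descending.
    components_ : (n, n), row s-1 = channel-s eigenvector.
    n_pixels_ : epsilon, the number of state vectors.
    """

    def __init__(self, center: bool = False) -> None:
        self.center = center

    def fit(self, X, y=None) -> "TemporalPCA":
        U = np.asarray(X, dtype=float)
        if U.ndim != 2:
            raise DimensionError("expected an (epsilon, n) state-vector array")
        eps, n = U.shape
        if eps < 2:
            raise DegenerateInputError("need at least 2 state vectors")
        self.mean_ = U.mean(axis=0)
        dev = U - self.mean_
        self.covariance_ = dev.T @ dev / eps
        w, E = np.linalg.eigh(self.covariance_)
        order = np.argsort(w)[::-1]
        w, E = w[order], E[:, order]
        idx = np.abs(E).argmax(axis=0)
        signs = np.sign(E[idx, np.arange(n)])
        signs[signs == 0] = 1.0
        self.eigenvalues_ = w
        self.components_ = (E * signs).T
        self.n_pixels_ = eps
        return self

    def transform(self, X) -> np.ndarray:
        U = np.asarray(X, dtype=float)
        if self.center:
            U = U - self.mean_
        return U @ self.components_.T


@dataclass
class TemporalPCAModel:
    """Fitted temporal PCA of one mode's basis stack."""

    mode: int
    mean: np.ndarray
    covariance: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns, descending eigenvalue
    n_pixels: int
    center: bool = False


def fit_temporal_pca(stack: TemporalBasisStack, center: bool = False) -> TemporalPCAModel:
    """Fit the temporal PCA of a sign-aligned basis stack (see
    :class:`TemporalPCA`)."""
    if not stack.sign_aligned:
        raise ParameterError("stack must be sign-aligned before temporal PCA")
    est = TemporalPCA(center=center).fit(stack.state_vectors())
    return TemporalPCAModel(
        mode=stack.mode,
        mean=est.mean_,
        covariance=est.covariance_,
        eigenvalues=est.eigenvalues_,
        eigenvectors=est.components_.T,
        n_pixels=est.n_pixels_,
        center=center,
    )


def project_channel_basis(
    stack: TemporalBasisStack, model: TemporalPCAModel, channel: int = 1
) -> np.ndarray:
    """Channel-``channel`` basis image of one mode.

    Per-entry score s_j = u_j . e_channel (raw projection by default;
    mean-removed when the model was fitted with ``center=True``),
    matricised back to the basis-matrix shape in the same C order used to
    build the state vectors.
    """
    if not 1 <= channel <= stack.n:
        raise ParameterError(f"channel must lie in 1..{stack.n}, got {channel}")
    U = stack.state_vectors()
    if model.center:
        U = U - model.mean
    scores = U @ model.eigenvectors[:, channel - 1]
    return scores.reshape(stack.basis_shape)


@dataclass
class ChannelReconstruction:
    """Channel reconstruction Gamma plus the pieces it was built from."""

    channel: int
    channel_bases: tuple[np.ndarray, np.ndarray, np.ndarray]
    averaged_core: np.ndarray
    volume: np.ndarray  # ROI-box shaped
    models: tuple[TemporalPCAModel, TemporalPCAModel, TemporalPCAModel] | None = None


def reconstruct_channel(
    factors: Sequence[HOSVDFactors],
    channel: int = 1,
    core_frames: Sequence[int] = (1, 2, 3),
    center: bool = False,
    orient_to: np.ndarray | None = None,
) -> ChannelReconstruction:
    """Build the channel reconstruction from sign-aligned per-frame factors.

    Parameters
    ----------
    factors : sign-aligned HOSVD factors, one per frame (tau = 1..n).
    channel : temporal channel (1 = dominant enhancement dynamic).
    core_frames : 1-based frame indices whose cores are averaged into
        C_A (default the early frames 1-3).
    center : use mean-removed projections for the channel bases.
    orient_to : optional ROI-box array (e.g. the peak enhancement
        frame); the result is sign-flipped if its inner product with
        this reference is negative.  The overall sign of Gamma is
        otherwise arbitrary because eigenvector signs are.
    """
    n = len(factors)
    if n < 2:
        raise ParameterError("need at least two frames to reconstruct")
    if not core_frames:
        raise ParameterError("core_frames must be non-empty")
    bad = [t for t in core_frames if not 1 <= t <= n]
    if bad:
        raise ParameterError(f"core_frames {bad} outside 1..{n}")

    channel_bases = []
    models = []
    for mode in range(3):
        stack = build_temporal_stack(factors, mode)
        model = fit_temporal_pca(stack, center=center)
        channel_bases.append(project_channel_basis(stack, model, channel))
        models.append(model)
    core_avg = np.mean([factors[t - 1].core for t in core_frames], axis=0)
    gamma = core_avg
    for mode in range(3):
        gamma = mode_multiply(gamma, channel_bases[mode], mode)
    if orient_to is not None and float(np.vdot(gamma, orient_to)) < 0:
        gamma = -gamma
        channel_bases[0] = -channel_bases[0]
    return ChannelReconstruction(
        channel=channel,
        channel_bases=tuple(channel_bases),
        averaged_core=core_avg,
        volume=gamma,
        models=tuple(models),
    )


def hybrid_segment(
    recon_volume: np.ndarray,
    roi_mask: BinaryMask | np.ndarray,
    fcm_params: FCMParams | None = None,
    k_top: int = 1,
) -> BinaryMask:
    """FCM classification of the reconstruction inside the ROI.

    Gamma values restricted to the ROI are clustered; the tumour mask is
    the set of voxels hard-assigned to the ``k_top`` highest-center
    clusters.  No connected-component pruning is applied — disconnected
    voxels are measured by the noise metrics, not silently removed.
    """
    roi = roi_mask.values if isinstance(roi_mask, BinaryMask) else np.asarray(roi_mask, bool)
    vol = np.asarray(recon_volume, dtype=float)
    if vol.shape != roi.shape:
        raise DimensionError(f"reconstruction shape {vol.shape} != ROI shape {roi.shape}")
    vals = vol[roi]
    if vals.size == 0 or np.ptp(vals) == 0:
        raise DegenerateInputError("reconstruction is constant within the ROI")
    params = fcm_params or FCMParams()
    result = fcm_cluster(vals, params)
    top = assign_tumour_cluster(result, k_top=k_top)
    seg = np.zeros(roi.shape, dtype=bool)
    seg[roi] = np.isin(result.labels, list(top))
    if isinstance(roi_mask, BinaryMask):
        return BinaryMask(seg, spacing=roi_mask.spacing, affine=roi_mask.affine)
    return BinaryMask(seg)
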