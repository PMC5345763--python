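"""Data model for dynamic contrast-enhanced (DCE) MRI studies.

A dynamic study is one pre-contrast (baseline) 3D volume followed by an
ordered series of post-contrast volumes acquired on the same voxel grid,
typically at 60-second intervals.  The enhancement series (ES) is the
voxelwise difference between each post-contrast frame and the baseline;
it is the quantity every downstream stage (masking, tensor reconstruction,
segmentation) operates on.

Conventions
-----------
* Arrays are indexed ``(x, y, z)``, 0-based, matching the stored NIfTI
  array; the affine is carried through for display and round-tripping.
* Negative enhancement (post < pre) is retained, never clipped: clipping
  would bias the temporal covariance used by the channel reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DimensionError, ParameterError

__all__ = [
    "VolumeImage",
    "DynamicStudy",
    "EnhancementSeries",
    "BinaryMask",
    "compute_enhancement_series",
]


def _check_finite(values: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(values)):
        raise ParameterError(f"{what} contains non-finite values")


@dataclass
class VolumeImage:
    """A single 3D intensity volume on a Cartesian voxel grid.

    Parameters
    ----------
    values : ndarray, shape (I1, I2, I3)
        Voxel intensities (arbitrary units).
    spacing : tuple of float
        Voxel size along each axis, in mm.
    frame_time : float, optional
        Acquisition time offset in seconds (0 for the baseline).
    affine : ndarray (4, 4), optional
        Voxel-to-world transform; defaults to a diagonal built from
        ``spacing``.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    frame_time: float | None = None
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise DimensionError(
                f"volume must be 3D, got shape {self.values.shape}"
            )
        if min(self.values.shape) < 1:
            raise DimensionError("all dimensions must be >= 1")
        _check_finite(self.values, "volume")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ParameterError(f"spacing must be 3 positive floats, got {self.spacing}")
        if self.affine is None:
            self.affine = np.diag([*self.spacing, 1.0])
        else:
            self.affine = np.asarray(self.affine, dtype=float)
            if self.affine.shape != (4, 4):
                raise DimensionError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class DynamicStudy:
    """One baseline volume plus ordered post-contrast volumes (the dynamic
    tensor X_tau, tau = 0..n)."""

    baseline: VolumeImage
    post_frames: list[VolumeImage]
    frame_interval: float = 60.0  # seconds between successive frames

    def __post_init__(self) -> None:
        if len(self.post_frames) < 1:
            raise ParameterError("a dynamic study needs at least one post-contrast frame")
        shape, spacing = self.baseline.shape, self.baseline.spacing
        for k, frame in enumerate(self.post_frames):
            if frame.shape != shape:
                raise DimensionError(
                    f"post frame {k + 1} has shape {frame.shape}, baseline {shape}"
                )
            if frame.spacing != spacing:
                raise DimensionError(
                    f"post frame {k + 1} spacing {frame.spacing} != baseline {spacing}"
                )

    @property
    def n_post(self) -> int:
        return len(self.post_frames)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.baseline.shape


@dataclass
class EnhancementSeries:
    """Ordered enhancement (post minus baseline) volumes, tau = 1..n."""

    frames: list[VolumeImage]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.frames:
            raise ParameterError("enhancement series must contain at least one frame")
        shape = self.frames[0].shape
        for k, frame in enumerate(self.frames):
            if frame.shape != shape:
                raise DimensionError(f"ES frame {k + 1} shape {frame.shape} != {shape}")

    @property
    def n(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames[0].shape

    def as_array(self) -> np.ndarray:
        """Stack frames into an (n, I1, I2, I3) array."""
        return np.stack([f.values for f in self.frames])


@dataclass
class BinaryMask:
    """A 3D {0, 1} mask sharing the geometry of its parent volume."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 3:
            raise DimensionError(f"mask must be 3D, got shape {arr.shape}")
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ParameterError("mask values must be in {0, 1}")
            arr = arr.astype(bool)
        self.values = arr
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.affine is None:
            self.affine = np.diag([*self.spacing, 1.0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def count(self) -> int:
        return int(self.values.sum())


def compute_enhancement_series(study: DynamicStudy) -> EnhancementSeries:
    """Voxelwise post-minus-baseline difference for every post-contrast frame.

    Negative values are retained (see module docstring).  The result has
    exactly ``study.n_post`` frames in acquisition order.
    """
    frames = [
        VolumeImage(
            post.values - study.baseline.values,
            spacing=study.baseline.spacing,
            frame_time=post.frame_time,
            affine=study.baseline.affine,
        )
        for post in study.post_frames
    ]
    return EnhancementSeries(frames, source="post - baseline difference")


def frames_from_array(
    data: np.ndarray,
    spacing: Sequence[float] = (1.0, 1.0, 1.0),
    frame_interval: float = 60.0,
    affine: np.ndarray | None = None,
) -> DynamicStudy:
    """Build a :class:`DynamicStudy` from a 4D array whose first axis is time
    (frame 0 is the baseline)."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 4:
        raise DimensionError(f"expected a 4D (t, x, y, z) array, got shape {data.shape}")
    if data.shape[0] < 2:
        raise ParameterError("need a baseline plus at least one post-contrast frame")
    vols = [
        VolumeImage(data[t], spacing=tuple(spacing), frame_time=t * frame_interval, affine=affine)
        for t in range(data.shape[0])
    ]
    return DynamicStudy(vols[0], vols[1:], frame_interval=frame_interval)
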