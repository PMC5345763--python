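"""Synthetic DCE-MRI phantoms with known ground truth.

The generator emulates the structure of a breast DCE-MRI study: a "body"
ellipsoid of constant soft-tissue intensity surrounded by air, a thin
enhancing skin shell at the body surface, one or more tumour ellipsoids
following clinically motivated enhancement kinetics (wash-in/wash-out,
plateau, or persistent rise), moderately enhancing fatty-tissue
confounders, a smooth multiplicative intensity-inhomogeneity (bias) field
on the baseline tissue, and i.i.d. Gaussian noise per voxel and frame.

Kinetic curves are piecewise linear between frames — the simplest family
that exhibits the three clinical patterns; no pharmacokinetic (Tofts-type)
model is implied.  Enhancement is added on top of the biased baseline, so
at zero noise the enhancement series is exactly piecewise constant per
region and zero elsewhere, which makes every downstream stage testable
against closed-form expectations.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage
from skimage.morphology import ball

from .core import BinaryMask, DynamicStudy, VolumeImage
from .errors import ParameterError

__all__ = [
    "KineticProfile",
    "Ellipsoid",
    "PhantomSpec",
    "PhantomTruth",
    "kinetic_curve",
    "ellipsoid_mask",
    "generate_phantom",
]

Kind = Literal["washout", "plateau", "persistent"]


@dataclass(frozen=True)
class KineticProfile:
    """Tissue enhancement-versus-time curve family.

    ``washout`` rises linearly to ``peak_amplitude`` at ``peak_frame`` and
    then declines linearly, losing ``washout_fraction`` of the peak by the
    last frame (the malignant-pattern curve).  ``plateau`` rises to the
    peak and stays constant.  ``persistent`` rises monotonically through
    the last frame (benign pattern); its ``washout_fraction`` must be 0.
    The pre-injection value (tau = 0) is 0 by definition.
    """

    kind: Kind = "washout"
    peak_frame: int = 4
    peak_amplitude: float = 100.0
    washout_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("washout", "plateau", "persistent"):
            raise ParameterError(f"unknown kinetic kind {self.kind!r}")
        if self.peak_amplitude < 0:
            raise ParameterError("peak_amplitude must be >= 0")
        if not 0 <= self.washout_fraction <= 1:
            raise ParameterError("washout_fraction must lie in [0, 1]")
        if self.kind == "persistent" and self.washout_fraction != 0:
            raise ParameterError("persistent profiles must have washout_fraction = 0")
        if self.peak_frame < 1:
            raise ParameterError("peak_frame must be >= 1")


def kinetic_curve(profile: KineticProfile, n: int) -> np.ndarray:
    """Enhancement values at frames tau = 1..n for a kinetic profile."""
    if n < 1:
        raise ParameterError("need at least one frame")
    if profile.kind != "persistent" and profile.peak_frame > n:
        raise ParameterError(f"peak_frame {profile.peak_frame} exceeds frame count {n}")
    amp, peak = profile.peak_amplitude, profile.peak_frame
    out = np.empty(n, dtype=float)
    for tau in range(1, n + 1):
        if profile.kind == "persistent":
            out[tau - 1] = amp * tau / n
        elif profile.kind == "plateau":
            out[tau - 1] = amp * min(tau / peak, 1.0)
        else:  # washout
            if tau <= peak:
                out[tau - 1] = amp * tau / peak
            elif n == peak:  # peak at the last frame: nothing to wash out
                out[tau - 1] = amp
            else:
                out[tau - 1] = amp * (1.0 - profile.washout_fraction * (tau - peak) / (n - peak))
    return out


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid in voxel coordinates: center, semi-axes, profile."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    profile: KineticProfile

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes):
            raise ParameterError("semi-axes must be positive")


def ellipsoid_mask(shape: Sequence[int], center: Sequence[float], semi_axes: Sequence[float]) -> np.ndarray:
    """Boolean mask of grid points with sum_i ((x_i - c_i)/a_i)^2 <= 1."""
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return r2 <= 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic dynamic study.

    Defaults describe the canonical desk-scale phantom: a 64x64x32 grid,
    n = 6 post-contrast frames at 60 s spacing, one washout tumour peaking
    at frame 4 (peak enhancement 100), one plateau fatty confounder at a
    quarter of the tumour amplitude, a 2-voxel persistent-enhancing skin
    shell, noise sigma = 5 (5% of tumour peak) and a 10% bias field.
    """

    shape: tuple[int, int, int] = (64, 64, 32)
    n_frames: int = 6
    frame_interval: float = 60.0
    tumour_ellipsoids: tuple[Ellipsoid, ...] = (
        Ellipsoid((26, 30, 16), (8, 8, 5), KineticProfile("washout", 4, 100.0, 0.3)),
    )
    fat_regions: tuple[Ellipsoid, ...] = (
        Ellipsoid((44, 26, 14), (5, 5, 3), KineticProfile("plateau", 4, 25.0, 0.0)),
    )
    body_center: tuple[float, float, float] | None = None  # grid centre if None
    body_semi_axes: tuple[float, float, float] | None = None
    background_intensity: float = 100.0
    skin_thickness: int = 2
    skin_profile: KineticProfile = KineticProfile("persistent", 4, 30.0, 0.0)
    noise_sigma: float = 5.0
    bias_field_amplitude: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")
        if self.skin_thickness < 0:
            raise ParameterError("skin_thickness must be >= 0")
        if self.n_frames < 1:
            raise ParameterError("n_frames must be >= 1")
        for ell in (*self.tumour_ellipsoids, *self.fat_regions):
            for c, a, s in zip(ell.center, ell.semi_axes, self.shape):
                if c - a < 0 or c + a > s - 1:
                    raise ParameterError(
                        f"ellipsoid at {ell.center} with semi-axes {ell.semi_axes} "
                        f"extends outside the {self.shape} grid"
                    )


@dataclass
class PhantomTruth:
    """Ground-truth masks; pairwise disjoint by construction."""

    tumour_mask: BinaryMask
    fat_mask: BinaryMask
    skin_mask: BinaryMask
    body_mask: BinaryMask


def _bias_field(shape: Sequence[int], amplitude: float) -> np.ndarray:
    """Smooth multiplicative field: 1 + amplitude * low-order polynomial."""
    gx, gy, gz = np.meshgrid(*[np.linspace(-1, 1, s) for s in shape], indexing="ij")
    poly = 0.5 * gx + 0.3 * gy * gz - 0.4 * gx * gz
    return 1.0 + amplitude * poly


def generate_phantom(spec: PhantomSpec) -> tuple[DynamicStudy, PhantomTruth]:
    """Render a :class:`PhantomSpec` into a dynamic study plus ground truth.

    The baseline is ``background_intensity`` inside the body ellipsoid
    (air = 0 outside), multiplied by the bias field.  Post-contrast frame
    tau adds, inside each region, its kinetic-curve value at tau.
    Gaussian noise of ``noise_sigma`` is then added independently per voxel
    to every post-contrast frame.  Identical specs (same seed) produce
    bit-identical studies.
    """
    shape = tuple(spec.shape)
    rng = np.random.default_rng(spec.seed)
    centre = spec.body_center or tuple((s - 1) / 2.0 for s in shape)
    semi = spec.body_semi_axes or tuple(s / 2.0 - 4.0 for s in shape)
    body = ellipsoid_mask(shape, centre, semi)
    if spec.skin_thickness > 0:
        interior = ndimage.binary_erosion(body, ball(spec.skin_thickness))
    else:
        interior = body
    skin = body & ~interior

    tumour = np.zeros(shape, dtype=bool)
    tumour_curves: list[tuple[np.ndarray, np.ndarray]] = []
    for ell in spec.tumour_ellipsoids:
        m = ellipsoid_mask(shape, ell.center, ell.semi_axes)
        tumour |= m
        tumour_curves.append((m, kinetic_curve(ell.profile, spec.n_frames)))
    fat = np.zeros(shape, dtype=bool)
    fat_curves: list[tuple[np.ndarray, np.ndarray]] = []
    for ell in spec.fat_regions:
        m = ellipsoid_mask(shape, ell.center, ell.semi_axes)
        fat |= m
        fat_curves.append((m, kinetic_curve(ell.profile, spec.n_frames)))
    if np.any(tumour & fat):
        raise ParameterError("tumour and fat ellipsoids overlap")
    # keep enhancing parenchymal regions off the skin shell so truth masks
    # stay pairwise disjoint
    tumour &= interior
    fat &= interior

    skin_curve = kinetic_curve(spec.skin_profile, spec.n_frames)
    baseline = np.where(body, spec.background_intensity, 0.0)
    baseline *= _bias_field(shape, spec.bias_field_amplitude)

    # noise perturbs the post-contrast frames; the baseline is the clean
    # reference, so the enhancement-series noise level equals noise_sigma
    vols = [VolumeImage(baseline, frame_time=0.0)]
    for tau in range(1, spec.n_frames + 1):
        frame = baseline.copy()
        for m, curve in tumour_curves:
            frame[m & interior] += curve[tau - 1]
        for m, curve in fat_curves:
            frame[m & interior] += curve[tau - 1]
        frame[skin] += skin_curve[tau - 1]
        if spec.noise_sigma > 0:
            frame = frame + rng.normal(0.0, spec.noise_sigma, shape)
        vols.append(VolumeImage(frame, frame_time=tau * spec.frame_interval))

    study = DynamicStudy(vols[0], vols[1:], frame_interval=spec.frame_interval)
    truth = PhantomTruth(
        tumour_mask=BinaryMask(tumour),
        fat_mask=BinaryMask(fat),
        skin_mask=BinaryMask(skin),
        body_mask=BinaryMask(body),
    )
    return study, truth


def spec_to_dict(spec: PhantomSpec) -> dict:
    """JSON-serializable echo of a phantom spec (for provenance sidecars)."""
    return asdict(spec)
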