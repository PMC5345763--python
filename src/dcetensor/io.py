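"""NIfTI I/O for dynamic studies, volumes and masks.

Accepts either one NIfTI file per time frame (first file = baseline) or a
single 4D NIfTI whose last axis is time (frame 0 = baseline).  Masks are
written as uint8, volumes as float32; the source affine is preserved and a
JSON sidecar records provenance (stage name, parameters, seed).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Iterable, Mapping

import nibabel as nib
import numpy as np

from .core import BinaryMask, DynamicStudy, EnhancementSeries, VolumeImage
from .errors import DimensionError, ParameterError

__all__ = ["load_dynamic_study", "load_volume", "load_mask", "write_outputs"]


def _zooms(img: nib.Nifti1Image) -> tuple[float, float, float]:
    z = img.header.get_zooms()[:3]
    return tuple(float(v) for v in z)


def load_volume(path: str | Path) -> VolumeImage:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise DimensionError(f"{path}: expected a 3D volume, got shape {data.shape}")
    return VolumeImage(data, spacing=_zooms(img), affine=np.asarray(img.affine))


def load_mask(path: str | Path) -> BinaryMask:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    return BinaryMask(data > 0, spacing=_zooms(img), affine=np.asarray(img.affine))


def load_dynamic_study(
    paths: str | Path | Iterable[str | Path],
    frame_interval: float = 60.0,
) -> DynamicStudy:
    """Load a dynamic study from NIfTI.

    Parameters
    ----------
    paths : path or list of paths
        Either a single 4D file (last axis = time) or >= 2 per-frame 3D
        files ordered baseline first.
    frame_interval : float
        Seconds between successive frames (60 s canonical).
    """
    if isinstance(paths, (str, Path)):
        img = nib.load(str(paths))
        data = np.asanyarray(img.dataobj, dtype=float)
        if data.ndim != 4:
            raise DimensionError(
                f"{paths}: a single input file must be 4D, got shape {data.shape}"
            )
        if data.shape[-1] < 2:
            raise ParameterError("4D study must hold a baseline plus >= 1 post frame")
        spacing, affine = _zooms(img), np.asarray(img.affine)
        vols = [
            VolumeImage(data[..., t], spacing=spacing, frame_time=t * frame_interval, affine=affine)
            for t in range(data.shape[-1])
        ]
    else:
        path_list = [Path(p) for p in paths]
        if len(path_list) < 2:
            raise ParameterError(
                f"need a baseline plus >= 1 post-contrast file, got {len(path_list)}"
            )
        vols = []
        for t, p in enumerate(path_list):
            vol = load_volume(p)
            vol.frame_time = t * frame_interval
            vols.append(vol)
        shape = vols[0].shape
        for t, vol in enumerate(vols):
            if vol.shape != shape:
                raise DimensionError(
                    f"{path_list[t]} has shape {vol.shape}, expected {shape}"
                )
    return DynamicStudy(vols[0], vols[1:], frame_interval=frame_interval)


def _save(item: Any, path: Path) -> None:
    if isinstance(item, BinaryMask):
        img = nib.Nifti1Image(item.values.astype(np.uint8), item.affine)
    elif isinstance(item, VolumeImage):
        img = nib.Nifti1Image(item.values.astype(np.float32), item.affine)
    elif isinstance(item, EnhancementSeries):
        data = np.stack([f.values for f in item.frames], axis=-1).astype(np.float32)
        img = nib.Nifti1Image(data, item.frames[0].affine)
    elif isinstance(item, DynamicStudy):
        data = np.stack(
            [item.baseline.values] + [f.values for f in item.post_frames], axis=-1
        ).astype(np.float32)
        img = nib.Nifti1Image(data, item.baseline.affine)
    else:
        raise ParameterError(f"cannot serialize object of type {type(item).__name__}")
    nib.save(img, str(path))


def write_outputs(
    items: Mapping[str, Any],
    destination: str | Path,
    provenance: Mapping[str, Any] | None = None,
) -> dict[str, Path]:
    """Write named volumes/masks/series to ``destination`` as NIfTI.

    A ``provenance.json`` sidecar records the stage, its parameters and the
    seed of any stochastic stage.  Returns the mapping name -> written path.
    """
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, item in items.items():
        path = dest / f"{name}.nii.gz"
        _save(item, path)
        written[name] = path
    if provenance is not None:
        sidecar = dest / "provenance.json"
        sidecar.write_text(json.dumps(dict(provenance), indent=2, default=str))
        written["provenance"] = sidecar
    return written
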