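"""Self-referencing reconstruction-quality metrics.

Without a ground truth for patient data, reconstruction quality is
assessed by comparing the hybrid tumour mask against the per-frame FCM
segmentation of the enhancement series, using a three-label overlay:

    label 1 — voxels only in the FCM enhancement-series (ES) mask,
    label 2 — voxels only in the hybrid (reconstruction) mask,
    label 3 — voxels in both.

Counts: NCD = TuRI = |label 1| (non-covered), TuOI = |label 2|,
OVL = |label 3| (overlap), REC = |2| + |3| (hybrid tumour voxels),
ESI = |1| + |3| (ES tumour voxels), DIF = TuRI + TuOI.

The five ratios, reported in percent:

    NcReR = NCD / REC,  OvReR = OVL / REC,  DiReR = DIF / REC,
    NoReR = NOI / REC,  NoEsR = NOI / ESI,

where NOI counts mask voxels not connected to the largest (main) mask
component — disconnected voxels are treated as noise.  NoEsR is infinite
when the ES mask is empty.  Noise ratios may exceed 100% because NOI is
normalized by the other method's voxel count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import BinaryMask
from .errors import DimensionError, ParameterError, PipelineError

__all__ = [
    "OverlapLabeling",
    "MetricsReport",
    "label_overlap",
    "noise_voxels",
    "compute_ratios",
    "evaluate_masks",
    "dice",
]

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def _as_bool(mask: BinaryMask | np.ndarray) -> np.ndarray:
    if isinstance(mask, BinaryMask):
        return mask.values
    return np.asarray(mask, dtype=bool)


@dataclass
class OverlapLabeling:
    """Three-label overlay of an ES mask against a hybrid mask, with counts."""

    label_volume: np.ndarray  # {0, 1, 2, 3}
    ncd: int  # |label 1|: ES-only (non-covered by the reconstruction)
    tuoi: int  # |label 2|: hybrid-only
    ovl: int  # |label 3|: overlap

    @property
    def turi(self) -> int:
        return self.ncd

    @property
    def rec(self) -> int:
        return self.tuoi + self.ovl

    @property
    def esi(self) -> int:
        return self.ncd + self.ovl

    @property
    def dif(self) -> int:
        return self.turi + self.tuoi


def label_overlap(
    es_mask: BinaryMask | np.ndarray, hybrid_mask: BinaryMask | np.ndarray
) -> OverlapLabeling:
    """Label each voxel 1 (ES only), 2 (hybrid only) or 3 (both)."""
    es = _as_bool(es_mask)
    hyb = _as_bool(hybrid_mask)
    if es.shape != hyb.shape:
        raise DimensionError(f"mask shapes differ: {es.shape} vs {hyb.shape}")
    labels = np.zeros(es.shape, dtype=np.uint8)
    labels[es & ~hyb] = 1
    labels[~es & hyb] = 2
    labels[es & hyb] = 3
    return OverlapLabeling(
        label_volume=labels,
        ncd=int(np.count_nonzero(labels == 1)),
        tuoi=int(np.count_nonzero(labels == 2)),
        ovl=int(np.count_nonzero(labels == 3)),
    )


def noise_voxels(
    mask: BinaryMask | np.ndarray, connectivity: int = 26
) -> tuple[np.ndarray, int]:
    """Split a mask into its main connected component and noise voxels.

    The main component is the largest one under the given connectivity
    (6, 18 or 26); among equally large components the one containing the
    lexicographically smallest voxel wins.  NOI is the count of mask
    voxels outside the main component.
    """
    if connectivity not in _STRUCTURES:
        raise ParameterError("connectivity must be one of 6, 18, 26")
    m = _as_bool(mask)
    if not m.any():
        warnings.warn("empty mask passed to noise_voxels")
        return np.zeros_like(m), 0
    labeled, n_comp = ndimage.label(m, structure=_STRUCTURES[connectivity])
    sizes = np.bincount(labeled.ravel())[1:]  # component sizes, 1..n_comp
    best = sizes.max()
    candidates = np.flatnonzero(sizes == best) + 1
    if candidates.size == 1:
        main_label = int(candidates[0])
    else:  # tie: component containing the lexicographically smallest voxel
        flat = labeled.ravel()
        first_idx = {int(lab): int(np.flatnonzero(flat == lab)[0]) for lab in candidates}
        main_label = min(first_idx, key=first_idx.get)
    main = labeled == main_label
    return main, int(m.sum() - main.sum())


@dataclass
class MetricsReport:
    """Per-frame overlap ratios plus the two noise ratios, in percent."""

    ncrer: list[float] = field(default_factory=list)
    ovrer: list[float] = field(default_factory=list)
    direr: list[float] = field(default_factory=list)
    noesr: list[float] = field(default_factory=list)  # per ES frame
    norer: float = 0.0  # hybrid mask, single value
    noi_es: list[int] = field(default_factory=list)
    noi_hybrid: int = 0
    connectivity: int = 26

    def to_dict(self) -> dict:
        return {
            "per_frame": [
                {
                    "frame": t + 1,
                    "NcReR": self.ncrer[t],
                    "OvReR": self.ovrer[t],
                    "DiReR": self.direr[t],
                    "NoEsR": self.noesr[t],
                    "NOI_es": self.noi_es[t],
                }
                for t in range(len(self.ncrer))
            ],
            "hybrid": {"NoReR": self.norer, "NOI": self.noi_hybrid},
            "connectivity": self.connectivity,
        }

    def to_dataframe(self):
        """Table mirroring the per-frame report layout (one row per frame,
        a final row for the hybrid mask)."""
        import pandas as pd

        rows = [
            {
                "image": f"{t + 1}th enhanced" if t >= 3 else ["1st", "2nd", "3rd"][t] + " enhanced",
                "NcReR": self.ncrer[t],
                "OvReR": self.ovrer[t],
                "DiReR": self.direr[t],
                "NoEsR_or_NoReR": self.noesr[t],
            }
            for t in range(len(self.ncrer))
        ]
        rows.append(
            {
                "image": "hybrid classification",
                "NcReR": np.nan,
                "OvReR": np.nan,
                "DiReR": np.nan,
                "NoEsR_or_NoReR": self.norer,
            }
        )
        return pd.DataFrame(rows)


def compute_ratios(
    labelings: list[OverlapLabeling],
    noi_es: list[int],
    noi_hybrid: int,
    rec_total: int | None = None,
    esi_totals: list[int] | None = None,
    connectivity: int = 26,
) -> MetricsReport:
    """Assemble the five ratios (percent) from per-frame labelings.

    The noise ratios are normalized by the raw mask sizes: ``rec_total``
    (hybrid voxel count, default REC of the first labeling) and
    ``esi_totals`` (per-frame ES voxel counts, default the labelings'
    ESI).  The distinction matters when the labelings were computed on
    main components only.  Raises :class:`PipelineError` when a labeling
    has REC = 0.
    """
    if len(labelings) != len(noi_es):
        raise ParameterError("need one ES noise count per labeling")
    if esi_totals is not None and len(esi_totals) != len(labelings):
        raise ParameterError("need one ESI total per labeling")
    report = MetricsReport(connectivity=connectivity, noi_hybrid=noi_hybrid)
    for t, (lab, noi) in enumerate(zip(labelings, noi_es)):
        if lab.rec == 0:
            raise PipelineError("labeling has REC = 0: empty hybrid mask")
        esi = esi_totals[t] if esi_totals is not None else lab.esi
        report.ncrer.append(100.0 * lab.ncd / lab.rec)
        report.ovrer.append(100.0 * lab.ovl / lab.rec)
        report.direr.append(100.0 * lab.dif / lab.rec)
        report.noesr.append(100.0 * noi / esi if esi > 0 else np.inf)
        report.noi_es.append(noi)
    rec = rec_total if rec_total is not None else labelings[0].rec
    if rec == 0:
        raise PipelineError("hybrid mask empty: REC = 0")
    report.norer = 100.0 * noi_hybrid / rec
    return report


def evaluate_masks(
    es_masks: list[BinaryMask | np.ndarray],
    hybrid_mask: BinaryMask | np.ndarray,
    connectivity: int = 26,
    main_components_only: bool = True,
) -> MetricsReport:
    """Full metric evaluation of per-frame ES masks against a hybrid mask.

    Noise (NOI) counts always come from the raw masks.  For the overlap
    ratios, the default drops disconnected voxels and compares main
    components only; ``main_components_only=False`` compares raw masks.
    """
    hyb = _as_bool(hybrid_mask)
    hyb_main, noi_hyb = noise_voxels(hyb, connectivity)
    hyb_cmp = hyb_main if main_components_only else hyb
    labelings, noi_list, esi_totals = [], [], []
    for es in es_masks:
        es_arr = _as_bool(es)
        es_main, noi = noise_voxels(es_arr, connectivity)
        labelings.append(label_overlap(es_main if main_components_only else es_arr, hyb_cmp))
        noi_list.append(noi)
        esi_totals.append(int(es_arr.sum()))
    return compute_ratios(
        labelings,
        noi_list,
        noi_hyb,
        rec_total=int(hyb.sum()),
        esi_totals=esi_totals,
        connectivity=connectivity,
    )


def dice(a: BinaryMask | np.ndarray, b: BinaryMask | np.ndarray) -> float:
    """Dice overlap coefficient of two masks (1 = identical)."""
    x, y = _as_bool(a), _as_bool(b)
    if x.shape != y.shape:
        raise DimensionError(f"mask shapes differ: {x.shape} vs {y.shape}")
    denom = x.sum() + y.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.count_nonzero(x & y) / float(denom)
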