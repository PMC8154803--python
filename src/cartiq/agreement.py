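"""3D segmentation-agreement metrics: DSC, VOE, HD and ASSD per plate.

Metric dialect: voxel sets are compared on identical grids; surface voxels
are set members with at least one 6-connected neighbour outside the set
(including the grid border); distances are Euclidean between surface voxel
*centers* in physical mm with anisotropic spacing honoured — no sub-voxel
surface interpolation. Empty-set conventions: DSC(∅,∅)=1 and VOE(∅,∅)=0;
distances between an empty and a non-empty set are undefined and raise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .volume import NAME_TO_LABEL, LabelVolume

_CROSS3 = ndimage.generate_binary_structure(3, 1)


def _check_grids(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")


def dsc(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|); DSC(∅,∅) = 1."""
    _check_grids(a, b)
    a, b = a.astype(bool), b.astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.count_nonzero(a & b) / denom)


def voe(a: np.ndarray, b: np.ndarray) -> float:
    """Volume overlap error 100 x (1 − |A∩B|/|A∪B|) in %; VOE(∅,∅) = 0."""
    _check_grids(a, b)
    a, b = a.astype(bool), b.astype(bool)
    union = np.count_nonzero(a | b)
    if union == 0:
        return 0.0
    return float(100.0 * (1.0 - np.count_nonzero(a & b) / union))


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """(N, 3) indices of set members with a 6-neighbour outside the set."""
    mask = mask.astype(bool)
    interior = ndimage.binary_erosion(mask, _CROSS3, border_value=0)
    return np.argwhere(mask & ~interior)


def _surface_points_mm(mask: np.ndarray, spacing) -> np.ndarray:
    return surface_voxels(mask) * np.asarray(spacing, dtype=float)


def hausdorff(a: np.ndarray, b: np.ndarray, spacing) -> float:
    """3D Hausdorff distance between surface point sets, mm (symmetric max)."""
    _check_grids(a, b)
    if not a.any() or not b.any():
        raise ValueError("Hausdorff distance is undefined for an empty set")
    pa, pb = _surface_points_mm(a, spacing), _surface_points_mm(b, spacing)
    dab, _ = cKDTree(pb).query(pa)
    dba, _ = cKDTree(pa).query(pb)
    return float(max(dab.max(), dba.max()))


def assd(a: np.ndarray, b: np.ndarray, spacing) -> float:
    """Average symmetric surface distance in mm.

    (Σ d(p, S(B)) + Σ d(q, S(A))) / (|S(A)| + |S(B)|) over surface voxel
    centers, same surface definition as the Hausdorff distance.
    """
    _check_grids(a, b)
    if not a.any() or not b.any():
        raise ValueError("ASSD is undefined for an empty set")
    pa, pb = _surface_points_mm(a, spacing), _surface_points_mm(b, spacing)
    dab, _ = cKDTree(pb).query(pa)
    dba, _ = cKDTree(pa).query(pb)
    return float((dab.sum() + dba.sum()) / (len(pa) + len(pb)))


@dataclass
class AgreementResult:
    """Per-plate agreement between two segmentations of one knee."""

    knee_id: str
    values: dict[str, dict[str, float]] = field(default_factory=dict)

    report_kind = "agreement"

    def to_frame(self) -> pd.DataFrame:
        rows = [{"knee_id": self.knee_id, "region": region, **vals}
                for region, vals in self.values.items()]
        return pd.DataFrame(rows)


def compute_agreement(a: LabelVolume, b: LabelVolume,
                      plates: tuple[str, ...] = ("MT", "cMF", "LT", "cLF"),
                      knee_id: str = "knee") -> AgreementResult:
    """DSC/VOE/HD/ASSD for each requested plate between two label volumes.

    Plates empty in both volumes report the empty-set conventions with
    distances as NaN; distances are likewise NaN (rather than an error) when
    exactly one side is empty, so cohort summaries remain computable.
    """
    _check_grids(a.voxels, b.voxels)
    res = AgreementResult(knee_id=knee_id)
    for name in plates:
        plate = NAME_TO_LABEL[name]
        ma, mb = a.voxels == plate, b.voxels == plate
        vals = {"DSC": dsc(ma, mb), "VOE_pct": voe(ma, mb)}
        if ma.any() and mb.any():
            vals["HD_mm"] = hausdorff(ma, mb, a.spacing)
            vals["ASSD_mm"] = assd(ma, mb, a.spacing)
        else:
            vals["HD_mm"] = float("nan")
            vals["ASSD_mm"] = float("nan")
        res.values[name] = vals
    return res
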