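"""Quantitative cartilage morphometry: thickness, volume, bone-interface area.

Measures are computed per cartilage plate (MT, cMF, LT, cLF) from a cleaned
label volume and its tAB/AC/IC surface partition, and aggregated to the
medial and lateral femorotibial compartments (MFTC = MT + cMF,
LFTC = LT + cLF) as plate sums — including thickness, which is therefore a
compartment *sum*, not a mean.

Measurement conventions:

* cartilage volume = voxel count x voxel volume (exact);
* tAB area = per-slice polyline length of the bone-interface chain x slice
  spacing, summed over slices and reported in cm^2. Chains are lightly
  smoothed (moving average) and extended by half a segment at both ends
  before measuring, which removes the staircase overestimate of rasterised
  curves while keeping axis-aligned planar interfaces exact. Through-plane
  tilt is not captured (known underestimate, documented);
* mean thickness = average over tAB surface points of the minimal 3D
  Euclidean distance to the AC surface point set, in mm. Surface points sit
  on voxel faces (half-voxel offsets toward background), so a flat slab of
  n voxel layers measures n x spacing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .postproc import SurfacePartition
from .volume import COMPARTMENTS, NAME_TO_LABEL, PLATE_NAMES, LabelVolume

logger = logging.getLogger("cartiq")

MEASURES = ("thickness_mm", "volume_mm3", "tab_area_cm2")


def cartilage_volume(volume: LabelVolume, plate: int) -> float:
    """Cartilage volume of a plate in mm^3 (0 for an absent plate)."""
    return float(np.count_nonzero(volume.voxels == plate)
                 * np.prod(volume.spacing))


def _smooth_chain(pts: np.ndarray, window: int) -> np.ndarray:
    """Endpoint-preserving moving average (window shrinks near the ends)."""
    n = len(pts)
    half = window // 2
    out = np.empty_like(pts)
    for i in range(n):
        h = min(i, n - 1 - i, half)
        out[i] = pts[i - h:i + h + 1].mean(axis=0)
    return out


def chain_length_mm(chain: list[tuple[int, int]],
                    spacing_rc: tuple[float, float],
                    smooth_window: int = 5, subsample: int = 2) -> float:
    """Physical polyline length (mm) of an ordered boundary chain.

    Raw rasterised chains overestimate curved interfaces (staircase bias),
    so coordinates are smoothed with a short moving average and the polyline
    is measured over every ``subsample``-th point (chord approximation).
    Half of the first/last raw segment is appended at each end so that an
    axis-aligned chain of n pixels measures exactly n x spacing (the pixels'
    outer faces bound the interface). A single-pixel chain measures one
    pixel footprint.
    """
    if not chain:
        return 0.0
    pts = np.asarray(chain, dtype=float) * np.asarray(spacing_rc)
    if len(pts) == 1:
        return float(max(spacing_rc))
    ext = 0.5 * (np.linalg.norm(pts[1] - pts[0])
                 + np.linalg.norm(pts[-1] - pts[-2]))
    pts = _smooth_chain(pts, smooth_window)
    if subsample > 1 and len(pts) > 2 * subsample:
        idx = list(range(0, len(pts) - 1, subsample)) + [len(pts) - 1]
        pts = pts[idx]
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return float(seg.sum() + ext)


def bone_interface_area(partition: SurfacePartition, plate: int,
                        smooth_window: int = 5) -> float:
    """Total subchondral bone (tAB) area of a plate in cm^2.

    Per slice, the in-plane length of the tAB chain (anisotropy honoured)
    is multiplied by the slice spacing; slice contributions are summed.
    Absent plate -> 0.
    """
    sr, sc, ss = partition.spacing
    total = 0.0
    for _, sp in sorted(partition.slices(plate).items()):
        for part in (sp, *sp.extra):
            total += chain_length_mm(part.tab_meas, (sr, sc), smooth_window) * ss
    return total / 100.0


def mean_thickness(partition: SurfacePartition, volume: LabelVolume,
                   plate: int) -> float | None:
    """Mean cartilage thickness of a plate in mm.

    For every tAB surface point (3D, across slices) the minimal Euclidean
    distance to the AC surface point set is taken; the mean over tAB points
    is returned. Returns None (missing, not 0) when either surface is empty.
    """
    tab = partition.tab_points_mm(plate)
    ac = partition.ac_points_mm(plate)
    if len(tab) == 0 or len(ac) == 0:
        logger.warning("mean_thickness: plate %s has an empty surface",
                       PLATE_NAMES.get(plate, plate))
        return None
    d, _ = cKDTree(ac).query(tab)
    return float(np.mean(d))


@dataclass
class MorphometryResult:
    """Per-plate and per-compartment morphometry with provenance."""

    knee_id: str
    visit_id: str
    source: str
    values: dict[str, dict[str, float | None]] = field(default_factory=dict)

    report_kind = "morphometry"

    def to_frame(self) -> pd.DataFrame:
        rows = [{"knee_id": self.knee_id, "visit_id": self.visit_id,
                 "source": self.source, "region": region, **vals}
                for region, vals in self.values.items()]
        return pd.DataFrame(rows)


def aggregate_compartments(per_plate: dict[str, dict[str, float | None]]
                           ) -> dict[str, dict[str, float | None]]:
    """Compartment measures as plate sums (MFTC = MT + cMF, LFTC = LT + cLF).

    A compartment whose constituent plate is missing (no voxels) is flagged
    missing (all values None) without affecting the other compartment.
    """
    out: dict[str, dict[str, float | None]] = {}
    for comp, (p1, p2) in COMPARTMENTS.items():
        a, b = per_plate.get(p1), per_plate.get(p2)
        missing = (a is None or b is None
                   or a.get("volume_mm3", 0) == 0 or b.get("volume_mm3", 0) == 0)
        if missing:
            out[comp] = {m: None for m in MEASURES}
            continue
        vals = {}
        for m in MEASURES:
            if a[m] is None or b[m] is None:
                vals[m] = None
            else:
                vals[m] = a[m] + b[m]
        out[comp] = vals
    return out


def compute_morphometry(volume: LabelVolume, partition: SurfacePartition,
                        knee_id: str = "knee", visit_id: str = "visit",
                        source: str = "auto") -> MorphometryResult:
    """All three measures for the four plates and the two compartments."""
    per_plate: dict[str, dict[str, float | None]] = {}
    for name, plate in NAME_TO_LABEL.items():
        vol = cartilage_volume(volume, plate)
        per_plate[name] = {
            "thickness_mm": mean_thickness(partition, volume, plate)
            if vol > 0 else None,
            "volume_mm3": vol,
            "tab_area_cm2": bone_interface_area(partition, plate),
        }
    values = dict(per_plate)
    values.update(aggregate_compartments(per_plate))
    return MorphometryResult(knee_id=knee_id, visit_id=visit_id,
                             source=source, values=values)
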