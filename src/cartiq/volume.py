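"""Core containers for plate-labelled cartilage volumes.

A :class:`LabelVolume` is a 3D integer grid in which each voxel carries one of
four femorotibial cartilage plate labels (or background), together with the
anisotropic voxel spacing and the mapping of grid axes to anatomical
directions. All physical coordinates in this package are voxel-center
positions, ``index * spacing``, in millimetres.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("cartiq")

# Plate label encoding (fixed): 0 background, then the four cartilage plates.
BACKGROUND = 0
MT = 1    # medial tibia
CMF = 2   # central (weight-bearing) medial femoral condyle
LT = 3    # lateral tibia
CLF = 4   # central lateral femoral condyle

PLATE_LABELS = (MT, CMF, LT, CLF)
PLATE_NAMES = {MT: "MT", CMF: "cMF", LT: "LT", CLF: "cLF"}
NAME_TO_LABEL = {v: k for k, v in PLATE_NAMES.items()}
TIBIAL_LABELS = frozenset({MT, LT})
FEMORAL_LABELS = frozenset({CMF, CLF})

# Compartments are plate sums: medial = MT + cMF, lateral = LT + cLF.
COMPARTMENTS = {"MFTC": ("MT", "cMF"), "LFTC": ("LT", "cLF")}

# Anatomical direction codes: the value names the direction in which the grid
# index increases, e.g. "sup-inf" means index 0 is most superior.
_AXIS_FAMILY = {
    "sup-inf": "SI", "inf-sup": "SI",
    "ant-post": "AP", "post-ant": "AP",
    "med-lat": "ML", "lat-med": "ML",
}
GRID_AXES = ("row", "col", "slice")


@dataclass
class LabelVolume:
    """3D plate-label grid with physical spacing and axis semantics.

    Parameters
    ----------
    voxels
        3D integer array; values must lie in ``{0..4}``.
    spacing
        (row, col, slice) voxel spacing in mm, all strictly positive.
    plane
        Acquisition plane, ``"coronal"`` or ``"sagittal"``. The slice axis is
        anterior–posterior for coronal and medial–lateral for sagittal data.
    axes
        Mapping ``{"row": ..., "col": ..., "slice": ...}`` of grid axes to
        anatomical direction codes (see module docstring); must cover the SI,
        AP and ML families exactly once each.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    plane: str
    axes: dict[str, str]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.validate()

    def validate(self) -> None:
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D, got {self.voxels.ndim}D")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise ValueError("voxels must be an integer array")
        bad = np.setdiff1d(np.unique(self.voxels), [0, *PLATE_LABELS])
        if bad.size:
            raise ValueError(f"unknown label value(s) {bad.tolist()}; "
                             f"expected labels in 0..4")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if self.plane not in ("coronal", "sagittal"):
            raise ValueError(f"plane must be coronal or sagittal, got {self.plane!r}")
        if set(self.axes) != set(GRID_AXES):
            raise ValueError(f"axes must map exactly {GRID_AXES}, got {set(self.axes)}")
        fams = [_AXIS_FAMILY.get(v) for v in self.axes.values()]
        if None in fams or sorted(fams) != ["AP", "ML", "SI"]:
            raise ValueError(f"axes values must cover SI/AP/ML exactly once, got {self.axes}")

    # -- axis helpers -----------------------------------------------------
    def axis_of(self, family: str) -> int:
        """Grid axis index (0/1/2) mapped to the SI, AP or ML family."""
        for i, name in enumerate(GRID_AXES):
            if _AXIS_FAMILY[self.axes[name]] == family:
                return i
        raise KeyError(family)

    def axis_sign(self, family: str, positive: str) -> int:
        """+1 if the index increases toward `positive` (e.g. "inf", "post")."""
        code = self.axes[GRID_AXES[self.axis_of(family)]]
        return 1 if code.endswith(positive) else -1

    def positions(self, family: str) -> np.ndarray:
        """Physical voxel-center positions (mm) along an anatomical axis."""
        ax = self.axis_of(family)
        return np.arange(self.voxels.shape[ax]) * self.spacing[ax]

    def plate_mask(self, label: int) -> np.ndarray:
        return self.voxels == label

    def plate_counts(self) -> dict[str, int]:
        return {PLATE_NAMES[p]: int(np.count_nonzero(self.voxels == p))
                for p in PLATE_LABELS}

    def copy(self) -> "LabelVolume":
        return LabelVolume(self.voxels.copy(), self.spacing, self.plane,
                           dict(self.axes))


@dataclass
class KneeMetadata:
    """Per-knee acquisition metadata and femoral ROI landmarks.

    Landmarks are physical positions (mm) along the volume's AP axis
    (``index * spacing`` convention) for each femoral plate: the
    inter-condylar notch and the posterior end of the condyle. The weight-
    bearing ROI extends from the notch over ``roi_fraction`` of the distance
    to the posterior end.
    """

    knee_id: str = "knee"
    visit_id: str = "visit"
    landmarks: dict[str, dict[str, float]] = field(default_factory=dict)
    roi_fraction: float = 0.6
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 < self.roi_fraction <= 1.0):
            raise ValueError(f"roi_fraction must be in (0, 1], got {self.roi_fraction}")
        for plate, lm in self.landmarks.items():
            if "notch_mm" not in lm or "posterior_mm" not in lm:
                raise ValueError(f"landmarks for {plate} need notch_mm and posterior_mm")
            if lm["notch_mm"] == lm["posterior_mm"]:
                raise ValueError(f"landmarks for {plate}: notch equals posterior end")

    def has_landmarks(self, plate_name: str) -> bool:
        return plate_name in self.landmarks


def log_plate_counts(stage: str, volume: LabelVolume) -> None:
    """Audit hook: log per-plate foreground voxel counts for a pipeline stage."""
    counts = volume.plate_counts()
    logger.info("%s: %s", stage, " ".join(f"{k}={v}" for k, v in counts.items()))
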