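"""NIfTI-1 + JSON-sidecar I/O and tabular CSV reports.

NIfTI alone cannot express the acquisition plane, the anatomical meaning of
the grid axes, or the femoral ROI landmarks, so every label volume travels
with a JSON sidecar::

    {
      "plane": "sagittal",
      "axes": {"row": "sup-inf", "col": "ant-post", "slice": "med-lat"},
      "knee_id": "k01", "visit_id": "V01",
      "roi_fraction": 0.6,
      "landmarks": {"cMF": {"notch_mm": 7.4, "posterior_mm": 40.7}, ...},
      "label_map": {"1": 1, "2": 2, ...}          # optional remap for foreign files
    }

``label_map`` remaps foreign integer codes onto the fixed 0..4 encoding
before validation.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .volume import (FEMORAL_LABELS, PLATE_LABELS, PLATE_NAMES, KneeMetadata,
                     LabelVolume)

logger = logging.getLogger("cartiq")

_REQUIRED_SIDECAR_KEYS = ("plane", "axes")


def read_label_volume(path, sidecar) -> tuple[LabelVolume, KneeMetadata]:
    """Read a plate-label volume and its metadata sidecar.

    Raises on unknown label values (naming the value), missing spacing, or a
    sidecar missing required keys (naming the key). A sidecar without ROI
    landmarks while femoral plates are present is accepted, but a warning is
    recorded on the metadata; ROI-dependent steps will refuse to run later.
    """
    path, sidecar = Path(path), Path(sidecar)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded, atol=1e-6):
            raise ValueError(f"{path}: label volume has non-integer values")
        data = rounded.astype(np.int16)
    zooms = img.header.get_zooms()[:3]
    if len(zooms) < 3 or any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise ValueError(f"{path}: missing or invalid voxel spacing in header")

    with open(sidecar) as fh:
        meta_json = json.load(fh)
    missing = [k for k in _REQUIRED_SIDECAR_KEYS if k not in meta_json]
    if missing:
        raise ValueError(f"{sidecar}: missing sidecar key(s): {', '.join(missing)}")

    if "label_map" in meta_json:
        remap = {int(k): int(v) for k, v in meta_json["label_map"].items()}
        out = np.zeros_like(data)
        for src, dst in remap.items():
            out[data == src] = dst
        unmapped = np.setdiff1d(np.unique(data), list(remap) + [0])
        if unmapped.size:
            raise ValueError(f"{path}: label value(s) {unmapped.tolist()} not in label_map")
        data = out
    bad = np.setdiff1d(np.unique(data), [0, *PLATE_LABELS])
    if bad.size:
        raise ValueError(f"{path}: unknown label value(s) {bad.tolist()}")

    volume = LabelVolume(data.astype(np.int16), tuple(float(z) for z in zooms),
                         meta_json["plane"], dict(meta_json["axes"]))
    meta = KneeMetadata(
        knee_id=meta_json.get("knee_id", path.stem),
        visit_id=meta_json.get("visit_id", "visit"),
        landmarks={k: dict(v) for k, v in meta_json.get("landmarks", {}).items()},
        roi_fraction=float(meta_json.get("roi_fraction", 0.6)),
    )
    femoral_present = [PLATE_NAMES[p] for p in sorted(FEMORAL_LABELS)
                       if np.any(data == p)]
    for name in femoral_present:
        if not meta.has_landmarks(name):
            msg = (f"femoral plate {name} present but ROI landmarks missing; "
                   f"ROI-dependent steps will refuse to run")
            meta.warnings.append(msg)
            logger.warning("%s: %s", path, msg)
    return volume, meta


def write_label_volume(volume: LabelVolume, meta: KneeMetadata, path) -> Path:
    """Write a NIfTI-1 label volume (integer dtype) plus its JSON sidecar.

    The sidecar is written next to the volume as ``<stem>.json``;
    :func:`read_label_volume` inverts this exactly.
    """
    path = Path(path)
    if not path.parent.is_dir():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    affine = np.diag([*volume.spacing, 1.0])
    img = nib.Nifti1Image(volume.voxels.astype(np.int16), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))
    sidecar = sidecar_path(path)
    payload = {
        "plane": volume.plane,
        "axes": volume.axes,
        "knee_id": meta.knee_id,
        "visit_id": meta.visit_id,
        "roi_fraction": meta.roi_fraction,
        "landmarks": meta.landmarks,
    }
    with open(sidecar, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    return sidecar


def sidecar_path(path) -> Path:
    """Sidecar path for a volume path (strips .nii/.nii.gz)."""
    path = Path(path)
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[:-len(suffix)] + ".json")
    return path.with_suffix(".json")


# ---------------------------------------------------------------------------
# Tabular reports
# ---------------------------------------------------------------------------

_ROW_ORDER = ["MT", "cMF", "LT", "cLF", "MFTC", "LFTC"]


def _region_sort(df: pd.DataFrame) -> pd.DataFrame:
    order = {name: i for i, name in enumerate(_ROW_ORDER)}
    df = df.copy()
    df["_ord"] = df["region"].map(order).fillna(len(order))
    keys = [c for c in ("knee_id", "measure") if c in df.columns] + ["_ord"]
    df = df.sort_values(keys, kind="mergesort").drop(columns="_ord")
    return df.reset_index(drop=True)


def report(results, path) -> dict[str, Path]:
    """Write tidy CSVs for a collection of result objects.

    One file per result kind (``morphometry.csv``, ``agreement.csv``,
    ``precision.csv``); row order follows the plate/compartment convention
    MT, cMF, LT, cLF, MFTC, LFTC and is byte-stable across runs.
    """
    if not results:
        raise ValueError("no results to report")
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    frames: dict[str, list[pd.DataFrame]] = {}
    for res in results:
        frames.setdefault(res.report_kind, []).append(res.to_frame())
    written = {}
    for kind, parts in frames.items():
        df = pd.concat(parts, ignore_index=True)
        if "region" in df.columns:
            df = _region_sort(df)
        out = outdir / f"{kind}.csv"
        df.to_csv(out, index=False, float_format="%.17g", lineterminator="\n")
        written[kind] = out
        logger.info("report: wrote %s (%d rows)", out, len(df))
    return written
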