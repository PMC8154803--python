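"""Synthetic knee phantoms with known cartilage morphometry.

The generator emulates the geometry of segmented femorotibial cartilage on
the two MRI protocols the pipeline targets: a FLASH-like coronal grid
(0.3125 x 0.3125 mm in-plane, 1.5 mm slices) and a DESS-like sagittal grid
(0.37 x 0.37 mm in-plane, 0.7 mm slices). Four plates (MT, cMF, LT, cLF) are
built as thin slabs of prescribed thickness on analytic bone-interface
surfaces: tibial plates sit on a gently upward-convex paraboloid, femoral
plates on a circular-arc condyle profile so the 60% weight-bearing ROI cut is
geometrically meaningful in sagittal phantoms. Ground-truth thickness, volume
and subchondral bone (tAB) area are recorded analytically per plate before
any defects (enclosed holes, distant spurious blobs) are injected, so the
rule-based post-processing can be tested for recovering the clean mask.

All randomness derives from one explicit integer seed via
``numpy.random.SeedSequence`` spawn keys; no global RNG state is used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .postproc import remove_disconnected, smooth_spikes
from .volume import NAME_TO_LABEL, PLATE_NAMES, KneeMetadata, LabelVolume

logger = logging.getLogger("cartiq")

#: canonical (si, ml, ap) voxel spacing per preset, mm
PRESET_SPACING = {"flash": (0.3125, 0.3125, 1.5), "dess": (0.37, 0.7, 0.37)}
PRESET_PLANE = {"flash": "coronal", "dess": "sagittal"}
PRESET_SHAPE = {"flash": (112, 112, 20), "dess": (96, 28, 110)}

_CORONAL_AXES = {"row": "sup-inf", "col": "med-lat", "slice": "ant-post"}
_SAGITTAL_AXES = {"row": "sup-inf", "col": "ant-post", "slice": "med-lat"}

# fractional footprints (of the canonical ML / AP extents)
_ML_MEDIAL = (0.08, 0.46)
_ML_LATERAL = (0.54, 0.92)
_AP_TIBIAL = (0.10, 0.90)

_CROSS3 = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


@dataclass
class PhantomConfig:
    """Geometry, grid, noise and defect model of one synthetic knee.

    ``thickness_mm`` defaults follow typical healthy-knee plate means
    (MT 1.7, cMF 1.8, LT 2.1, cLF 1.7 mm); ``geometry`` may be ``"curved"``
    (default) or ``"flat"`` (axis-aligned slabs with exactly
    ``round(t / si spacing)`` voxel layers, for which truth is exact).
    """

    preset: str = "flash"
    shape: tuple[int, int, int] | None = None      # canonical (si, ml, ap)
    spacing_mm: tuple[float, float, float] | None = None
    geometry: str = "curved"
    plates: tuple[str, ...] = ("MT", "cMF", "LT", "cLF")
    thickness_mm: dict[str, float] = field(default_factory=lambda: {
        "MT": 1.7, "cMF": 1.8, "LT": 2.1, "cLF": 1.7})
    thickness_variation_mm: float = 0.0
    tibial_curvature: float = 0.015       # 1/mm, paraboloid coefficient
    femoral_ml_curvature: float = 0.004   # 1/mm
    condyle_radius_factor: float = 0.75   # x (posterior - notch) span
    gap_mm: float = 2.5                   # femorotibial joint space
    notch_frac: float = 0.15              # AP position of notch / extent
    posterior_frac: float = 0.95
    roi_fraction: float = 0.6
    noise_sigma: float = 0.05
    corner_artifacts: bool = False
    n_holes: int = 0
    hole_radius_px: int = 1
    n_blobs: int = 0
    blob_radius_px: int = 2
    origin_shift_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    knee_id: str = "phantom"
    visit_id: str = "V1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.preset not in PRESET_SPACING:
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.geometry not in ("curved", "flat"):
            raise ValueError(f"geometry must be curved or flat, got {self.geometry!r}")
        if self.shape is None:
            self.shape = PRESET_SHAPE[self.preset]
        if self.spacing_mm is None:
            self.spacing_mm = PRESET_SPACING[self.preset]
        for name in self.plates:
            if name not in NAME_TO_LABEL:
                raise ValueError(f"unknown plate {name!r}")
            if self.thickness_mm.get(name, 0) <= 0:
                raise ValueError(f"thickness for {name} must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class PhantomTruth:
    """Analytic per-plate ground truth and the clean (defect-free) mask.

    Truth values are consistent with ``clean_labels`` to within one boundary
    voxel layer; thickness is the footprint mean of the local thickness
    measured perpendicular to the bone interface.
    """

    plates: dict[str, dict[str, float]]
    clean_labels: LabelVolume


@dataclass
class Phantom:
    gray: np.ndarray
    labels: LabelVolume
    meta: KneeMetadata
    truth: PhantomTruth


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _col_range(lo_mm: float, hi_mm: float, n: int, s: float) -> np.ndarray:
    pos = np.arange(n) * s
    return np.where((pos >= lo_mm) & (pos < hi_mm))[0]


class _Geometry:
    """Analytic surfaces and footprints in canonical (si, ml, ap) mm space."""

    def __init__(self, cfg: PhantomConfig):
        self.cfg = cfg
        n_si, n_ml, n_ap = cfg.shape
        self.s_si, self.s_ml, self.s_ap = cfg.spacing_mm
        self.H, self.Wm, self.Wa = (n_si * self.s_si, n_ml * self.s_ml,
                                    n_ap * self.s_ap)
        d_si, d_ml, d_ap = cfg.origin_shift_mm
        self.d_ml, self.d_ap = d_ml, d_ap
        self.z_tib_base = 0.72 * self.H + d_si
        self.notch = cfg.notch_frac * self.Wa + d_ap
        self.posterior = cfg.posterior_frac * self.Wa + d_ap
        span = self.posterior - self.notch
        self.cut = self.notch + cfg.roi_fraction * span
        self.ap_c = 0.5 * (self.notch + self.posterior)
        self.R = cfg.condyle_radius_factor * span
        t_tib = max(cfg.thickness_mm.get(p, 0.0) for p in ("MT", "LT"))
        t_fem = max(cfg.thickness_mm.get(p, 0.0) for p in ("cMF", "cLF"))
        self.si_c = self.z_tib_base - t_tib - cfg.gap_mm - t_fem - self.R

    def footprint(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        cfg = self.cfg
        n_si, n_ml, n_ap = cfg.shape
        ml_lo, ml_hi = _ML_MEDIAL if name in ("MT", "cMF") else _ML_LATERAL
        ml_cols = _col_range(ml_lo * self.Wm + self.d_ml,
                             ml_hi * self.Wm + self.d_ml, n_ml, self.s_ml)
        if name in ("MT", "LT"):
            ap_lo, ap_hi = (_AP_TIBIAL[0] * self.Wa + self.d_ap,
                            _AP_TIBIAL[1] * self.Wa + self.d_ap)
        else:
            ap_lo, ap_hi = self.notch, self.cut
        ap_cols = _col_range(ap_lo, ap_hi, n_ap, self.s_ap)
        if ml_cols.size == 0 or ap_cols.size == 0:
            raise ValueError(f"plate {name}: footprint does not fit inside the grid")
        return ml_cols, ap_cols

    def thickness(self, name: str, ml: np.ndarray, ap: np.ndarray) -> np.ndarray:
        cfg = self.cfg
        t0 = cfg.thickness_mm[name]
        if cfg.thickness_variation_mm == 0:
            return np.full(np.broadcast_shapes(ml.shape, ap.shape), t0)
        ml_lo, ml_hi = _ML_MEDIAL if name in ("MT", "cMF") else _ML_LATERAL
        u = (ml - ml_lo * self.Wm - self.d_ml) / ((ml_hi - ml_lo) * self.Wm)
        return t0 + cfg.thickness_variation_mm * np.sin(2 * np.pi * u) \
            * np.ones_like(ap)

    def surface(self, name: str, ml: np.ndarray, ap: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Bone-interface height z(ml, ap) and its analytic gradient (mm/mm)."""
        cfg = self.cfg
        ml_lo, ml_hi = _ML_MEDIAL if name in ("MT", "cMF") else _ML_LATERAL
        m0 = 0.5 * (ml_lo + ml_hi) * self.Wm + self.d_ml
        if name in ("MT", "LT"):
            a0 = 0.5 * (_AP_TIBIAL[0] + _AP_TIBIAL[1]) * self.Wa + self.d_ap
            c = cfg.tibial_curvature
            z = self.z_tib_base + c * ((ml - m0) ** 2 + (ap - a0) ** 2)
            return z, 2 * c * (ml - m0) * np.ones_like(ap), \
                2 * c * (ap - a0) * np.ones_like(ml)
        u = ap - self.ap_c
        root = np.sqrt(np.maximum(self.R ** 2 - u ** 2, 1e-9))
        cf = cfg.femoral_ml_curvature
        z = self.si_c + root - cf * (ml - m0) ** 2
        return z, -2 * cf * (ml - m0) * np.ones_like(ap), \
            -u / root * np.ones_like(ml)


def _voxelize_canonical(cfg: PhantomConfig
                        ) -> tuple[np.ndarray, dict[str, dict[str, float]], _Geometry]:
    """Rasterise the plates into the canonical grid and record analytic truth."""
    geo = _Geometry(cfg)
    n_si, n_ml, n_ap = cfg.shape
    s_si, s_ml, s_ap = cfg.spacing_mm
    si_pos = np.arange(n_si) * s_si
    labels = np.zeros(cfg.shape, dtype=np.int16)
    truth: dict[str, dict[str, float]] = {}

    for name in cfg.plates:
        lab = NAME_TO_LABEL[name]
        tibial = name in ("MT", "LT")
        ml_cols, ap_cols = geo.footprint(name)
        ml_mm = ml_cols[:, None] * s_ml
        ap_mm = ap_cols[None, :] * s_ap

        if cfg.geometry == "flat":
            n_t = max(1, round(cfg.thickness_mm[name] / s_si))
            r_tib = round(0.72 * n_si)
            if tibial:
                rows = np.arange(r_tib - n_t, r_tib)
            else:
                t_tib_max = max(max(1, round(cfg.thickness_mm.get(p, s_si) / s_si))
                                for p in ("MT", "LT"))
                gap_rows = int(np.ceil(cfg.gap_mm / s_si))
                bottom = r_tib - t_tib_max - gap_rows
                rows = np.arange(bottom - n_t, bottom)
            if rows[0] < 0 or rows[-1] >= n_si:
                raise ValueError(f"plate {name}: slab exceeds the grid in SI")
            labels[np.ix_(rows, ml_cols, ap_cols)] = lab
            area = ml_cols.size * s_ml * ap_cols.size * s_ap
            truth[name] = {"thickness_mm": n_t * s_si,
                           "volume_mm3": n_t * s_si * area,
                           "tab_area_cm2": area / 100.0}
            continue

        z, zx, zy = geo.surface(name, ml_mm, ap_mm)
        t = geo.thickness(name, ml_mm, ap_mm)
        if tibial:
            lo, hi = z - t, z
        else:
            lo, hi = z, z + t
        if lo.min() < 0 or hi.max() > geo.H:
            raise ValueError(f"plate {name}: slab exceeds the grid in SI")
        mask = (si_pos[:, None, None] >= lo[None]) & (si_pos[:, None, None] < hi[None])
        sub = labels[:, ml_cols[:, None], ap_cols[None, :]]
        sub[mask] = lab
        labels[:, ml_cols[:, None], ap_cols[None, :]] = sub
        grad2 = zx ** 2 + zy ** 2
        cos = 1.0 / np.sqrt(1.0 + grad2)
        truth[name] = {
            "thickness_mm": float(np.mean(t * cos)),
            "volume_mm3": float(np.sum(t) * s_ml * s_ap),
            "tab_area_cm2": float(np.sum(np.sqrt(1.0 + grad2)) * s_ml * s_ap / 100.0),
        }
    return labels, truth, geo


def _canonical_to_grid(arr: np.ndarray, preset: str) -> np.ndarray:
    return arr if PRESET_PLANE[preset] == "coronal" else arr.transpose(0, 2, 1)


def _grid_layout(cfg: PhantomConfig) -> tuple[tuple[float, float, float], str, dict]:
    s_si, s_ml, s_ap = cfg.spacing_mm
    if PRESET_PLANE[cfg.preset] == "coronal":
        return (s_si, s_ml, s_ap), "coronal", dict(_CORONAL_AXES)
    return (s_si, s_ap, s_ml), "sagittal", dict(_SAGITTAL_AXES)


def _normal_form(vol: LabelVolume) -> LabelVolume:
    """Spike-pruning / connectivity fixpoint; truth masks live in this form."""
    for _ in range(5):
        nxt = remove_disconnected(smooth_spikes(vol))
        if np.array_equal(nxt.voxels, vol.voxels):
            return nxt
        vol = nxt
    return vol


def _intensity(cfg: PhantomConfig, labels_canon: np.ndarray, geo: _Geometry,
               rng: np.random.Generator) -> np.ndarray:
    """Three-level piecewise-constant contrast + Gaussian noise (canonical)."""
    n_si, n_ml, n_ap = cfg.shape
    s_si, s_ml, s_ap = cfg.spacing_mm
    si = (np.arange(n_si) * s_si)[:, None, None]
    ml = (np.arange(n_ml) * s_ml)[None, :, None]
    ap = (np.arange(n_ap) * s_ap)[None, None, :]
    gray = np.full(cfg.shape, 0.4, dtype=np.float64)
    if cfg.geometry == "flat":
        r_tib = round(0.72 * n_si)
        gray[r_tib:] = 0.2
        t_tib_max = max(max(1, round(cfg.thickness_mm.get(p, s_si) / s_si))
                        for p in ("MT", "LT"))
        bottom = r_tib - t_tib_max - int(np.ceil(cfg.gap_mm / s_si))
        t_fem_max = max(max(1, round(cfg.thickness_mm.get(p, s_si) / s_si))
                        for p in ("cMF", "cLF"))
        gray[: max(bottom - t_fem_max, 0)] = 0.2
    else:
        c = cfg.tibial_curvature
        z_tib = geo.z_tib_base + c * ((ml - 0.5 * geo.Wm) ** 2 + (ap - 0.5 * geo.Wa) ** 2)
        gray = np.where(si >= z_tib, 0.2, gray)
        u = ap - geo.ap_c
        inside = np.abs(u) < geo.R
        z_fem = geo.si_c + np.sqrt(np.maximum(geo.R ** 2 - u ** 2, 0.0)) \
            - cfg.femoral_ml_curvature * (ml - 0.5 * geo.Wm) ** 2
        gray = np.where(inside & (si <= z_fem), 0.2, gray)
    gray[labels_canon > 0] = 0.9
    return gray


def _add_corner_artifacts(gray_grid: np.ndarray, size: int = 15,
                          value: float = 5.0) -> None:
    gray_grid[:size, :size, :] = value
    gray_grid[:size, -size:, :] = value
    gray_grid[-size:, :size, :] = value
    gray_grid[-size:, -size:, :] = value


def _disk_offsets(r: int) -> np.ndarray:
    dr, dc = np.mgrid[-r:r + 1, -r:r + 1]
    keep = dr ** 2 + dc ** 2 <= r ** 2
    return np.stack([dr[keep], dc[keep]], axis=1)


def _inject_holes(labels: np.ndarray, plate: int, n: int, r: int,
                  rng: np.random.Generator) -> None:
    """Carve `n` enclosed background holes of radius `r`, one per slice."""
    cross = ndimage.generate_binary_structure(2, 1)
    cand = []
    for k in range(labels.shape[2]):
        m = labels[:, :, k] == plate
        if not m.any():
            continue
        interior = ndimage.binary_erosion(m, cross, iterations=r + 1)
        if interior.any():
            cand.append((k, np.argwhere(interior)))
    if len(cand) < n:
        raise ValueError(f"cannot place {n} enclosed holes for plate {plate}: "
                         f"only {len(cand)} slices have enough interior")
    offs = _disk_offsets(r)
    for idx in rng.choice(len(cand), size=n, replace=False):
        k, pts = cand[idx]
        ctr = pts[rng.integers(len(pts))]
        rr, cc = (ctr[None, :] + offs).T
        labels[rr, cc, k] = 0


def _inject_blobs(labels: np.ndarray, plate: int, n: int, r: int,
                  rng: np.random.Generator) -> None:
    """Place `n` spurious blobs in slices >= 2 away from the plate's slab."""
    present = np.where((labels == plate).any(axis=(0, 1)))[0]
    all_slices = np.arange(labels.shape[2])
    if present.size:
        dist = np.min(np.abs(all_slices[:, None] - present[None, :]), axis=1)
        cand = all_slices[dist >= 2]
    else:
        cand = all_slices
    offs = _disk_offsets(r)
    placed = 0
    for k in rng.permutation(cand):
        if placed == n:
            break
        sl = labels[:, :, k]
        for ctr in ((2 + r, 2 + r), (2 + r, sl.shape[1] - 3 - r),
                    (sl.shape[0] - 3 - r, 2 + r)):
            rr, cc = (np.asarray(ctr)[None, :] + offs).T
            if (rr >= 0).all() and (rr < sl.shape[0]).all() and \
                    (cc >= 0).all() and (cc < sl.shape[1]).all() and \
                    (sl[rr.min() - 1:rr.max() + 2, cc.min() - 1:cc.max() + 2] == 0).all():
                sl[rr, cc] = plate
                placed += 1
                break
    if placed < n:
        raise ValueError(f"could not place {n} spurious blobs for plate {plate}")


def generate_phantom(config: PhantomConfig) -> Phantom:
    """Generate one phantom: grayscale volume, labels, metadata and truth.

    Deterministic for a fixed config (including its seed). The returned label
    volume carries any configured defects; ``truth.clean_labels`` is the
    defect-free mask in post-processing normal form.
    """
    labels_canon, truth_vals, geo = _voxelize_canonical(config)
    spacing, plane, axes = _grid_layout(config)
    raw = LabelVolume(_canonical_to_grid(labels_canon, config.preset).copy(),
                      spacing, plane, axes)
    clean = _normal_form(raw)

    landmarks = {name: {"notch_mm": geo.notch, "posterior_mm": geo.posterior}
                 for name in config.plates if name in ("cMF", "cLF")}
    meta = KneeMetadata(knee_id=config.knee_id, visit_id=config.visit_id,
                        landmarks=landmarks, roi_fraction=config.roi_fraction)

    rng_noise = _rng(config.seed, 0)
    rng_defect = _rng(config.seed, 1)
    # intensity is built from the canonical clean mask
    clean_canon = clean.voxels if plane == "coronal" else clean.voxels.transpose(0, 2, 1)
    gray = _canonical_to_grid(_intensity(config, clean_canon, geo, rng_noise),
                              config.preset).copy()
    if config.corner_artifacts:
        _add_corner_artifacts(gray)
    if config.noise_sigma > 0:
        gray = gray + rng_noise.normal(0.0, config.noise_sigma, size=gray.shape)

    defective = clean.voxels.copy()
    for name in config.plates:
        lab = NAME_TO_LABEL[name]
        if config.n_holes > 0:
            _inject_holes(defective, lab, config.n_holes,
                          config.hole_radius_px, rng_defect)
        if config.n_blobs > 0:
            _inject_blobs(defective, lab, config.n_blobs,
                          config.blob_radius_px, rng_defect)
    out = LabelVolume(defective, spacing, plane, axes)
    truth = PhantomTruth(plates=truth_vals, clean_labels=clean)
    logger.info("generate_phantom[%s/%s]: %s", config.knee_id, config.visit_id,
                out.plate_counts())
    return Phantom(gray=gray, labels=out, meta=meta, truth=truth)


def generate_followup_pair(config: PhantomConfig, jitter_mm: float = 0.0,
                           boundary_flip_p: float = 0.0
                           ) -> tuple[Phantom, Phantom]:
    """Two visits of the same knee with zero true change.

    Visit 2 differs from visit 1 only by a rigid sub-voxel repositioning
    (each canonical axis shifted by N(0, jitter_mm)) followed by independent
    per-voxel boundary-layer flips with probability ``boundary_flip_p`` —
    emulating repositioning plus segmentation noise between follow-up visits.
    Both visits share the identical :class:`PhantomTruth`.
    """
    if jitter_mm < 0 or not (0.0 <= boundary_flip_p <= 1.0):
        raise ValueError("perturbation parameters must be >= 0 (p in [0, 1])")
    v1 = generate_phantom(config)
    rng = _rng(config.seed, 2)
    shift = tuple(rng.normal(0.0, jitter_mm, size=3)) if jitter_mm > 0 else (0., 0., 0.)
    cfg2 = replace(config, origin_shift_mm=shift, visit_id="V2",
                   seed=(config.seed * 2 + 1) % 2 ** 31)
    v2 = generate_phantom(cfg2)
    if boundary_flip_p > 0:
        vox = v2.labels.voxels
        for lab in [NAME_TO_LABEL[p] for p in config.plates]:
            m = vox == lab
            outer = ndimage.binary_dilation(m, _CROSS3) & (vox == 0)
            inner = m & ~ndimage.binary_erosion(m, _CROSS3)
            # balance add/drop rates so the perturbation is volume-
            # preserving in expectation (zero true change)
            n_out, n_in = np.count_nonzero(outer), np.count_nonzero(inner)
            p_add = boundary_flip_p * (n_in / n_out if n_out > n_in else 1.0)
            p_drop = boundary_flip_p * (n_out / n_in if n_in > n_out else 1.0)
            add = outer & (rng.random(vox.shape) < p_add)
            drop = inner & (rng.random(vox.shape) < min(p_drop, 1.0))
            vox[add] = lab
            vox[drop] = 0
    v2 = Phantom(gray=v2.gray, labels=v2.labels, meta=v2.meta, truth=v1.truth)
    return v1, v2


def split_sizes(n: int, fractions: tuple[float, float, float]) -> tuple[int, int, int]:
    """Largest-remainder rounding of split fractions to integer set sizes."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    if n < 3:
        raise ValueError("need n >= 3 for non-empty train/val/test sets")
    raw = [n * f for f in fractions]
    sizes = [int(np.floor(x)) for x in raw]
    rem = n - sum(sizes)
    order = np.argsort([-(x - np.floor(x)) for x in raw], kind="stable")
    for i in range(rem):
        sizes[order[i]] += 1
    if any(s == 0 for s in sizes):
        raise ValueError(f"n={n} too small for non-empty sets with {fractions}")
    return tuple(sizes)


def generate_cohort(n: int, split: tuple[float, float, float],
                    config: PhantomConfig, seed: int
                    ) -> dict[str, list[PhantomConfig]]:
    """Disjoint train/val/test phantom configs with derived per-phantom seeds.

    Returns configs rather than volumes so large cohorts can be generated
    lazily; membership is deterministic for a fixed master seed.
    """
    sizes = split_sizes(n, split)
    names = ("train", "val", "test")
    out: dict[str, list[PhantomConfig]] = {k: [] for k in names}
    i = 0
    for set_name, size in zip(names, sizes):
        for _ in range(size):
            child = int(np.random.SeedSequence(seed, spawn_key=(3, i))
                        .generate_state(1)[0] % 2 ** 31)
            out[set_name].append(replace(config, seed=child,
                                         knee_id=f"{config.knee_id}-{i:03d}"))
            i += 1
    return out
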