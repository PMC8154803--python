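"""Rule-based post-processing of plate-label segmentations.

Raw per-slice cartilage predictions may contain enclosed holes, spurious
fragments at implausible locations, single-pixel spikes, and femoral
cartilage outside the weight-bearing region of interest. Five deterministic
steps turn such a volume into a morphometry-ready segmentation:

1. fill enclosed, unsegmented gaps (per slice, per plate),
2. remove components not connected to the main segmentation (3D, 26-conn),
3. prune spikes (iterative deletion of weakly connected pixels),
4. crop femoral plates to the (60%) ROI between the inter-condylar notch
   and the posterior end of the condyles,
5. partition each plate's per-slice boundary into the subchondral bone
   interface (tAB) and the articular surface (AC) by splitting the traced
   contour at the two boundary points farthest apart in physical mm;
   non-border voxels form the inner cartilage (IC).

Conventions fixed here (the method description leaves them open): boundary
pixels are foreground pixels with a 4-connected background neighbour;
contours are traced with Moore neighbour following, clockwise in image
coordinates, starting at the minimum-index boundary pixel; farthest pairs
are measured on physical coordinates and ties resolved toward the
lexicographically smallest pixel-index pair; the tAB chain is the one closer
to the bone (inferior for tibial plates, superior for femoral plates). Where
a femoral plate abuts the ROI cut line, the cut-edge corners become the
chain endpoints and cut-edge interior pixels are assigned to IC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import (FEMORAL_LABELS, GRID_AXES, PLATE_LABELS, PLATE_NAMES,
                     KneeMetadata, LabelVolume)

logger = logging.getLogger("cartiq")

_CROSS2 = ndimage.generate_binary_structure(2, 1)
_CUBE3 = np.ones((3, 3, 3), dtype=bool)
_NB4_KERNEL = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=np.uint8)

# clockwise Moore neighbourhood in image coordinates (row down, col right)
_DIRS8 = ((0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1))
_DIR_INDEX = {d: i for i, d in enumerate(_DIRS8)}


# ---------------------------------------------------------------------------
# Steps 1-4: mask clean-up
# ---------------------------------------------------------------------------

def fill_gaps(volume: LabelVolume, max_area: int | None = None) -> LabelVolume:
    """Fill enclosed, unsegmented areas (step 1).

    Per slice, a 4-connected background region that does not touch the slice
    border and whose entire neighbourhood belongs to a single plate is
    relabelled to that plate, provided its pixel count does not exceed
    ``max_area`` (default: no cap — gaps enclosed by thin cartilage
    structures are intrinsically small). Foreground never decreases.
    """
    vox = volume.voxels.copy()
    for k in range(vox.shape[2]):
        sl = vox[:, :, k]
        if not sl.any():
            continue
        lbl, n = ndimage.label(sl == 0, structure=_CROSS2)
        if n == 0:
            continue
        border = np.unique(np.concatenate([lbl[0], lbl[-1], lbl[:, 0], lbl[:, -1]]))
        sizes = np.bincount(lbl.ravel(), minlength=n + 1)
        for comp in range(1, n + 1):
            if comp in border:
                continue
            if max_area is not None and sizes[comp] > max_area:
                continue
            m = lbl == comp
            ring = ndimage.binary_dilation(m, _CROSS2) & ~m
            vals = np.unique(sl[ring])
            if vals.size == 1 and vals[0] in PLATE_LABELS:
                sl[m] = vals[0]
    return LabelVolume(vox, volume.spacing, volume.plane, dict(volume.axes))


def remove_disconnected(volume: LabelVolume,
                        keep_fraction: float = 1.0) -> LabelVolume:
    """Remove segmentations at implausible locations (step 2).

    Per plate, 3D 26-connected components are computed and only the largest
    is retained (a size tie keeps the component with the lexicographically
    smallest minimum voxel index). With ``keep_fraction < 1``, secondary
    components of at least that fraction of the largest one are also kept.
    Foreground never increases.
    """
    vox = volume.voxels.copy()
    for plate in PLATE_LABELS:
        mask = vox == plate
        if not mask.any():
            continue
        lbl, n = ndimage.label(mask, structure=_CUBE3)
        if n <= 1:
            continue
        sizes = np.bincount(lbl.ravel(), minlength=n + 1)
        sizes[0] = 0
        largest = sizes.max()
        tied = np.where(sizes == largest)[0]
        if tied.size > 1:
            mins = [tuple(np.argwhere(lbl == c).min(axis=0)) for c in tied]
            main = tied[int(np.lexsort(tuple(np.array([m[i] for m in mins])
                                             for i in (2, 1, 0)))[0])]
        else:
            main = tied[0]
        keep = {int(main)}
        if keep_fraction < 1.0:
            keep |= {c for c in range(1, n + 1)
                     if sizes[c] >= keep_fraction * largest}
        drop = ~np.isin(lbl, sorted(keep)) & mask
        vox[drop] = 0
    return LabelVolume(vox, volume.spacing, volume.plane, dict(volume.axes))


def smooth_spikes(volume: LabelVolume) -> LabelVolume:
    """Prune spikes (step 3).

    Per plate and slice, foreground pixels with at most one 4-connected
    same-plate neighbour are deleted iteratively until a fixpoint: this
    removes one-pixel-wide protrusions while leaving compact shapes intact.
    Never increases foreground; idempotent.
    """
    vox = volume.voxels.copy()
    for plate in PLATE_LABELS:
        for k in range(vox.shape[2]):
            sl = vox[:, :, k]
            m = sl == plate
            if not m.any():
                continue
            while True:
                nb = ndimage.convolve(m.astype(np.uint8), _NB4_KERNEL,
                                      mode="constant", cval=0)
                spikes = m & (nb <= 1)
                if not spikes.any():
                    break
                m &= ~spikes
            sl[(sl == plate) & ~m] = 0
    return LabelVolume(vox, volume.spacing, volume.plane, dict(volume.axes))


def roi_cut_position(notch_mm: float, posterior_mm: float,
                     fraction: float = 0.6) -> float:
    """Position of the femoral ROI cut along the AP axis (mm).

    The weight-bearing ROI extends from the inter-condylar notch over
    ``fraction`` (default 60%) of the distance to the posterior end of the
    condyles; the sign convention follows the landmark ordering.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if notch_mm == posterior_mm:
        raise ValueError("notch and posterior-end positions coincide")
    return notch_mm + fraction * (posterior_mm - notch_mm)


def apply_femoral_roi(volume: LabelVolume, meta: KneeMetadata) -> LabelVolume:
    """Remove femoral cartilage outside the weight-bearing ROI (step 4).

    Voxels of cMF/cLF whose AP position lies posterior to the ROI cut (or
    anterior to an optional ``anterior_mm`` landmark) are cleared; tibial
    plates are never modified. Requires ROI landmarks for every femoral
    plate present.
    """
    vox = volume.voxels.copy()
    ap_axis = volume.axis_of("AP")
    pos = np.arange(vox.shape[ap_axis]) * volume.spacing[ap_axis]
    for plate in sorted(FEMORAL_LABELS):
        name = PLATE_NAMES[plate]
        if not np.any(vox == plate):
            continue
        if not meta.has_landmarks(name):
            raise ValueError(f"femoral plate {name} present but ROI landmarks missing")
        lm = meta.landmarks[name]
        cut = roi_cut_position(lm["notch_mm"], lm["posterior_mm"], meta.roi_fraction)
        sign = 1.0 if lm["posterior_mm"] > lm["notch_mm"] else -1.0
        outside = sign * pos > sign * cut + 1e-9
        if "anterior_mm" in lm:
            outside |= sign * pos < sign * lm["anterior_mm"] - 1e-9
        sel = [None, None, None]
        sel[ap_axis] = outside
        idx = np.ix_(*[s if s is not None else np.ones(vox.shape[i], bool)
                       for i, s in enumerate(sel)])
        sub = vox[idx]
        sub[sub == plate] = 0
        vox[idx] = sub
    return LabelVolume(vox, volume.spacing, volume.plane, dict(volume.axes))


# ---------------------------------------------------------------------------
# Step 5: tAB / AC / IC surface partition
# ---------------------------------------------------------------------------

@dataclass
class SlicePartition:
    """tAB/AC/IC partition of one plate in one slice.

    ``tab``/``ac`` are ordered pixel chains (row, col); the two margin
    ``endpoints`` belong to both. ``tab_meas``/``ac_meas`` are the
    measurement sub-chains: terminal runs without a background face on the
    bone side (tAB) or the articular side (AC) — i.e. pixels lying on the
    plate margin rather than on the surface itself — are trimmed from the
    chain ends. ``tab_face``/``ac_face`` hold the matching in-plane physical
    coordinates (mm) of the measurement chains, with each pixel offset by
    half a voxel toward its background neighbours (onto the voxel face that
    forms the actual surface). ``ic`` lists interior pixels (plus any ROI
    cut-edge pixels).
    """

    slice_index: int
    tab: list[tuple[int, int]]
    ac: list[tuple[int, int]]
    endpoints: tuple[tuple[int, int], tuple[int, int]]
    ic: list[tuple[int, int]]
    tab_meas: list[tuple[int, int]]
    ac_meas: list[tuple[int, int]]
    tab_face: np.ndarray
    ac_face: np.ndarray
    cut_edge: list[tuple[int, int]] = field(default_factory=list)
    degenerate: bool = False
    #: partitions of further in-plane 4-components (noisy masks only; the
    #: post-processing chain normally leaves a single component per slice)
    extra: list["SlicePartition"] = field(default_factory=list)


@dataclass
class SurfacePartition:
    """Per-plate, per-slice surface partition of a label volume."""

    plates: dict[int, dict[int, SlicePartition]]
    spacing: tuple[float, float, float]
    plane: str
    axes: dict[str, str]

    def slices(self, plate: int) -> dict[int, SlicePartition]:
        return self.plates.get(plate, {})

    def _points_mm(self, plate: int, which: str) -> np.ndarray:
        pts = []
        for k, sp in sorted(self.slices(plate).items()):
            for part in (sp, *sp.extra):
                face = part.tab_face if which == "tab" else part.ac_face
                if face.size:
                    z = np.full((face.shape[0], 1), k * self.spacing[2])
                    pts.append(np.hstack([face, z]))
        if not pts:
            return np.empty((0, 3))
        return np.vstack(pts)

    def tab_points_mm(self, plate: int) -> np.ndarray:
        """3D physical coordinates (mm) of all tAB surface points."""
        return self._points_mm(plate, "tab")

    def ac_points_mm(self, plate: int) -> np.ndarray:
        return self._points_mm(plate, "ac")

    def to_frame(self) -> pd.DataFrame:
        """Long-format point list (plate, slice, class, row, col) for audit."""
        rows = []
        for plate, slices in sorted(self.plates.items()):
            pname = PLATE_NAMES[plate]
            for k, sp in sorted(slices.items()):
                for part in (sp, *sp.extra):
                    ep = set(part.endpoints)
                    for cls, pix in (("tAB", part.tab), ("AC", part.ac),
                                     ("IC", part.ic)):
                        for p in pix:
                            rows.append((pname, k, cls, p[0], p[1],
                                         tuple(p) in ep))
        return pd.DataFrame(rows, columns=["plate", "slice", "class",
                                           "row", "col", "endpoint"])


def _moore_trace(mask: np.ndarray) -> list[tuple[int, int]]:
    """Ordered clockwise outer contour of a 4-connected region."""
    rs, cs = np.nonzero(mask)
    o = np.lexsort((cs, rs))
    start = (int(rs[o[0]]), int(cs[o[0]]))
    h, w = mask.shape

    def fg(p):
        return 0 <= p[0] < h and 0 <= p[1] < w and mask[p]

    contour = [start]
    cur, back = start, (start[0], start[1] - 1)   # W neighbour is background
    state0 = (cur, back)
    for _ in range(4 * len(rs) + 8):
        d0 = _DIR_INDEX[(back[0] - cur[0], back[1] - cur[1])]
        nxt, nback = None, back
        for i in range(1, 9):
            d = _DIRS8[(d0 + i) % 8]
            cand = (cur[0] + d[0], cur[1] + d[1])
            if fg(cand):
                nxt = cand
                break
            nback = cand
        if nxt is None:
            return contour          # isolated pixel
        cur, back = nxt, nback
        if (cur, back) == state0:
            break
        contour.append(cur)
    return contour


def _farthest_pair(pixels: np.ndarray, spacing_rc: tuple[float, float]
                   ) -> tuple[tuple[int, int], tuple[int, int]]:
    """Farthest pixel pair in physical mm; ties -> smallest index pair."""
    phys = pixels * np.asarray(spacing_rc)
    d2 = ((phys[:, None, :] - phys[None, :, :]) ** 2).sum(-1)
    best = d2.max()
    ii, jj = np.where(d2 >= best - 1e-12)
    pairs = sorted(
        tuple(sorted((tuple(pixels[i]), tuple(pixels[j]))))
        for i, j in zip(ii, jj) if i < j
    )
    a, b = pairs[0]
    return (int(a[0]), int(a[1])), (int(b[0]), int(b[1]))


def _face_coords(pixels: list[tuple[int, int]], mask: np.ndarray,
                 spacing_rc: tuple[float, float]) -> np.ndarray:
    """Half-voxel face offsets toward background for surface pixels.

    Offsets in opposite directions cancel, so a free-standing pixel stays at
    its centre (a single-voxel plate has coincident tAB/AC surfaces).
    """
    if not pixels:
        return np.empty((0, 2))
    h, w = mask.shape
    sr, sc = spacing_rc
    out = np.empty((len(pixels), 2))
    for i, (r, c) in enumerate(pixels):
        def bg(rr, cc):
            return not (0 <= rr < h and 0 <= cc < w and mask[rr, cc])
        dr = 0.5 * sr * (int(bg(r + 1, c)) - int(bg(r - 1, c)))
        dc = 0.5 * sc * (int(bg(r, c + 1)) - int(bg(r, c - 1)))
        out[i] = (r * sr + dr, c * sc + dc)
    return out


def _trim_chain(chain: list[tuple[int, int]], mask: np.ndarray,
                axis: int, step: int) -> list[tuple[int, int]]:
    """Strip terminal pixels lacking a background neighbour at +step on axis.

    Margin pixels (exposed only laterally) sit at the chain ends after the
    farthest-pair split; interior pixels are never removed, so gently curved
    staircase chains stay intact. Falls back to the full chain if trimming
    would empty it.
    """
    h, w = mask.shape

    def exposed(p):
        r, c = (p[0] + step, p[1]) if axis == 0 else (p[0], p[1] + step)
        return not (0 <= r < h and 0 <= c < w and mask[r, c])

    i0, i1 = 0, len(chain)
    while i0 < i1 and not exposed(chain[i0]):
        i0 += 1
    while i1 > i0 and not exposed(chain[i1 - 1]):
        i1 -= 1
    return chain[i0:i1] if i0 < i1 else list(chain)


def _split_chains(trace: list[tuple[int, int]],
                  e1: tuple[int, int], e2: tuple[int, int]
                  ) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    i, j = trace.index(e1), trace.index(e2)
    if i > j:
        i, j = j, i
    chain_a = trace[i:j + 1]
    chain_b = trace[j:] + trace[:i + 1]
    return chain_a, chain_b


def _dedupe(chain: list[tuple[int, int]]) -> list[tuple[int, int]]:
    seen, out = set(), []
    for p in chain:
        if p not in seen:
            seen.add(p)
            out.append(p)
    return out


def partition_surfaces(volume: LabelVolume, meta: KneeMetadata,
                       tab_flip: tuple[str, ...] = ()) -> SurfacePartition:
    """Separate every plate's segmentation into tAB, AC and IC (step 5).

    Each per-slice mask is assumed to be a single 4-connected region (as
    guaranteed by the preceding steps). Slices whose boundary has <= 2
    pixels are not traced: both surfaces collapse onto those pixels, which
    is recorded with a warning. ``tab_flip`` lists plate names whose
    bone-side convention should be inverted (foreign data).
    """
    sr, sc, _ = volume.spacing
    si_axis = volume.axis_of("SI")
    if si_axis == 2:
        raise ValueError("SI axis must be in-plane for surface partitioning")
    inf_sign = volume.axis_sign("SI", "inf")
    ap_axis = volume.axis_of("AP")
    plates: dict[int, dict[int, SlicePartition]] = {}

    for plate in PLATE_LABELS:
        name = PLATE_NAMES[plate]
        mask3 = volume.plate_mask(plate)
        if not mask3.any():
            continue
        femoral = plate in FEMORAL_LABELS
        cut = post_sign = None
        if femoral and ap_axis != 2 and meta.has_landmarks(name):
            lm = meta.landmarks[name]
            cut = roi_cut_position(lm["notch_mm"], lm["posterior_mm"],
                                   meta.roi_fraction)
            post_sign = 1.0 if lm["posterior_mm"] > lm["notch_mm"] else -1.0
        per_slice: dict[int, SlicePartition] = {}
        for k in range(volume.voxels.shape[2]):
            m = mask3[:, :, k]
            if not m.any():
                continue
            per_slice[k] = _partition_slice(
                m, k, (sr, sc), tibial=not femoral,
                inf_axis=si_axis, inf_sign=inf_sign,
                flip=name in tab_flip, ap_axis=ap_axis,
                cut=cut, post_sign=post_sign, plate_name=name)
        plates[plate] = per_slice
    return SurfacePartition(plates=plates, spacing=volume.spacing,
                            plane=volume.plane, axes=dict(volume.axes))


def _partition_slice(m: np.ndarray, k: int, spacing_rc, **kw) -> SlicePartition:
    lbl, n = ndimage.label(m, structure=_CROSS2)
    if n == 1:
        return _partition_region(m, k, spacing_rc, **kw)
    logger.warning("partition %s slice %d: %d 4-connected regions "
                   "(expected 1 after clean-up)", kw["plate_name"], k, n)
    sizes = np.bincount(lbl.ravel())[1:]
    order = np.argsort(-sizes, kind="stable") + 1
    parts = [_partition_region(lbl == c, k, spacing_rc, **kw) for c in order]
    parts[0].extra = parts[1:]
    return parts[0]


def _partition_region(m: np.ndarray, k: int, spacing_rc, *, tibial: bool,
                      inf_axis: int, inf_sign: int, flip: bool, ap_axis: int,
                      cut: float | None, post_sign: float | None,
                      plate_name: str) -> SlicePartition:
    nb = ndimage.convolve(m.astype(np.uint8), _NB4_KERNEL, mode="constant", cval=0)
    boundary = m & (nb < 4)
    bpix = [tuple(p) for p in np.argwhere(boundary)]
    all_pix = {tuple(p) for p in np.argwhere(m)}

    if len(bpix) <= 2:
        logger.warning("partition %s slice %d: degenerate boundary "
                       "(%d pixel(s)); surfaces coincide", plate_name, k, len(bpix))
        face = _face_coords(bpix, m, spacing_rc)
        ep = (bpix[0], bpix[-1])
        ic = sorted(all_pix - set(bpix))
        return SlicePartition(k, list(bpix), list(bpix), ep, ic,
                              list(bpix), list(bpix), face,
                              face.copy(), degenerate=True)

    trace = _moore_trace(m)
    e1, e2 = _farthest_pair(np.array(bpix), spacing_rc)

    # where the plate abuts the femoral ROI cut, the cut line bounds the
    # chains: the cut-edge pixels (except chain endpoints) belong to IC
    cut_edge: list[tuple[int, int]] = []
    if cut is not None:
        s_ap = spacing_rc[ap_axis]
        ap_idx = np.array([p[ap_axis] for p in bpix])
        signed = post_sign * ap_idx * s_ap
        extreme = signed.max()
        if post_sign * cut - extreme <= 0.75 * s_ap:
            h, w = m.shape

            def only_cut_exposed(p):
                # background only across the cut face, not on any surface side
                for d in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    if (d[ap_axis] and np.sign(d[ap_axis]) == np.sign(post_sign)):
                        continue
                    r, c = p[0] + d[0], p[1] + d[1]
                    if not (0 <= r < h and 0 <= c < w and m[r, c]):
                        return False
                return True

            cut_edge = [p for p, s in zip(bpix, signed)
                        if s >= extreme - 1e-9 and p not in (e1, e2)
                        and only_cut_exposed(p)]

    chain_a, chain_b = _split_chains(trace, e1, e2)
    chain_a, chain_b = _dedupe(chain_a), _dedupe(chain_b)
    if cut_edge:
        drop = set(cut_edge)
        chain_a = [p for p in chain_a if p not in drop]
        chain_b = [p for p in chain_b if p not in drop]

    def mean_inf(chain):
        return inf_sign * float(np.mean([p[inf_axis] for p in chain]))

    a_inf, b_inf = mean_inf(chain_a), mean_inf(chain_b)
    tab_first = a_inf >= b_inf if tibial else a_inf <= b_inf
    if flip:
        tab_first = not tab_first
    tab, ac = (chain_a, chain_b) if tab_first else (chain_b, chain_a)
    ic = sorted((all_pix - set(tab) - set(ac)) | set(cut_edge))

    # measurement chains: strip terminal margin runs without a background
    # face on the expected side (bone side for tAB, articular side for AC)
    bone_step = inf_sign if tibial else -inf_sign
    tab_meas = _trim_chain(tab, m, inf_axis, bone_step)
    ac_meas = _trim_chain(ac, m, inf_axis, -bone_step)
    return SlicePartition(
        k, tab, ac, (e1, e2), ic, tab_meas, ac_meas,
        _face_coords(tab_meas, m, spacing_rc),
        _face_coords(ac_meas, m, spacing_rc),
        cut_edge=cut_edge)


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------

@dataclass
class PostprocConfig:
    fill_max_area: int | None = None
    keep_fraction: float = 1.0
    apply_roi: bool = True
    tab_flip: tuple[str, ...] = ()


def run_postprocessing(volume: LabelVolume, meta: KneeMetadata,
                       config: PostprocConfig | None = None
                       ) -> tuple[LabelVolume, SurfacePartition]:
    """Run the five steps in order and return the cleaned volume + partition."""
    cfg = config or PostprocConfig()
    stages = [("fill_gaps", lambda v: fill_gaps(v, cfg.fill_max_area)),
              ("remove_disconnected",
               lambda v: remove_disconnected(v, cfg.keep_fraction)),
              ("smooth_spikes", smooth_spikes)]
    if cfg.apply_roi and any(np.any(volume.voxels == p) for p in FEMORAL_LABELS):
        stages.append(("apply_femoral_roi", lambda v: apply_femoral_roi(v, meta)))
    out = volume
    for stage, fn in stages:
        before = int(np.count_nonzero(out.voxels))
        out = fn(out)
        after = int(np.count_nonzero(out.voxels))
        logger.info("postproc %s: foreground %d -> %d (%+d)",
                    stage, before, after, after - before)
    partition = partition_surfaces(out, meta, tab_flip=cfg.tab_flip)
    return out, partition
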