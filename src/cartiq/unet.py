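"""Toy-scale 2D U-Net segmentation stage (pure numpy).

A 4-level encoder–decoder U-Net for per-slice semantic segmentation of
cartilage plates, with one architectural departure from the classic design:
the transpose convolutions of the up-sampling path produce as many feature
maps as there are feature classes. Training minimises a weighted
cross-entropy (background weight 1/(1+2n), foreground weight 2/(1+2n) for n
feature classes) with the ADAM optimiser (initial learning rate 0.01, decay
rate 0.1 applied as an exponential staircase once at 50% of the epochs by
default, beta1 0.9, beta2 0.999). Weights are variance-scaling initialised
from an explicit seed; only slices containing a segmented feature class are
used for training, and the epoch with the best validation foreground Dice
score provides the final weights.

The forward/backward passes are hand-written on numpy (im2col convolutions),
which keeps the stage dependency-free and bit-reproducible for a fixed seed;
it is intended for toy problem sizes (e.g. 64 x 64 slices), not full-scale
MRI training.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .volume import LabelVolume

logger = logging.getLogger("cartiq")


# ---------------------------------------------------------------------------
# Slice preprocessing and class weighting
# ---------------------------------------------------------------------------

def preprocess_slice(slice2d: np.ndarray, corner: int = 15) -> np.ndarray:
    """Zero the four image corners, then z-score the slice.

    The ``corner x corner`` patches are set to zero *before* the statistics
    are taken (bright corner artefacts would otherwise dominate the
    normalisation); the mean/SD are computed over the full slice including
    the zeroed corners. A slice with near-zero SD after corner zeroing
    yields an all-zero output with a logged warning.
    """
    x = np.asarray(slice2d, dtype=np.float64).copy()
    if corner > 0:
        if x.shape[0] < 2 * corner or x.shape[1] < 2 * corner:
            raise ValueError(f"slice {x.shape} smaller than 2x corner size {corner}")
        x[:corner, :corner] = 0.0
        x[:corner, -corner:] = 0.0
        x[-corner:, :corner] = 0.0
        x[-corner:, -corner:] = 0.0
    sd = x.std()
    if sd < 1e-8:
        logger.warning("preprocess_slice: constant slice, returning zeros")
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def class_weights(n_classes: int) -> tuple[float, float]:
    """Cross-entropy weights (background, foreground) for n feature classes.

    background = 1/(1 + 2n), foreground = 2/(1 + 2n); the foreground weight
    applies to every non-background class, so foreground pixels always count
    twice as much as background pixels.
    """
    if n_classes < 1:
        raise ValueError(f"n_classes must be >= 1, got {n_classes}")
    return 1.0 / (1 + 2 * n_classes), 2.0 / (1 + 2 * n_classes)


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

def _im2col3(x: np.ndarray) -> np.ndarray:
    """3x3 same-padding patches: (N,C,H,W) -> (N,H,W,C*9)."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    s = xp.strides
    win = np.lib.stride_tricks.as_strided(
        xp, (n, c, h, w, 3, 3), (s[0], s[1], s[2], s[3], s[2], s[3]))
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h, w, c * 9)


class _Conv3x3:
    def __init__(self, cin, cout, rng):
        std = np.sqrt(2.0 / (cin * 9))
        self.W = rng.normal(0.0, std, size=(cout, cin * 9))
        self.b = np.zeros(cout)
        self.cin, self.cout = cin, cout

    def forward(self, x):
        self._cols = _im2col3(x)
        self._shape = x.shape
        y = self._cols @ self.W.T + self.b
        return y.transpose(0, 3, 1, 2)

    def backward(self, dy):
        n, _, h, w = self._shape
        d = dy.transpose(0, 2, 3, 1).reshape(-1, self.cout)
        self.dW = d.T @ self._cols.reshape(-1, self.cin * 9)
        self.db = d.sum(axis=0)
        dcols = (d @ self.W).reshape(n, h, w, self.cin, 3, 3)
        dxp = np.zeros((n, self.cin, h + 2, w + 2))
        for p in range(3):
            for q in range(3):
                dxp[:, :, p:p + h, q:q + w] += dcols[:, :, :, :, p, q].transpose(0, 3, 1, 2)
        return dxp[:, :, 1:-1, 1:-1]

    def params(self):
        return [("W", self), ("b", self)]


class _Conv1x1:
    def __init__(self, cin, cout, rng):
        self.W = rng.normal(0.0, np.sqrt(2.0 / cin), size=(cout, cin))
        self.b = np.zeros(cout)

    def forward(self, x):
        self._x = x
        return np.einsum("oc,nchw->nohw", self.W, x) + self.b[None, :, None, None]

    def backward(self, dy):
        self.dW = np.einsum("nohw,nchw->oc", dy, self._x)
        self.db = dy.sum(axis=(0, 2, 3))
        return np.einsum("oc,nohw->nchw", self.W, dy)


class _ReLU:
    def forward(self, x):
        self._m = x > 0
        return x * self._m

    def backward(self, dy):
        return dy * self._m


class _MaxPool2:
    def forward(self, x):
        n, c, h, w = x.shape
        r = x.reshape(n, c, h // 2, 2, w // 2, 2)
        y = r.max(axis=(3, 5))
        self._mask = r == y[:, :, :, None, :, None]
        # break ties deterministically: keep only the first max per window
        flat = self._mask.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        first = np.cumsum(flat, axis=-1) == 1
        self._mask = (flat & first).reshape(n, c, h // 2, w // 2, 2, 2) \
            .transpose(0, 1, 2, 4, 3, 5)
        self._shape = x.shape
        return y

    def backward(self, dy):
        n, c, h, w = self._shape
        d = self._mask * dy[:, :, :, None, :, None]
        return d.reshape(n, c, h, w)


class _TConv2x2:
    """Stride-2 transpose convolution (the up-sampling step)."""

    def __init__(self, cin, cout, rng):
        self.W = rng.normal(0.0, np.sqrt(2.0 / cin), size=(cin, cout, 2, 2))
        self.b = np.zeros(cout)

    def forward(self, x):
        self._x = x
        n, c, h, w = x.shape
        t = np.einsum("ncij,copq->noipjq", x, self.W)
        return t.reshape(n, -1, 2 * h, 2 * w) + self.b[None, :, None, None]

    def backward(self, dy):
        n, _, h2, w2 = dy.shape
        t = dy.reshape(n, dy.shape[1], h2 // 2, 2, w2 // 2, 2)
        self.dW = np.einsum("ncij,noipjq->copq", self._x, t)
        self.db = dy.sum(axis=(0, 2, 3))
        return np.einsum("noipjq,copq->ncij", t, self.W)


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

@dataclass
class NetConfig:
    """Configuration of the segmentation stage.

    ``classes`` lists the plate labels this network predicts (all four for a
    coronal network; the medial or lateral pair for per-compartment sagittal
    networks). The transpose convolutions output ``len(classes)`` feature
    maps (the architecture delta).
    """

    classes: tuple[int, ...] = (1, 2, 3, 4)
    slice_shape: tuple[int, int] = (64, 64)
    epochs: int = 50
    learning_rate: float = 0.01
    decay_rate: float = 0.1
    decay_step_frac: float = 0.5     # staircase drop at this fraction of epochs
    beta1: float = 0.9
    beta2: float = 0.999
    corner: int = 15
    base_width: int = 16
    batch_size: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be > 0")
        if not self.classes or 0 in self.classes:
            raise ValueError("classes must be non-empty and exclude background")


class UNet2D:
    """4-level encoder–decoder U-Net over numpy arrays."""

    def __init__(self, cfg: NetConfig):
        self.cfg = cfg
        b, c = cfg.base_width, len(cfg.classes)
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(0,)))
        mk = lambda ci, co: (_Conv3x3(ci, co, rng), _ReLU())
        self.enc = [[*mk(1, b), *mk(b, b)],
                    [*mk(b, 2 * b), *mk(2 * b, 2 * b)],
                    [*mk(2 * b, 4 * b), *mk(4 * b, 4 * b)]]
        self.bott = [*mk(4 * b, 8 * b), *mk(8 * b, 8 * b)]
        self.up = [_TConv2x2(8 * b, c, rng), _TConv2x2(4 * b, c, rng),
                   _TConv2x2(2 * b, c, rng)]
        self.dec = [[*mk(4 * b + c, 4 * b), *mk(4 * b, 4 * b)],
                    [*mk(2 * b + c, 2 * b), *mk(2 * b, 2 * b)],
                    [*mk(b + c, b), *mk(b, b)]]
        self.pools = [_MaxPool2() for _ in range(3)]
        self.final = _Conv1x1(b, c + 1, rng)

    def _layers(self):
        out = []
        for blk in self.enc + [self.bott] + self.dec:
            out.extend(blk)
        out.extend(self.up)
        out.append(self.final)
        return [l for l in out if hasattr(l, "W")]

    def forward(self, x: np.ndarray) -> np.ndarray:
        skips = []
        for level, blk in enumerate(self.enc):
            for layer in blk:
                x = layer.forward(x)
            skips.append(x)
            x = self.pools[level].forward(x)
        for layer in self.bott:
            x = layer.forward(x)
        self._splits = []
        for level in range(3):
            u = self.up[level].forward(x)
            skip = skips[2 - level]
            self._splits.append(skip.shape[1])
            x = np.concatenate([skip, u], axis=1)
            for layer in self.dec[level]:
                x = layer.forward(x)
        return self.final.forward(x)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.final.backward(dlogits)
        dskips = [None, None, None]
        for level in range(2, -1, -1):
            for layer in reversed(self.dec[level]):
                d = layer.backward(d)
            ns = self._splits[level]
            dskip, du = d[:, :ns], d[:, ns:]
            dskips[2 - level] = dskip
            d = self.up[level].backward(du)
        for layer in reversed(self.bott):
            d = layer.backward(d)
        for level in range(2, -1, -1):
            d = self.pools[level].backward(d)
            d = d + dskips[level] if dskips[level] is not None else d
            for layer in reversed(self.enc[level]):
                d = layer.backward(d)

    # -- weight state -----------------------------------------------------
    def get_weights(self) -> dict[str, np.ndarray]:
        return {f"p{i}_{n}": getattr(l, n).copy()
                for i, l in enumerate(self._layers()) for n in ("W", "b")}

    def set_weights(self, state: dict[str, np.ndarray]) -> None:
        for i, l in enumerate(self._layers()):
            for n in ("W", "b"):
                setattr(l, n, state[f"p{i}_{n}"].copy())


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _weighted_ce(logits: np.ndarray, target: np.ndarray,
                 w_bg: float, w_fg: float) -> tuple[float, np.ndarray]:
    """Weighted cross-entropy loss (weighted pixel mean) and its gradient."""
    p = _softmax(logits)
    wmap = np.where(target > 0, w_fg, w_bg)
    pt = np.take_along_axis(p, target[:, None], axis=1)[:, 0]
    loss = float((wmap * -np.log(np.maximum(pt, 1e-12))).sum() / wmap.sum())
    onehot = np.zeros_like(p)
    np.put_along_axis(onehot, target[:, None], 1.0, axis=1)
    dlogits = wmap[:, None] * (p - onehot) / wmap.sum()
    return loss, dlogits


class _Adam:
    def __init__(self, layers, cfg: NetConfig):
        self.layers, self.cfg = layers, cfg
        self.m = [np.zeros_like(getattr(l, n)) for l in layers for n in ("W", "b")]
        self.v = [np.zeros_like(x) for x in self.m]
        self.t = 0

    def step(self, lr: float) -> None:
        cfg = self.cfg
        self.t += 1
        i = 0
        for l in self.layers:
            for n in ("W", "b"):
                g = getattr(l, "d" + n)
                self.m[i] = cfg.beta1 * self.m[i] + (1 - cfg.beta1) * g
                self.v[i] = cfg.beta2 * self.v[i] + (1 - cfg.beta2) * g * g
                mh = self.m[i] / (1 - cfg.beta1 ** self.t)
                vh = self.v[i] / (1 - cfg.beta2 ** self.t)
                setattr(l, n, getattr(l, n) - lr * mh / (np.sqrt(vh) + 1e-8))
                i += 1


# ---------------------------------------------------------------------------
# Training / inference
# ---------------------------------------------------------------------------

@dataclass
class TrainingRecord:
    """Per-epoch loss / validation Dice and the selected best weights."""

    train_loss: list[float]
    val_dsc: list[float]
    selected_epoch: int
    weights: dict[str, np.ndarray]
    config: NetConfig

    def __post_init__(self) -> None:
        if self.val_dsc and self.val_dsc[self.selected_epoch] != max(self.val_dsc):
            raise AssertionError("selected epoch must attain the best validation DSC")


def filter_segmented(slices, classes) -> list:
    """Keep only slices containing at least one pixel of the given classes."""
    keep = [s for s in slices if np.isin(s[1], classes).any()]
    return keep


def _encode_target(lab: np.ndarray, classes: tuple[int, ...]) -> np.ndarray:
    out = np.zeros(lab.shape, dtype=np.int64)
    for i, c in enumerate(sorted(classes), start=1):
        out[lab == c] = i
    return out


def mean_foreground_dsc(model: UNet2D, slices, cfg: NetConfig) -> float:
    """Mean per-class Dice over pooled validation pixels."""
    n_cls = len(cfg.classes)
    inter = np.zeros(n_cls)
    size = np.zeros(n_cls)
    for img, lab in slices:
        x = preprocess_slice(img, cfg.corner)[None, None]
        pred = np.argmax(model.forward(x)[0], axis=0)
        t = _encode_target(lab, cfg.classes)
        for c in range(1, n_cls + 1):
            inter[c - 1] += 2 * np.count_nonzero((pred == c) & (t == c))
            size[c - 1] += np.count_nonzero(pred == c) + np.count_nonzero(t == c)
    dscs = np.where(size > 0, inter / np.maximum(size, 1), 1.0)
    return float(dscs.mean())


def train_model(train_slices, val_slices, cfg: NetConfig) -> TrainingRecord:
    """Train a U-Net and return the record with best-validation weights.

    ``train_slices``/``val_slices`` are lists of ``(image2d, label2d)``
    pairs; only slices containing a configured class are trained on.
    Fully reproducible for a fixed config seed.
    """
    train = filter_segmented(train_slices, cfg.classes)
    if not train:
        raise ValueError("no training slices contain the configured classes")
    w_bg, w_fg = class_weights(len(cfg.classes))
    model = UNet2D(cfg)
    opt = _Adam(model._layers(), cfg)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(1,)))
    x_all = np.stack([preprocess_slice(img, cfg.corner) for img, _ in train])
    t_all = np.stack([_encode_target(lab, cfg.classes) for _, lab in train])
    drop_at = max(1, int(np.floor(cfg.epochs * cfg.decay_step_frac)))
    losses, dscs = [], []
    best = (-1.0, 0, None)
    for epoch in range(cfg.epochs):
        lr = cfg.learning_rate * (cfg.decay_rate if epoch >= drop_at
                                  and cfg.epochs > 1 else 1.0)
        order = rng.permutation(len(train))
        ep_loss, nb = 0.0, 0
        for s in range(0, len(order), cfg.batch_size):
            sel = order[s:s + cfg.batch_size]
            loss, dlog = _weighted_ce(model.forward(x_all[sel][:, None]),
                                      t_all[sel], w_bg, w_fg)
            model.backward(dlog)
            opt.step(lr)
            ep_loss += loss
            nb += 1
        losses.append(ep_loss / nb)
        d = mean_foreground_dsc(model, val_slices, cfg) if val_slices else 0.0
        dscs.append(d)
        if d > best[0]:
            best = (d, epoch, model.get_weights())
        logger.info("epoch %d: loss %.4f val DSC %.4f", epoch, losses[-1], d)
    weights = best[2] if best[2] is not None else model.get_weights()
    model.set_weights(weights)
    return TrainingRecord(train_loss=losses, val_dsc=dscs,
                          selected_epoch=best[1], weights=weights, config=cfg)


def segment_volume(record: TrainingRecord, gray: np.ndarray,
                   spacing, plane: str, axes: dict,
                   return_probs: bool = False):
    """Per-slice argmax segmentation of a grayscale volume.

    The output is not quality-controlled or corrected. With
    ``return_probs=True`` the per-voxel winning softmax probability is also
    returned (used for merging per-compartment networks).
    """
    cfg = record.config
    if gray.shape[:2] != tuple(cfg.slice_shape):
        raise ValueError(f"slice shape {gray.shape[:2]} does not match "
                         f"config {cfg.slice_shape}")
    model = UNet2D(cfg)
    model.set_weights(record.weights)
    classes = sorted(cfg.classes)
    out = np.zeros(gray.shape, dtype=np.int16)
    probs = np.zeros(gray.shape)
    for k in range(gray.shape[2]):
        x = preprocess_slice(gray[:, :, k], cfg.corner)[None, None]
        p = _softmax(model.forward(x))[0]
        pred = np.argmax(p, axis=0)
        probs[:, :, k] = np.take_along_axis(p, pred[None], axis=0)[0]
        for i, c in enumerate(classes, start=1):
            out[:, :, k][pred == i] = c
    vol = LabelVolume(out, spacing, plane, axes)
    return (vol, probs) if return_probs else vol


def merge_segmentations(preds: list[tuple[LabelVolume, np.ndarray]]
                        ) -> LabelVolume:
    """Merge per-compartment network outputs into one label volume.

    Non-overlapping foreground is united; where two networks claim the same
    voxel, the higher softmax score wins and ties go to the lower label id.
    Conflicts are logged.
    """
    base, prob = preds[0][0].copy(), preds[0][1].copy()
    conflicts = 0
    for vol, p in preds[1:]:
        fg = vol.voxels > 0
        take = fg & (base.voxels == 0)
        clash = fg & (base.voxels > 0) & (base.voxels != vol.voxels)
        conflicts += int(np.count_nonzero(clash))
        win = clash & ((p > prob) | ((p == prob) & (vol.voxels < base.voxels)))
        base.voxels[take] = vol.voxels[take]
        prob[take] = p[take]
        base.voxels[win] = vol.voxels[win]
        prob[win] = p[win]
    if conflicts:
        logger.info("merge_segmentations: %d conflicting voxels", conflicts)
    return base


def save_model(record: TrainingRecord, path) -> None:
    """Store weights (npz) plus a JSON manifest of config and selection."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **record.weights)
    manifest = {"config": asdict(record.config),
                "selected_epoch": record.selected_epoch,
                "train_loss": record.train_loss, "val_dsc": record.val_dsc}
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=1))


def load_model(path) -> TrainingRecord:
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    cfg_d = manifest["config"]
    cfg_d["classes"] = tuple(cfg_d["classes"])
    cfg_d["slice_shape"] = tuple(cfg_d["slice_shape"])
    cfg = NetConfig(**cfg_d)
    with np.load(path.with_suffix(".npz")) as z:
        weights = {k: z[k] for k in z.files}
    return TrainingRecord(train_loss=manifest["train_loss"],
                          val_dsc=manifest["val_dsc"],
                          selected_epoch=manifest["selected_epoch"],
                          weights=weights, config=cfg)
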