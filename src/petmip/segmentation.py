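"""Pluggable 2D lymphoma segmenters for PET MIP images.

Two segmenters share one contract — a 2D MIP in, a binary MIP mask of the same
shape out, coronal and sagittal views handled by the same model:

* :func:`baseline_segment` — a deterministic relative-intensity thresholder
  with optional physiologic-region templates (brain/heart/bladder analogues
  are removed from the candidates, mirroring how readers discard physiologic
  uptake).  It is pure and stateless, so the downstream pipeline is testable
  without any training.
* :class:`MipSegmenterCNN` — a compact encoder-decoder convolutional network
  (three resolution levels with skip connections, ~7k parameters) implemented
  directly on numpy with im2col convolutions, manual backpropagation and Adam.
  Inputs are intensity-normalized (clipped at the 99.9th percentile, scaled to
  [0, 1]) with an added vertical-coordinate channel so the network can learn
  the axial position of physiologic hot regions.  Loss is the sum of a soft
  Dice term and a binary cross-entropy whose rare lesion pixels are upweighted
  (``pos_weight``); the output bias starts at the low lesion prior so the
  sigmoid is not saturated at initialization.

The training harness follows the evaluation protocol used for MIP biomarker
studies: the coronal and sagittal views are independent training samples, but
cross-validation folds are split **by patient**, never by view.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.special import expit

from petmip.projection import MipImage, MipMask

__all__ = [
    "BaselineConfig",
    "CnnConfig",
    "TrainingSplit",
    "MipSegmenterCNN",
    "baseline_segment",
    "make_split",
    "train_cnn",
    "predict",
]


# ---------------------------------------------------------------------------
# baseline segmenter
# ---------------------------------------------------------------------------


@dataclass
class BaselineConfig:
    """Relative-intensity threshold segmenter settings.

    ``threshold`` is the fraction of the robust intensity range above which a
    pixel is a lesion candidate.  The robust maximum is the maximum of the
    3x3-median-filtered image (isolated noise spikes cannot set it, while any
    lesion plateau of a few pixels can — a fixed high percentile would miss
    lesions occupying a tiny image fraction); the robust minimum is the 1st
    intensity percentile.  Pixels inside a physiologic template are excluded
    both from the candidates and from the robust-range estimate, so hot organs
    neither count as lesions nor inflate the cutoff.
    """

    threshold: float = 0.5
    robust_lo_percentile: float = 1.0
    physiologic_templates: dict[str, np.ndarray] = field(default_factory=dict)


def baseline_segment(mip: MipImage, config: BaselineConfig | None = None) -> MipMask:
    """Deterministic thresholding segmenter.

    A pixel is a lesion iff its intensity strictly exceeds
    ``lo + threshold * (hi - lo)`` with (lo, hi) the robust range of the
    non-physiologic pixels; an all-constant image therefore yields an empty
    mask.  Pure and stateless: identical input gives identical output.
    """
    config = config or BaselineConfig()
    img = mip.data
    if img.size == 0:
        raise ValueError("empty MIP image")
    template = config.physiologic_templates.get(mip.view)
    if template is not None:
        template = np.asarray(template, dtype=bool)
        if template.shape != img.shape:
            raise ValueError(f"template shape {template.shape} != image shape {img.shape}")
        keep = ~template
    else:
        keep = np.ones(img.shape, dtype=bool)
    smoothed = ndimage.median_filter(img, size=3, mode="nearest")
    lo = np.percentile(img[keep], config.robust_lo_percentile)
    hi = smoothed[keep].max()
    cutoff = lo + config.threshold * (hi - lo)
    mask = (img > cutoff) & keep
    return MipMask(data=mask.astype(np.uint8), pixel_spacing=mip.pixel_spacing, view=mip.view)


# ---------------------------------------------------------------------------
# patientwise cross-validation splits
# ---------------------------------------------------------------------------


@dataclass
class TrainingSplit:
    """Fold assignment per patient (both views of a patient share a fold)."""

    fold_of: dict[str, int]
    k: int

    def patients(self, fold: int, role: str = "validation") -> list[str]:
        if role == "validation":
            return [p for p, f in self.fold_of.items() if f == fold]
        return [p for p, f in self.fold_of.items() if f != fold]


def make_split(patient_ids, k: int = 5, seed: int = 0) -> TrainingSplit:
    """Randomly partition patients into *k* folds of size within +-1."""
    ids = list(patient_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("patient ids must be unique")
    if len(ids) < k:
        raise ValueError(f"need at least {k} patients for {k} folds, got {len(ids)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    fold_of = {ids[j]: i % k for i, j in enumerate(order)}
    return TrainingSplit(fold_of=fold_of, k=k)


# ---------------------------------------------------------------------------
# numpy encoder-decoder
# ---------------------------------------------------------------------------


@dataclass
class CnnConfig:
    grid: int = 64  # model input size (grid x grid)
    base_width: int = 8  # channels at the finest level
    learning_rate: float = 2e-2
    epochs: int = 10
    batch_size: int = 4
    pos_weight: float = 8.0  # lesion-pixel weight in the cross-entropy (masks are sparse)
    binarization_cutoff: float = 0.5
    clip_percentile: float = 99.9
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.binarization_cutoff < 1:
            raise ValueError("binarization cutoff must be in (0, 1)")


def _resize(arr: np.ndarray, shape: tuple[int, int], order: int) -> np.ndarray:
    """Exact-shape resize by center-aligned coordinate mapping."""
    if arr.shape == shape:
        return arr.astype(float)
    coords = np.meshgrid(
        *[(np.arange(n_out) + 0.5) * n_in / n_out - 0.5 for n_out, n_in in zip(shape, arr.shape)],
        indexing="ij",
    )
    return ndimage.map_coordinates(arr.astype(float), coords, order=order, mode="nearest")


def _normalize(img: np.ndarray, clip_percentile: float) -> np.ndarray:
    hi = np.percentile(img, clip_percentile)
    if hi <= 0:
        return np.zeros_like(img, dtype=float)
    return np.clip(img, 0, hi) / hi


def _to_model_grid(img: np.ndarray, grid: int, order: int) -> tuple[np.ndarray, tuple]:
    """Aspect-preserving resize to fit in (grid, grid), then zero-pad."""
    h, w = img.shape
    scale = grid / max(h, w)
    nh, nw = max(2, round(h * scale)), max(2, round(w * scale))
    resized = _resize(img, (nh, nw), order)
    out = np.zeros((grid, grid), dtype=float)
    out[:nh, :nw] = resized
    return out, (h, w, nh, nw)


def _from_model_grid(arr: np.ndarray, transform: tuple, order: int) -> np.ndarray:
    h, w, nh, nw = transform
    return _resize(arr[:nh, :nw], (h, w), order)


def _conv_forward(x, Wk, b):
    # x: (B, H, W, Cin); Wk: (9, Cin, Cout)
    B, H, W, Cin = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    cols = np.empty((B, H, W, 9, Cin))
    for k in range(9):
        di, dj = divmod(k, 3)
        cols[:, :, :, k, :] = xp[:, di : di + H, dj : dj + W, :]
    y = np.tensordot(cols, Wk, axes=([3, 4], [0, 1])) + b
    return y, cols


def _conv_backward(dy, cols, Wk):
    B, H, W, _ = dy.shape
    dWk = np.tensordot(cols, dy, axes=([0, 1, 2], [0, 1, 2]))
    db = dy.sum(axis=(0, 1, 2))
    dcols = np.tensordot(dy, Wk, axes=([3], [2]))  # (B,H,W,9,Cin)
    Cin = Wk.shape[1]
    dxp = np.zeros((B, H + 2, W + 2, Cin))
    for k in range(9):
        di, dj = divmod(k, 3)
        dxp[:, di : di + H, dj : dj + W, :] += dcols[:, :, :, k, :]
    return dxp[:, 1 : H + 1, 1 : W + 1, :], dWk, db


def _pool2(x):
    B, H, W, C = x.shape
    return x.reshape(B, H // 2, 2, W // 2, 2, C).mean(axis=(2, 4))


def _pool2_backward(dy):
    return np.repeat(np.repeat(dy, 2, axis=1), 2, axis=2) / 4.0


def _up2(x):
    return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)


def _up2_backward(dy):
    B, H, W, C = dy.shape
    return dy.reshape(B, H // 2, 2, W // 2, 2, C).sum(axis=(2, 4))


class MipSegmenterCNN:
    """Compact encoder-decoder for MIP lesion segmentation (numpy backend).

    Architecture (base width C): conv-relu(2->C) / pool / conv-relu(C->2C) /
    pool / conv-relu(2C->2C) / up / concat / conv-relu(4C->C) / up / concat /
    conv-relu(2C->C) / 1x1 conv -> logit.  Trained with Adam on equally
    weighted soft-Dice + binary cross-entropy.
    """

    def __init__(self, config: CnnConfig | None = None):
        self.config = config or CnnConfig()
        self.params: dict[str, np.ndarray] | None = None
        self._adam_m: dict[str, np.ndarray] = {}
        self._adam_v: dict[str, np.ndarray] = {}
        self._adam_t = 0

    # -- parameters -----------------------------------------------------
    def _init_params(self, rng: np.random.Generator) -> None:
        C = self.config.base_width

        def conv(cin, cout):
            return rng.normal(0.0, np.sqrt(2.0 / (9 * cin)), size=(9, cin, cout))

        self.params = {
            "W1": conv(2, C), "b1": np.zeros(C),
            "W2": conv(C, 2 * C), "b2": np.zeros(2 * C),
            "W3": conv(2 * C, 2 * C), "b3": np.zeros(2 * C),
            "W4": conv(4 * C, C), "b4": np.zeros(C),
            "W5": conv(2 * C, C), "b5": np.zeros(C),
            # start the output near the (low) lesion prior so the sigmoid
            # is not saturated and the Dice gradient can flow
            "W6": rng.normal(0.0, np.sqrt(2.0 / C), size=(C, 1)), "b6": np.full(1, -2.0),
        }
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # -- forward / backward ---------------------------------------------
    def _forward(self, x):
        p = self.params
        z1, c1 = _conv_forward(x, p["W1"], p["b1"]); a1 = np.maximum(z1, 0)
        d1 = _pool2(a1)
        z2, c2 = _conv_forward(d1, p["W2"], p["b2"]); a2 = np.maximum(z2, 0)
        d2 = _pool2(a2)
        z3, c3 = _conv_forward(d2, p["W3"], p["b3"]); a3 = np.maximum(z3, 0)
        u2 = np.concatenate([_up2(a3), a2], axis=3)
        z4, c4 = _conv_forward(u2, p["W4"], p["b4"]); a4 = np.maximum(z4, 0)
        u1 = np.concatenate([_up2(a4), a1], axis=3)
        z5, c5 = _conv_forward(u1, p["W5"], p["b5"]); a5 = np.maximum(z5, 0)
        logits = np.tensordot(a5, p["W6"], axes=([3], [0])) + p["b6"]
        cache = (x, z1, c1, a1, z2, c2, a2, z3, c3, a3, u2, z4, c4, a4, u1, z5, c5, a5)
        return logits[..., 0], cache

    def _backward(self, dlogits, cache):
        p = self.params
        (x, z1, c1, a1, z2, c2, a2, z3, c3, a3, u2, z4, c4, a4, u1, z5, c5, a5) = cache
        g: dict[str, np.ndarray] = {}
        dl = dlogits[..., None]
        g["W6"] = np.tensordot(a5, dl, axes=([0, 1, 2], [0, 1, 2]))
        g["b6"] = dl.sum(axis=(0, 1, 2))
        da5 = np.tensordot(dl, p["W6"], axes=([3], [1])) * (z5 > 0)
        du1, g["W5"], g["b5"] = _conv_backward(da5, c5, p["W5"])
        C4 = a4.shape[3]
        da4 = _up2_backward(du1[..., :C4]) * (z4 > 0)
        da1_skip = du1[..., C4:]
        du2, g["W4"], g["b4"] = _conv_backward(da4, c4, p["W4"])
        C3 = a3.shape[3]
        da3 = _up2_backward(du2[..., :C3]) * (z3 > 0)
        da2_skip = du2[..., C3:]
        dd2, g["W3"], g["b3"] = _conv_backward(da3, c3, p["W3"])
        da2 = (_pool2_backward(dd2) + da2_skip) * (z2 > 0)
        dd1, g["W2"], g["b2"] = _conv_backward(da2, c2, p["W2"])
        da1 = (_pool2_backward(dd1) + da1_skip) * (z1 > 0)
        _, g["W1"], g["b1"] = _conv_backward(da1, c1, p["W1"])
        return g

    @staticmethod
    def _loss_grad(logits, targets, pos_weight: float = 8.0):
        """Weighted BCE + soft Dice, equally summed; returns (loss, dloss/dlogits).

        Lesion pixels are rare, so the cross-entropy weights them by
        ``pos_weight``; the Dice term is differentiated through the sigmoid
        analytically (its gradient vanishes where the sigmoid saturates, which
        the bias initialization and the weighted BCE counteract).
        """
        prob = expit(logits)
        B = logits.shape[0]
        npix = logits[0].size
        eps = 1.0
        w = np.where(targets > 0, pos_weight, 1.0)
        bce = float(np.sum(-w * (targets * np.log(prob + 1e-12) + (1 - targets) * np.log(1 - prob + 1e-12)))) / (
            B * npix
        )
        dbce_dz = w * (prob - targets) / (B * npix)
        inter = (prob * targets).sum(axis=(1, 2))
        denom = prob.sum(axis=(1, 2)) + targets.sum(axis=(1, 2)) + eps
        dice = (2 * inter + eps) / denom
        ddice_dp = (2 * targets * denom[:, None, None] - (2 * inter + eps)[:, None, None]) / denom[:, None, None] ** 2
        ddice_dz = -ddice_dp / B * prob * (1 - prob)
        return float(bce + (1 - dice.mean())), dbce_dz + ddice_dz

    def _adam_step(self, grads):
        lr, b1, b2, eps = self.config.learning_rate, 0.9, 0.999, 1e-8
        self._adam_t += 1
        t = self._adam_t
        for k, gk in grads.items():
            self._adam_m[k] = b1 * self._adam_m[k] + (1 - b1) * gk
            self._adam_v[k] = b2 * self._adam_v[k] + (1 - b2) * gk**2
            mhat = self._adam_m[k] / (1 - b1**t)
            vhat = self._adam_v[k] / (1 - b2**t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    # -- public API ------------------------------------------------------
    def _prepare(self, mip: MipImage):
        img, transform = _to_model_grid(_normalize(mip.data, self.config.clip_percentile), self.config.grid, order=1)
        vcoord = np.tile(np.linspace(0, 1, self.config.grid), (self.config.grid, 1))
        x = np.stack([img, vcoord], axis=-1)
        return x, transform

    def fit(self, samples: list[tuple[MipImage, MipMask]], epochs: int | None = None, rng=None) -> list[float]:
        """Train on (image, mask) samples; returns per-epoch mean loss."""
        rng = rng if rng is not None else np.random.default_rng(self.config.seed)
        if self.params is None:
            self._init_params(rng)
        xs, ys = [], []
        for img, msk in samples:
            x, tf = self._prepare(img)
            y, _ = _to_model_grid(msk.data.astype(float), self.config.grid, order=0)
            xs.append(x)
            ys.append(y)
        X = np.stack(xs)
        Y = np.stack(ys)
        losses = []
        bs = self.config.batch_size
        for _ in range(epochs if epochs is not None else self.config.epochs):
            order = rng.permutation(len(X))
            epoch_loss = 0.0
            for start in range(0, len(X), bs):
                idx = order[start : start + bs]
                logits, cache = self._forward(X[idx])
                loss, dlogits = self._loss_grad(logits, Y[idx], self.config.pos_weight)
                grads = self._backward(dlogits, cache)
                self._adam_step(grads)
                epoch_loss += loss * len(idx)
            losses.append(epoch_loss / len(X))
        return losses

    def predict_mask(self, mip: MipImage) -> MipMask:
        if self.params is None:
            raise RuntimeError("model is untrained; call fit() first")
        x, transform = self._prepare(mip)
        logits, _ = self._forward(x[None])
        prob = expit(logits[0])
        native = _from_model_grid(prob, transform, order=1)
        mask = native >= self.config.binarization_cutoff
        return MipMask(data=mask.astype(np.uint8), pixel_spacing=mip.pixel_spacing, view=mip.view)


def predict(mip: MipImage, model: MipSegmenterCNN) -> MipMask:
    """Apply a trained model to one MIP (either view); shape-preserving."""
    return model.predict_mask(mip)


def _dice(a: np.ndarray, b: np.ndarray) -> float:
    denom = a.sum() + b.sum()
    return 1.0 if denom == 0 else 2.0 * float((a & b).sum()) / float(denom)


def train_cnn(
    samples: list[tuple[str, MipImage, MipMask]],
    split: TrainingSplit,
    config: CnnConfig | None = None,
) -> tuple[dict[int, MipSegmenterCNN], dict[int, float]]:
    """K-fold cross-validated training on per-view samples.

    ``samples`` are (patient_id, image, mask) triples — coronal and sagittal
    views are independent samples but always land in the same fold as their
    patient.  Returns one trained model per fold and the per-fold mean
    validation Dice.  A fold whose training set has no lesion pixels is
    skipped with a warning.
    """
    config = config or CnnConfig()
    patients = {pid for pid, _, _ in samples}
    if len(patients) < 10:
        raise ValueError(f"need >= 10 patients to train, got {len(patients)}")
    missing = patients - set(split.fold_of)
    if missing:
        raise ValueError(f"patients missing from split: {sorted(missing)[:5]}")
    models: dict[int, MipSegmenterCNN] = {}
    fold_dice: dict[int, float] = {}
    for fold in range(split.k):
        train_s = [(img, msk) for pid, img, msk in samples if split.fold_of[pid] != fold]
        val_s = [(pid, img, msk) for pid, img, msk in samples if split.fold_of[pid] == fold]
        if not val_s or not train_s:
            warnings.warn(f"fold {fold}: empty train or validation set; skipped", stacklevel=2)
            continue
        if sum(int(m.data.sum()) for _, m in train_s) == 0:
            warnings.warn(f"fold {fold}: no lesion pixels in training data; skipped", stacklevel=2)
            continue
        cfg = CnnConfig(**{**config.__dict__, "seed": config.seed + fold})
        model = MipSegmenterCNN(cfg)
        model.fit(train_s)
        dices = [_dice(model.predict_mask(img).data.astype(bool), msk.data.astype(bool)) for _, img, msk in val_s]
        models[fold] = model
        fold_dice[fold] = float(np.mean(dices))
    return models, fold_dice
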