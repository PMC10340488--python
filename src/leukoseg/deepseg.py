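"""Deep-learning nuclei segmentation: U-Net, Mish, Unified Focal Loss, k-fold harness.

The segmenter is a five-level encoder–decoder with skip connections.  Channel
widths expand 32 -> 512 along the encoder; downsampling is by strided
convolution (stride 1 at the first level, 2 afterwards, so the bottleneck is
1/16 of the input resolution).  Blocks use instance normalization, dropout
and the Mish activation.  Training uses the Unified Focal Loss — a λ-mixture
of a focal (distribution-based) term and a focal Tversky (region-based) term
— with Adam and plateau-based learning-rate reduction, under 10-fold
cross-validation with on-the-fly augmentation.

The network runs on the package's own NumPy autodiff engine
(:mod:`leukoseg.nn`), so it is sized for CPU-scale experiments rather than
full-resolution clinical training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import exposure
from skimage.transform import resize

from . import nn
from .exceptions import ConfigError, DimensionError, ModelError
from .metrics import evaluate


# --------------------------------------------------------------------------
# activation & loss
# --------------------------------------------------------------------------

def mish(x):
    """Mish activation, x * tanh(ln(1 + e^x)), numerically stable elementwise."""
    x = np.asarray(x, dtype=np.float64)
    return x * np.tanh(np.logaddexp(0.0, x))


@dataclass
class LossParams:
    """Unified Focal Loss parameters.

    delta weighs positive vs negative classes (and FN vs FP inside the
    Tversky index); gamma is the focusing exponent; lam mixes the focal
    (distribution-based) term with the focal Tversky (region-based) term.
    ``printed_exponent`` selects the focal modulator (1-p)^(1-gamma); set it
    to False for the conventional (1-p)^gamma.
    """

    delta: float = 0.6
    gamma: float = 0.5
    lam: float = 0.5
    n_classes: int = 2
    printed_exponent: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta <= 1.0:
            raise ConfigError(f"delta must be in [0, 1], got {self.delta}")
        if self.gamma < 0.0:
            raise ConfigError(f"gamma must be >= 0, got {self.gamma}")
        if not 0.0 <= self.lam <= 1.0:
            raise ConfigError(f"lam must be in [0, 1], got {self.lam}")
        if self.n_classes < 2:
            raise ConfigError(f"n_classes must be >= 2, got {self.n_classes}")

    @property
    def focal_exponent(self) -> float:
        return 1.0 - self.gamma if self.printed_exponent else self.gamma


_EPS = 1e-12


def _ufl_terms_numpy(pred: np.ndarray, gt: np.ndarray, params: LossParams):
    p_true = pred * gt + (1.0 - pred) * (1.0 - gt)
    p_true = np.clip(p_true, _EPS, 1.0)
    bce = -np.log(p_true)
    focal = float(np.mean(params.delta * (1.0 - p_true) ** params.focal_exponent * bce))

    tversky = 0.0
    for p_c, g_c in ((pred, gt), (1.0 - pred, 1.0 - gt)):   # foreground, background
        tp = float(np.sum(p_c * g_c))
        fn = float(np.sum((1.0 - p_c) * g_c))
        fp = float(np.sum(p_c * (1.0 - g_c)))
        mti = (tp + _EPS) / (tp + params.delta * fn + (1.0 - params.delta) * fp + _EPS)
        tversky += (1.0 - mti) ** params.gamma
    return focal, tversky


def unified_focal_loss(pred: np.ndarray, gt: np.ndarray,
                       params: LossParams | None = None) -> float:
    """Unified Focal Loss of a probability map against a binary target.

    loss = lam * focal + (1 - lam) * focal_Tversky, with the focal term
    delta * (1-p)^exponent * BCE averaged over pixels (p = probability of the
    true class) and the Tversky term summed over the foreground and
    background soft-count classes.
    """
    params = params or LossParams()
    pred = np.asarray(pred, dtype=np.float64)
    gt = np.asarray(gt, dtype=np.float64)
    if pred.shape != gt.shape:
        raise DimensionError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    if pred.min() < 0.0 or pred.max() > 1.0:
        raise ValueError("pred must be a probability map in [0, 1]")
    focal, tversky = _ufl_terms_numpy(pred, gt, params)
    return params.lam * focal + (1.0 - params.lam) * tversky


def unified_focal_loss_tensor(pred: nn.Tensor, gt: np.ndarray,
                              params: LossParams) -> nn.Tensor:
    """Differentiable Unified Focal Loss for training (same formula as above)."""
    gt = np.asarray(gt, dtype=np.float64)
    p_true = pred * gt + (1.0 - pred) * (1.0 - gt)
    p_true = p_true.clip_min(_EPS)
    bce = -p_true.log()
    base = (1.0 - p_true).clip_min(_EPS)
    focal = (params.delta * base.pow_const(params.focal_exponent) * bce).mean()

    tversky = None
    for p_c, g_c in ((pred, gt), (1.0 - pred, 1.0 - gt)):
        tp = (p_c * g_c).sum()
        fn = ((1.0 - p_c) * g_c).sum()
        fp = (p_c * (1.0 - g_c)).sum()
        mti = (tp + _EPS) / (tp + params.delta * fn + (1.0 - params.delta) * fp + _EPS)
        term = (1.0 - mti).clip_min(_EPS).pow_const(params.gamma)
        tversky = term if tversky is None else tversky + term
    return params.lam * focal + (1.0 - params.lam) * tversky


# --------------------------------------------------------------------------
# architecture
# --------------------------------------------------------------------------

@dataclass
class UNetSpec:
    """U-Net architecture contract."""

    in_channels: int = 3
    levels: int = 5
    channels_per_level: tuple[int, ...] = (32, 64, 128, 256, 512)
    strides: tuple[int, ...] = (1, 2, 2, 2, 2)
    dropout_p: float = 0.5
    out_channels: int = 1

    def __post_init__(self) -> None:
        if len(self.channels_per_level) != self.levels or len(self.strides) != self.levels:
            raise ConfigError("channels_per_level and strides must have `levels` entries")
        if any(s not in (1, 2) for s in self.strides):
            raise ConfigError("strides must be 1 or 2")
        if self.strides[0] != 1:
            raise ConfigError("first level must have stride 1")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ConfigError(f"dropout_p must be in [0, 1), got {self.dropout_p}")

    @property
    def reduction(self) -> int:
        """Total spatial reduction at the bottleneck (product of strides)."""
        return int(np.prod(self.strides))


def _he_init(rng: np.random.Generator, f: int, c: int, k: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / (c * k * k)), size=(f, c, k, k))


class _ConvBlock:
    """conv(stride) -> IN -> Mish -> dropout -> conv(1) -> IN -> Mish."""

    def __init__(self, rng, c_in: int, c_out: int, stride: int, dropout_p: float):
        self.stride = stride
        self.dropout_p = dropout_p
        self.w1 = nn.Tensor(_he_init(rng, c_out, c_in, 3), requires_grad=True)
        self.b1 = nn.Tensor(np.zeros(c_out), requires_grad=True)
        self.g1 = nn.Tensor(np.ones((1, c_out, 1, 1)), requires_grad=True)
        self.h1 = nn.Tensor(np.zeros((1, c_out, 1, 1)), requires_grad=True)
        self.w2 = nn.Tensor(_he_init(rng, c_out, c_out, 3), requires_grad=True)
        self.b2 = nn.Tensor(np.zeros(c_out), requires_grad=True)
        self.g2 = nn.Tensor(np.ones((1, c_out, 1, 1)), requires_grad=True)
        self.h2 = nn.Tensor(np.zeros((1, c_out, 1, 1)), requires_grad=True)

    def params(self):
        return [self.w1, self.b1, self.g1, self.h1, self.w2, self.b2, self.g2, self.h2]

    def __call__(self, x, rng, train):
        x = nn.conv2d(x, self.w1, self.b1, stride=self.stride, padding=1)
        x = nn.instance_norm(x, self.g1, self.h1).mish()
        x = nn.dropout(x, self.dropout_p, rng, train)
        x = nn.conv2d(x, self.w2, self.b2, stride=1, padding=1)
        return nn.instance_norm(x, self.g2, self.h2).mish()


class UNet:
    """Encoder–decoder segmentation network with skip connections.

    Forward maps (N, in_channels, H, W) -> (N, out_channels, H, W) sigmoid
    probabilities, for H, W divisible by ``spec.reduction``.
    """

    def __init__(self, spec: UNetSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        ch = spec.channels_per_level
        self.enc = []
        c_in = spec.in_channels
        for c_out, s in zip(ch, spec.strides):
            self.enc.append(_ConvBlock(rng, c_in, c_out, s, spec.dropout_p))
            c_in = c_out
        # decoder level i fuses upsampled deeper features with encoder skip i
        self.dec = []
        for i in range(spec.levels - 2, -1, -1):
            self.dec.append(_ConvBlock(rng, ch[i + 1] + ch[i], ch[i], 1, spec.dropout_p))
        self.w_out = nn.Tensor(_he_init(rng, spec.out_channels, ch[0], 1),
                               requires_grad=True)
        self.b_out = nn.Tensor(np.zeros(spec.out_channels), requires_grad=True)
        self.trained = False

    def parameters(self) -> list[nn.Tensor]:
        ps: list[nn.Tensor] = []
        for blk in self.enc + self.dec:
            ps.extend(blk.params())
        ps.extend([self.w_out, self.b_out])
        return ps

    def forward(self, x: np.ndarray, rng: np.random.Generator | None = None,
                train: bool = False) -> nn.Tensor:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 4 or x.shape[1] != self.spec.in_channels:
            raise DimensionError(
                f"expected (N, {self.spec.in_channels}, H, W) input, got {x.shape}")
        red = self.spec.reduction
        if x.shape[2] % red or x.shape[3] % red:
            raise DimensionError(
                f"spatial size {x.shape[2:]} must be divisible by {red} "
                f"(product of the level strides)")
        rng = rng or np.random.default_rng(0)
        t = nn.Tensor(x)
        skips = []
        for blk in self.enc:
            t = blk(t, rng, train)
            skips.append(t)
        for blk, skip in zip(self.dec, reversed(skips[:-1])):
            t = nn.concat_channels(nn.upsample_nearest2(t), skip)
            t = blk(t, rng, train)
        logits = nn.conv2d(t, self.w_out, self.b_out, stride=1, padding=0)
        return logits.sigmoid()

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        arrays = {f"p{i}": p.data for i, p in enumerate(self.parameters())}
        np.savez(path, trained=np.array(self.trained), **arrays)

    @classmethod
    def load(cls, path: str | Path, spec: UNetSpec | None = None) -> "UNet":
        model = cls(spec or UNetSpec(), seed=0)
        with np.load(path) as data:
            for i, p in enumerate(model.parameters()):
                stored = data[f"p{i}"]
                if stored.shape != p.data.shape:
                    raise ModelError(
                        f"checkpoint parameter {i} has shape {stored.shape}, "
                        f"expected {p.data.shape}")
                p.data = stored
            model.trained = bool(data["trained"])
        return model


def build_unet(spec: UNetSpec | None = None, seed: int = 0) -> UNet:
    """Construct a randomly initialized U-Net from its architecture spec."""
    return UNet(spec or UNetSpec(), seed=seed)


# --------------------------------------------------------------------------
# data handling: folds, augmentation
# --------------------------------------------------------------------------

@dataclass
class FoldPlan:
    """A shuffled partition of sample indices into near-equal folds."""

    n_folds: int = 10
    shuffle_seed: int = 0
    fold_assignments: np.ndarray | None = None

    def assign(self, n_samples: int) -> np.ndarray:
        if n_samples < self.n_folds:
            raise ConfigError(
                f"need at least {self.n_folds} samples for {self.n_folds} folds, "
                f"got {n_samples}")
        rng = np.random.default_rng(self.shuffle_seed)
        order = rng.permutation(n_samples)
        assignments = np.empty(n_samples, dtype=np.intp)
        for k, chunk in enumerate(np.array_split(order, self.n_folds)):
            assignments[chunk] = k
        self.fold_assignments = assignments
        return assignments


@dataclass
class AugmentPolicy:
    """On-the-fly training augmentation.

    Geometric transforms (vertical/horizontal flip, 90-degree rotation,
    transpose) are applied with probability 0.5 each; photometric transforms
    (random gamma, CLAHE, Gaussian noise) with probability 0.2; a resize to
    ``resize_to`` is always applied.  Validation images get only the resize.
    """

    enabled: bool = True
    resize_to: tuple[int, int] = (256, 256)
    p_geom: float = 0.5
    p_photo: float = 0.2
    gamma_range: tuple[float, float] = (0.8, 1.2)
    noise_var_limit: float = 10.0

    def apply(self, image: np.ndarray, mask: np.ndarray,
              rng: np.random.Generator, train: bool = True):
        """Return (image float [0,1] HWC, mask bool) after augmentation."""
        img = np.asarray(image, dtype=np.float64) / 255.0
        msk = np.asarray(mask, dtype=bool)
        if train and self.enabled:
            if rng.random() < self.p_geom:
                img, msk = img[::-1], msk[::-1]
            if rng.random() < self.p_geom:
                img, msk = img[:, ::-1], msk[:, ::-1]
            if rng.random() < self.p_geom:
                k = int(rng.integers(1, 4))
                img, msk = np.rot90(img, k), np.rot90(msk, k)
            if rng.random() < self.p_geom:
                img, msk = img.transpose(1, 0, 2), msk.T
            if rng.random() < self.p_photo:
                img = img ** rng.uniform(*self.gamma_range)
            if rng.random() < self.p_photo:
                img = exposure.equalize_adapthist(np.clip(img, 0, 1))
            if rng.random() < self.p_photo:
                sigma = np.sqrt(rng.uniform(0.0, self.noise_var_limit)) / 255.0
                img = img + rng.normal(0.0, sigma, img.shape)
        if img.shape[:2] != tuple(self.resize_to):
            img = resize(img, self.resize_to, order=1, anti_aliasing=True)
            msk = resize(msk.astype(float), self.resize_to, order=0,
                         anti_aliasing=False) > 0.5
        return np.ascontiguousarray(np.clip(img, 0.0, 1.0)), np.ascontiguousarray(msk)


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

@dataclass
class TrainConfig:
    epochs: int = 50
    learning_rate: float = 1e-3
    batch_size: int = 8
    lr_patience: int = 10
    seed: int = 0


def _to_batch(images: list[np.ndarray]) -> np.ndarray:
    return np.stack([img.transpose(2, 0, 1) for img in images])


def _soft_dice(pred: np.ndarray, gt: np.ndarray) -> float:
    inter = float(np.sum((pred > 0.5) & (gt > 0.5)))
    denom = float(np.sum(pred > 0.5) + np.sum(gt > 0.5))
    return 1.0 if denom == 0 else 2.0 * inter / denom


def train_unet(
    images: list[np.ndarray],
    masks: list[np.ndarray],
    spec: UNetSpec | None = None,
    params: LossParams | None = None,
    augment: AugmentPolicy | None = None,
    train_cfg: TrainConfig | None = None,
    val_images: list[np.ndarray] | None = None,
    val_masks: list[np.ndarray] | None = None,
) -> tuple[UNet, pd.DataFrame]:
    """Train a U-Net on (image, mask) pairs; returns the model and loss/IoU curves.

    Images are 8-bit HWC RGB; masks boolean.  All randomness (weight init,
    shuffling, augmentation draws, dropout) derives from ``train_cfg.seed``.
    """
    spec = spec or UNetSpec()
    params = params or LossParams()
    augment = augment or AugmentPolicy()
    cfg = train_cfg or TrainConfig()

    model = build_unet(spec, seed=cfg.seed)
    opt = nn.Adam(model.parameters(), lr=cfg.learning_rate)
    sched = nn.ReduceLROnPlateau(opt, patience=cfg.lr_patience)
    rng = np.random.default_rng(cfg.seed + 1)

    history = []
    n = len(images)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss, epoch_iou, n_batches = 0.0, 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            pairs = [augment.apply(images[i], masks[i], rng, train=True) for i in idx]
            xb = _to_batch([p[0] for p in pairs])
            yb = np.stack([p[1] for p in pairs])[:, None].astype(np.float64)
            opt.zero_grad()
            pred = model.forward(xb, rng, train=True)
            loss = unified_focal_loss_tensor(pred, yb, params)
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            epoch_iou += evaluate(pred.data > 0.5, yb > 0.5).iou
            n_batches += 1
        row = {"epoch": epoch, "train_loss": epoch_loss / n_batches,
               "train_iou": epoch_iou / n_batches,
               "val_loss": np.nan, "val_iou": np.nan, "lr": opt.lr}
        if val_images:
            vl, vi = _validate(model, val_images, val_masks, params, augment)
            row["val_loss"], row["val_iou"] = vl, vi
        history.append(row)
        sched.step(row["train_loss"])
    model.trained = True
    return model, pd.DataFrame(history)


def _validate(model, images, masks, params, augment):
    losses, ious = [], []
    for img, msk in zip(images, masks):
        x, y = augment.apply(img, msk, np.random.default_rng(0), train=False)
        pred = model.forward(_to_batch([x]), train=False)
        losses.append(unified_focal_loss(pred.data, y[None, None].astype(float), params))
        ious.append(evaluate(pred.data[0, 0] > 0.5, y).iou)
    return float(np.mean(losses)), float(np.mean(ious))


def train_crossval(
    images: list[np.ndarray],
    masks: list[np.ndarray],
    spec: UNetSpec | None = None,
    params: LossParams | None = None,
    plan: FoldPlan | None = None,
    augment: AugmentPolicy | None = None,
    train_cfg: TrainConfig | None = None,
) -> dict:
    """K-fold cross-validation: train on k-1 folds, predict the held-out fold.

    Returns {"folds": per-fold history DataFrames, "assignments": fold index
    per sample, "test_masks": predicted masks for each held-out sample,
    "test_iou": per-fold mean IoU on the held-out fold}.
    """
    plan = plan or FoldPlan()
    cfg = train_cfg or TrainConfig()
    assignments = plan.assign(len(images))
    fold_histories, fold_test_iou = [], []
    test_masks: dict[int, np.ndarray] = {}
    for k in range(plan.n_folds):
        tr = np.flatnonzero(assignments != k)
        te = np.flatnonzero(assignments == k)
        model, hist = train_unet(
            [images[i] for i in tr], [masks[i] for i in tr],
            spec, params, augment, cfg,
            val_images=[images[i] for i in te],
            val_masks=[masks[i] for i in te])
        fold_histories.append(hist)
        ious = []
        for i in te:
            pm = predict_mask(model, images[i])
            test_masks[int(i)] = pm
            ious.append(evaluate(pm, masks[i]).iou)
        fold_test_iou.append(float(np.mean(ious)))
    return {"folds": fold_histories, "assignments": assignments,
            "test_masks": test_masks, "test_iou": fold_test_iou}


def predict_mask(model: UNet, image: np.ndarray) -> np.ndarray:
    """Segment one RGB image: pad to a stride-compatible shape, threshold at 0.5."""
    if not getattr(model, "trained", False):
        raise ModelError("model has not been trained")
    img = np.asarray(image, dtype=np.float64) / 255.0
    h, w = img.shape[:2]
    red = model.spec.reduction
    ph, pw = (-h) % red, (-w) % red
    padded = np.pad(img, ((0, ph), (0, pw), (0, 0)), mode="edge")
    pred = model.forward(_to_batch([padded]), train=False)
    return pred.data[0, 0, :h, :w] > 0.5
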