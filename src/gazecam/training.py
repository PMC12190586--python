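"""Training protocol: paired augmentation, cosine-annealing warm restarts,
and the mini-batch loop minimizing CE + lambda * attention-MSE with Adam.

Gradients are computed analytically through the whole graph: GAP + linear
head for the classification term, and rectified-class-weight channel sum ->
bilinear upsample -> sigmoid -> MSE for the attention-consistency term. The
argmax that selects the predicted class is treated as a constant during
differentiation (the standard convention for CAM training).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .attention import ClassifierBundle
from .nn import Adam, bilinear_resize, bilinear_resize_backward, sigmoid, softmax

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "TrainState",
    "Sample",
    "augment",
    "scheduler_lr",
    "train",
    "evaluate_accuracy",
]


@dataclass
class TrainConfig:
    """Hyperparameters of the training protocol.

    Defaults follow the reference protocol: Adam at lr 0.001 with framework
    betas (0.9, 0.999, eps 1e-8), cosine-annealing warm restarts with
    T0 = 10 epochs and Tmult = 2, train/val batch sizes 8/16, 150 epochs,
    equal weighting of the gaze term (lambda_gaze = 1; 0 is the no-gaze
    ablation), right-angle rotations and both flips for augmentation.
    """

    lr: float = 1e-3
    t0: int = 10
    tmult: int = 2
    batch_train: int = 8
    batch_val: int = 16
    max_epochs: int = 150
    lambda_gaze: float = 1.0
    seed: int = 0
    lr_min: float = 0.0
    flip_lr: bool = True
    flip_ud: bool = True
    rotate: bool = True
    angles: tuple[int, ...] = (0, 90, 180, 270)
    relu_on: str = "weights"
    cam_class: str = "predicted"

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.t0 < 1 or self.tmult < 1:
            raise ValueError("t0 and tmult must be >= 1")
        if self.batch_train < 1 or self.batch_val < 1:
            raise ValueError("batch sizes must be >= 1")
        if self.lambda_gaze < 0:
            raise ValueError("lambda_gaze must be >= 0")
        if self.cam_class not in ("predicted", "true"):
            raise ValueError("cam_class must be 'predicted' or 'true'")


@dataclass
class Sample:
    """One training/evaluation item: image in [0,1] floats, optional
    gaze map (required when lambda_gaze > 0) and lesion mask."""

    image_id: str
    image: np.ndarray
    label: int
    gaze_map: np.ndarray | None = None
    mask: np.ndarray | None = None


@dataclass
class TrainState:
    epoch: int = 0
    best_val_acc: float = -np.inf
    best_epoch: int = -1
    history: list[dict] = field(default_factory=list)


def augment(image: np.ndarray, gaze_map: np.ndarray | None,
            rng: np.random.Generator, flip_lr: bool = True, flip_ud: bool = True,
            angles: tuple[int, ...] = (0, 90, 180, 270)):
    """Apply one random geometric transform to an image and its gaze map.

    The same draw (horizontal flip p=0.5, vertical flip p=0.5, rotation
    angle uniform over `angles`) is applied to both arrays so they stay
    spatially registered. Right-angle rotations avoid interpolation
    artifacts on the gaze map. `gaze_map` may be None (no-gaze training).
    """
    if gaze_map is not None and image.shape[:2] != gaze_map.shape:
        raise ValueError(f"image {image.shape[:2]} and gaze map "
                         f"{gaze_map.shape} shapes differ")
    do_h = flip_lr and rng.random() < 0.5
    do_v = flip_ud and rng.random() < 0.5
    angle = int(angles[rng.integers(len(angles))]) if angles else 0

    def apply(arr):
        if do_h:
            arr = arr[:, ::-1]
        if do_v:
            arr = arr[::-1, :]
        k = (angle // 90) % 4
        if k:
            arr = np.rot90(arr, k=k)
        return np.ascontiguousarray(arr)

    return apply(image), (None if gaze_map is None else apply(gaze_map))


def scheduler_lr(epoch_progress: float, cfg: TrainConfig) -> float:
    """Cosine-annealing-warm-restarts learning rate at a fractional epoch.

    Within a cycle of length T_i, lr = lr_min + (lr_max - lr_min) *
    (1 + cos(pi * t / T_i)) / 2 with lr_max = cfg.lr; cycle lengths grow
    geometrically by tmult (T0, T0*tmult, ...), restarting at lr_max.
    """
    if epoch_progress < 0:
        raise ValueError("epoch_progress must be >= 0")
    t = float(epoch_progress)
    period = float(cfg.t0)
    while t >= period:
        t -= period
        period *= cfg.tmult
    frac = (1.0 + np.cos(np.pi * t / period)) / 2.0
    return float(cfg.lr_min + (cfg.lr - cfg.lr_min) * frac)


def _train_step(bundle: ClassifierBundle, images: np.ndarray, labels: np.ndarray,
                gaze_maps: np.ndarray | None, cfg: TrainConfig,
                compute_grads: bool = True):
    """Forward + analytic backward for one mini-batch.

    Returns (ce, mse, grads) with grads aligned to bundle.parameters().
    `gaze_maps` is (B, Hg, Wg) or None when lambda_gaze == 0.
    """
    B = images.shape[0]
    W, b = bundle.head_weights, bundle.head_bias
    x = np.ascontiguousarray(images.transpose(0, 3, 1, 2))
    fmap = bundle.extractor.forward(x)          # (B, C, h, w)
    _, C, h, w = fmap.shape
    gap = fmap.mean(axis=(2, 3))                # (B, C)
    logits = gap @ W.T + b
    probs = softmax(logits, axis=1)
    ce = float(-np.mean(np.log(probs[np.arange(B), labels] + 1e-300)))

    lam = cfg.lambda_gaze
    mse = 0.0
    if lam > 0:
        if gaze_maps is None:
            raise ValueError("gaze maps required when lambda_gaze > 0")
        hg, wg = gaze_maps.shape[1], gaze_maps.shape[2]
        cls = labels if cfg.cam_class == "true" else np.argmax(logits, axis=1)
        wsel = W[cls]                            # (B, C)
        if cfg.relu_on == "weights":
            wplus = np.maximum(wsel, 0.0)
            raw = np.einsum("bc,bchw->bhw", wplus, fmap, optimize=True)
            relu_mask_map = None
        else:
            raw_signed = np.einsum("bc,bchw->bhw", wsel, fmap, optimize=True)
            relu_mask_map = raw_signed > 0
            raw = np.where(relu_mask_map, raw_signed, 0.0)
            wplus = wsel
        up = bilinear_resize(raw, hg, wg)
        att = sigmoid(up)
        resid = att - gaze_maps
        mse = float(np.mean(resid ** 2))

    if not compute_grads:
        return ce, mse, None

    onehot = np.zeros_like(probs)
    onehot[np.arange(B), labels] = 1.0
    dlogits = (probs - onehot) / B
    dW = dlogits.T @ gap
    db = dlogits.sum(axis=0)
    dgap = dlogits @ W
    dfmap = np.broadcast_to(dgap[:, :, None, None] / (h * w), fmap.shape).copy()

    if lam > 0:
        datt = (2.0 * lam / (B * hg * wg)) * resid
        dup = datt * att * (1.0 - att)
        draw = bilinear_resize_backward(dup, h, w)
        if cfg.relu_on == "map":
            draw = np.where(relu_mask_map, draw, 0.0)
            dfmap += np.einsum("bhw,bc->bchw", draw, wsel, optimize=True)
            dwsel = np.einsum("bhw,bchw->bc", draw, fmap, optimize=True)
        else:
            dfmap += np.einsum("bhw,bc->bchw", draw, wplus, optimize=True)
            dwsel = np.einsum("bhw,bchw->bc", draw, fmap, optimize=True)
            dwsel = np.where(wsel > 0, dwsel, 0.0)
        np.add.at(dW, cls, dwsel)

    bundle.extractor.backward(dfmap)
    grads = bundle.extractor.grads() + [dW, db]
    return ce, mse, grads


def evaluate_accuracy(bundle: ClassifierBundle, samples: list[Sample],
                      batch_size: int = 16) -> float:
    """Fraction of samples whose argmax prediction matches the label."""
    if not samples:
        raise ValueError("empty evaluation set")
    correct = 0
    for i in range(0, len(samples), batch_size):
        chunk = samples[i:i + batch_size]
        images = np.stack([s.image for s in chunk])
        logits, _ = bundle.forward_batch(images)
        correct += int(np.sum(np.argmax(logits, axis=1)
                              == np.array([s.label for s in chunk])))
    return correct / len(samples)


def train(model: ClassifierBundle, train_set: list[Sample], val_set: list[Sample],
          cfg: TrainConfig) -> tuple[ClassifierBundle, TrainState]:
    """Run the full training protocol and return the best checkpoint.

    Mini-batch Adam on total_loss = CE + lambda * MSE; per-epoch cosine
    warm-restart learning rate; validation accuracy after every epoch with
    the best-so-far parameters retained (strict improvement saves). Fully
    reproducible from cfg.seed: shuffling and augmentation draws all come
    from one seeded generator, data order is single-threaded.
    """
    if cfg.lambda_gaze > 0:
        for s in train_set:
            if s.gaze_map is None:
                raise ValueError(
                    f"lambda_gaze > 0 but sample {s.image_id!r} has no gaze map")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr)
    state = TrainState()
    best = model.copy()
    n = len(train_set)
    angles = cfg.angles if cfg.rotate else (0,)

    for epoch in range(cfg.max_epochs):
        lr = scheduler_lr(float(epoch), cfg)
        order = rng.permutation(n)
        ce_sum = mse_sum = 0.0
        n_batches = 0
        for start in range(0, n, cfg.batch_train):
            idx = order[start:start + cfg.batch_train]
            imgs, gmaps = [], []
            labels = np.array([train_set[i].label for i in idx])
            for i in idx:
                s = train_set[i]
                img, gm = augment(s.image, s.gaze_map, rng,
                                  flip_lr=cfg.flip_lr, flip_ud=cfg.flip_ud,
                                  angles=angles)
                imgs.append(img)
                gmaps.append(gm)
            images = np.stack(imgs)
            gaze = np.stack(gmaps) if cfg.lambda_gaze > 0 else None
            ce, mse, grads = _train_step(model, images, labels, gaze, cfg)
            opt.step(grads, lr=lr)
            ce_sum += ce
            mse_sum += mse
            n_batches += 1
        ce_mean = ce_sum / n_batches
        mse_mean = mse_sum / n_batches
        val_acc = evaluate_accuracy(model, val_set, batch_size=cfg.batch_val)
        record = {
            "epoch": epoch,
            "lr": lr,
            "ce": ce_mean,
            "mse": mse_mean,
            "total": ce_mean + cfg.lambda_gaze * mse_mean,
            "val_acc": val_acc,
        }
        state.history.append(record)
        state.epoch = epoch + 1
        if val_acc > state.best_val_acc:
            state.best_val_acc = val_acc
            state.best_epoch = epoch
            best = model.copy()
        logger.debug("epoch %d lr=%.5f ce=%.4f mse=%.4f val_acc=%.4f",
                     epoch, lr, ce_mean, mse_mean, val_acc)
    return best, state
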