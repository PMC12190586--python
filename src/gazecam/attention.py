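"""Classifier contract, class-activation attention, and the joint loss.

The classifier is a backbone-agnostic bundle: a feature extractor ending in
an (h, w, C) spatial map, global average pooling, and a fully connected
head. The network's attention map is the classic CAM: the head weights of
the predicted class (rectified), used as channel weights over the final
feature map, summed, upsampled to the gaze map's resolution and passed
through a sigmoid. Training minimizes cross-entropy plus the mean squared
error between this network attention map and the human gaze map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import TinyConvNet, bilinear_resize, sigmoid, softmax

__all__ = [
    "ClassifierBundle",
    "FeatureMap",
    "NetworkAttentionMap",
    "create_tiny_bundle",
    "forward",
    "compute_network_attention",
    "cross_entropy_loss",
    "attention_mse_loss",
    "total_loss",
]


@dataclass
class FeatureMap:
    """Last spatial output of the feature extractor, channel-last (h, w, C)."""

    values: np.ndarray
    image_id: str = ""


@dataclass
class NetworkAttentionMap:
    """Sigmoid-activated CAM for one class; values strictly in (0, 1)."""

    values: np.ndarray
    predicted_class: int


@dataclass
class ClassifierBundle:
    """Feature extractor + GAP + fully connected head.

    `head_weights` is (num_classes, C), `head_bias` length num_classes.
    The extractor must provide forward/backward/params/grads/copy (see
    :class:`gazecam.nn.TinyConvNet`); any backbone honoring that contract
    (including wrapped pretrained networks) is pluggable.
    """

    extractor: TinyConvNet
    head_weights: np.ndarray
    head_bias: np.ndarray
    num_classes: int
    input_size: int = 64
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        C = self.extractor.out_channels
        if self.head_weights.shape != (self.num_classes, C):
            raise ValueError("head_weights shape must be (num_classes, C)")
        if self.head_bias.shape != (self.num_classes,):
            raise ValueError("head_bias length must equal num_classes")
        if not self.class_names:
            self.class_names = [f"class_{k}" for k in range(self.num_classes)]

    def forward_batch(self, images: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Batched forward pass. images (B, H, W, 3) -> (logits (B, K), fmap NCHW)."""
        if images.ndim != 4 or images.shape[1] != self.input_size \
                or images.shape[2] != self.input_size or images.shape[3] != 3:
            raise ValueError(
                f"expected (B, {self.input_size}, {self.input_size}, 3) images, "
                f"got {images.shape}")
        x = np.ascontiguousarray(images.transpose(0, 3, 1, 2))
        fmap = self.extractor.forward(x)
        gap = fmap.mean(axis=(2, 3))
        logits = gap @ self.head_weights.T + self.head_bias
        return logits, fmap

    def predict_proba(self, images: np.ndarray, batch_size: int = 16) -> np.ndarray:
        probs = []
        for i in range(0, len(images), batch_size):
            logits, _ = self.forward_batch(images[i:i + batch_size])
            probs.append(softmax(logits, axis=1))
        return np.concatenate(probs, axis=0)

    def parameters(self) -> list[np.ndarray]:
        return self.extractor.params() + [self.head_weights, self.head_bias]

    def copy(self) -> "ClassifierBundle":
        return ClassifierBundle(
            extractor=self.extractor.copy(),
            head_weights=self.head_weights.copy(),
            head_bias=self.head_bias.copy(),
            num_classes=self.num_classes,
            input_size=self.input_size,
            class_names=list(self.class_names),
        )


def create_tiny_bundle(num_classes: int = 3, input_size: int = 64,
                       seed: int = 0,
                       class_names: list[str] | None = None) -> ClassifierBundle:
    """Reference bundle: TinyConvNet backbone + zero-initialized linear head."""
    rng = np.random.default_rng(seed)
    extractor = TinyConvNet(in_channels=3, rng=rng)
    C = extractor.out_channels
    head_w = rng.normal(0.0, 0.01, size=(num_classes, C))
    head_b = np.zeros(num_classes)
    return ClassifierBundle(extractor=extractor, head_weights=head_w,
                            head_bias=head_b, num_classes=num_classes,
                            input_size=input_size,
                            class_names=class_names or [])


def forward(bundle: ClassifierBundle, image: np.ndarray) -> tuple[np.ndarray, FeatureMap]:
    """Single-image forward pass: logits (K,) and the channel-last feature map."""
    logits, fmap = bundle.forward_batch(image[None])
    return logits[0], FeatureMap(values=np.ascontiguousarray(fmap[0].transpose(1, 2, 0)))


def compute_network_attention(fmap, bundle: ClassifierBundle, predicted_class: int,
                              out_h: int, out_w: int,
                              relu_on: str = "weights") -> NetworkAttentionMap:
    """CAM for one class, resized and sigmoid-activated.

    With relu_on='weights' (default) the class weight vector is rectified
    before the channel-weighted sum, guaranteeing a nonnegative raw map for
    nonnegative features; relu_on='map' instead rectifies the summed map.
    The raw map is bilinearly upsampled (align_corners=False) to
    (out_h, out_w) and passed through a sigmoid.
    """
    if not 0 <= predicted_class < bundle.num_classes:
        raise IndexError(f"class index {predicted_class} out of range "
                         f"[0, {bundle.num_classes})")
    if relu_on not in ("weights", "map"):
        raise ValueError("relu_on must be 'weights' or 'map'")
    values = fmap.values if isinstance(fmap, FeatureMap) else np.asarray(fmap)
    w = bundle.head_weights[predicted_class]
    if relu_on == "weights":
        raw = values @ np.maximum(w, 0.0)
    else:
        raw = np.maximum(values @ w, 0.0)
    resized = bilinear_resize(raw, out_h, out_w)
    return NetworkAttentionMap(values=sigmoid(resized),
                               predicted_class=int(predicted_class))


def cross_entropy_loss(logits: np.ndarray, true_class: int) -> float:
    """Multiclass cross-entropy -log softmax(logits)[true_class]."""
    logits = np.asarray(logits, dtype=float)
    if not np.all(np.isfinite(logits)):
        raise ValueError("logits must be finite")
    if not 0 <= true_class < logits.shape[-1]:
        raise IndexError(f"class index {true_class} out of range")
    z = logits - logits.max()
    return float(np.log(np.exp(z).sum()) - z[true_class])


def attention_mse_loss(a_model, a_human) -> float:
    """Mean squared error between network and human attention maps.

    Mean over all N*M pixels, so the loss is resolution-independent and,
    with both maps living on [0, 1] scales, commensurate with cross-entropy.
    Symmetric in its arguments; zero iff the maps are identical.
    """
    m = a_model.values if hasattr(a_model, "values") else np.asarray(a_model)
    h = a_human.values if hasattr(a_human, "values") else np.asarray(a_human)
    if m.shape != h.shape:
        raise ValueError(f"attention map shapes differ: {m.shape} vs {h.shape}")
    return float(np.mean((m - h) ** 2))


def total_loss(ce: float, mse: float, lambda_gaze: float = 1.0) -> float:
    """Joint objective: classification loss plus the attention-consistency
    term, LOSS = CE + lambda * MSE (lambda defaults to 1; 0 disables gaze
    supervision for the ablation baseline)."""
    return float(ce + lambda_gaze * mse)
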