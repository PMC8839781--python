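"""Deep-spectrum feature extraction from scalogram images.

A MobileNet-V2-style convolutional backbone (inverted residual blocks
built from depthwise-separable 3x3 convolutions, total output stride 32,
final width 1280) turns a 160 x 160 x 3 scalogram into a 5 x 5 x 1280
feature block; global average pooling collapses it to the 1280-element
*deep spectrum feature* vector used by the comparison layer.  A single
dense unit on top (1280 weights + 1 bias = 1281 parameters) gives a binary
tinnitus/control logit: positive logits predict class 1 (control),
non-positive ones class 0 (tinnitus).

The backbone runs on plain NumPy with seeded random weights; externally
trained weight arrays can be supplied through ``weights=`` for real-data
use.  Tests never need anything but random weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "MobileNetV2Backbone",
    "ClassifierHead",
    "TrainConfig",
    "preprocess_image",
    "extract_feature_block",
    "global_average_pool",
    "extract_features",
    "train_head",
    "predict",
]


# ---------------------------------------------------------------------------
# image preprocessing


def preprocess_image(img: np.ndarray, size: tuple[int, int] = (160, 160)) -> np.ndarray:
    """Resize to ``size`` (bilinear) and rescale [0, 255] -> [-1, 1].

    An already-correctly-sized input skips resampling entirely.
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 image, got shape {img.shape}")
    if img.shape[:2] != size:
        from PIL import Image

        pil = Image.fromarray(np.clip(img, 0, 255).astype(np.uint8))
        img = np.asarray(pil.resize(size[::-1], Image.BILINEAR))
    return img.astype(np.float64) / 127.5 - 1.0


# ---------------------------------------------------------------------------
# convolution primitives (HWC layout)


def _pad_same(x: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    h, w = x.shape[:2]
    out_h, out_w = -(-h // stride), -(-w // stride)
    ph = max((out_h - 1) * stride + kh - h, 0)
    pw = max((out_w - 1) * stride + kw - w, 0)
    return np.pad(x, ((ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2), (0, 0)))


def _conv2d(x: np.ndarray, w: np.ndarray, stride: int = 1) -> np.ndarray:
    """SAME-padded 2-D convolution; ``w`` is (kh, kw, c_in, c_out)."""
    kh, kw, _, _ = w.shape
    xp = _pad_same(x, kh, kw, stride)
    win = sliding_window_view(xp, (kh, kw), axis=(0, 1))[::stride, ::stride]
    return np.einsum("hwcij,ijcd->hwd", win, w, optimize=True)


def _depthwise_conv2d(x: np.ndarray, w: np.ndarray, stride: int = 1) -> np.ndarray:
    """Per-channel SAME convolution; ``w`` is (kh, kw, c)."""
    kh, kw, _ = w.shape
    xp = _pad_same(x, kh, kw, stride)
    win = sliding_window_view(xp, (kh, kw), axis=(0, 1))[::stride, ::stride]
    return np.einsum("hwcij,ijc->hwc", win, w, optimize=True)


def _relu6(x: np.ndarray) -> np.ndarray:
    return np.clip(x, 0.0, 6.0)


# ---------------------------------------------------------------------------
# backbone

# (expansion t, out channels, stride) per inverted residual stage
_BLOCK_SPECS = [
    (1, 16, 1),
    (6, 24, 2),
    (6, 32, 2),
    (6, 64, 2),
    (6, 96, 1),
    (6, 160, 2),
    (6, 320, 1),
]
_STEM_CHANNELS = 32
_OUTPUT_STRIDE = 32


class MobileNetV2Backbone:
    """Inverted-residual feature extractor, output stride 32, width 1280.

    Weights are He-initialized from ``seed`` unless an explicit weight dict
    (same keys/shapes as :attr:`weights`) is supplied.  The forward pass is
    deterministic given the weights.
    """

    def __init__(self, seed: int = 0, out_channels: int = 1280,
                 weights: dict[str, np.ndarray] | None = None) -> None:
        self.out_channels = out_channels
        if weights is not None:
            self.weights = {k: np.asarray(v, dtype=np.float64) for k, v in weights.items()}
        else:
            self.weights = self._init_weights(np.random.default_rng(seed))

    def _init_weights(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        def he(shape, fan_in):
            return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)

        w = {"stem": he((3, 3, 3, _STEM_CHANNELS), 27)}
        c_in = _STEM_CHANNELS
        for i, (t, c_out, _) in enumerate(_BLOCK_SPECS):
            hidden = c_in * t
            if t != 1:
                w[f"b{i}_expand"] = he((1, 1, c_in, hidden), c_in)
            w[f"b{i}_dw"] = he((3, 3, hidden), 9)
            w[f"b{i}_project"] = he((1, 1, hidden, c_out), hidden)
            c_in = c_out
        w["head"] = he((1, 1, c_in, self.out_channels), c_in)
        return w

    def features(self, img: np.ndarray) -> np.ndarray:
        """Preprocessed image (H, W, 3) -> spatial feature block (H/32, W/32, 1280)."""
        img = np.asarray(img, dtype=np.float64)
        if img.ndim != 3 or img.shape[2] != 3:
            raise ValueError(f"backbone expects H x W x 3 input, got {img.shape}")
        if img.shape[0] % _OUTPUT_STRIDE or img.shape[1] % _OUTPUT_STRIDE:
            raise ValueError(
                f"input size {img.shape[:2]} not a multiple of the output stride "
                f"{_OUTPUT_STRIDE}"
            )
        x = _relu6(_conv2d(img, self.weights["stem"], stride=2))
        for i, (t, _, stride) in enumerate(_BLOCK_SPECS):
            x_in = x
            if t != 1:
                x = _relu6(_conv2d(x, self.weights[f"b{i}_expand"]))
            x = _relu6(_depthwise_conv2d(x, self.weights[f"b{i}_dw"], stride=stride))
            x = _conv2d(x, self.weights[f"b{i}_project"])  # linear bottleneck
            if stride == 1 and x.shape == x_in.shape:
                x = x + x_in
        return _relu6(_conv2d(x, self.weights["head"]))

    def weights_checksum(self) -> float:
        """Cheap frozen-weights fingerprint (sum of absolute values)."""
        return float(sum(np.abs(v).sum() for v in self.weights.values()))


def extract_feature_block(img: np.ndarray, backbone: MobileNetV2Backbone) -> np.ndarray:
    """Preprocessed image -> spatial feature block (5 x 5 x 1280 at 160 x 160)."""
    return backbone.features(img)


def global_average_pool(block: np.ndarray) -> np.ndarray:
    """Spatial mean per channel: (h, w, c) -> (c,)."""
    block = np.asarray(block)
    if block.ndim != 3 or block.shape[0] < 1 or block.shape[1] < 1:
        raise ValueError(f"expected a non-empty h x w x c block, got {block.shape}")
    return block.mean(axis=(0, 1))


def extract_features(
    images: np.ndarray, backbone: MobileNetV2Backbone
) -> np.ndarray:
    """Raw uint8 images (n, H, W, 3) -> deep-spectrum vectors (n, 1280)."""
    return np.stack(
        [global_average_pool(backbone.features(preprocess_image(im))) for im in images]
    )


# ---------------------------------------------------------------------------
# classifier head


@dataclass
class TrainConfig:
    """Adam training recipe for the dense head."""

    learning_rate: float = 1e-4
    dropout: float = 0.2
    batch_size: int = 32
    epochs: int = 25
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")


@dataclass
class ClassifierHead:
    """Single dense unit on pooled features: logit = w . x + b."""

    weights: np.ndarray = field(default_factory=lambda: np.zeros(1280))
    bias: float = 0.0
    trained: bool = False
    history: list[dict] = field(default_factory=list)

    @property
    def n_parameters(self) -> int:
        return self.weights.size + 1

    def logits(self, vectors: np.ndarray) -> np.ndarray:
        return np.atleast_2d(vectors) @ self.weights + self.bias


def _stratified_split(labels: np.ndarray, val_fraction: float,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    train_idx, val_idx = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        n_val = max(1, int(round(val_fraction * idx.size)))
        val_idx.append(idx[:n_val])
        train_idx.append(idx[n_val:])
    return np.concatenate(train_idx), np.concatenate(val_idx)


def train_head(
    vectors: np.ndarray,
    labels: np.ndarray,
    cfg: TrainConfig | None = None,
    backbone: MobileNetV2Backbone | None = None,
) -> ClassifierHead:
    """Train the dense head with Adam on binary cross-entropy.

    ``vectors`` may be pooled feature vectors (n, c) or raw images
    (n, H, W, 3) with a ``backbone`` to featurize them (the backbone itself
    is never updated).  Labels: 0 = tinnitus, 1 = control.  The 80/20
    validation split is stratified by class and seeded; dropout acts on the
    input features during training only.
    """
    cfg = cfg or TrainConfig()
    vectors = np.asarray(vectors, dtype=np.float64)
    if vectors.ndim == 4:
        if backbone is None:
            raise ValueError("raw images need a backbone to featurize")
        vectors = extract_features(vectors, backbone)
    if vectors.ndim != 2 or vectors.shape[0] == 0:
        raise ValueError("need a non-empty (n, c) feature matrix")
    labels = np.asarray(labels).astype(int).ravel()
    if labels.size != vectors.shape[0]:
        raise ValueError("labels/vectors length mismatch")
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("training needs both classes present")
    if not np.isin(classes, [0, 1]).all():
        raise ValueError("labels must be 0 (tinnitus) or 1 (control)")

    rng = np.random.default_rng(cfg.seed)
    tr, va = _stratified_split(labels, cfg.val_fraction, rng)
    x_tr, y_tr = vectors[tr], labels[tr]
    x_va, y_va = vectors[va], labels[va]

    # feature standardization keeps Adam well-conditioned at lr 1e-4
    mu = x_tr.mean(axis=0)
    sd = x_tr.std(axis=0)
    sd[sd == 0] = 1.0
    x_tr = (x_tr - mu) / sd
    x_va = (x_va - mu) / sd

    n_feat = vectors.shape[1]
    w = np.zeros(n_feat)
    b = 0.0
    m = np.zeros(n_feat + 1)
    v = np.zeros(n_feat + 1)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    history = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(x_tr.shape[0])
        for start in range(0, order.size, cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            xb, yb = x_tr[batch], y_tr[batch]
            if cfg.dropout > 0:
                keep = rng.random(xb.shape) >= cfg.dropout
                xb = xb * keep / (1.0 - cfg.dropout)
            logit = xb @ w + b
            prob = 1.0 / (1.0 + np.exp(-logit))
            err = prob - yb  # d(BCE)/d(logit)
            grad_w = xb.T @ err / batch.size
            grad_b = err.mean()
            grad = np.concatenate([grad_w, [grad_b]])
            step += 1
            m = beta1 * m + (1 - beta1) * grad
            v = beta2 * v + (1 - beta2) * grad**2
            m_hat = m / (1 - beta1**step)
            v_hat = v / (1 - beta2**step)
            update = cfg.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
            w -= update[:-1]
            b -= update[-1]
        train_acc = float(((x_tr @ w + b > 0).astype(int) == y_tr).mean())
        val_acc = float(((x_va @ w + b > 0).astype(int) == y_va).mean())
        history.append({"epoch": epoch + 1, "train_acc": train_acc, "val_acc": val_acc})

    # fold the standardization into the head so it applies to raw features
    w_raw = w / sd
    b_raw = float(b - (w * mu / sd).sum())
    return ClassifierHead(weights=w_raw, bias=b_raw, trained=True, history=history)


def predict(head: ClassifierHead, vec: np.ndarray) -> tuple[float, int]:
    """Logit and class for one feature vector; class 1 (control) iff logit > 0."""
    if not head.trained:
        raise ValueError("head is not trained")
    logit = float(np.asarray(vec, dtype=float) @ head.weights + head.bias)
    return logit, int(logit > 0)


def grid_search_head(
    vectors: np.ndarray,
    labels: np.ndarray,
    learning_rates=(1e-3, 1e-4, 1e-5, 1e-6),
    dropouts=(0.1, 0.2, 0.3, 0.4, 0.5),
    epochs_grid=(15, 25, 50, 100),
    batch_sizes=(25, 32, 45),
    seed: int = 0,
) -> tuple[TrainConfig, float]:
    """Exhaustive hyperparameter search; returns (best config, best val acc).

    Optional utility — nothing in the default pipeline runs it.
    """
    best_cfg, best_acc = None, -1.0
    for lr in learning_rates:
        for dp in dropouts:
            for ep in epochs_grid:
                for bs in batch_sizes:
                    cfg = TrainConfig(learning_rate=lr, dropout=dp, epochs=ep,
                                      batch_size=bs, seed=seed)
                    head = train_head(vectors, labels, cfg)
                    acc = head.history[-1]["val_acc"]
                    if acc > best_acc:
                        best_cfg, best_acc = cfg, acc
    return best_cfg, best_acc
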