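"""Unsupervised backpropagating CNN segmentation with SLIC superpixel refinement.

Engine 3. A small convolutional network is trained on a single image by
alternating three stages until only a few labels survive:

1. Forward pass: three 3x3 convolutional layers (ReLU + batch
   normalization each) followed by a 1x1 classification head with batch
   normalization produce a per-pixel response vector; the argmax channel
   is the pixel's current cluster label.
2. Refinement: SLIC superpixels are imposed on the image and every pixel
   takes the majority label within its superpixel, forcing spatial
   homogeneity.
3. Self-training: the cross-entropy between the response map and the
   refined labels is backpropagated with SGD (momentum), pulling the
   network toward the spatially coherent labeling.

The loop repeats until the number of surviving labels reaches
``min_labels`` (typically five land-cover segments) or an update cap.
Label diversity starts high -- on textured scenes typically tens of
groups -- and collapses as training proceeds.

The network is a plain NumPy implementation (im2col-free shifted-matmul
convolutions, training-mode batch statistics, softmax cross-entropy);
float32 arithmetic, deterministic for a fixed seed on one platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.segmentation import slic as _skimage_slic

from .clustering import MASKED, SegmentMap
from .indices import ChannelStack

__all__ = [
    "CnnConfig",
    "SuperpixelMap",
    "slic_superpixels",
    "refine_by_superpixel",
    "cnn_train_segment",
]


@dataclass(frozen=True)
class CnnConfig:
    """Architecture and training protocol for the unsupervised CNN.

    Defaults follow the study protocol: 3 conv layers of 100 filters,
    SGD at learning rate 0.1 with momentum 0.9, cross-entropy loss,
    10,000 SLIC superpixels at compactness 10, stopping at 5 labels.
    ``slic_target`` selects whether superpixels are computed once on the
    input stack (default; deterministic and cheap) or recomputed on the
    evolving feature map every update.
    """

    n_layers: int = 3
    filters_per_layer: int = 100
    learning_rate: float = 0.1
    momentum: float = 0.9
    n_superpixels: int = 10_000
    compactness: float = 10.0
    min_labels: int = 5
    max_updates: int = 100
    seed: int = 0
    slic_target: str = "input_stack"

    def __post_init__(self) -> None:
        if self.n_layers < 1 or self.filters_per_layer < 1:
            raise ValueError("layer and filter counts must be >= 1")
        if not (self.learning_rate > 0):
            raise ValueError("learning_rate must be > 0")
        if not (0 <= self.momentum < 1):
            raise ValueError("momentum must be in [0, 1)")
        if self.min_labels < 1:
            raise ValueError("min_labels must be >= 1")
        if self.slic_target not in ("input_stack", "feature_map"):
            raise ValueError(f"unknown slic_target {self.slic_target!r}")


@dataclass
class SuperpixelMap:
    """Contiguous-region partition of the image plane."""

    labels: np.ndarray
    n_regions: int
    requested: int


def slic_superpixels(image: np.ndarray, n_superpixels: int,
                     compactness: float = 10.0, seed: int = 0) -> SuperpixelMap:
    """SLIC superpixels on an arbitrary-channel image.

    Localized k-means in joint (channel, spatial) space; ``compactness``
    weights the spatial term against channel distance. Channels are
    standardized first so the published compactness scale applies to
    multispectral stacks as it does to color images. The algorithm is
    grid-initialized and deterministic; ``seed`` is accepted for
    interface uniformity and recorded but has no effect.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 2:
        img = img[:, :, None]
    h, w = img.shape[:2]
    if h < 2 or w < 2:
        raise ValueError("image must be at least 2x2")
    if n_superpixels < 1:
        raise ValueError("n_superpixels must be >= 1")
    if n_superpixels >= h * w:
        labels = np.arange(h * w, dtype=np.int64).reshape(h, w)
        return SuperpixelMap(labels=labels, n_regions=h * w, requested=n_superpixels)
    sd = img.reshape(-1, img.shape[2]).std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    mu = img.reshape(-1, img.shape[2]).mean(axis=0)
    img = (img - mu) / sd
    labels = _skimage_slic(
        img, n_segments=n_superpixels, compactness=compactness,
        channel_axis=-1, start_label=0, enforce_connectivity=True,
        convert2lab=False,
    ).astype(np.int64)
    return SuperpixelMap(labels=labels, n_regions=int(labels.max()) + 1,
                         requested=n_superpixels)


def refine_by_superpixel(labels: np.ndarray, sp: SuperpixelMap,
                         valid: np.ndarray | None = None) -> np.ndarray:
    """Replace every pixel's label by the majority label in its superpixel.

    Ties break toward the lowest label. With a ``valid`` plane, the vote
    counts only valid pixels; a superpixel with no valid pixel keeps its
    input labels. Refinement can only merge labels, never split them, so
    the number of unique labels never increases.
    """
    labels = np.asarray(labels)
    if labels.shape != sp.labels.shape:
        raise ValueError("label plane and superpixel map shapes differ")
    out = labels.copy()
    flat_sp = sp.labels.ravel()
    flat_lab = labels.ravel()
    if valid is not None:
        sel = np.asarray(valid, dtype=bool).ravel()
    else:
        sel = np.ones(flat_lab.shape, dtype=bool)
    n_classes = int(flat_lab[sel].max()) + 1 if sel.any() else 0
    if n_classes == 0:
        return out
    n_regions = sp.n_regions
    # joint histogram of (superpixel, label) over valid pixels
    combined = flat_sp[sel] * n_classes + flat_lab[sel]
    counts = np.bincount(combined, minlength=n_regions * n_classes)
    counts = counts.reshape(n_regions, n_classes)
    majority = counts.argmax(axis=1)  # ties -> lowest label
    has_votes = counts.sum(axis=1) > 0
    flat_out = out.ravel()
    apply_px = has_votes[flat_sp] & sel
    flat_out[apply_px] = majority[flat_sp[apply_px]]
    return flat_out.reshape(labels.shape)


# ---------------------------------------------------------------------------
# NumPy network layers

class _Conv:
    """2-D convolution, 'same' padding, via shifted matmuls."""

    def __init__(self, c_in: int, c_out: int, ksize: int, rng: np.random.Generator):
        fan_in = c_in * ksize * ksize
        self.ksize = ksize
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(ksize, ksize, c_in, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.vW = np.zeros_like(self.W)
        self.vb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        k = self.ksize
        p = k // 2
        h, w, _ = x.shape
        self.xpad = np.pad(x, ((p, p), (p, p), (0, 0)))
        out = np.zeros((h, w, self.W.shape[3]), dtype=np.float32)
        for dy in range(k):
            for dx in range(k):
                patch = self.xpad[dy:dy + h, dx:dx + w]  # (h, w, c_in)
                out += patch @ self.W[dy, dx]
        return out + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        k = self.ksize
        p = k // 2
        h, w, _ = dout.shape
        dxpad = np.zeros_like(self.xpad)
        self.dW = np.zeros_like(self.W)
        self.db = dout.sum(axis=(0, 1))
        for dy in range(k):
            for dx in range(k):
                patch = self.xpad[dy:dy + h, dx:dx + w]
                self.dW[dy, dx] = np.einsum("hwc,hwf->cf", patch, dout)
                dxpad[dy:dy + h, dx:dx + w] += dout @ self.W[dy, dx].T
        return dxpad[p:p + h, p:p + w] if p else dxpad

    def step(self, lr: float, mom: float) -> None:
        self.vW = mom * self.vW - lr * self.dW
        self.vb = mom * self.vb - lr * self.db
        self.W += self.vW
        self.b += self.vb


class _BatchNorm:
    """Per-channel batch normalization over all pixels (training statistics)."""

    eps = 1e-5

    def __init__(self, c: int):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.vg = np.zeros_like(self.gamma)
        self.vb = np.zeros_like(self.beta)

    def forward(self, x: np.ndarray) -> np.ndarray:
        flat = x.reshape(-1, x.shape[-1])
        self.mu = flat.mean(axis=0)
        self.var = flat.var(axis=0)
        self.xhat = (x - self.mu) / np.sqrt(self.var + self.eps)
        return self.gamma * self.xhat + self.beta

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n = dout.shape[0] * dout.shape[1]
        flat_dout = dout.reshape(-1, dout.shape[-1])
        flat_xhat = self.xhat.reshape(-1, dout.shape[-1])
        self.dgamma = (flat_dout * flat_xhat).sum(axis=0)
        self.dbeta = flat_dout.sum(axis=0)
        inv_sd = 1.0 / np.sqrt(self.var + self.eps)
        dxhat = dout * self.gamma
        flat_dxhat = dxhat.reshape(-1, dout.shape[-1])
        dx = (flat_dxhat - flat_dxhat.mean(axis=0)
              - flat_xhat * (flat_dxhat * flat_xhat).mean(axis=0)) * inv_sd
        return dx.reshape(dout.shape).astype(np.float32)

    def step(self, lr: float, mom: float) -> None:
        self.vg = mom * self.vg - lr * self.dgamma
        self.vb = mom * self.vb - lr * self.dbeta
        self.gamma += self.vg
        self.beta += self.vb


class _Net:
    """conv3x3+ReLU+BN (x n_layers) -> conv1x1 -> BN -> response map."""

    def __init__(self, c_in: int, config: CnnConfig, rng: np.random.Generator):
        f = config.filters_per_layer
        self.convs = []
        self.bns = []
        c = c_in
        for _ in range(config.n_layers):
            self.convs.append(_Conv(c, f, 3, rng))
            self.bns.append(_BatchNorm(f))
            c = f
        self.head = _Conv(c, f, 1, rng)
        self.head_bn = _BatchNorm(f)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.relu_masks = []
        for conv, bn in zip(self.convs, self.bns):
            x = conv.forward(x)
            mask = x > 0
            self.relu_masks.append(mask)
            x = bn.forward(np.where(mask, x, 0.0).astype(np.float32))
        x = self.head.forward(x)
        return self.head_bn.forward(x)

    def backward(self, dout: np.ndarray) -> None:
        d = self.head_bn.backward(dout)
        d = self.head.backward(d)
        for conv, bn, mask in zip(reversed(self.convs), reversed(self.bns),
                                  reversed(self.relu_masks)):
            d = bn.backward(d)
            d = np.where(mask, d, 0.0).astype(np.float32)
            d = conv.backward(d)

    def step(self, lr: float, mom: float) -> None:
        for layer in (*self.convs, *self.bns, self.head, self.head_bn):
            layer.step(lr, mom)


def _cross_entropy(resp: np.ndarray, targets: np.ndarray,
                   valid: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy over valid pixels and its gradient."""
    z = resp - resp.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=-1, keepdims=True)
    n = int(valid.sum())
    idx = np.nonzero(valid)
    t = targets[idx]
    loss = float(-np.log(p[idx[0], idx[1], t] + 1e-12).mean())
    grad = np.zeros_like(resp)
    grad[idx] = p[idx]
    grad[idx[0], idx[1], t] -= 1.0
    grad /= n
    return loss, grad.astype(np.float32)


def cnn_train_segment(stack: ChannelStack, keep: np.ndarray | None = None,
                      config: CnnConfig = CnnConfig()):
    """Train the unsupervised CNN on one stack and return its segment map.

    Runs the three-stage loop (forward/argmax, superpixel majority
    refinement, cross-entropy backpropagation) until the surviving-label
    count is at most ``config.min_labels`` or ``config.max_updates`` is
    reached. Masked pixels are excluded from the loss and carry the -1
    sentinel in the output.

    Returns ``(SegmentMap, trace)`` where ``trace`` is a list of
    ``{"update", "loss", "n_labels"}`` records.
    """
    if keep is None:
        keep = np.ones(stack.nodata_mask.shape, dtype=bool)
    valid = np.asarray(keep, dtype=bool) & ~stack.nodata_mask
    if not valid.any():
        raise ValueError("no valid pixels to segment")

    x = stack.values.astype(np.float32)
    flat = x.reshape(-1, x.shape[-1])
    sd = flat.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    x = (x - flat.mean(axis=0)) / sd  # standardized network input

    rng = np.random.default_rng(config.seed)
    net = _Net(x.shape[-1], config, rng)

    sp = None
    if config.slic_target == "input_stack":
        sp = slic_superpixels(stack.values, config.n_superpixels,
                              config.compactness, config.seed)

    trace: list[dict] = []
    labels = None
    for update in range(1, config.max_updates + 1):
        resp = net.forward(x)
        argmax_labels = resp.argmax(axis=-1)
        if config.slic_target == "feature_map":
            sp = slic_superpixels(resp, config.n_superpixels,
                                  config.compactness, config.seed)
        labels = refine_by_superpixel(argmax_labels, sp, valid=valid)
        n_labels = int(np.unique(labels[valid]).size)
        loss, grad = _cross_entropy(resp, labels, valid)
        if not np.isfinite(loss):
            raise RuntimeError(f"non-finite loss at update {update}")
        trace.append({"update": update, "loss": loss, "n_labels": n_labels})
        if n_labels <= config.min_labels:
            break
        net.backward(grad)
        net.step(config.learning_rate, config.momentum)

    out = np.full(valid.shape, MASKED, dtype=np.int64)
    # compact surviving labels to 0..m-1 in order of appearance
    survivors = np.unique(labels[valid])
    remap = {int(s): i for i, s in enumerate(survivors)}
    out[valid] = np.vectorize(remap.get)(labels[valid])
    return SegmentMap(labels=out), trace
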