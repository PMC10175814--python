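"""Small convolutional classifier with a global-average-pooling linear head.

Implemented directly on NumPy so the whole stack (forward pass, parameter
training, and input-space gradients for adversarial perturbation) runs on one
CPU with no deep-learning framework. The architecture is deliberately tiny:
a few 3x3 conv + ReLU + 2x2 average-pool blocks, spatial global pooling of
the last feature maps, and a bias-free linear softmax head.

Conventions that the activation-map math relies on:

* pooling of the last conv layer is a spatial **sum**, ``G_k = sum_{x,y}
  g_k(x,y)`` (a mean-pooling backend would need the head weights rescaled);
* the head has no bias, so the class score is exactly
  ``S_i = sum_k w_ki * G_k`` and equals the spatial sum of the class
  activation map.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "ClassifierOutput",
    "GapNet",
    "train",
    "forward",
    "forward_batch",
    "input_gradient",
]


class TrainingError(RuntimeError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyper-parameters.

    ``conv_channels`` gives the output channels of each conv block; the last
    entry is K, the number of feature maps feeding the GAP head.
    """

    conv_channels: tuple[int, ...] = (8, 16, 32)
    classes: int = 2
    input_size: int = 128
    kernel: int = 3
    dtype: str = "float32"  # conv internals; CAM-facing outputs are float64

    def __post_init__(self) -> None:
        if len(self.conv_channels) < 1:
            raise ValueError("need at least one conv block")
        if self.input_size % (2 ** len(self.conv_channels)) != 0:
            raise ValueError("input_size must be divisible by 2**n_blocks")
        if self.dtype not in ("float32", "float64"):
            raise ValueError("dtype must be float32 or float64")

    @property
    def channels_last_conv(self) -> int:
        return self.conv_channels[-1]

    @property
    def grid_size(self) -> int:
        """Side length of the last-conv spatial grid after all poolings."""
        return self.input_size // (2 ** len(self.conv_channels))


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 15
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    val_fraction: float = 0.25
    target_val_auc: float | None = None  # early stop once reached
    n_restarts: int = 0  # deterministic re-inits if the target is missed

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")


@dataclass
class ClassifierOutput:
    """Everything a CAM needs from one forward pass."""

    feature_stack: np.ndarray  # g_k(x,y), shape (K, h, w)
    pooled: np.ndarray  # G_k = sum_{x,y} g_k(x,y), shape (K,)
    class_scores: np.ndarray  # S_i, shape (classes,)
    probabilities: np.ndarray  # softmax(S), shape (classes,)
    predicted_class: int
    head_weights: np.ndarray  # w_ki, shape (K, classes)


def _softmax(scores: np.ndarray) -> np.ndarray:
    z = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """Same-padded patch matrix: (B, C, H, W) -> (B*H*W, C*k*k)."""
    B, C, H, W = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # (B, C, H, W, k, k) -> (B, H, W, C, k, k), one contiguous copy
    return np.ascontiguousarray(windows.transpose(0, 2, 3, 1, 4, 5)).reshape(
        B * H * W, C * k * k
    )


def _conv2d(cols: np.ndarray, w: np.ndarray, b: np.ndarray, shape) -> np.ndarray:
    """GEMM convolution on a precomputed patch matrix; returns NCHW."""
    B, _, H, W = shape
    c_out = w.shape[0]
    out = cols @ w.reshape(c_out, -1).T + b
    return out.reshape(B, H, W, c_out).transpose(0, 3, 1, 2)


def _conv2d_backward(
    cols: np.ndarray, w: np.ndarray, dout: np.ndarray, in_shape
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of the same-padded conv w.r.t. input, weight, bias."""
    B, C, H, W = in_shape
    c_out, _, k, _ = w.shape
    p = k // 2
    dout_flat = dout.transpose(0, 2, 3, 1).reshape(-1, c_out)  # (B*H*W, Cout)
    dw = (dout_flat.T @ cols).reshape(w.shape)
    db = dout_flat.sum(axis=0)
    dcols = (dout_flat @ w.reshape(c_out, -1)).reshape(B, H, W, C, k, k)
    dxp = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=dout.dtype)
    for ki in range(k):
        for kj in range(k):
            dxp[:, :, ki : ki + H, kj : kj + W] += dcols[:, :, :, :, ki, kj].transpose(
                0, 3, 1, 2
            )
    dx = dxp[:, :, p : p + H, p : p + W]
    return dx, dw, db


def _avgpool2(x: np.ndarray) -> np.ndarray:
    B, C, H, W = x.shape
    return x.reshape(B, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))


def _avgpool2_backward(dout: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(dout, 2, axis=2), 2, axis=3) / 4.0


class GapNet:
    """Conv blocks + GAP(sum) + bias-free linear softmax head."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        dtype = np.dtype(spec.dtype)
        rng = np.random.default_rng(seed)
        self.conv_weights: list[np.ndarray] = []
        self.conv_biases: list[np.ndarray] = []
        c_in = 1
        for c_out in spec.conv_channels:
            fan_in = c_in * spec.kernel**2
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, spec.kernel, spec.kernel))
            self.conv_weights.append(w.astype(dtype))
            self.conv_biases.append(np.zeros(c_out, dtype=dtype))
            c_in = c_out
        # head weights w_ki; small init because pooled sums are O(grid area)
        self.head_weights = rng.normal(
            0.0, 1e-3, size=(spec.channels_last_conv, spec.classes)
        ).astype(dtype)

    # ------------------------------------------------------------------ #

    def _forward_cached(self, x: np.ndarray) -> tuple[dict, np.ndarray]:
        """Batch forward keeping every intermediate needed for backprop."""
        cache = {"shapes": [], "cols": [], "relu_mask": []}
        h = x
        for w, b in zip(self.conv_weights, self.conv_biases):
            cache["shapes"].append(h.shape)
            cols = _im2col(h, self.spec.kernel)
            cache["cols"].append(cols)
            z = _conv2d(cols, w, b, h.shape)
            cache["relu_mask"].append(z > 0)
            h = _avgpool2(np.maximum(z, 0.0))
        cache["features"] = h  # (B, K, h, w)
        pooled = h.sum(axis=(2, 3))  # GAP as a sum
        cache["pooled"] = pooled
        scores = pooled @ self.head_weights
        cache["scores"] = scores
        return cache, scores

    def _backward(
        self, cache: dict, dscores: np.ndarray, want_param_grads: bool = True
    ) -> tuple[np.ndarray, list[np.ndarray] | None, list[np.ndarray] | None, np.ndarray | None]:
        """Propagate dL/dS back to the input (and optionally the parameters)."""
        dhead = cache["pooled"].T @ dscores if want_param_grads else None
        dpooled = dscores @ self.head_weights.T  # (B, K)
        feat = cache["features"]
        dh = np.broadcast_to(
            dpooled[:, :, None, None], feat.shape
        ).astype(feat.dtype).copy()
        dws: list[np.ndarray] = []
        dbs: list[np.ndarray] = []
        for i in range(len(self.conv_weights) - 1, -1, -1):
            da = _avgpool2_backward(dh)
            dz = da * cache["relu_mask"][i]
            dx, dw, db = _conv2d_backward(
                cache["cols"][i], self.conv_weights[i], dz, cache["shapes"][i]
            )
            if want_param_grads:
                dws.append(dw)
                dbs.append(db)
            dh = dx
        if want_param_grads:
            dws.reverse()
            dbs.reverse()
            return dh, dws, dbs, dhead
        return dh, None, None, None

    # ------------------------------------------------------------------ #

    def parameters(self) -> list[np.ndarray]:
        return [*self.conv_weights, *self.conv_biases, self.head_weights]

    def save(self, path: str | Path) -> None:
        arrays = {f"conv_w{i}": w for i, w in enumerate(self.conv_weights)}
        arrays.update({f"conv_b{i}": b for i, b in enumerate(self.conv_biases)})
        arrays["head"] = self.head_weights
        arrays["channels"] = np.array(self.spec.conv_channels)
        arrays["meta"] = np.array([self.spec.classes, self.spec.input_size, self.spec.kernel])
        arrays["dtype"] = np.array(self.spec.dtype)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "GapNet":
        data = np.load(path)
        channels = tuple(int(c) for c in data["channels"])
        classes, input_size, kernel = (int(v) for v in data["meta"])
        spec = ModelSpec(conv_channels=channels, classes=classes,
                         input_size=input_size, kernel=kernel,
                         dtype=str(data["dtype"]))
        model = cls(spec, seed=0)
        model.conv_weights = [data[f"conv_w{i}"] for i in range(len(channels))]
        model.conv_biases = [data[f"conv_b{i}"] for i in range(len(channels))]
        model.head_weights = data["head"]
        return model


def _as_batch(image: np.ndarray, spec: ModelSpec) -> np.ndarray:
    image = np.asarray(image, dtype=spec.dtype)
    if image.shape != (spec.input_size, spec.input_size):
        raise ValueError(
            f"image shape {image.shape} does not match input_size {spec.input_size}"
        )
    return image[None, None]


def forward(model: GapNet, image: np.ndarray) -> ClassifierOutput:
    """Single-image forward pass exposing every CAM ingredient.

    The GAP/head arithmetic is redone in float64 on the conv features so the
    activation-map identity ``S_i = sum_xy M_i(x,y)`` holds to tight
    tolerance even with a float32 conv backend.
    """
    x = _as_batch(image, model.spec)
    cache, _ = model._forward_cached(x)
    features = cache["features"][0].astype(np.float64)
    head = model.head_weights.astype(np.float64)
    pooled = features.sum(axis=(1, 2))
    scores = pooled @ head
    probs = _softmax(scores)
    return ClassifierOutput(
        feature_stack=features,
        pooled=pooled,
        class_scores=scores,
        probabilities=probs,
        predicted_class=int(np.argmax(probs)),
        head_weights=head,
    )


def forward_batch(model: GapNet, images: np.ndarray) -> np.ndarray:
    """Probabilities for a stack of images, shape (B, H, W) -> (B, classes)."""
    x = np.asarray(images, dtype=model.spec.dtype)[:, None]
    _, scores = model._forward_cached(x)
    return _softmax(scores.astype(np.float64))


def input_gradient(model: GapNet, image: np.ndarray, label: int) -> np.ndarray:
    """Gradient of the cross-entropy loss w.r.t. the input pixels."""
    x = _as_batch(image, model.spec)
    cache, scores = model._forward_cached(x)
    probs = _softmax(scores)
    dscores = probs.copy()
    dscores[0, label] -= 1.0  # d(CE)/dS for a one-hot target
    dx, _, _, _ = model._backward(cache, dscores, want_param_grads=False)
    return dx[0, 0].astype(np.float64)


# ---------------------------------------------------------------------- #
# training


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mh = m / (1 - self.b1**self.t)
            vh = v / (1 - self.b2**self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)


def _cross_entropy(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    probs = _softmax(scores)
    n = len(labels)
    loss = -np.log(np.clip(probs[np.arange(n), labels], 1e-300, None)).mean()
    dscores = probs
    dscores[np.arange(n), labels] -= 1.0
    return float(loss), dscores / n


def train(
    model_spec: ModelSpec,
    dataset: Sequence,
    cfg: TrainConfig,
    target_val_auc: float | None = None,
):
    """Train a :class:`GapNet` on phantom nodules.

    ``dataset`` is any sequence of objects with ``image`` and ``label``
    attributes (``label`` in {"benign", "malignant"}) or ``(image, label)``
    pairs with integer labels. Returns ``(model, metrics)`` where metrics is
    a list of per-epoch dicts (loss, val_auc). Training stops early once
    ``target_val_auc`` is reached, if given; if the target is missed and
    ``cfg.n_restarts`` > 0, training reruns with deterministically shifted
    seeds and the best attempt (by final validation AUC) is returned.
    """
    images, labels = _coerce_dataset(dataset)
    images = images.astype(model_spec.dtype)
    if target_val_auc is None:
        target_val_auc = cfg.target_val_auc
    if len(np.unique(labels)) < 2:
        raise TrainingError("training requires both classes present")

    best: tuple[float, "GapNet", list] | None = None
    for attempt in range(cfg.n_restarts + 1):
        seed = cfg.seed + 1009 * attempt
        model, metrics = _train_once(
            model_spec, images, labels, cfg, seed, target_val_auc
        )
        val = metrics[-1].get("val_auc", 0.0)
        if target_val_auc is None or val >= target_val_auc:
            return model, metrics
        if best is None or val > best[0]:
            best = (val, model, metrics)
    return best[1], best[2]


def _train_once(
    model_spec: ModelSpec,
    images: np.ndarray,
    labels: np.ndarray,
    cfg: TrainConfig,
    seed: int,
    target_val_auc: float | None,
):
    rng = np.random.default_rng(seed)
    n = len(labels)
    order = rng.permutation(n)
    n_val = max(1, int(round(cfg.val_fraction * n))) if n > 3 else 0
    val_idx, train_idx = order[:n_val], order[n_val:]
    if len(np.unique(labels[train_idx])) < 2:
        raise TrainingError("train split lost a class; lower val_fraction")

    x_train = images[train_idx][:, None]
    y_train = labels[train_idx]
    x_val = images[val_idx][:, None] if n_val else None
    y_val = labels[val_idx] if n_val else None

    model = GapNet(model_spec, seed=seed)
    opt = _Adam(model.parameters(), cfg.learning_rate)
    metrics = []
    for epoch in range(cfg.epochs):
        perm = rng.permutation(len(y_train))
        losses = []
        for start in range(0, len(perm), cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            cache, scores = model._forward_cached(x_train[idx])
            loss, dscores = _cross_entropy(scores, y_train[idx])
            _, dws, dbs, dhead = model._backward(cache, dscores)
            opt.step(model.parameters(), [*dws, *dbs, dhead])
            losses.append(loss)
        entry = {"epoch": epoch, "loss": float(np.mean(losses))}
        if n_val and len(np.unique(y_val)) == 2:
            _, val_scores = model._forward_cached(x_val)
            val_p = _softmax(val_scores)[:, 1]
            entry["val_auc"] = float(roc_auc_score(y_val, val_p))
        metrics.append(entry)
        if (
            target_val_auc is not None
            and entry.get("val_auc", 0.0) >= target_val_auc
        ):
            break
    return model, metrics


def _coerce_dataset(dataset: Sequence) -> tuple[np.ndarray, np.ndarray]:
    images, labels = [], []
    for item in dataset:
        if hasattr(item, "image") and hasattr(item, "label"):
            images.append(np.asarray(item.image, dtype=np.float64))
            labels.append(1 if item.label == "malignant" else 0)
        else:
            img, lab = item
            images.append(np.asarray(img, dtype=np.float64))
            labels.append(int(lab))
    if not images:
        raise TrainingError("empty dataset")
    return np.stack(images), np.asarray(labels, dtype=np.intp)
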