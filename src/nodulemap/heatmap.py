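"""Class activation maps and the malignancy-probability-scaled heat map.

The activation map for class *i* is the head-weight projection of the last
conv feature stack, ``M_i(x,y) = sum_k w_ki g_k(x,y)``, so its spatial sum
equals the class score ``S_i`` exactly (GAP is a sum in this stack). The
malignancy heat map rescales the malignant-class map to [0, 1] by its max
and multiplies by the predicted malignancy probability, so peak heat equals
that probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from skimage.transform import resize

from .gapnet import ClassifierOutput

__all__ = [
    "ActivationMap",
    "MalignancyHeatMap",
    "compute_cam",
    "upsample_cam",
    "malignancy_heatmap",
    "render",
]


@dataclass
class ActivationMap:
    values: np.ndarray  # signed M_i(x,y) on the conv grid
    class_index: int
    source_score: float
    upsampled: np.ndarray | None = None  # image-resolution raster

    def clamped(self, upsampled: bool = True) -> np.ndarray:
        """Non-negative raster used for rendering and region segmentation."""
        raster = self.upsampled if (upsampled and self.upsampled is not None) else self.values
        return np.maximum(raster, 0.0)


@dataclass
class MalignancyHeatMap:
    values: np.ndarray  # in [0, p_malignant]
    p_malignant: float


def compute_cam(output: ClassifierOutput, class_index: int) -> ActivationMap:
    """Project head weights onto the feature stack for one class."""
    n_classes = output.head_weights.shape[1]
    if not 0 <= class_index < n_classes:
        raise IndexError(f"class_index {class_index} out of range [0, {n_classes})")
    weights = output.head_weights[:, class_index]  # (K,)
    values = np.tensordot(weights, output.feature_stack, axes=([0], [0]))
    return ActivationMap(
        values=values,
        class_index=class_index,
        source_score=float(output.class_scores[class_index]),
    )


def upsample_cam(cam: ActivationMap, target: tuple[int, int] | int) -> ActivationMap:
    """Bilinear upsampling of the conv-grid map to image resolution."""
    if isinstance(target, int):
        target = (target, target)
    h, w = cam.values.shape
    if target[0] < h or target[1] < w:
        raise ValueError(f"target {target} smaller than conv grid {(h, w)}")
    if target == (h, w):
        up = cam.values.copy()
    else:
        up = resize(
            cam.values, target, order=1, mode="edge",
            anti_aliasing=False, preserve_range=True,
        )
        # bilinear interpolation cannot escape the source range
        up = np.clip(up, cam.values.min(), cam.values.max())
    return ActivationMap(
        values=cam.values,
        class_index=cam.class_index,
        source_score=cam.source_score,
        upsampled=up,
    )


def malignancy_heatmap(cam: ActivationMap, p_malignant: float) -> MalignancyHeatMap:
    """Normalize the malignant-class CAM by its max, then scale by probability."""
    if not 0.0 <= p_malignant <= 1.0:
        raise ValueError(f"p_malignant={p_malignant} outside [0, 1]")
    raster = cam.clamped()
    peak = raster.max()
    if peak > 0:
        raster = raster / peak
    values = raster * p_malignant
    return MalignancyHeatMap(values=values, p_malignant=float(p_malignant))


def render(
    heat: ActivationMap | MalignancyHeatMap | np.ndarray,
    mode: str = "conventional",
    image: np.ndarray | None = None,
    alpha: float = 0.45,
) -> np.ndarray:
    """Render a heat raster to an RGB uint8 array, optionally overlaid.

    ``conventional``: warm single-ended colormap of relative intensity
    (per-map max normalization). ``malignancy``: diverging blue-to-red map
    anchored on the absolute [0, 1] malignancy-heat scale, so color
    temperature encodes absolute heat (blue = benign end, red = malignant).
    """
    if isinstance(heat, ActivationMap):
        raster = heat.clamped()
    elif isinstance(heat, MalignancyHeatMap):
        raster = heat.values
    else:
        raster = np.maximum(np.asarray(heat, dtype=float), 0.0)
    if not np.all(np.isfinite(raster)):
        raise ValueError("heat raster contains non-finite values")

    if mode == "conventional":
        peak = raster.max()
        norm = raster / peak if peak > 0 else raster
        rgba = colormaps["jet"](norm)
    elif mode == "malignancy":
        rgba = colormaps["bwr"](np.clip(raster, 0.0, 1.0))
    else:
        raise ValueError(f"unknown render mode {mode!r}")
    rgb = rgba[..., :3]

    if image is not None:
        gray = np.asarray(image, dtype=float)
        if gray.shape != raster.shape:
            raise ValueError("overlay image shape mismatch")
        base = np.repeat(gray[..., None], 3, axis=-1)
        rgb = (1.0 - alpha) * base + alpha * rgb
    return np.round(np.clip(rgb, 0, 1) * 255).astype(np.uint8)
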