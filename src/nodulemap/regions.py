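"""Equal-area level-set partition of a nodular activation map.

The positive support of the (clamped, upsampled) CAM defines the nodular
area N. Peeling the lowest-valued N/k pixels yields region I (outermost),
the next N/k region II, and so on up to the hottest remainder, region V —
equivalent to value-quantile binning of the positive pixels. Regions are
nested by value, not geometry, so a bimodal map can produce a region V with
two components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RegionPartition", "segment_equal_areas", "threshold_sweep"]


class DegenerateInputError(ValueError):
    pass


@dataclass
class RegionPartition:
    labels: np.ndarray  # 0 background, 1 = region I (outermost) .. k = innermost
    areas: np.ndarray  # pixel count per region, index 0 -> region I
    thresholds: np.ndarray  # internal level-set cut values (k-1 of them)
    k: int

    def mask(self, region: int) -> np.ndarray:
        """Binary mask of one region; ``region`` is 1-based (1 = outermost)."""
        if not 1 <= region <= self.k:
            raise ValueError(f"region must be in [1, {self.k}]")
        return self.labels == region

    @property
    def total_area(self) -> int:
        return int(self.areas.sum())


def _region_sizes(n: int, k: int) -> np.ndarray:
    """floor(N/k) each, remainder given one pixel each to the innermost regions."""
    sizes = np.full(k, n // k, dtype=np.intp)
    remainder = n % k
    if remainder:
        sizes[-remainder:] += 1
    return sizes


def segment_equal_areas(cam_raster: np.ndarray, k: int = 5) -> RegionPartition:
    """Partition the positive pixels of ``cam_raster`` into k equal-area level sets.

    Ties at quantile boundaries break deterministically by raster scan order.
    """
    cam = np.asarray(cam_raster, dtype=float)
    flat = cam.ravel()
    positive = np.flatnonzero(flat > 0)
    n = positive.size
    if n < k:
        raise DegenerateInputError(
            f"need at least k={k} positive pixels, found {n}"
        )
    # stable sort on value => raster-order tie-break for free
    order = positive[np.argsort(flat[positive], kind="stable")]
    sizes = _region_sizes(n, k)
    labels = np.zeros(flat.size, dtype=np.intp)
    thresholds = []
    start = 0
    for region, size in enumerate(sizes, start=1):
        block = order[start : start + size]
        labels[block] = region
        start += size
        if region < k:
            thresholds.append(flat[order[start]])  # first value of next region
    return RegionPartition(
        labels=labels.reshape(cam.shape),
        areas=sizes,
        thresholds=np.asarray(thresholds),
        k=k,
    )


def threshold_sweep(
    cam_raster: np.ndarray, thresholds: np.ndarray | list[float]
) -> list[np.ndarray]:
    """Binary masks of the nodular support at or above each threshold.

    Thresholds must be ascending; masks shrink monotonically. Threshold 0
    returns the full positive support (area N).
    """
    cam = np.asarray(cam_raster, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size and np.any(np.diff(thresholds) < 0):
        raise ValueError("thresholds must be ascending")
    support = cam > 0
    return [support & (cam >= t) for t in thresholds]
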