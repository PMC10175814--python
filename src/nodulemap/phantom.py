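"""Synthetic ultrasound-like nodule phantom.

Generates seeded 2-D grayscale images that emulate B-mode nodule appearance:
an elliptical nodule (optionally with an irregular, sinusoidally perturbed
margin) embedded in parenchyma-level background, multiplied by a right-skewed
speckle field. Malignant nodules carry localized discriminative cues — a very
hypoechoic sub-region and/or punctate bright foci — whose pixel positions are
recorded in ``cue_mask`` so that regional-importance claims can be checked
against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

__all__ = [
    "PhantomConfig",
    "SyntheticNodule",
    "generate_nodule",
    "generate_dataset",
    "save_dataset",
    "load_dataset",
]

BENIGN = "benign"
MALIGNANT = "malignant"

CueLocalization = Literal["center", "annulus", "random"]


class PhantomConfigError(ValueError):
    """Raised when a phantom configuration is internally inconsistent."""


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters controlling phantom image synthesis.

    All intensity levels live in [0, 1]. Identical config + seed reproduces
    identical rasters bit-for-bit.
    """

    image_size: int = 128
    nodule_area_range: tuple[int, int] = (900, 2200)
    benign_echogenicity: float = 0.62
    malignant_echogenicity: float = 0.34
    background_echogenicity: float = 0.48
    cue_echogenicity: float = 0.10
    cue_area_fraction: float = 0.25
    calcification_count_range: tuple[int, int] = (2, 5)
    macrocalcification_count_range: tuple[int, int] = (0, 0)
    margin_irregularity: float = 0.12
    speckle_scale: float = 0.30
    cue_localization: CueLocalization = "center"
    seed: int = 0

    def __post_init__(self) -> None:
        levels = {
            "benign_echogenicity": self.benign_echogenicity,
            "malignant_echogenicity": self.malignant_echogenicity,
            "background_echogenicity": self.background_echogenicity,
            "cue_echogenicity": self.cue_echogenicity,
        }
        for name, value in levels.items():
            if not 0.0 <= value <= 1.0:
                raise PhantomConfigError(f"{name}={value} outside [0, 1]")
        lo, hi = self.nodule_area_range
        if not (0 < lo <= hi):
            raise PhantomConfigError("nodule_area_range must be a positive interval")
        if hi > self.image_size**2:
            raise PhantomConfigError("nodule_area_range exceeds image area")
        # The most eccentric, most irregular nodule must still fit with margin.
        max_radius = np.sqrt(hi / (np.pi * _MIN_ASPECT)) * (1.0 + self.margin_irregularity)
        if max_radius > self.image_size / 2.0 - 3.0:
            raise PhantomConfigError(
                f"nodule_area_range upper bound {hi} infeasible for "
                f"image_size={self.image_size}"
            )
        if self.margin_irregularity < 0:
            raise PhantomConfigError("margin_irregularity must be >= 0")
        if self.speckle_scale < 0:
            raise PhantomConfigError("speckle_scale must be >= 0")
        if not 0 < self.cue_area_fraction <= 1:
            raise PhantomConfigError("cue_area_fraction must be in (0, 1]")
        if self.cue_localization not in ("center", "annulus", "random"):
            raise PhantomConfigError(
                f"unknown cue_localization {self.cue_localization!r}"
            )


@dataclass
class SyntheticNodule:
    """A generated phantom image with its ground-truth annotations."""

    image: np.ndarray  # float64 in [0, 1], shape (H, W)
    nodule_mask: np.ndarray  # bool, shape (H, W)
    label: str  # "benign" | "malignant"
    cue_mask: np.ndarray  # bool, subset of nodule_mask
    feature_record: dict = field(default_factory=dict)

    @property
    def n_pixels(self) -> int:
        return int(self.nodule_mask.sum())


_MIN_ASPECT = 0.55  # minimum semi-axis ratio b/a
_N_HARMONICS = 3


def _boundary_radius(
    theta: np.ndarray,
    a: float,
    b: float,
    amplitude: float,
    phases: np.ndarray,
    harmonics: Sequence[int],
) -> np.ndarray:
    """Ellipse polar radius with sinusoidal perturbation; stays positive."""
    r_ell = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    wobble = np.zeros_like(theta)
    for m, phi in zip(harmonics, phases):
        wobble += np.sin(m * theta + phi)
    return r_ell * (1.0 + amplitude / len(harmonics) * wobble)


def _render_mask(
    size: int,
    center: tuple[float, float],
    a: float,
    b: float,
    amplitude: float,
    rng: np.random.Generator,
) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    dy = yy - center[0]
    dx = xx - center[1]
    theta = np.arctan2(dy, dx)
    r = np.hypot(dy, dx)
    harmonics = (2, 3, 5)
    phases = rng.uniform(0, 2 * np.pi, size=_N_HARMONICS)
    return r <= _boundary_radius(theta, a, b, amplitude, phases, harmonics)


def _cue_center(
    config: PhantomConfig,
    mask: np.ndarray,
    centroid: tuple[float, float],
    rng: np.random.Generator,
) -> tuple[float, float]:
    if config.cue_localization == "center":
        return centroid
    # random: pick an interior pixel away from the margin
    interior = ndimage.binary_erosion(mask, iterations=3)
    candidates = np.argwhere(interior if interior.any() else mask)
    cy, cx = candidates[rng.integers(len(candidates))]
    return float(cy), float(cx)


def _cue_region(
    config: PhantomConfig,
    mask: np.ndarray,
    centroid: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Pixel set carrying the class signal; always a subset of the mask."""
    n = int(mask.sum())
    target = max(4, int(round(config.cue_area_fraction * n)))
    yy, xx = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
    if config.cue_localization == "annulus":
        # ring at mid normalized distance from the centroid
        d = np.hypot(yy - centroid[0], xx - centroid[1])
        dmax = d[mask].max()
        dn = d / max(dmax, 1e-9)
        lo, hi = 0.45, 0.8
        ring = mask & (dn >= lo) & (dn <= hi)
        return ring
    cy, cx = _cue_center(config, mask, centroid, rng)
    d = np.hypot(yy - cy, xx - cx)
    radius = np.sqrt(target / np.pi)
    return mask & (d <= radius)


def _place_foci(
    region: np.ndarray,
    count: int,
    min_px: int,
    max_px: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Bright punctate/macro foci as tiny pixel clusters inside ``region``."""
    foci = np.zeros_like(region)
    candidates = np.argwhere(region)
    if len(candidates) == 0 or count == 0:
        return foci
    h, w = region.shape
    for _ in range(count):
        cy, cx = candidates[rng.integers(len(candidates))]
        n_px = int(rng.integers(min_px, max_px + 1))
        foci[cy, cx] = True
        # grow by raster-adjacent pixels to reach the requested size
        offsets = [(0, 1), (1, 0), (0, -1), (-1, 0), (1, 1), (-1, -1)]
        placed = 1
        for dy, dx in offsets:
            if placed >= n_px:
                break
            y, x = cy + dy, cx + dx
            if 0 <= y < h and 0 <= x < w and region[y, x]:
                foci[y, x] = True
                placed += 1
    return foci


def generate_nodule(
    config: PhantomConfig, label: str, seed: int
) -> SyntheticNodule:
    """Render one phantom nodule.

    Benign nodules are smooth iso/hyper-echoic ellipses; malignant nodules
    are hypoechoic with an irregular margin, a very hypoechoic cue region at
    the configured localization, and punctate bright foci inside the cue.
    Both are embedded in multiplicative speckle and clipped to [0, 1].
    """
    if label not in (BENIGN, MALIGNANT):
        raise ValueError(f"label must be '{BENIGN}' or '{MALIGNANT}', got {label!r}")
    rng = np.random.default_rng(seed)
    size = config.image_size

    area = float(rng.uniform(*config.nodule_area_range))
    aspect = float(rng.uniform(_MIN_ASPECT, 1.0))
    a = np.sqrt(area / (np.pi * aspect))
    b = a * aspect
    jitter = size * 0.04
    center = (
        size / 2.0 + float(rng.uniform(-jitter, jitter)),
        size / 2.0 + float(rng.uniform(-jitter, jitter)),
    )
    amplitude = config.margin_irregularity if label == MALIGNANT else 0.0
    mask = _render_mask(size, center, a, b, amplitude, rng)
    # star-shaped construction keeps one component; enforce regardless
    labeled, n_comp = ndimage.label(mask)
    if n_comp > 1:
        sizes = ndimage.sum(mask, labeled, range(1, n_comp + 1))
        mask = labeled == (1 + int(np.argmax(sizes)))

    envelope = np.full((size, size), config.background_echogenicity)
    cue_mask = np.zeros((size, size), dtype=bool)
    record: dict = {"composition": "solid"}

    if label == BENIGN:
        envelope[mask] = config.benign_echogenicity
        record["echogenicity"] = (
            "hyperechoic"
            if config.benign_echogenicity > config.background_echogenicity
            else "isoechoic"
        )
        record["foci"] = "none"
    else:
        envelope[mask] = config.malignant_echogenicity
        cue = _cue_region(config, mask, ndimage.center_of_mass(mask), rng)
        envelope[cue] = config.cue_echogenicity
        n_punctate = int(rng.integers(config.calcification_count_range[0],
                                      config.calcification_count_range[1] + 1))
        foci = _place_foci(cue if cue.any() else mask, n_punctate, 1, 3, rng)
        n_macro_lo, n_macro_hi = config.macrocalcification_count_range
        n_macro = int(rng.integers(n_macro_lo, n_macro_hi + 1)) if n_macro_hi else 0
        macro = _place_foci(mask, n_macro, 4, 6, rng)
        envelope[foci | macro] = 0.95
        cue_mask = cue | foci | macro
        if not cue_mask.any():  # guarantee non-empty malignant cue
            cy, cx = np.argwhere(mask)[0]
            cue_mask[cy, cx] = True
            envelope[cy, cx] = config.cue_echogenicity
        record["echogenicity"] = (
            "very hypoechoic" if config.cue_echogenicity < 0.2 else "hypoechoic"
        )
        if n_macro > 0:
            record["foci"] = "macro-calcification"
        elif n_punctate > 0:
            record["foci"] = "punctate calcification"
        else:
            record["foci"] = "none"

    envelope = ndimage.gaussian_filter(envelope, sigma=0.8)

    if config.speckle_scale > 0:
        # gamma speckle: mean 1, std = speckle_scale (right-skewed, positive)
        shape = 1.0 / config.speckle_scale**2
        speckle = rng.gamma(shape, scale=1.0 / shape, size=(size, size))
        image = envelope * speckle
    else:
        image = envelope.copy()
    image = np.clip(image, 0.0, 1.0)

    cue_mask &= mask
    record["n_pixels"] = int(mask.sum())
    return SyntheticNodule(
        image=image,
        nodule_mask=mask,
        label=label,
        cue_mask=cue_mask,
        feature_record=record,
    )


def generate_dataset(
    config: PhantomConfig,
    n_benign: int,
    n_malignant: int,
    seed: int | None = None,
) -> list[SyntheticNodule]:
    """Generate ``n_benign`` benign then ``n_malignant`` malignant nodules.

    Per-nodule seeds derive deterministically from the dataset seed (which
    defaults to ``config.seed``) via a seed sequence, so datasets with
    different seeds are fully decorrelated.
    """
    if n_benign < 0 or n_malignant < 0:
        raise ValueError("counts must be >= 0")
    if seed is None:
        seed = config.seed
    total = n_benign + n_malignant
    child_seeds = np.random.SeedSequence(seed).generate_state(max(total, 1))
    labels = [BENIGN] * n_benign + [MALIGNANT] * n_malignant
    return [
        generate_nodule(config, lab, int(child_seeds[i]))
        for i, lab in enumerate(labels)
    ]


def save_dataset(dataset: Sequence[SyntheticNodule], outdir: str | Path) -> Path:
    """Write images/masks as 8-bit PNGs plus a CSV manifest; returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, nod in enumerate(dataset):
        stem = f"nodule_{i:04d}"
        img8 = np.round(nod.image * 255).astype(np.uint8)
        Image.fromarray(img8, mode="L").save(outdir / f"{stem}.png")
        Image.fromarray(
            (nod.nodule_mask.astype(np.uint8) * 255), mode="L"
        ).save(outdir / f"{stem}_mask.png")
        Image.fromarray(
            (nod.cue_mask.astype(np.uint8) * 255), mode="L"
        ).save(outdir / f"{stem}_cue.png")
        rows.append(
            {
                "id": stem,
                "label": nod.label,
                "echogenicity": nod.feature_record.get("echogenicity", ""),
                "composition": nod.feature_record.get("composition", ""),
                "foci": nod.feature_record.get("foci", ""),
                "n_pixels": nod.n_pixels,
            }
        )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_dataset(directory: str | Path) -> list[SyntheticNodule]:
    """Read back a dataset written by :func:`save_dataset`."""
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    out = []
    for _, row in manifest.iterrows():
        stem = row["id"]
        image = np.asarray(Image.open(directory / f"{stem}.png"), dtype=np.float64) / 255.0
        mask = np.asarray(Image.open(directory / f"{stem}_mask.png")) > 127
        cue_path = directory / f"{stem}_cue.png"
        cue = np.asarray(Image.open(cue_path)) > 127 if cue_path.exists() else np.zeros_like(mask)
        record = {
            "echogenicity": row.get("echogenicity", ""),
            "composition": row.get("composition", ""),
            "foci": row.get("foci", ""),
            "n_pixels": int(row["n_pixels"]),
        }
        out.append(
            SyntheticNodule(
                image=image,
                nodule_mask=mask,
                label=row["label"],
                cue_mask=cue,
                feature_record=record,
            )
        )
    return out
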