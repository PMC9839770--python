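"""Synthetic bitewing-like radiograph generator with ground-truth lesion masks.

The generator emulates the pixel statistics that make caries segmentation
hard: small dark lesion blobs (side ~10 px on average) sitting on the
boundaries of bright tooth-like structures inside a mostly dark ~300x300
frame, giving an extreme foreground/background pixel imbalance (foreground
fraction on the order of 0.1%). Every draw is fully reproducible from
``(config.seed, draw_index)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import ndimage

from .core import Radiograph, SegmentationMask

__all__ = ["SyntheticConfig", "generate_radiograph", "generate_dataset", "write_dataset"]

_BACKGROUND = 0.15
_TOOTH_INTENSITY = 0.7


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic radiograph generator.

    Defaults follow the regime of a small bitewing dataset: 300x300 frames,
    a row of bright teeth, 1-3 lesions per image with side drawn from
    Normal(10, 2) px, lesions 0.3 intensity units darker than the tooth they
    sit on, and additive Gaussian pixel noise with sd 0.03.
    """

    height: int = 300
    width: int = 300
    n_teeth: int = 6
    lesions_min: int = 1
    lesions_max: int = 3
    lesion_side_mean: float = 10.0
    lesion_side_sd: float = 2.0
    lesion_contrast: float = 0.3
    noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("frame dimensions must be positive")
        if self.n_teeth < 0:
            raise ValueError("n_teeth must be >= 0")
        if not (0 <= self.lesions_min <= self.lesions_max):
            raise ValueError("need 0 <= lesions_min <= lesions_max")
        if self.lesion_side_mean < 2:
            raise ValueError("lesion_side_mean must be >= 2 px")
        if self.lesion_side_sd < 0:
            raise ValueError("lesion_side_sd must be >= 0")
        if not (0 < self.lesion_contrast <= 1):
            raise ValueError("lesion_contrast must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")


def _tooth_layout(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Background plus a row of bright elliptical teeth, softly blurred."""
    h, w = config.height, config.width
    base = np.full((h, w), _BACKGROUND)
    if config.n_teeth == 0:
        return base
    rows, cols = np.mgrid[0:h, 0:w].astype(np.float64)
    pitch = w / config.n_teeth
    semi_r = 0.30 * h
    semi_c = 0.38 * pitch
    for t in range(config.n_teeth):
        cc = (t + 0.5) * pitch + rng.uniform(-0.05, 0.05) * pitch
        cr = 0.5 * h + rng.uniform(-0.06, 0.06) * h
        a_r = semi_r * rng.uniform(0.85, 1.1)
        a_c = semi_c * rng.uniform(0.85, 1.0)
        q = ((rows - cr) / a_r) ** 2 + ((cols - cc) / a_c) ** 2
        intensity = _TOOTH_INTENSITY * rng.uniform(0.92, 1.08)
        base[q <= 1.0] = np.maximum(base[q <= 1.0], min(intensity, 0.95))
    # soften tooth edges so boundaries are gradients, as in real radiographs
    return ndimage.gaussian_filter(base, sigma=1.2)


def _lesion_support(
    side: float, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """An irregular connected blob with extent <= ``side``, as a local grid.

    The blob is the sub-level set of an anisotropic quadratic form perturbed
    by smooth positive noise (noise only erodes, so the blob stays within
    the side x side bounding budget), restricted to the connected component
    containing the centre.
    """
    half = int(np.ceil(side / 2.0))
    n = 2 * half + 1
    rr, cc = np.mgrid[-half : half + 1, -half : half + 1].astype(np.float64)
    theta = rng.uniform(0, np.pi)
    elong = rng.uniform(1.0, 1.35)
    a = side / 2.0  # semi-major axis
    b = max(side / (2.0 * elong), 1.0)  # semi-minor axis
    u = rr * np.cos(theta) + cc * np.sin(theta)
    v = -rr * np.sin(theta) + cc * np.cos(theta)
    q = (u / a) ** 2 + (v / b) ** 2
    rough = ndimage.gaussian_filter(rng.standard_normal((n, n)), sigma=1.0)
    rough = np.abs(rough) / max(np.abs(rough).max(), 1e-12)
    blob = (q + 0.5 * rough) <= 1.0
    blob[half, half] = True  # centre pixel always present
    labels, _ = ndimage.label(blob, structure=np.ones((3, 3), dtype=int))
    blob = labels == labels[half, half]
    return blob, half


def _place_lesions(
    config: SyntheticConfig, image: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Carve dark lesion blobs into the image in place; return their mask.

    Lesions are centred on points of tooth-boundary-like intensity
    gradients. Rejection sampling (<=100 attempts per lesion) keeps lesions
    mutually non-adjacent so each stays its own connected component.
    """
    h, w = image.shape
    max_side = min(h, w) / 4.0
    n_lesions = int(rng.integers(config.lesions_min, config.lesions_max + 1))
    mask = np.zeros((h, w), dtype=np.uint8)
    blocked = np.zeros((h, w), dtype=bool)  # existing lesions, dilated
    # candidate centres: mid-intensity pixels = soft tooth boundaries
    boundary = (image > _BACKGROUND + 0.1) & (image < _TOOTH_INTENSITY - 0.1)
    cand = np.argwhere(boundary)
    if len(cand) == 0:
        cand = np.argwhere(image >= image.mean())
    for _ in range(n_lesions):
        for _attempt in range(100):
            side = float(np.clip(
                rng.normal(config.lesion_side_mean, config.lesion_side_sd),
                2.0, max_side,
            ))
            cr, cc = cand[rng.integers(len(cand))]
            blob, half = _lesion_support(side, rng)
            r0, c0 = cr - half, cc - half
            br0, bc0 = max(0, -r0), max(0, -c0)
            br1 = blob.shape[0] - max(0, r0 + blob.shape[0] - h)
            bc1 = blob.shape[1] - max(0, c0 + blob.shape[1] - w)
            if br1 <= br0 or bc1 <= bc0:
                continue
            sub = blob[br0:br1, bc0:bc1]
            rs = slice(r0 + br0, r0 + br1)
            cs = slice(c0 + bc0, c0 + bc1)
            if sub.sum() < 3 or blocked[rs, cs][sub].any():
                continue
            image[rs, cs][sub] -= config.lesion_contrast
            mask[rs, cs][sub] = 1
            grown = ndimage.binary_dilation(
                mask.astype(bool), structure=np.ones((3, 3), dtype=bool), iterations=2
            )
            blocked |= grown
            break
    return mask


def generate_radiograph(
    config: SyntheticConfig, draw_index: int
) -> tuple[Radiograph, SegmentationMask]:
    """Generate one (image, mask) pair, reproducible from (seed, draw_index)."""
    if draw_index < 0:
        raise ValueError("draw_index must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, draw_index]))
    image = _tooth_layout(config, rng)
    mask = _place_lesions(config, image, rng)
    if config.noise_sd > 0:
        image = image + rng.normal(0.0, config.noise_sd, size=image.shape)
    image = np.clip(image, 0.0, 1.0)
    return (
        Radiograph(id=f"synth-{config.seed}-{draw_index:04d}", pixels=image),
        SegmentationMask(mask),
    )


def generate_dataset(
    n: int, config: SyntheticConfig, seed: Optional[int] = None
) -> list[tuple[Radiograph, SegmentationMask]]:
    """Generate ``n`` pairs with draw indices 0..n-1.

    If ``seed`` is given it overrides ``config.seed``, so the same config
    object can serve several independent replicates.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if seed is not None:
        config = replace(config, seed=seed)
    return [generate_radiograph(config, i) for i in range(n)]


def write_dataset(pairs, out_dir) -> None:
    """Materialise pairs to ``images/*.png``, ``masks/*.png`` and a manifest TSV."""
    from . import io_annotations as ioa

    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    lines = ["id\tn_lesions\tfg_pixels"]
    for image, mask in pairs:
        ioa.write_image(image, out_dir / "images" / f"{image.id}.png")
        ioa.write_mask_image(mask, out_dir / "masks" / f"{image.id}.png")
        n_comp = ndimage.label(mask.pixels, structure=np.ones((3, 3), dtype=int))[1]
        lines.append(f"{image.id}\t{n_comp}\t{mask.foreground_pixels}")
    (out_dir / "manifest.tsv").write_text("\n".join(lines) + "\n")
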