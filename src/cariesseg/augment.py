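"""Deterministic 5-way joint image/mask augmentation.

Each cropped pair expands into a fixed, ordered list of transformed pairs:
identity, horizontal flip, vertical flip, rotation and shear. Parameters
are fixed constants (not random draws), so the expansion factor and every
output are exactly reproducible: N input pairs always become 5N.

Images are interpolated bilinearly; masks use nearest neighbour and are
re-binarised, so masks stay strictly {0, 1}. Pixels mapped from outside
the patch are set to a constant fill value (default 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage import transform as sktf

from .core import check_aligned
from .ccs import CroppedPair

__all__ = [
    "AugmentationSpec",
    "AugmentedPair",
    "transform_pair",
    "augment_pair",
    "augment_dataset",
]

TRANSFORM_NAMES = ("identity", "hflip", "vflip", "rotate", "shear")


@dataclass(frozen=True)
class AugmentationSpec:
    """Fixed parameters of the 5-way augmentation scheme."""

    rotation_deg: float = 15.0
    shear_factor: float = 0.2  # x-shear: col' = col + shear * (row - centre)
    fill_value: float = 0.0
    transforms: tuple[str, ...] = TRANSFORM_NAMES

    def __post_init__(self) -> None:
        if not (-180.0 < self.rotation_deg <= 180.0):
            raise ValueError("rotation_deg must be in (-180, 180]")
        if not np.isfinite(self.shear_factor):
            raise ValueError("shear_factor must be finite")
        unknown = set(self.transforms) - set(TRANSFORM_NAMES)
        if unknown:
            raise ValueError(f"unknown transforms: {sorted(unknown)}")


@dataclass(eq=False)
class AugmentedPair:
    """A transformed patch pair with provenance back to its source crop."""

    image: np.ndarray
    mask: np.ndarray
    source_id: str
    component_index: int
    transform: str


def _warp_pair(image, mask, matrix, fill):
    """Apply an affine map to both grids; bilinear image, nearest mask."""
    tf = sktf.AffineTransform(matrix=matrix)
    img_out = sktf.warp(image, tf, order=1, mode="constant", cval=fill,
                        preserve_range=True)
    mask_out = sktf.warp(mask.astype(np.float64), tf, order=0, mode="constant",
                         cval=0.0, preserve_range=True)
    return img_out, (mask_out >= 0.5).astype(np.uint8)


def _centered(matrix: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Conjugate an (x, y) affine matrix so it acts about the patch centre.

    skimage warps in (x=col, y=row) coordinates; the returned matrix is the
    *inverse* map (output -> input), as ``skimage.transform.warp`` expects.
    """
    h, w = shape
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    to_centre = np.array([[1, 0, -cx], [0, 1, -cy], [0, 0, 1]], dtype=np.float64)
    back = np.array([[1, 0, cx], [0, 1, cy], [0, 0, 1]], dtype=np.float64)
    return back @ matrix @ to_centre


def transform_pair(
    image: np.ndarray, mask: np.ndarray, transform: str, spec: AugmentationSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one named transform jointly to an aligned image/mask pair."""
    check_aligned(image, mask, "image and mask patches")
    if transform not in TRANSFORM_NAMES:
        raise ValueError(f"unknown transform {transform!r}; expected one of {TRANSFORM_NAMES}")
    if transform == "identity":
        return image.copy(), mask.astype(np.uint8).copy()
    if transform == "hflip":
        return image[:, ::-1].copy(), mask[:, ::-1].astype(np.uint8).copy()
    if transform == "vflip":
        return image[::-1, :].copy(), mask[::-1, :].astype(np.uint8).copy()
    if transform == "rotate":
        # inverse map: rotate output coords by -angle to find input coords
        ang = np.deg2rad(spec.rotation_deg)
        inv = np.array(
            [[np.cos(ang), -np.sin(ang), 0.0],
             [np.sin(ang), np.cos(ang), 0.0],
             [0.0, 0.0, 1.0]]
        )
    else:  # shear
        inv = np.array([[1.0, -spec.shear_factor, 0.0],
                        [0.0, 1.0, 0.0],
                        [0.0, 0.0, 1.0]])
    matrix = _centered(inv, image.shape)
    return _warp_pair(image, mask, matrix, spec.fill_value)


def augment_pair(
    image: np.ndarray, mask: np.ndarray, spec: AugmentationSpec = AugmentationSpec()
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Expand one pair into ``len(spec.transforms)`` pairs in fixed order."""
    return [transform_pair(image, mask, name, spec) for name in spec.transforms]


def augment_dataset(
    pairs: Sequence[CroppedPair], spec: AugmentationSpec = AugmentationSpec()
) -> list[AugmentedPair]:
    """Expand every cropped pair; output count = len(transforms) x input count."""
    out: list[AugmentedPair] = []
    for pair in pairs:
        for name in spec.transforms:
            img, msk = transform_pair(pair.image, pair.mask, name, spec)
            out.append(
                AugmentedPair(
                    image=img,
                    mask=msk,
                    source_id=pair.source_id,
                    component_index=pair.component_index,
                    transform=name,
                )
            )
    return out
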