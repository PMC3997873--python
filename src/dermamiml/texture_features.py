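"""Nine-dimensional block-wavelet texture descriptor per region.

For a region of a segmented image the descriptor holds

* ``f1..f3`` — mean L, U, V values over all region pixels (CIE LUV, D65);
* ``f4..f6`` — mean single-level 2-D Haar DWT detail coefficients (HH, HL,
  LH) of the L channel over all *valid* 4x4 blocks;
* ``f7..f9`` — 1st/2nd/3rd order normalized criteria of the region's L
  values: mean, standard deviation and skewness, each scaled by the L range
  (100).  The criteria are a configurable plug-in point
  (:data:`NORMALIZED_CRITERIA`).

Blocks tile the region's bounding box on a grid anchored at the bounding-box
top-left corner; a block is valid only if all 16 of its pixels belong to the
region, so padding pixels (the black fill of an irregular region's bounding
box) never contribute.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pywt
from skimage.color import rgb2luv

from .segmentation import SegmentationMask

logger = logging.getLogger(__name__)

L_RANGE = 100.0


def _criteria_mean(L: np.ndarray) -> float:
    return float(np.mean(L)) / L_RANGE


def _criteria_std(L: np.ndarray) -> float:
    return float(np.std(L)) / L_RANGE


def _criteria_skew(L: np.ndarray) -> float:
    sd = np.std(L)
    if sd < 1e-12:
        return 0.0
    return float(np.mean(((L - np.mean(L)) / sd) ** 3)) / L_RANGE


#: 1st/2nd/3rd order normalized criteria (f7, f8, f9); replaceable.
NORMALIZED_CRITERIA = (_criteria_mean, _criteria_std, _criteria_skew)


@dataclass(frozen=True)
class TextureVector:
    values: np.ndarray  # f1..f9

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (9,) or not np.isfinite(v).all():
            raise ValueError("texture vector must hold 9 finite values")
        object.__setattr__(self, "values", v)


def region_blocks(
    mask: SegmentationMask, region_id: int, block: int = 4
) -> list[tuple[int, int]]:
    """Top-left corners (row, col) of fully interior blocks of a region.

    The grid is anchored at the region's bounding-box origin; a block
    qualifies only if all ``block**2`` pixels belong to the region.
    """
    inside = mask.labels == region_id
    if not inside.any():
        raise ValueError(f"region {region_id} does not exist in mask")
    ys, xs = np.nonzero(inside)
    y0, y1 = ys.min(), ys.max() + 1
    x0, x1 = xs.min(), xs.max() + 1
    corners = []
    for by in range(y0, y1 - block + 1, block):
        for bx in range(x0, x1 - block + 1, block):
            if inside[by:by + block, bx:bx + block].all():
                corners.append((by, bx))
    return corners


def texture_vector(
    image: np.ndarray,
    mask: SegmentationMask,
    region_id: int,
    block: int = 4,
) -> TextureVector:
    """Compute f1..f9 for one region of an RGB image."""
    inside = mask.labels == region_id
    if not inside.any():
        raise ValueError(f"region {region_id} is empty")
    luv = rgb2luv(np.asarray(image))
    L = luv[..., 0]
    f1, f2, f3 = luv[inside].mean(axis=0)

    corners = region_blocks(mask, region_id, block=block)
    if corners:
        hh = hl = lh = 0.0
        for by, bx in corners:
            blk = L[by:by + block, bx:bx + block]
            _, (cH, cV, cD) = pywt.dwt2(blk, "haar")
            # cD: diagonal (HH); cV: detail along rows (HL); cH: along columns (LH)
            hh += cD.mean()
            hl += cV.mean()
            lh += cH.mean()
        f4, f5, f6 = hh / len(corners), hl / len(corners), lh / len(corners)
    else:
        logger.warning(
            "region %d has no fully interior %dx%d block; f4..f6 set to 0",
            region_id, block, block,
        )
        f4 = f5 = f6 = 0.0

    Lr = L[inside]
    f7, f8, f9 = (crit(Lr) for crit in NORMALIZED_CRITERIA)
    return TextureVector(np.array([f1, f2, f3, f4, f5, f6, f7, f8, f9]))
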