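"""End-to-end plumbing: image -> segmentation -> region descriptors -> bag."""

from __future__ import annotations

import numpy as np

from .graph_features import region_graph_features
from .imaging_io import Bag
from .segmentation import SegmentationMask, normalized_cut
from .texture_features import texture_vector


def image_to_bag(
    image: np.ndarray,
    k: int = 11,
    min_pixels: int = 1500,
    mask: SegmentationMask | None = None,
    block: int = 4,
    p: int = 4,
    min_blob: int = 20,
    source_id: str = "",
    seed: int = 0,
) -> tuple[Bag, SegmentationMask]:
    """Convert one RGB image into a multi-instance bag.

    Segments the image into ``k`` regions by normalized cut (unless a
    ground-truth ``mask`` is supplied), then concatenates the 9-dim texture
    and the ``p + p(p-1) + 1``-dim graph descriptor per region (26 features
    with the defaults).
    """
    if mask is None:
        # an image with fewer visually distinct areas than k yields a
        # smaller bag; the MI assumption handles variable instance counts
        mask = normalized_cut(image, k=k, min_pixels=min_pixels, strict=False)
    rows = []
    for r in range(mask.k):
        tex = texture_vector(image, mask, r, block=block).values
        gra = region_graph_features(image, mask, r, p=p, min_blob=min_blob, seed=seed)
        rows.append(np.concatenate([tex, gra]))
    return Bag(np.array(rows), source_id=source_id, region_ids=list(range(mask.k))), mask
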