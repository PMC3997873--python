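"""Synthetic skin-biopsy-like images and feature-space bags.

The clinical corpus this package is aimed at (thousands of annotated biopsy
images) is private, so this module generates data with the same statistical
structure: an image is composed of several spatially contiguous textured
regions, each region carries (at most) one annotation term, and the image's
term vector is the union of its regions' terms — the standard multi-instance
assumption.  A feature-space twin (:func:`generate_bags`) produces bags of
Gaussian instances directly, for fast learner tests.

The generator emulates region geometry with Voronoi cells of random seed
points (irregular, contiguous shapes) and term-specific textures built from
a base color, additive Gaussian noise and an optional stripe or spot mask,
so that both texture and graph descriptors carry term signal.  It does not
attempt photorealistic histology or staining models.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, field

import numpy as np

from .imaging_io import (
    DEFAULT_TERM_FREQUENCIES,
    DEFAULT_VOCABULARY,
    Bag,
    TermVector,
)
from .segmentation import SegmentationMask

_PATTERNS = ("solid", "stripes", "spots")
_LINKERS = ("with", "and", "showing", "areas of", "scattered", "focal")


@dataclass(frozen=True)
class TextureParams:
    """Appearance of one term's regions: base RGB color, noise sd, pattern.

    Pattern contrasts are kept below the hue separation between terms so
    that regions stay visually coherent — the texture modulates a region,
    it does not split it."""

    color: tuple[int, int, int]
    noise: float = 6.0
    pattern: str = "solid"
    stripe_contrast: float = 0.15
    spot_contrast: float = 0.30

    def __post_init__(self) -> None:
        if self.pattern not in _PATTERNS:
            raise ValueError(f"pattern must be one of {_PATTERNS}")


def default_palette(s: int) -> list[TextureParams]:
    """Visually distinct textures: evenly spaced hues, cycling patterns."""
    out = []
    for t in range(s):
        r, g, b = colorsys.hsv_to_rgb(t / s, 0.75, 0.85)
        out.append(
            TextureParams(
                color=(int(r * 255), int(g * 255), int(b * 255)),
                noise=6.0,
                pattern=_PATTERNS[t % len(_PATTERNS)],
            )
        )
    return out


@dataclass
class SynthConfig:
    """Study conditions for the synthetic corpus.

    Defaults mirror the clinical setting the package targets: 800x600
    images, the 15-term vocabulary with its corpus occurrence frequencies,
    11 regions per image, and 5-11 instances per feature-space bag.
    """

    image_width: int = 800
    image_height: int = 600
    n_terms: int = 15
    term_frequencies: tuple[float, ...] = DEFAULT_TERM_FREQUENCIES
    regions_per_image: int = 11
    texture_params: list[TextureParams] | None = None
    background: TextureParams = field(
        default_factory=lambda: TextureParams(color=(205, 205, 205), noise=6.0)
    )
    instance_dim: int = 2
    instance_range: tuple[int, int] = (5, 11)
    effect_separation: float = 3.0
    max_term_repeats: int = 0  # 0 = unlimited (background fills spare regions)
    vocabulary: tuple[str, ...] = DEFAULT_VOCABULARY
    seed: int = 0

    def __post_init__(self) -> None:
        freqs = tuple(float(f) for f in self.term_frequencies)
        if len(freqs) != self.n_terms:
            raise ValueError("term_frequencies length must equal n_terms")
        if any(not 0.0 <= f <= 1.0 for f in freqs):
            raise ValueError("term_frequencies must lie in [0, 1]")
        if self.regions_per_image < 1:
            raise ValueError("regions_per_image must be >= 1")
        if self.effect_separation < 0:
            raise ValueError("effect_separation must be >= 0")
        if self.instance_dim < 1:
            raise ValueError("instance_dim must be >= 1")
        if self.instance_range[0] < 1 or self.instance_range[1] < self.instance_range[0]:
            raise ValueError("instance_range must be an increasing pair >= 1")
        if (
            self.max_term_repeats > 0
            and self.regions_per_image > self.n_terms * self.max_term_repeats
        ):
            raise ValueError(
                "regions_per_image exceeds n_terms * max_term_repeats with no "
                "background regions allowed"
            )
        if len(self.vocabulary) != self.n_terms:
            if self.vocabulary is DEFAULT_VOCABULARY:
                self.vocabulary = tuple(f"term{i + 1}" for i in range(self.n_terms))
            else:
                raise ValueError("vocabulary length must equal n_terms")
        self.term_frequencies = freqs
        if self.texture_params is None:
            self.texture_params = default_palette(self.n_terms)
        elif len(self.texture_params) != self.n_terms:
            raise ValueError("texture_params must have one entry per term")


def _sample_term_set(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Independent Bernoulli draw per term, capped at regions_per_image."""
    present = np.flatnonzero(
        rng.random(config.n_terms) < np.asarray(config.term_frequencies)
    )
    if len(present) > config.regions_per_image:
        present = np.sort(
            rng.choice(present, size=config.regions_per_image, replace=False)
        )
    return present


def _assign_regions(
    config: SynthConfig, present: np.ndarray, n_regions: int, rng: np.random.Generator
) -> np.ndarray:
    """Map each region to a term id or -1 (background); every present term
    gets at least one region (union rule holds by construction)."""
    region_terms = np.full(n_regions, -1, dtype=int)
    slots = rng.permutation(n_regions)
    for i, t in enumerate(present):
        region_terms[slots[i]] = t
    for r in slots[len(present):]:
        if len(present) > 0 and rng.random() < 0.35:
            region_terms[r] = int(rng.choice(present))
    if config.max_term_repeats > 0:
        # enforce the repetition cap by resetting overflow regions
        for t in present:
            hits = np.flatnonzero(region_terms == t)
            for r in hits[config.max_term_repeats:]:
                region_terms[r] = -1
    return region_terms


def _paint_region(
    image: np.ndarray, mask: np.ndarray, params: TextureParams, rng: np.random.Generator
) -> None:
    h, w = image.shape[:2]
    yy, xx = np.nonzero(mask)
    base = np.asarray(params.color, dtype=float)
    px = np.tile(base, (len(yy), 1))
    if params.pattern == "stripes":
        band = (yy // 3) % 2 == 0
        px[band] *= 1.0 + params.stripe_contrast
        px[~band] *= 1.0 - params.stripe_contrast
    elif params.pattern == "spots":
        spot = ((yy % 8) < 3) & ((xx % 8) < 3)
        px[spot] *= 1.0 - params.spot_contrast
    px += rng.normal(0.0, params.noise, size=px.shape)
    image[yy, xx] = np.clip(px, 1.0, 255.0)  # floor 1: black is reserved for padding


def generate_image(
    config: SynthConfig, rng_seed: int
) -> tuple[np.ndarray, SegmentationMask, TermVector]:
    """One synthetic image: Voronoi regions, term textures, union label.

    Returns the uint8 RGB image, the ground-truth region mask and the term
    vector (bit t set iff at least one region carries term t).
    """
    rng = np.random.default_rng(rng_seed)
    h, w = config.image_height, config.image_width
    n_reg = config.regions_per_image

    # seeds on distinct pixel centers so every Voronoi cell is nonempty
    flat = rng.choice(h * w, size=n_reg, replace=False)
    pts = np.column_stack([flat // w, flat % w]).astype(float)
    yy, xx = np.mgrid[0:h, 0:w]
    d2 = (yy[..., None] - pts[:, 0]) ** 2 + (xx[..., None] - pts[:, 1]) ** 2
    labels = np.argmin(d2, axis=-1)

    present = _sample_term_set(config, rng)
    region_terms = _assign_regions(config, present, n_reg, rng)

    image = np.zeros((h, w, 3), dtype=np.uint8)
    for r in range(n_reg):
        params = (
            config.background if region_terms[r] < 0
            else config.texture_params[region_terms[r]]
        )
        _paint_region(image, labels == r, params, rng)

    bits = np.zeros(config.n_terms, dtype=np.int8)
    bits[region_terms[region_terms >= 0]] = 1
    mask = SegmentationMask(labels, k=n_reg, min_pixels=1)
    return image, mask, TermVector(bits, config.vocabulary)


def _term_centers(s: int, d: int, separation: float, rng: np.random.Generator) -> np.ndarray:
    """Per-term cluster centers at the given distance from the origin.

    Directions are spread out — evenly spaced angles in 2-D (randomly
    rotated), orthonormal when s <= d — so ``effect_separation`` really is
    the distance between any term cluster and the background; random
    directions could place two terms almost on top of each other.
    """
    if d == 2:
        theta = rng.uniform(0, 2 * np.pi) + 2 * np.pi * np.arange(s) / max(s, 1)
        dirs = np.column_stack([np.cos(theta), np.sin(theta)])
    elif s <= d:
        a = rng.normal(size=(d, s))
        q, _ = np.linalg.qr(a)
        dirs = q[:, :s].T
    else:
        dirs = rng.normal(size=(s, d))
        dirs /= np.maximum(np.linalg.norm(dirs, axis=1, keepdims=True), 1e-12)
    return dirs * separation


def generate_bags(
    config: SynthConfig,
    n_bags: int,
    rng_seed: int,
    return_instance_labels: bool = False,
):
    """Feature-space bags: Gaussian instance clusters, one per term.

    Each positive instance for term t is drawn from an isotropic unit
    Gaussian centered ``effect_separation`` away from the background cluster
    at the origin (direction fixed per term for the call).  The bag label is
    the union of its instance labels.
    """
    if n_bags < 1:
        raise ValueError("n_bags must be >= 1")
    rng = np.random.default_rng(rng_seed)
    s, d = config.n_terms, config.instance_dim
    centers = _term_centers(s, d, config.effect_separation, rng)

    bags, labels, inst_labels = [], [], []
    lo, hi = config.instance_range
    for b in range(n_bags):
        n_inst = int(rng.integers(lo, hi + 1))
        present = _sample_term_set(config, rng)
        if len(present) > n_inst:
            present = np.sort(rng.choice(present, size=n_inst, replace=False))
        who = np.full(n_inst, -1, dtype=int)
        slots = rng.permutation(n_inst)
        for i, t in enumerate(present):
            who[slots[i]] = t
        for r in slots[len(present):]:
            if len(present) > 0 and rng.random() < 0.35:
                who[r] = int(rng.choice(present))
        X = rng.normal(size=(n_inst, d))
        for i in range(n_inst):
            if who[i] >= 0:
                X[i] += centers[who[i]]
        bits = np.zeros(s, dtype=np.int8)
        bits[present] = 1
        bags.append(Bag(X, source_id=f"synth-{b:05d}"))
        labels.append(TermVector(bits, config.vocabulary))
        inst_labels.append(who)
    if return_instance_labels:
        return bags, labels, inst_labels
    return bags, labels


def generate_description(
    terms: TermVector, vocabulary=None, rng_seed: int = 0
) -> str:
    """Render a term vector as a plain-text description.

    The sentence contains exactly the names of the set terms joined by random
    linker words, so it round-trips through
    :func:`dermamiml.imaging_io.terms_to_binary`.
    """
    vocabulary = tuple(vocabulary) if vocabulary is not None else terms.vocabulary
    if len(vocabulary) != len(terms.bits):
        raise ValueError("vocabulary length must match the term vector")
    names = [vocabulary[t] for t in np.flatnonzero(terms.bits)]
    if not names:
        return "No notable findings."
    rng = np.random.default_rng(rng_seed)
    parts = [names[0]]
    for name in names[1:]:
        parts.append(str(rng.choice(_LINKERS)))
        parts.append(name)
    return "Biopsy shows " + " ".join(parts) + "."
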