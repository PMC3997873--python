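"""Image loading, term-vocabulary handling and bag serialization.

A skin-biopsy image is represented downstream as a *bag*: one feature row per
visually disjoint region, plus a binary term vector over a fixed vocabulary of
dermatopathology annotation terms.  This module owns the light-weight
containers (:class:`TermVector`, :class:`Bag`), the word-matching conversion
of free-text descriptions into binary term vectors, and a diffable on-disk
format (TSV instance tables + TSV labels + JSON vocabulary).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

#: The 15 standard dermatopathology annotation terms, in canonical order.
DEFAULT_VOCABULARY: tuple[str, ...] = (
    "Retraction space",
    "Papillomatosis",
    "Follicular plug",
    "Hypergranulosis",
    "Horn cyst",
    "Basal cell liquefaction degeneration",
    "Thin prickle cell layer",
    "Infiltration of lymphocytes",
    "Hyperpigmentation of Basal cell layer",
    "Nevocytic nests",
    "Munro microabscess",
    "Acanthosis",
    "Absent granular cell layer",
    "Parakeratosis",
    "Hyperkeratosis",
)

#: Occurrence frequency of each term in a representative clinical corpus,
#: aligned with :data:`DEFAULT_VOCABULARY`.
DEFAULT_TERM_FREQUENCIES: tuple[float, ...] = (
    0.2865,
    0.2271,
    0.018,
    0.3215,
    0.0414,
    0.0648,
    0.0261,
    0.0912,
    0.3699,
    0.1856,
    0.0772,
    0.1905,
    0.2324,
    0.0681,
    0.1130,
)

DEFAULT_IMAGE_SIZE: tuple[int, int] = (800, 600)  # (width, height)


@dataclass(frozen=True)
class TermVector:
    """Binary indicator vector over a term vocabulary.

    Bit ``t`` is set iff the image (bag) is annotated with vocabulary term
    ``t``.  Length always equals the vocabulary size.
    """

    bits: np.ndarray
    vocabulary: tuple[str, ...] = DEFAULT_VOCABULARY

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=np.int8)
        if bits.ndim != 1 or len(bits) != len(self.vocabulary):
            raise ValueError(
                f"term vector length {bits.shape} does not match vocabulary "
                f"size {len(self.vocabulary)}"
            )
        if not np.isin(bits, (0, 1)).all():
            raise ValueError("term vector entries must be binary")
        object.__setattr__(self, "bits", bits)

    @property
    def terms(self) -> tuple[str, ...]:
        """Names of the set terms, in vocabulary order."""
        return tuple(t for t, b in zip(self.vocabulary, self.bits) if b)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TermVector):
            return NotImplemented
        return (
            self.vocabulary == other.vocabulary
            and np.array_equal(self.bits, other.bits)
        )


@dataclass
class Bag:
    """One image as a multi-instance example: one feature row per region."""

    instances: np.ndarray
    source_id: str = ""
    region_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        inst = np.asarray(self.instances, dtype=float)
        if inst.ndim != 2 or inst.shape[0] < 1:
            raise ValueError("a bag needs a 2-D instance matrix with >= 1 row")
        if not np.isfinite(inst).all():
            raise ValueError("bag instances must be finite")
        self.instances = inst
        if not self.region_ids:
            self.region_ids = list(range(inst.shape[0]))
        elif len(self.region_ids) != inst.shape[0]:
            raise ValueError("region_ids length must match instance count")

    @property
    def n_instances(self) -> int:
        return self.instances.shape[0]

    @property
    def dim(self) -> int:
        return self.instances.shape[1]


def load_and_rescale(path, target_size: tuple[int, int] = DEFAULT_IMAGE_SIZE) -> np.ndarray:
    """Load a raster image and resize it to ``target_size`` (width, height).

    Returns an ``(H, W, 3)`` uint8 RGB array.  Aspect ratio is not preserved:
    the image is resized directly to the target geometry.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im = im.convert("RGB")
            if im.size != tuple(target_size):
                im = im.resize(tuple(target_size), Image.BILINEAR)
            return np.asarray(im, dtype=np.uint8)
    except OSError as exc:
        raise OSError(f"cannot read image file {path!s}: {exc}") from exc


def terms_to_binary(text: str, vocabulary=DEFAULT_VOCABULARY) -> TermVector:
    """Word-match a free-text description against a term vocabulary.

    Bit ``t`` is set iff the full term name occurs in ``text``,
    case-insensitively and on word boundaries.  Matching is set-valued:
    repeating a term in the text does not change the result.
    """
    vocabulary = tuple(vocabulary)
    if not vocabulary:
        raise ValueError("vocabulary must be nonempty")
    lowered = [v.lower() for v in vocabulary]
    if len(set(lowered)) != len(lowered):
        raise ValueError("vocabulary names must be unique (case-insensitive)")
    bits = np.zeros(len(vocabulary), dtype=np.int8)
    for t, name in enumerate(vocabulary):
        pattern = r"(?<!\w)" + re.escape(name) + r"(?!\w)"
        if re.search(pattern, text, flags=re.IGNORECASE):
            bits[t] = 1
    return TermVector(bits, vocabulary)


def _label_path(path: Path) -> Path:
    return path.with_name(path.stem + ".labels.tsv")


def _vocab_path(path: Path) -> Path:
    return path.with_name(path.stem + ".vocab.json")


def write_bags(bags: list[Bag], labels: list[TermVector], path) -> None:
    """Serialize bags + labels to TSV with a JSON vocabulary side-car.

    The main file has columns ``bag_id, region_id, f1..fd``; the side-car
    ``<stem>.labels.tsv`` has ``bag_id, t1..ts``; the vocabulary is stored in
    ``<stem>.vocab.json``.  All floats are written at full precision.
    """
    path = Path(path)
    if len(bags) != len(labels):
        raise ValueError("bags and labels must have equal length")
    dims = {b.dim for b in bags}
    if len(dims) > 1:
        raise ValueError(f"all bags must share one feature dimension, got {dims}")
    d = dims.pop() if dims else 0
    vocab = labels[0].vocabulary if labels else DEFAULT_VOCABULARY

    rows = []
    for b in bags:
        for rid, row in zip(b.region_ids, b.instances):
            rows.append([b.source_id, rid, *row])
    cols = ["bag_id", "region_id"] + [f"f{j + 1}" for j in range(d)]
    pd.DataFrame(rows, columns=cols).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )

    lab_rows = [[b.source_id, *lv.bits] for b, lv in zip(bags, labels)]
    lab_cols = ["bag_id"] + [f"t{j + 1}" for j in range(len(vocab))]
    pd.DataFrame(lab_rows, columns=lab_cols).to_csv(
        _label_path(path), sep="\t", index=False
    )
    _vocab_path(path).write_text(json.dumps(list(vocab), indent=1))


def read_bags(path) -> tuple[list[Bag], list[TermVector]]:
    """Read bags written by :func:`write_bags`; inverse up to float precision."""
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", dtype={"bag_id": str}, float_precision="round_trip"
    )
    for col in ("bag_id", "region_id"):
        if col not in df.columns:
            raise ValueError(f"bag file {path!s} is missing column {col!r}")
    fcols = [c for c in df.columns if re.fullmatch(r"f\d+", c)]
    expected = [f"f{j + 1}" for j in range(len(fcols))]
    if fcols != expected:
        raise ValueError(f"bag file {path!s} has malformed feature columns {fcols}")
    if df[fcols].isna().any().any():
        raise ValueError(
            f"bag file {path!s}: missing feature values (inconsistent dimension d)"
        )

    vocab = tuple(json.loads(_vocab_path(path).read_text()))
    lab = pd.read_csv(_label_path(path), sep="\t", dtype={"bag_id": str})
    tcols = [f"t{j + 1}" for j in range(len(vocab))]
    for col in ["bag_id"] + tcols:
        if col not in lab.columns:
            raise ValueError(f"label file for {path!s} is missing column {col!r}")

    bags, labels = [], []
    by_label = lab.set_index("bag_id")
    for bag_id, grp in df.groupby("bag_id", sort=False):
        bags.append(
            Bag(
                instances=grp[fcols].to_numpy(float),
                source_id=str(bag_id),
                region_ids=[int(r) for r in grp["region_id"]],
            )
        )
        if bag_id not in by_label.index:
            raise ValueError(f"bag {bag_id!r} has no label row")
        labels.append(
            TermVector(by_label.loc[bag_id, tcols].to_numpy(np.int8), vocab)
        )
    return bags, labels


def write_predictions(bag_ids, prob_matrix, path, vocabulary=DEFAULT_VOCABULARY) -> None:
    """Write per-bag term probabilities as a TSV (bag_id + one column per term)."""
    prob_matrix = np.asarray(prob_matrix, dtype=float)
    cols = ["bag_id"] + [f"t{j + 1}" for j in range(len(vocabulary))]
    rows = [[bid, *p] for bid, p in zip(bag_ids, prob_matrix)]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False, float_format="%.17g")
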