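"""Instance-mask data model, overlap measures and binary morphology.

Conventions used throughout the package:

* masks and label maps are 2-D, row-major, 0-based, origin at the top-left;
* connected components use 8-connectivity (nucleus blobs are compact and
  8-connectivity is the standard choice for them);
* a label map stores ``0`` for background and positive integers for
  instances; no pixel ever carries two labels;
* run-length encoding is COCO-style *uncompressed* RLE: column-major
  (Fortran order) pixel stream, ``counts`` alternating runs starting with
  the background run.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from PIL import Image
from scipy import ndimage as ndi
from skimage.morphology import disk

#: connectivity used for every component-labeling call in the package
CONNECTIVITY_STRUCT = np.ones((3, 3), dtype=bool)


class GeometryError(ValueError):
    """Two grids that must share a geometry do not."""


class EmptyMaskError(ValueError):
    """An operation received an all-background mask where foreground is required."""


def _check_same_geometry(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise GeometryError(f"mask geometry mismatch: {a.shape} vs {b.shape}")


def _as_bool(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m)
    if m.ndim != 2:
        raise GeometryError(f"expected a 2-D mask, got shape {m.shape}")
    return m.astype(bool, copy=False)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ScoredMask:
    """One binary instance mask plus the confidence of the model that produced it.

    Parameters
    ----------
    pixels
        Boolean foreground mask over the full tile grid.
    score
        Classification confidence in ``[0, 1]``.
    source_id
        Identifier of the producing model or cross-validation fold.
    """

    pixels: np.ndarray
    score: float
    source_id: int = 0

    def __post_init__(self) -> None:
        self.pixels = _as_bool(self.pixels)
        if not self.pixels.any():
            raise EmptyMaskError("a ScoredMask needs at least one foreground pixel")
        score = float(self.score)
        if not np.isfinite(score):
            raise ValueError(f"non-finite score: {self.score!r}")
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"score must lie in [0, 1], got {score}")
        self.score = score

    @property
    def area(self) -> int:
        return int(self.pixels.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class MaskSet:
    """An ordered collection of :class:`ScoredMask` sharing one grid geometry."""

    masks: list[ScoredMask] = field(default_factory=list)

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.masks}
        if len(shapes) > 1:
            raise GeometryError(f"masks with mixed geometries: {sorted(shapes)}")

    @property
    def shape(self) -> tuple[int, int] | None:
        return self.masks[0].shape if self.masks else None

    def __len__(self) -> int:
        return len(self.masks)

    def __iter__(self) -> Iterator[ScoredMask]:
        return iter(self.masks)

    def __getitem__(self, i: int) -> ScoredMask:
        return self.masks[i]


@dataclass
class InstanceLabelMap:
    """2-D grid of non-negative integer labels; 0 = background, k>0 = instance k."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise GeometryError(f"label map must be 2-D, got shape {lab.shape}")
        if lab.size and lab.min() < 0:
            raise ValueError("label map contains negative labels")
        self.labels = lab.astype(np.int32, copy=False)

    @property
    def height(self) -> int:
        return self.labels.shape[0]

    @property
    def width(self) -> int:
        return self.labels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def instance_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_instances(self) -> int:
        return int(self.instance_ids.size)

    def foreground(self) -> np.ndarray:
        return self.labels > 0

    def instance_mask(self, label: int) -> np.ndarray:
        return self.labels == label


def as_labels(lm: InstanceLabelMap | np.ndarray) -> np.ndarray:
    """Coerce a label map or bare integer array to the underlying array."""
    return lm.labels if isinstance(lm, InstanceLabelMap) else InstanceLabelMap(np.asarray(lm)).labels


# ---------------------------------------------------------------------------
# overlap measures
# ---------------------------------------------------------------------------


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union (Jaccard index) of two binary masks.

    Raises if the two masks are both empty: a 0/0 comparison almost always
    means a degenerate fixture upstream and should surface, not score 1.
    """
    a, b = _as_bool(a), _as_bool(b)
    _check_same_geometry(a, b)
    inter = int(np.count_nonzero(a & b))
    union_ = int(np.count_nonzero(a)) + int(np.count_nonzero(b)) - inter
    if union_ == 0:
        raise EmptyMaskError("iou of two empty masks is undefined")
    return inter / union_


def dice_binary(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient ``2|a∩b| / (|a|+|b|)`` of two binary masks."""
    a, b = _as_bool(a), _as_bool(b)
    _check_same_geometry(a, b)
    sa, sb = int(np.count_nonzero(a)), int(np.count_nonzero(b))
    if sa + sb == 0:
        raise EmptyMaskError("dice of two empty masks is undefined")
    return 2 * int(np.count_nonzero(a & b)) / (sa + sb)


def union(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pixelwise OR of two masks sharing a geometry."""
    a, b = _as_bool(a), _as_bool(b)
    _check_same_geometry(a, b)
    return a | b


# ---------------------------------------------------------------------------
# morphology
# ---------------------------------------------------------------------------


def fill_holes(m: np.ndarray) -> np.ndarray:
    """Fill background components not connected to the grid border.

    Output is always a superset of the input and the operation is idempotent.
    """
    m = _as_bool(m)
    if not m.any():
        raise EmptyMaskError("fill_holes of an empty mask")
    return ndi.binary_fill_holes(m)


def split_touching(m: np.ndarray, erosion_radius: int = 2) -> InstanceLabelMap:
    """Split fused blobs by erosion, relabeling and seed-limited dilation.

    The mask is eroded with a disk of ``erosion_radius``, the surviving
    components become seeds, and every original foreground pixel within
    ``erosion_radius`` (Euclidean) of a seed is assigned to its nearest
    seed — ties go to the lower seed label.  Labeled pixels are always a
    subset of the input foreground.  If the erosion removes all foreground
    the input is returned as a single instance with a warning.
    """
    m = _as_bool(m)
    if erosion_radius < 1:
        raise ValueError("erosion_radius must be >= 1")
    if not m.any():
        raise EmptyMaskError("split_touching of an empty mask")
    selem = disk(erosion_radius).astype(bool)
    eroded = ndi.binary_erosion(m, structure=selem)
    if not eroded.any():
        warnings.warn("over-eroded: erosion removed all foreground; "
                      "returning the input as one instance", stacklevel=2)
        return InstanceLabelMap(m.astype(np.int32))
    seeds, n = ndi.label(eroded, structure=CONNECTIVITY_STRUCT)
    if n == 1:
        # single seed: the opening question is moot; keep all pixels within
        # reach of the seed
        dist = ndi.distance_transform_edt(seeds == 0)
        out = np.where(m & (dist <= erosion_radius), 1, 0)
        if not out.any():  # pragma: no cover - defensive
            out = m.astype(np.int32)
        return InstanceLabelMap(out.astype(np.int32))
    # per-seed distance maps; argmin resolves contested pixels to the lower
    # label because np.argmin takes the first minimum
    dists = np.stack([ndi.distance_transform_edt(seeds != k) for k in range(1, n + 1)])
    nearest = np.argmin(dists, axis=0)
    mindist = np.min(dists, axis=0)
    keep = m & (mindist <= erosion_radius)
    out = np.where(keep, nearest + 1, 0).astype(np.int32)
    return InstanceLabelMap(out)


# ---------------------------------------------------------------------------
# conversions
# ---------------------------------------------------------------------------


def label_map_to_masks(lm: InstanceLabelMap | np.ndarray,
                       default_score: float = 1.0) -> MaskSet:
    """Explode a label map into one :class:`ScoredMask` per instance."""
    labels = as_labels(lm)
    masks = [ScoredMask(labels == k, default_score, source_id=int(k))
             for k in np.unique(labels) if k > 0]
    return MaskSet(masks)


def _priority_order(ms: MaskSet) -> list[int]:
    """Indices of ``ms`` from lowest to highest paint priority.

    Higher score wins, then larger area, then lower source_id, then lower
    insertion index — so the winner is painted last.
    """
    def key(i: int):
        m = ms[i]
        return (m.score, m.area, -_source_rank(m.source_id), -i)

    return sorted(range(len(ms)), key=key)


def _source_rank(source_id) -> float:
    try:
        return float(source_id)
    except (TypeError, ValueError):
        return float(abs(hash(str(source_id))) % 10**9)


def masks_to_label_map(ms: MaskSet,
                       shape: tuple[int, int] | None = None) -> InstanceLabelMap:
    """Rasterize a mask set; contested pixels go to the higher-priority mask.

    Priority: higher score, then larger area, then lower ``source_id``.
    Output labels are 1..n in the (deterministic) paint order of the winners.
    """
    if not len(ms):
        if shape is None:
            raise ValueError("cannot rasterize an empty MaskSet without a shape")
        return InstanceLabelMap(np.zeros(shape, dtype=np.int32))
    out = np.zeros(ms.shape, dtype=np.int32)
    order = _priority_order(ms)
    # stable instance numbering: label by position in the original set
    for i in order:
        out[ms[i].pixels] = i + 1
    # relabel to a contiguous 1..k range, dropping masks fully painted over
    kept = np.unique(out)
    kept = kept[kept > 0]
    remap = np.zeros(len(ms) + 1, dtype=np.int32)
    remap[kept] = np.arange(1, kept.size + 1)
    return InstanceLabelMap(remap[out])


# ---------------------------------------------------------------------------
# I/O — 16-bit label images and COCO-style uncompressed RLE JSON
# ---------------------------------------------------------------------------


def rle_encode(m: np.ndarray) -> dict:
    """Encode a binary mask as uncompressed column-major RLE."""
    m = _as_bool(m)
    h, w = m.shape
    flat = m.flatten(order="F").astype(np.int8)
    # run boundaries
    change = np.flatnonzero(np.diff(flat)) + 1
    bounds = np.concatenate(([0], change, [flat.size]))
    counts = np.diff(bounds).tolist()
    if flat.size and flat[0] == 1:  # counts must start with the zero-run
        counts = [0] + counts
    return {"size": [int(h), int(w)], "counts": [int(c) for c in counts]}


def rle_decode(rle: dict) -> np.ndarray:
    """Decode uncompressed column-major RLE into a boolean mask."""
    h, w = (int(v) for v in rle["size"])
    counts = rle["counts"]
    if sum(counts) != h * w:
        raise ValueError("RLE counts do not cover the grid")
    flat = np.zeros(h * w, dtype=bool)
    pos, val = 0, False
    for c in counts:
        if val:
            flat[pos:pos + c] = True
        pos += c
        val = not val
    return flat.reshape((h, w), order="F")


def save_mask_set(ms: MaskSet, path: str | os.PathLike) -> None:
    """Write a mask set as RLE JSON (atomic replace)."""
    payload = {
        "masks": [
            {**rle_encode(m.pixels), "score": m.score, "source_id": m.source_id}
            for m in ms
        ]
    }
    tmp = f"{path}.tmp"
    with open(tmp, "w") as fh:
        json.dump(payload, fh)
    os.replace(tmp, path)


def load_mask_set(path: str | os.PathLike) -> MaskSet:
    with open(path) as fh:
        payload = json.load(fh)
    masks = [
        ScoredMask(rle_decode(rec), float(rec.get("score", 1.0)),
                   rec.get("source_id", 0))
        for rec in payload["masks"]
    ]
    return MaskSet(masks)


def save_label_map(lm: InstanceLabelMap | np.ndarray, path: str | os.PathLike) -> None:
    """Write a label map as a 16-bit single-channel PNG or TIFF."""
    labels = as_labels(lm)
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 instances cannot be stored in 16-bit")
    arr = labels.astype(np.uint16)
    path = os.fspath(path)
    tmp = f"{path}.tmp"
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(tmp, arr)
    else:
        Image.fromarray(arr).save(tmp, format="PNG")
    os.replace(tmp, path)


def load_label_map(path: str | os.PathLike) -> InstanceLabelMap:
    path = os.fspath(path)
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        arr = tifffile.imread(path)
    else:
        arr = np.array(Image.open(path))
    return InstanceLabelMap(arr.astype(np.int32))


def relabel_canonical(lm: InstanceLabelMap | np.ndarray) -> InstanceLabelMap:
    """Relabel instances 1..k in order of first (row-major) pixel appearance.

    Two label maps describe the same segmentation iff their canonical forms
    are equal; used by tests comparing outputs up to relabeling.
    """
    labels = as_labels(lm)
    flat = labels.ravel()
    first = {}
    for pos in np.flatnonzero(flat):
        lab = flat[pos]
        if lab not in first:
            first[lab] = pos
    order = sorted(first, key=first.get)
    remap = np.zeros(labels.max() + 1, dtype=np.int32)
    for new, old in enumerate(order, start=1):
        remap[old] = new
    return InstanceLabelMap(remap[labels])
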