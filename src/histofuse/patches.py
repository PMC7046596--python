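"""Tissue detection and patch machinery for whole-slide tissue tiles.

The three case-classification strategies share a common front end: find
tissue on the slide (glass background is useless), carve the tissue into
fixed-size RGB patches, normalize stain color, optionally filter atypical
patches, and finally aggregate per-patch class probabilities into one
per-case probability pair.  This module implements that front end for
ordinary RGB tiles; pyramidal WSI container formats are out of scope.

Tissue detection comes in two flavors used by the respective methods:
HSV in-range thresholding with hole/clump cleanup, and Otsu thresholding on
a grayscale tile (the darker class is tissue).  Patch extraction likewise
comes as an exhaustive grid within tissue bounding boxes and as uniform
random sampling of tissue-covered windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from skimage import color as skcolor
from skimage import transform as sktransform
from skimage.measure import label as sklabel
from skimage.measure import regionprops
from skimage.morphology import remove_small_holes, remove_small_objects
from sklearn.ensemble import IsolationForest

from .cases import CaseProbabilities

#: default HSV bounds — anything with a little saturation counts as tissue
DEFAULT_HSV_LO: tuple[float, float, float] = (0.0, 0.05, 0.0)
DEFAULT_HSV_HI: tuple[float, float, float] = (1.0, 1.0, 1.0)
#: default downsample factor for tissue detection on large tiles
DEFAULT_DETECT_SCALE = 32
#: default cleanup sizes (pixels at the working scale)
DEFAULT_MIN_HOLE = 64
DEFAULT_MIN_OBJECT = 64


@dataclass
class TissueMask:
    """Binary tissue mask over a (possibly downsampled) tile."""

    pixels: np.ndarray
    scale: int = 1

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2:
            raise ValueError("tissue mask must be 2-D")
        if self.scale < 1:
            raise ValueError("scale must be >= 1")

    def at_full_resolution(self, shape: tuple[int, int]) -> np.ndarray:
        """Expand the mask back to source resolution, cropped to ``shape``."""
        if self.scale == 1 and self.pixels.shape == tuple(shape):
            return self.pixels
        big = np.repeat(np.repeat(self.pixels, self.scale, axis=0), self.scale, axis=1)
        h, w = shape
        out = np.zeros((h, w), dtype=bool)
        out[:min(h, big.shape[0]), :min(w, big.shape[1])] = \
            big[:min(h, big.shape[0]), :min(w, big.shape[1])]
        return out


@dataclass
class PatchRecord:
    """An extracted tile patch with its provenance."""

    origin: tuple[int, int]
    size: int
    pixels: np.ndarray
    label: int | None = None
    probs: CaseProbabilities | None = None
    augmented: bool = False
    padded: bool = False


def _as_rgb(rgb: np.ndarray) -> np.ndarray:
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"expected an H×W×3 RGB tile, got shape {rgb.shape}")
    return rgb


# ---------------------------------------------------------------------------
# tissue detection
# ---------------------------------------------------------------------------


def tissue_mask_hsv(rgb: np.ndarray,
                    lo: Sequence[float] = DEFAULT_HSV_LO,
                    hi: Sequence[float] = DEFAULT_HSV_HI,
                    min_hole: int = DEFAULT_MIN_HOLE,
                    min_object: int = DEFAULT_MIN_OBJECT,
                    scale: int = 1) -> TissueMask:
    """HSV in-range tissue detection with hole filling and clump removal.

    Pixels whose HSV triple lies channelwise within ``[lo, hi]`` become
    foreground; holes smaller than ``min_hole`` are filled and components
    smaller than ``min_object`` removed.  ``scale`` block-averages the tile
    before thresholding so detection on large tiles stays cheap.
    """
    rgb = _as_rgb(rgb)
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    if (lo > hi).any():
        raise ValueError("lo must be <= hi channelwise")
    if (lo == hi).all():
        warnings.warn("degenerate HSV thresholds (lo == hi); mask may be empty",
                      stacklevel=2)
    if scale > 1:
        rgb = sktransform.downscale_local_mean(
            rgb.astype(float), (scale, scale, 1))
        if rgb.max() > 1:
            rgb = np.clip(rgb / 255.0, 0, 1)
    hsv = skcolor.rgb2hsv(rgb)
    mask = np.all((hsv >= lo) & (hsv <= hi), axis=2)
    if mask.any():
        # thresholds are exclusive: holes/objects strictly smaller go
        if min_hole > 1:
            mask = remove_small_holes(mask, max_size=min_hole - 1)
        if min_object > 1:
            mask = remove_small_objects(mask, max_size=min_object - 1)
    return TissueMask(mask, scale=scale)


def tissue_mask_otsu(gray: np.ndarray, scale: int = 1) -> TissueMask:
    """Otsu split of a grayscale tile; the darker class is tissue.

    On an H&E slide the glass background is bright, so thresholding the
    intensity histogram and keeping the dark side isolates the tissue.
    """
    from skimage.filters import threshold_otsu

    gray = np.asarray(gray, dtype=float)
    if gray.ndim != 2:
        raise ValueError("expected a 2-D grayscale tile")
    if scale > 1:
        gray = sktransform.downscale_local_mean(gray, (scale, scale))
    if np.unique(gray).size < 2:
        raise ValueError("constant image: Otsu threshold undefined")
    t = threshold_otsu(gray)
    return TissueMask(gray < t, scale=scale)


def tissue_bounding_boxes(tm: TissueMask) -> list[tuple[int, int, int, int]]:
    """Half-open bounding boxes ``(r0, c0, r1, c1)`` per tissue component.

    Coordinates are in source pixels (the mask's downsample factor is
    applied).  Components are 8-connected.
    """
    lab = sklabel(tm.pixels, connectivity=2)
    s = tm.scale
    return [(p.bbox[0] * s, p.bbox[1] * s, p.bbox[2] * s, p.bbox[3] * s)
            for p in regionprops(lab)]


# ---------------------------------------------------------------------------
# patch extraction
# ---------------------------------------------------------------------------


def extract_patches_grid(rgb: np.ndarray,
                         boxes: Sequence[tuple[int, int, int, int]],
                         size: int, stride: int | None = None,
                         label: int | None = None) -> list[PatchRecord]:
    """Row-major grid of patches inside each bounding box.

    Patches that would cross a box edge are dropped, not padded.  ``stride``
    defaults to ``size`` (non-overlapping tiling).
    """
    rgb = _as_rgb(rgb)
    if size < 1:
        raise ValueError("size must be >= 1")
    stride = size if stride is None else stride
    if stride < 1:
        raise ValueError("stride must be >= 1")
    h, w = rgb.shape[:2]
    out: list[PatchRecord] = []
    for r0, c0, r1, c1 in boxes:
        r1, c1 = min(r1, h), min(c1, w)
        for r in range(r0, r1 - size + 1, stride):
            for c in range(c0, c1 - size + 1, stride):
                out.append(PatchRecord((r, c), size,
                                       rgb[r:r + size, c:c + size].copy(),
                                       label=label))
    return out


def extract_patches_random(rgb: np.ndarray, tm: TissueMask, size: int,
                           n: int, min_tissue_frac: float = 0.5,
                           seed: int = 0,
                           label: int | None = None) -> list[PatchRecord]:
    """Uniform random sampling of ``n`` tissue-covered patches.

    A window origin is valid when the tissue fraction under the window is at
    least ``min_tissue_frac``; origins are drawn uniformly without
    replacement, deterministically for a fixed ``seed``.  If fewer than
    ``n`` origins qualify, all of them are returned with a warning.
    """
    rgb = _as_rgb(rgb)
    if n < 1:
        raise ValueError("n must be >= 1")
    h, w = rgb.shape[:2]
    if size > h or size > w:
        raise ValueError("patch size exceeds the tile")
    full = tm.at_full_resolution((h, w)).astype(np.int64)
    ii = np.zeros((h + 1, w + 1), dtype=np.int64)
    ii[1:, 1:] = full.cumsum(0).cumsum(1)
    # tissue pixel count for every size×size window
    win = (ii[size:, size:] - ii[:-size, size:]
           - ii[size:, :-size] + ii[:-size, :-size])
    valid = np.flatnonzero(win >= min_tissue_frac * size * size - 1e-9)
    if valid.size == 0:
        warnings.warn("no window meets the tissue-fraction requirement",
                      stacklevel=2)
        return []
    rng = np.random.default_rng(seed)
    if valid.size < n:
        warnings.warn(f"only {valid.size} valid origins for {n} requested patches",
                      stacklevel=2)
        chosen = valid
    else:
        chosen = rng.choice(valid, size=n, replace=False)
    wcols = w - size + 1
    out = []
    for idx in chosen:
        r, c = divmod(int(idx), wcols)
        out.append(PatchRecord((r, c), size, rgb[r:r + size, c:c + size].copy(),
                               label=label))
    return out


# ---------------------------------------------------------------------------
# color normalization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReinhardStats:
    """Per-channel LAB means and standard deviations of a reference tile."""

    means: tuple[float, float, float]
    stds: tuple[float, float, float]


def reinhard_stats(rgb: np.ndarray) -> ReinhardStats:
    """LAB channel statistics of a tile, for use as a Reinhard target."""
    lab = skcolor.rgb2lab(_to_float(_as_rgb(rgb)))
    return ReinhardStats(tuple(lab.reshape(-1, 3).mean(0)),
                         tuple(lab.reshape(-1, 3).std(0)))


def _to_float(rgb: np.ndarray) -> np.ndarray:
    if rgb.dtype == np.uint8:
        return rgb / 255.0
    return np.clip(rgb.astype(float), 0, 1)


def color_normalize(p: PatchRecord, method: str = "reinhard",
                    target_stats: ReinhardStats | None = None) -> PatchRecord:
    """Stain-color normalization of one patch.

    ``reinhard`` matches per-channel mean and standard deviation in the LAB
    luminance-chrominance space to ``target_stats``; ``hist_eq`` applies the
    classic per-channel cumulative-histogram equalization, spreading each
    channel's levels to the full 0–255 range.  Output is uint8 RGB.
    """
    rgb = _as_rgb(p.pixels)
    if method == "reinhard":
        if target_stats is None:
            raise ValueError("reinhard normalization needs target_stats")
        lab = skcolor.rgb2lab(_to_float(rgb))
        flat = lab.reshape(-1, 3)
        mean, std = flat.mean(0), flat.std(0)
        if np.any(std < 1e-8):
            warnings.warn("constant-color patch: reinhard left it unchanged",
                          stacklevel=2)
            return replace(p)
        mapped = (lab - mean) / std * np.asarray(target_stats.stds) \
            + np.asarray(target_stats.means)
        out = np.clip(skcolor.lab2rgb(mapped), 0, 1)
        return replace(p, pixels=(out * 255).round().astype(np.uint8))
    if method == "hist_eq":
        img = rgb if rgb.dtype == np.uint8 else \
            np.clip(rgb * 255, 0, 255).round().astype(np.uint8)
        out = np.empty_like(img)
        for ch in range(3):
            out[..., ch] = _equalize_channel(img[..., ch])
        return replace(p, pixels=out)
    raise ValueError(f"unknown normalization method: {method!r}")


def _equalize_channel(ch: np.ndarray) -> np.ndarray:
    # classic equalization with min-shift so the darkest occupied level maps
    # to 0 and the brightest to 255
    hist = np.bincount(ch.ravel(), minlength=256)
    cdf = hist.cumsum()
    cdf_min = cdf[np.nonzero(hist)[0][0]]
    denom = cdf[-1] - cdf_min
    if denom == 0:  # constant channel
        return ch.copy()
    lut = np.round((cdf - cdf_min) / denom * 255).clip(0, 255).astype(np.uint8)
    return lut[ch]


# ---------------------------------------------------------------------------
# patch filtering, balancing and selection
# ---------------------------------------------------------------------------


def filter_patches_iforest(features: Sequence[np.ndarray],
                           contamination: float, seed: int = 0,
                           n_estimators: int = 100) -> list[int]:
    """Indices of inlier patches per an isolation forest.

    Atypical patches — pen marks, folds, blur, necrosis islands — isolate in
    few random splits and score as anomalies; the stated ``contamination``
    fraction of most anomalous patches is dropped.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least two equal-length feature vectors")
    if not 0.0 <= contamination < 0.5:
        raise ValueError("contamination must lie in [0, 0.5)")
    if contamination == 0.0:
        return list(range(X.shape[0]))
    forest = IsolationForest(n_estimators=n_estimators,
                             contamination=contamination, random_state=seed)
    flags = forest.fit_predict(X)
    return [int(i) for i in np.flatnonzero(flags == 1)]


_DIHEDRAL = (
    lambda a: np.rot90(a, 1),
    lambda a: np.rot90(a, 2),
    lambda a: np.rot90(a, 3),
    lambda a: a[:, ::-1],            # horizontal flip
    lambda a: a[::-1, :],            # vertical flip
    lambda a: np.rot90(a[:, ::-1], 1),
    lambda a: np.rot90(a[::-1, :], 1),
)


def balance_by_rotation(patches: Sequence[PatchRecord],
                        seed: int = 0,
                        max_angle: float = 15.0) -> list[PatchRecord]:
    """Equalize class counts by rotated/flipped copies of minority patches.

    Deterministic dihedral transforms (90°/180°/270° rotations, flips) are
    exhausted first, then random small-angle rotations (≤ ``max_angle``
    degrees, reflected padding).  Originals are always retained; augmented
    copies carry ``augmented=True``.
    """
    if not patches:
        raise ValueError("no patches to balance")
    by_class: dict[int, list[PatchRecord]] = {}
    for p in patches:
        if p.label is None:
            raise ValueError("every patch needs a class label to balance")
        by_class.setdefault(p.label, []).append(p)
    if any(len(v) == 0 for v in by_class.values()):  # pragma: no cover
        raise ValueError("a class with zero patches cannot be balanced")
    target = max(len(v) for v in by_class.values())
    rng = np.random.default_rng(seed)
    out: list[PatchRecord] = list(patches)
    for cls in sorted(by_class):
        group = by_class[cls]
        need = target - len(group)
        added = 0
        # deterministic transforms first: transform t of original i
        for t in range(len(_DIHEDRAL)):
            for src in group:
                if added >= need:
                    break
                out.append(replace(src, pixels=_DIHEDRAL[t](src.pixels).copy(),
                                   augmented=True))
                added += 1
            if added >= need:
                break
        while added < need:
            src = group[int(rng.integers(len(group)))]
            angle = float(rng.uniform(-max_angle, max_angle))
            rot = sktransform.rotate(src.pixels, angle, mode="reflect",
                                     preserve_range=True)
            out.append(replace(src, pixels=rot.astype(src.pixels.dtype),
                               augmented=True))
            added += 1
    return out


def select_effective_patches(patches: Sequence[PatchRecord],
                             threshold: float = 0.99) -> list[PatchRecord]:
    """Keep patches whose maximum class probability reaches ``threshold``.

    A high threshold keeps only patches the classifier is nearly certain
    about — the "effective" diseased areas.  If nothing qualifies the single
    most confident patch is returned with a warning so a case never ends up
    without evidence.
    """
    if not patches:
        raise ValueError("no patches to select from")
    if any(p.probs is None for p in patches):
        raise ValueError("every patch needs class probabilities")
    kept = [p for p in patches if p.probs.confidence >= threshold]
    if kept:
        return kept
    warnings.warn("no patch reached the confidence threshold; "
                  "falling back to the single most confident patch",
                  stacklevel=2)
    best = max(range(len(patches)), key=lambda i: (patches[i].probs.confidence, -i))
    return [patches[best]]


def aggregate_patch_votes(patches: Sequence[PatchRecord],
                          mode: str = "mean_prob") -> CaseProbabilities:
    """Pool per-patch probabilities into one per-case probability pair.

    ``mean_prob`` averages the probability vectors; ``majority_frac``
    counts argmax votes (exact ties contribute half a vote to each class).
    """
    if not patches:
        raise ValueError("no patches to aggregate")
    if any(p.probs is None for p in patches):
        raise ValueError("every patch needs class probabilities")
    P = np.array([p.probs.as_array for p in patches])
    if mode == "mean_prob":
        v = P.mean(axis=0)
    elif mode == "majority_frac":
        votes = np.zeros(2)
        for row in P:
            if row[0] > row[1]:
                votes[0] += 1
            elif row[1] > row[0]:
                votes[1] += 1
            else:
                votes += 0.5
        v = votes / len(patches)
    else:
        raise ValueError(f"unknown aggregation mode: {mode!r}")
    v = v / v.sum()
    return CaseProbabilities(float(v[0]), float(v[1]), modality="pathology")
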