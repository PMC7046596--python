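"""Deterministic synthetic stand-ins for challenge data and deep predictors.

Three generators cover the three data regimes the toolkit operates on:

* :func:`gen_nuclei_scene` — an H&E-like RGB tile with non-overlapping
  textured elliptical nuclei and its ground-truth instance label map;
* :func:`perturb_truth` — a scored candidate mask set emulating what one
  cross-validation fold's segmentation model would emit: per-instance
  jitter and morphological dither, dropped instances (false negatives),
  spurious blobs (false positives), split and merged instances, and
  overlap-correlated confidence scores;
* :func:`gen_cohort` — a two-modality case cohort with controllable
  class-informativeness per modality, plus dropout-style stochastic feature
  extractors satisfying the pluggable-predictor contract.

Everything is a pure function of its seed; identical calls are
bit-identical.  The synthetic tiles make no attempt at photorealism — they
exist so the geometry, scoring and fusion machinery can be exercised at
known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation, binary_erosion
from skimage.draw import ellipse as draw_ellipse

from .cases import CaseProbabilities, LABEL_ASTRO, LABEL_OLIGO
from .masks import InstanceLabelMap, MaskSet, ScoredMask, as_labels

# ---------------------------------------------------------------------------
# nuclei scenes
# ---------------------------------------------------------------------------

#: standard scene conditions used by the shipped fixtures: 10 nuclei on a
#: 256×256 tile, nucleus radii 5–9 px (densities comparable to the
#: challenge's hand-annotated tiles)
STANDARD_SCENE = dict(n=10, height=256, width=256, radius_range=(5.0, 9.0))


@dataclass
class NucleiScene:
    """A synthetic tile plus its ground-truth instance segmentation."""

    image: np.ndarray
    truth: InstanceLabelMap
    n_nuclei: int
    seed: int


def gen_nuclei_scene(n: int, height: int = 256, width: int = 256,
                     radius_range: tuple[float, float] = (5.0, 9.0),
                     seed: int = 0, max_attempts: int = 5000) -> NucleiScene:
    """Place ``n`` disjoint textured ellipses on an H&E-like background.

    Nuclei never touch (a one-pixel separation is enforced) so the truth
    label map has exactly ``n`` 8-connected instances.  Raises if rejection
    sampling cannot place all nuclei within the attempt budget.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    rmin, rmax = radius_range
    if not 0 < rmin <= rmax:
        raise ValueError("invalid radius_range")
    labels = np.zeros((height, width), dtype=np.int32)
    occupancy = np.zeros((height, width), dtype=bool)
    margin = int(np.ceil(rmax)) + 2
    if n > 0 and (height <= 2 * margin or width <= 2 * margin):
        raise ValueError("tile too small for the requested nucleus radii")
    for k in range(1, n + 1):
        for _ in range(max_attempts):
            ry = rng.uniform(rmin, rmax)
            rx = rng.uniform(rmin, rmax)
            theta = rng.uniform(0, np.pi)
            cy = rng.uniform(margin, height - margin)
            cx = rng.uniform(margin, width - margin)
            rr, cc = draw_ellipse(cy, cx, ry, rx, shape=(height, width),
                                  rotation=theta)
            if rr.size == 0:
                continue
            # require a 1-px free halo so instances never 8-touch
            r0, r1 = rr.min() - 1, rr.max() + 2
            c0, c1 = cc.min() - 1, cc.max() + 2
            cand = np.zeros((r1 - r0, c1 - c0), dtype=bool)
            cand[rr - r0, cc - c0] = True
            halo = binary_dilation(cand, np.ones((3, 3), dtype=bool))
            if (occupancy[r0:r1, c0:c1] & halo).any():
                continue
            labels[rr, cc] = k
            occupancy[rr, cc] = True
            break
        else:
            raise RuntimeError(f"could not place nucleus {k} of {n} "
                               f"within {max_attempts} attempts")
    image = _render_scene(labels, rng)
    return NucleiScene(image, InstanceLabelMap(labels), n, seed)


def _render_scene(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Paint a pinkish background and blue-purple textured nuclei."""
    h, w = labels.shape
    img = np.empty((h, w, 3), dtype=float)
    background = np.array([235.0, 222.0, 232.0])  # eosin-tinted glass/stroma
    img[:] = background + rng.normal(0, 4.0, size=(h, w, 3))
    for k in np.unique(labels):
        if k == 0:
            continue
        base = np.array([rng.uniform(80, 110),     # hematoxylin blue-purple
                         rng.uniform(60, 90),
                         rng.uniform(140, 170)])
        sel = labels == k
        img[sel] = base + rng.normal(0, 8.0, size=(int(sel.sum()), 3))
    return np.clip(img, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# fold-style perturbations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PerturbSpec:
    """How one simulated fold disagrees with the ground truth.

    Defaults are the standard fivefold-disagreement conditions: one pixel
    of jitter, 20% spurious masks, 10% missed nuclei, no splits or merges,
    mild score noise.
    """

    jitter_px: int = 1
    fp_rate: float = 0.2
    fn_rate: float = 0.1
    split_rate: float = 0.0
    merge_rate: float = 0.0
    score_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fp_rate", "fn_rate", "split_rate", "merge_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.jitter_px < 0:
            raise ValueError("jitter_px must be >= 0")
        if self.score_noise_sd < 0:
            raise ValueError("score_noise_sd must be >= 0")


@dataclass
class PerturbResult:
    """A fold's candidate masks plus bookkeeping that reconciles with them.

    ``meta`` records, by truth label: kept singles, dropped (false
    negatives), split labels (two masks each), merged pairs (one mask each),
    plus the count of added false positives and any masks lost to border
    clipping.  ``sources[i]`` lists the truth labels behind output mask i
    (empty for a false positive).
    """

    masks: MaskSet
    meta: dict
    sources: list[tuple[int, ...]] = field(default_factory=list)


def _shift_mask(mask: np.ndarray, dr: int, dc: int) -> np.ndarray:
    out = np.zeros_like(mask)
    rs, cs = np.nonzero(mask)
    rs, cs = rs + dr, cs + dc
    keep = (rs >= 0) & (rs < mask.shape[0]) & (cs >= 0) & (cs < mask.shape[1])
    out[rs[keep], cs[keep]] = True
    return out


def perturb_truth(truth: InstanceLabelMap | np.ndarray,
                  spec: PerturbSpec = PerturbSpec()) -> PerturbResult:
    """Emulate one segmentation model's candidate set for a known scene."""
    labels = as_labels(truth)
    rng = np.random.default_rng(spec.seed)
    ids = [int(i) for i in np.unique(labels) if i > 0]
    h, w = labels.shape

    dropped = [i for i in ids if rng.random() < spec.fn_rate]
    kept = [i for i in ids if i not in dropped]

    # merges: each kept instance may grab its nearest unclaimed neighbor
    centroids = {i: np.array(np.nonzero(labels == i)).mean(axis=1) for i in kept}
    merged_pairs: list[tuple[int, int]] = []
    claimed: set[int] = set()
    if spec.merge_rate > 0 and len(kept) > 1:
        for i in kept:
            if i in claimed or rng.random() >= spec.merge_rate:
                continue
            others = [j for j in kept if j != i and j not in claimed]
            if not others:
                break
            j = min(others, key=lambda j: np.linalg.norm(centroids[i] - centroids[j]))
            merged_pairs.append((min(i, j), max(i, j)))
            claimed.update((i, j))

    singles = [i for i in kept if i not in claimed]

    # splits among the remaining singles
    split_labels: list[int] = []
    if spec.split_rate > 0:
        split_labels = [i for i in singles if rng.random() < spec.split_rate]
    plain = [i for i in singles if i not in split_labels]

    units: list[tuple[tuple[int, ...], np.ndarray]] = []
    for i in plain:
        units.append(((i,), labels == i))
    for a, b in merged_pairs:
        units.append(((a, b), (labels == a) | (labels == b)))
    actually_split: list[int] = []
    for i in split_labels:
        mask = labels == i
        halves = _split_in_two(mask, rng)
        if halves is None:
            plain.append(i)
            units.append(((i,), mask))
        else:
            actually_split.append(i)
            units.append(((i,), halves[0]))
            units.append(((i,), halves[1]))

    out_masks: list[ScoredMask] = []
    sources: list[tuple[int, ...]] = []
    lost = 0
    struct = np.ones((3, 3), dtype=bool)
    for src, mask in units:
        m = mask
        if spec.jitter_px > 0:
            dr, dc = rng.integers(-spec.jitter_px, spec.jitter_px + 1, size=2)
            m = _shift_mask(m, int(dr), int(dc))
            # morphological dither: sometimes thicken or thin by one pixel
            u = rng.random()
            if u < 0.25:
                m = binary_dilation(m, struct)
            elif u < 0.5:
                thinner = binary_erosion(m, struct)
                if thinner.any():
                    m = thinner
        if not m.any():
            lost += 1
            continue
        truth_pixels = np.isin(labels, src)
        inter = int((m & truth_pixels).sum())
        base_iou = inter / int((m | truth_pixels).sum())
        score = float(np.clip(0.5 + 0.5 * base_iou
                              + rng.normal(0, spec.score_noise_sd), 0.05, 1.0))
        out_masks.append(ScoredMask(m, score))
        sources.append(src)

    n_fp = int(round(spec.fp_rate * len(ids)))
    for _ in range(n_fp):
        m = _random_blob(h, w, rng)
        score = float(np.clip(0.5 + rng.normal(0, spec.score_noise_sd), 0.05, 1.0))
        out_masks.append(ScoredMask(m, score))
        sources.append(())

    meta = {
        "kept": sorted(plain),
        "dropped": sorted(dropped),
        "split": sorted(actually_split),
        "merged": sorted(merged_pairs),
        "added": n_fp,
        "lost": lost,
    }
    return PerturbResult(MaskSet(out_masks), meta, sources)


def _split_in_two(mask: np.ndarray,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray] | None:
    rs, cs = np.nonzero(mask)
    cy, cx = rs.mean(), cs.mean()
    theta = rng.uniform(0, np.pi)
    side = (rs - cy) * np.cos(theta) + (cs - cx) * np.sin(theta) >= 0
    if not side.any() or side.all():
        return None
    a = np.zeros_like(mask)
    b = np.zeros_like(mask)
    a[rs[side], cs[side]] = True
    b[rs[~side], cs[~side]] = True
    if not a.any() or not b.any():
        return None
    return a, b


def _random_blob(h: int, w: int, rng: np.random.Generator) -> np.ndarray:
    for _ in range(100):
        ry, rx = rng.uniform(3, 6, size=2)
        cy = rng.uniform(ry + 1, h - ry - 2)
        cx = rng.uniform(rx + 1, w - rx - 2)
        rr, cc = draw_ellipse(cy, cx, ry, rx, shape=(h, w),
                              rotation=rng.uniform(0, np.pi))
        if rr.size:
            m = np.zeros((h, w), dtype=bool)
            m[rr, cc] = True
            return m
    raise RuntimeError("could not place a false-positive blob")


def gen_fold_candidates(truth: InstanceLabelMap | np.ndarray, n_folds: int = 5,
                        spec: PerturbSpec = PerturbSpec(),
                        seed: int = 0) -> list[PerturbResult]:
    """One independently perturbed candidate set per cross-validation fold."""
    ss = np.random.SeedSequence([int(seed), 101])
    fold_seeds = [int(s % (2**31)) for s in ss.generate_state(n_folds)]
    return [perturb_truth(truth, PerturbSpec(
        jitter_px=spec.jitter_px, fp_rate=spec.fp_rate, fn_rate=spec.fn_rate,
        split_rate=spec.split_rate, merge_rate=spec.merge_rate,
        score_noise_sd=spec.score_noise_sd, seed=fs)) for fs in fold_seeds]


# ---------------------------------------------------------------------------
# two-modality case cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Conditions of a synthetic two-modality cohort.

    ``informativeness_*`` is the class-mean separation of the modality's
    discriminant coordinate in units of its (unit) standard deviation; 0
    makes the modality pure noise, 3 gives roughly 93% Bayes accuracy.
    Defaults mirror the challenge's training cohort scale (32 cases, even
    class split) with an informative pathology stream and a weakly
    informative radiology stream.
    """

    n_cases: int = 32
    informativeness_path: float = 3.0
    informativeness_rad: float = 0.5
    feature_len_path: int = 50
    feature_len_rad: int = 50
    dropout_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 2:
            raise ValueError("n_cases must be >= 2")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.feature_len_path < 1 or self.feature_len_rad < 1:
            raise ValueError("feature lengths must be >= 1")


class DropoutExtractor:
    """Per-case feature source with optional multiplicative Bernoulli dropout.

    Emulates a trained network queried with dropout left on: each call
    masks a fresh random subset of the stored feature vector (inverted
    scaling keeps the expectation fixed).  With ``dropout_rate`` 0 the
    extractor is deterministic.
    """

    def __init__(self, features: dict, dropout_rate: float):
        lengths = {len(v) for v in features.values()}
        if len(lengths) != 1:
            raise ValueError("all case features must share one length")
        self._features = {k: np.asarray(v, dtype=float) for k, v in features.items()}
        self.length = lengths.pop()
        self.dropout_rate = float(dropout_rate)
        self.stochastic = self.dropout_rate > 0.0

    def sample(self, case_id, seed: int) -> np.ndarray:
        base = self._features[case_id]
        if not self.stochastic:
            return base.copy()
        rng = np.random.default_rng(seed)
        keep = rng.random(self.length) >= self.dropout_rate
        return base * keep / (1.0 - self.dropout_rate)


@dataclass
class Cohort:
    """A generated cohort: ids, labels, per-modality probabilities, extractors."""

    case_ids: list[str]
    labels: np.ndarray
    path_probs: list[CaseProbabilities]
    rad_probs: list[CaseProbabilities]
    path_extractor: DropoutExtractor
    rad_extractor: DropoutExtractor
    spec: CohortSpec


def _sigmoid(x: float) -> float:
    return float(1.0 / (1.0 + np.exp(-x)))


def gen_cohort(spec: CohortSpec = CohortSpec()) -> Cohort:
    """Draw a two-modality cohort of class-conditional Gaussian features.

    Each modality's feature vector is standard normal except its first
    coordinate, shifted by ±informativeness/2 by class (oligodendroglioma
    positive).  Modality probabilities are the Bayes posterior of that
    coordinate, ``sigmoid(d·x₀)`` — so a modality's probability stream is
    exactly as good as its informativeness allows, no better.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7]))
    n = spec.n_cases
    labels = np.array([LABEL_OLIGO] * (n - n // 2) + [LABEL_ASTRO] * (n // 2))
    case_ids = [f"case_{i:04d}" for i in range(n)]

    def build(d: float, length: int, modality: str):
        feats: dict[str, np.ndarray] = {}
        probs: list[CaseProbabilities] = []
        for cid, y in zip(case_ids, labels):
            x = rng.normal(size=length)
            shift = d / 2 if y == LABEL_OLIGO else -d / 2
            x[0] += shift
            feats[cid] = x
            p_oligo = _sigmoid(d * x[0])
            probs.append(CaseProbabilities(p_oligo, 1 - p_oligo, modality=modality))
        return feats, probs

    path_feats, path_probs = build(spec.informativeness_path,
                                   spec.feature_len_path, "pathology")
    rad_feats, rad_probs = build(spec.informativeness_rad,
                                 spec.feature_len_rad, "radiology")
    return Cohort(
        case_ids=case_ids,
        labels=labels,
        path_probs=path_probs,
        rad_probs=rad_probs,
        path_extractor=DropoutExtractor(path_feats, spec.dropout_rate),
        rad_extractor=DropoutExtractor(rad_feats, spec.dropout_rate),
        spec=spec,
    )
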