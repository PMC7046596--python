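"""Mask-level non-maximum suppression for ensembling instance segmentations.

Candidate masks from several models (typically the five folds of a
cross-trained ensemble) are fused greedily: the highest-scoring candidate M
is moved to the output set, and every remaining candidate whose IOU with M
exceeds the suppression threshold N is discarded.  In ``merge_union`` mode,
candidates that overlap M almost completely (IOU ≥ ``merge_iou``) are first
unioned into M — the "unions of masks with maximum overlap" behavior —
before the suppression pass; M keeps its own score.  The loop repeats until
no candidates remain, and the surviving masks are rasterized to a label map.

Determinism: score ties are broken by larger mask area, then lower
``source_id``, then input order.  Suppression uses a strict ``>`` against N
("greater than a threshold"), merging uses ``≥``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .masks import (GeometryError, InstanceLabelMap, MaskSet, ScoredMask,
                    _source_rank, iou, masks_to_label_map)


class MergeMode(str, Enum):
    suppress_only = "suppress_only"
    merge_union = "merge_union"


@dataclass(frozen=True)
class NmsConfig:
    """Fusion thresholds.

    suppress_iou
        The threshold N: overlaps strictly greater than this are suppressed.
        Default 0.5.
    merge_mode
        ``suppress_only`` discards overlapping candidates; ``merge_union``
        first unions near-duplicates (IOU ≥ ``merge_iou``) into the winner.
    merge_iou
        Minimum IOU for union-merging; must be ≥ ``suppress_iou``.
    """

    suppress_iou: float = 0.5
    merge_mode: MergeMode = MergeMode.merge_union
    merge_iou: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 < self.suppress_iou < 1.0:
            raise ValueError("suppress_iou must lie in (0, 1)")
        mode = MergeMode(self.merge_mode)
        object.__setattr__(self, "merge_mode", mode)
        if mode is MergeMode.merge_union:
            if not 0.0 < self.merge_iou < 1.0:
                raise ValueError("merge_iou must lie in (0, 1)")
            if self.merge_iou < self.suppress_iou:
                raise ValueError("merge_iou must be >= suppress_iou")


def _pick_order(masks: Sequence[ScoredMask]) -> list[int]:
    """Indices in greedy pick order: score desc, area desc, source_id asc."""
    return sorted(range(len(masks)),
                  key=lambda i: (-masks[i].score, -masks[i].area,
                                 _source_rank(masks[i].source_id), i))


def _nms_with_support(candidates: MaskSet, cfg: NmsConfig,
                      ) -> tuple[list[ScoredMask], list[set]]:
    """Greedy loop; for each survivor, the set of source_ids that attest to it.

    A source attests to an output instance when one of its candidates was
    the winner, was union-merged into it, or was suppressed by it — i.e.
    when that source predicted (approximately) the same object.
    """
    remaining = list(candidates)
    for m in remaining:
        if not np.isfinite(m.score):
            raise ValueError("candidate with non-finite score")
    out: list[ScoredMask] = []
    support: list[set] = []
    while remaining:
        order = _pick_order(remaining)
        best = remaining.pop(order[0])
        pixels = best.pixels
        attest = {best.source_id}
        if cfg.merge_mode is MergeMode.merge_union and remaining:
            # merge set decided against the winner as picked ...
            merged_idx = {i for i, c in enumerate(remaining)
                          if iou(best.pixels, c.pixels) >= cfg.merge_iou}
            for i in merged_idx:
                pixels = pixels | remaining[i].pixels
                attest.add(remaining[i].source_id)
            remaining = [c for i, c in enumerate(remaining) if i not in merged_idx]
        # ... suppression against the (possibly grown) winner
        kept = []
        for c in remaining:
            if iou(pixels, c.pixels) > cfg.suppress_iou:
                attest.add(c.source_id)
            else:
                kept.append(c)
        remaining = kept
        out.append(ScoredMask(pixels, best.score, best.source_id))
        support.append(attest)
    return out, support


def mask_nms_masks(candidates: MaskSet, cfg: NmsConfig = NmsConfig()) -> MaskSet:
    """Run the greedy fusion loop and return the surviving masks.

    See the module docstring for the algorithm.  An empty candidate set
    yields an empty output set (not an error).
    """
    out, _ = _nms_with_support(candidates, cfg)
    return MaskSet(out)


def mask_nms(candidates: MaskSet, cfg: NmsConfig = NmsConfig(),
             shape: tuple[int, int] | None = None) -> InstanceLabelMap:
    """Fuse candidates and rasterize the survivors to an instance label map.

    Residual overlaps (IOU ≤ N but non-zero) are resolved by the shared
    tie rule: higher score, then larger area, then lower ``source_id``.
    """
    if not len(candidates):
        if shape is None:
            raise ValueError("empty candidate set needs an explicit output shape")
        return InstanceLabelMap(np.zeros(shape, dtype=np.int32))
    return masks_to_label_map(mask_nms_masks(candidates, cfg))


def fuse_folds(per_fold: Sequence[MaskSet], cfg: NmsConfig = NmsConfig(),
               shape: tuple[int, int] | None = None,
               min_support: int | str = "majority") -> InstanceLabelMap:
    """Concatenate per-fold candidates (source_id = fold index) and fuse.

    This is the cross-trained-ensemble entry point: each fold's model emits
    its own candidate masks and duplicates across folds collapse onto the
    most confident copy.  The fused set then drops instances attested by
    fewer than ``min_support`` distinct folds — the ensemble's
    false-positive removal: a mask with only small overlap against every
    other fold's predictions is a single model's hallucination, while a
    real nucleus is re-detected by most folds.  ``"majority"`` (default)
    means ``ceil(n_folds / 2)``, which degenerates to keeping everything
    for a single fold; pass ``1`` to disable the filter.
    """
    if not per_fold:
        raise ValueError("need at least one fold")
    shapes = {ms.shape for ms in per_fold if ms.shape is not None}
    if len(shapes) > 1:
        raise GeometryError(f"folds with mixed geometries: {sorted(shapes)}")
    if min_support == "majority":
        need = -(-len(per_fold) // 2)
    else:
        need = int(min_support)
        if need < 1:
            raise ValueError("min_support must be >= 1")
    pooled = MaskSet([ScoredMask(m.pixels, m.score, source_id=fold)
                      for fold, ms in enumerate(per_fold) for m in ms])
    if not len(pooled):
        if shape is None:
            raise ValueError("empty candidate set needs an explicit output shape")
        return InstanceLabelMap(np.zeros(shape, dtype=np.int32))
    survivors, support = _nms_with_support(pooled, cfg)
    kept = MaskSet([m for m, s in zip(survivors, support) if len(s) >= need])
    if not len(kept):
        return InstanceLabelMap(np.zeros(pooled.shape, dtype=np.int32))
    return masks_to_label_map(kept)
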