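import numpy as np
import pytest

from histofuse.masks import InstanceLabelMap, MaskSet, ScoredMask


def square(shape, r0, c0, side):
    m = np.zeros(shape, dtype=bool)
    m[r0:r0 + side, c0:c0 + side] = True
    return m


@pytest.fixture
def shifted_squares():
    """2×2 square at (0,0) vs 2×2 square at (1,0): intersection 2, union 6."""
    return square((4, 4), 0, 0, 2), square((4, 4), 1, 0, 2)


@pytest.fixture
def split_in_two_maps():
    """One 8-px gt object; prediction tiles it exactly with two 4-px halves."""
    gt = np.zeros((4, 6), dtype=np.int32)
    gt[1:3, 1:5] = 1                      # 2×4 = 8 px
    pred = np.zeros((4, 6), dtype=np.int32)
    pred[1:3, 1:3] = 1                    # left half
    pred[1:3, 3:5] = 2                    # right half
    return InstanceLabelMap(gt), InstanceLabelMap(pred)


@pytest.fixture
def ap_fixture():
    """1 gt object; 2 predictions — best IOU exactly 0.5, other disjoint."""
    gt = np.zeros((8, 8), dtype=np.int32)
    gt[0:2, 0:2] = 1                      # 4 px
    best = np.zeros((8, 8), dtype=bool)
    best[0:2, 0:4] = True                 # inter 4, union 8 -> IOU exactly 0.5
    other = square((8, 8), 5, 5, 2)
    pred = MaskSet([ScoredMask(best, 0.9, 0), ScoredMask(other, 0.8, 1)])
    return InstanceLabelMap(gt), pred


def random_mask_pair(rng, shape=(16, 16)):
    """Two random non-empty masks sharing a geometry."""
    while True:
        a = rng.random(shape) < 0.3
        b = rng.random(shape) < 0.3
        if a.any() and b.any():
            return a, b


def random_label_map(rng, shape=(24, 24), n_blobs=4):
    """A label map of small random rectangles (possibly fewer than n_blobs)."""
    lm = np.zeros(shape, dtype=np.int32)
    nxt = 1
    for _ in range(n_blobs):
        h = int(rng.integers(2, 6))
        w = int(rng.integers(2, 6))
        r = int(rng.integers(0, shape[0] - h))
        c = int(rng.integers(0, shape[1] - w))
        region = lm[r:r + h, c:c + w]
        if (region == 0).all():
            region[:] = nxt
            nxt += 1
    return InstanceLabelMap(lm)


def random_mask_set(rng, shape=(20, 20), max_masks=8):
    """A random scored mask set of blobs with arbitrary overlaps."""
    n = int(rng.integers(1, max_masks + 1))
    masks = []
    for i in range(n):
        h = int(rng.integers(2, 8))
        w = int(rng.integers(2, 8))
        r = int(rng.integers(0, shape[0] - h))
        c = int(rng.integers(0, shape[1] - w))
        m = np.zeros(shape, dtype=bool)
        m[r:r + h, c:c + w] = True
        masks.append(ScoredMask(m, float(rng.uniform(0.05, 1.0)),
                                source_id=int(rng.integers(0, 5))))
    return MaskSet(masks)
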