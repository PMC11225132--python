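import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from hippofill import MaskVolume


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def random_mask_pair(rng):
    """A generic gt/pred pair of overlapping random masks on an 8^3 grid."""

    def make(shape=(8, 8, 8), p=0.3, spacing=(1.0, 1.0, 1.0)):
        gt = (rng.random(shape) < p).astype(np.uint8)
        pred = gt.copy()
        flip = rng.random(shape) < 0.15
        pred[flip] ^= 1
        return MaskVolume(gt, spacing), MaskVolume(pred, spacing)

    return make


@pytest.fixture
def hand_count_pair():
    """Fixed 4^3 fixture: gt has 4 voxels, pred has 6, overlap 3.

    Hand counts: tp=3, fp=3, fn=1, r_s=4, t_s=6 -> dice=0.6, iou=3/7,
    osr=0.3, usr=0.1.
    """
    gt = np.zeros((4, 4, 4), dtype=np.uint8)
    pred = np.zeros((4, 4, 4), dtype=np.uint8)
    gt[1, 1, 1] = gt[1, 1, 2] = gt[1, 2, 1] = gt[2, 1, 1] = 1
    pred[1, 1, 1] = pred[1, 1, 2] = pred[1, 2, 1] = 1  # overlap
    pred[0, 0, 0] = pred[3, 3, 3] = pred[2, 2, 2] = 1  # false positives
    return MaskVolume(gt), MaskVolume(pred)
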