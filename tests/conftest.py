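import numpy as np
import pytest

from gpanet.detection import BoxXYXY, Detection


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_box(rng, lo=0.0, hi=100.0, min_side=1.0, max_side=40.0):
    x1 = rng.uniform(lo, hi - max_side)
    y1 = rng.uniform(lo, hi - max_side)
    w = rng.uniform(min_side, max_side)
    h = rng.uniform(min_side, max_side)
    return BoxXYXY(float(x1), float(y1), float(x1 + w), float(y1 + h))


def random_detections(rng, n, n_classes=3, size=100.0):
    dets = []
    scores = rng.permutation(np.linspace(0.05, 0.99, n))  # distinct scores
    for i in range(n):
        dets.append(
            Detection(
                random_box(rng, hi=size),
                float(scores[i]),
                int(rng.integers(0, n_classes)),
            )
        )
    return dets


@pytest.fixture
def make_random_detections(rng):
    def _make(n, n_classes=3):
        return random_detections(rng, n, n_classes)

    return _make
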