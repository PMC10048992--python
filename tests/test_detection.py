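import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gpanet.autograd import Tensor
from gpanet.detection import (BoxXYXY, Detection, DetectionHead, decode_box,
                              decode_detections, encode_box, hard_nms, iou,
                              read_yolo_labels, soft_nms, write_yolo_labels)
from tests.conftest import random_detections


def reference_hard_nms(dets, nt):
    """Independent O(n^2) loop oracle for hard NMS (per class)."""
    kept = []
    for cls in {d.class_id for d in dets}:
        pool = sorted((d for d in dets if d.class_id == cls), key=lambda d: -d.score)
        alive = [True] * len(pool)
        for i in range(len(pool)):
            if not alive[i]:
                continue
            kept.append(pool[i])
            for j in range(i + 1, len(pool)):
                if alive[j] and iou(pool[i].box, pool[j].box) >= nt:
                    alive[j] = False
    return kept


def reference_soft_nms(dets, nt, floor):
    """Independent loop oracle for linear-decay Soft-NMS (per class)."""
    out = []
    for cls in {d.class_id for d in dets}:
        pool = [[d.box, d.score] for d in dets if d.class_id == cls]
        while pool:
            m = max(range(len(pool)), key=lambda i: pool[i][1])
            box, score = pool.pop(m)
            out.append(Detection(box, score, cls))
            survivors = []
            for b, s in pool:
                ov = iou(box, b)
                s2 = s * (1.0 - ov) if ov >= nt else s
                if s2 >= floor:
                    survivors.append([b, s2])
            pool = survivors
    return out


class TestIoU:
    def test_identical_is_one(self):
        b = BoxXYXY(3, 4, 10, 12)
        assert iou(b, b) == 1.0

    def test_disjoint_is_zero(self):
        assert iou(BoxXYXY(0, 0, 5, 5), BoxXYXY(10, 10, 20, 20)) == 0.0

    def test_hand_case_half(self):
        assert iou(BoxXYXY(0, 0, 10, 10), BoxXYXY(0, 0, 10, 5)) == pytest.approx(0.5)

    def test_symmetric_and_bounded(self, rng):
        from tests.conftest import random_box

        for _ in range(100):
            a, b = random_box(rng), random_box(rng)
            v = iou(a, b)
            assert 0.0 <= v <= 1.0
            assert v == pytest.approx(iou(b, a))

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            BoxXYXY(0, 0, 0, 5)


class TestHardNMS:
    def test_single_detection_kept(self):
        d = Detection(BoxXYXY(0, 0, 5, 5), 0.7)
        assert hard_nms([d], 0.5) == [d]

    def test_disjoint_boxes_both_kept(self):
        a = Detection(BoxXYXY(0, 0, 5, 5), 0.9)
        b = Detection(BoxXYXY(50, 50, 60, 60), 0.8)
        assert set(hard_nms([a, b], 0.5)) == {a, b}

    def test_oracle_equivalence_random_sets(self, rng):
        for trial in range(60):
            dets = random_detections(rng, int(rng.integers(1, 51)))
            nt = float(rng.uniform(0.2, 0.8))
            got = {(d.box, d.score, d.class_id) for d in hard_nms(dets, nt)}
            ref = {(d.box, d.score, d.class_id) for d in reference_hard_nms(dets, nt)}
            assert got == ref

    def test_empty_input(self):
        assert hard_nms([], 0.5) == []

    def test_output_scores_subset_of_input(self, rng):
        dets = random_detections(rng, 30)
        in_scores = {d.score for d in dets}
        assert all(d.score in in_scores for d in hard_nms(dets, 0.4))


class TestSoftNMS:
    def test_hand_decay(self):
        a = Detection(BoxXYXY(0, 0, 10, 10), 0.9)
        b = Detection(BoxXYXY(0, 0, 10, 5), 0.8)  # IoU 0.5 with a
        out = soft_nms([a, b], nt=0.3, score_floor=0.001)
        scores = sorted(d.score for d in out)
        assert scores == pytest.approx([0.8 * (1 - 0.5), 0.9])

    def test_identity_when_all_below_threshold(self, rng):
        a = Detection(BoxXYXY(0, 0, 5, 5), 0.9)
        b = Detection(BoxXYXY(20, 20, 30, 30), 0.6)
        out = soft_nms([a, b], nt=0.5, score_floor=0.0)
        assert sorted(d.score for d in out) == [0.6, 0.9]

    def test_oracle_equivalence_random_sets(self, rng):
        for _ in range(60):
            dets = random_detections(rng, int(rng.integers(1, 51)))
            nt = float(rng.uniform(0.2, 0.8))
            got = sorted((d.box.x1, round(d.score, 9)) for d in soft_nms(dets, nt, 0.01))
            ref = sorted((d.box.x1, round(d.score, 9)) for d in reference_soft_nms(dets, nt, 0.01))
            assert got == ref

    def test_zero_decay_reproduces_hard_kept_set(self, rng):
        for _ in range(30):
            dets = random_detections(rng, int(rng.integers(1, 40)))
            nt = float(rng.uniform(0.3, 0.7))
            hard_kept = {d.box for d in hard_nms(dets, nt)}
            # soft with total decay: decayed boxes get score 0 < floor
            zero_decay = []
            for cls in {d.class_id for d in dets}:
                pool = [[d.box, d.score] for d in dets if d.class_id == cls]
                while pool:
                    m = max(range(len(pool)), key=lambda i: pool[i][1])
                    box, score = pool.pop(m)
                    zero_decay.append(box)
                    pool = [[b, s] for b, s in pool if iou(box, b) < nt]
            assert set(zero_decay) == hard_kept

    def test_never_increases_scores(self, rng):
        dets = random_detections(rng, 40)
        by_box = {d.box: d.score for d in dets}
        for d in soft_nms(dets, 0.4, 0.0):
            assert d.score <= by_box[d.box] + 1e-12

    def test_nt_near_one_is_identity_on_scores(self, rng):
        dets = random_detections(rng, 25)
        out = soft_nms(dets, nt=0.999999, score_floor=0.0)
        assert sorted(d.score for d in out) == sorted(d.score for d in dets)

    @given(seed=st.integers(0, 5000))
    @settings(max_examples=20, deadline=None)
    def test_order_invariance_distinct_scores(self, seed):
        rng = np.random.default_rng(seed)
        dets = random_detections(rng, 15)
        shuffled = [dets[i] for i in rng.permutation(len(dets))]
        a = [(d.box, round(d.score, 10)) for d in soft_nms(dets, 0.4, 0.01)]
        b = [(d.box, round(d.score, 10)) for d in soft_nms(shuffled, 0.4, 0.01)]
        assert a == b
        ha = [(d.box, d.score) for d in hard_nms(dets, 0.4)]
        hb = [(d.box, d.score) for d in hard_nms(shuffled, 0.4)]
        assert ha == hb

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            soft_nms([], nt=1.5)
        with pytest.raises(ValueError):
            hard_nms([], nt=0.0)


class TestDetectionHead:
    def test_zero_logits_decode(self):
        anchors = [(8.0, 8.0)]
        raw = np.zeros((1, 5 + 4, 3, 3), dtype=np.float32)
        dets = decode_detections(raw[0].reshape(1, 9, 3, 3), anchors, 4, stride=8.0)
        assert len(dets) == 9  # S*S*A
        for d in dets:
            assert d.score == pytest.approx(0.5 * 0.25)
        cx, cy = dets[0].box.center
        assert (cx, cy) == pytest.approx((4.0, 4.0))  # centred on cell (0, 0)

    def test_encode_decode_roundtrip(self, rng):
        anchors = [(12.0, 9.0), (20.0, 25.0)]
        for _ in range(50):
            gx, gy = int(rng.integers(0, 8)), int(rng.integers(0, 8))
            anchor = anchors[int(rng.integers(0, 2))]
            stride = 8.0
            cx = (gx + rng.uniform(0.05, 0.95)) * stride
            cy = (gy + rng.uniform(0.05, 0.95)) * stride
            w, h = rng.uniform(4, 30, 2)
            box = BoxXYXY(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)
            t = encode_box(box, gx, gy, anchor, stride)
            back = decode_box(t, gx, gy, anchor, stride)
            for a, b in zip((box.x1, box.y1, box.x2, box.y2), (back.x1, back.y1, back.x2, back.y2)):
                assert a == pytest.approx(b, abs=1e-6)

    def test_raw_count_matches_grid(self, rng):
        head = DetectionHead(8, [(10, 10), (20, 16), (5, 8)], n_classes=2, stride=8,
                             rng=np.random.default_rng(0))
        x = Tensor(rng.normal(size=(1, 8, 4, 4)).astype(np.float32))
        raw = head(x)
        assert raw.shape == (1, 3, 7, 4, 4)
        dets = decode_detections(raw.data[0], head.anchors, 2, 8.0)
        assert len(dets) == 4 * 4 * 3

    def test_empty_anchors_rejected(self):
        with pytest.raises(ValueError):
            DetectionHead(8, [], 2, 8)


class TestYoloIO:
    def test_roundtrip_and_format(self, tmp_path, rng):
        truth = [(BoxXYXY(10, 20, 30, 60), 1), (BoxXYXY(0, 0, 16, 16), 0)]
        path = tmp_path / "labels.txt"
        write_yolo_labels(path, truth, 64, 64)
        lines = path.read_text().strip().split("\n")
        assert len(lines) == 2
        for line in lines:
            fields = line.split()
            assert len(fields) == 5
            assert all(0.0 <= float(f) <= 1.0 for f in fields[1:])
        back = read_yolo_labels(path, 64, 64)
        for (b0, c0), (b1, c1) in zip(truth, back):
            assert c0 == c1
            assert b0.x1 == pytest.approx(b1.x1, abs=0.01)
            assert b0.y2 == pytest.approx(b1.y2, abs=0.01)

    def test_score_column(self, tmp_path):
        dets = [Detection(BoxXYXY(4, 4, 12, 12), 0.75, 2)]
        path = tmp_path / "pred.txt"
        write_yolo_labels(path, dets, 32, 32, with_score=True)
        back = read_yolo_labels(path, 32, 32)
        assert isinstance(back[0], Detection)
        assert back[0].score == pytest.approx(0.75)
        assert back[0].class_id == 2


def test_detection_score_range_enforced():
    with pytest.raises(ValueError):
        Detection(BoxXYXY(0, 0, 1, 1), 1.5)
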