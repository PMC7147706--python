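import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from dermoseg.evaluate import (
    confusion,
    dice,
    evaluate_dataset,
    jaccard,
    metrics_record,
    pixel_accuracy,
    roc,
    sensitivity,
    specificity,
)
from oracles import mann_whitney_auc


def _shifted_blocks():
    """100-px pred block vs the same block shifted 5 rows: TP=FP=FN=50."""
    pred = np.zeros((20, 20), dtype=np.uint8)
    truth = np.zeros((20, 20), dtype=np.uint8)
    pred[0:10, 0:10] = 1
    truth[5:15, 0:10] = 1
    return pred, truth


class TestConfusion:
    def test_identical_masks(self, rng):
        m = rng.integers(0, 2, size=(16, 16)).astype(np.uint8)
        tp, fp, tn, fn = confusion(m, m)
        assert fp == fn == 0
        assert tp == m.sum()
        assert tp + fp + tn + fn == m.size

    def test_complement_masks(self, rng):
        m = rng.integers(0, 2, size=(16, 16)).astype(np.uint8)
        tp, fp, tn, fn = confusion(1 - m, m)
        assert tp == tn == 0

    def test_shifted_block_counts(self):
        pred, truth = _shifted_blocks()
        tp, fp, tn, fn = confusion(pred, truth)
        assert (tp, fp, fn) == (50, 50, 50)
        assert tn == 400 - 150

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            confusion(np.zeros((4, 4)), np.zeros((4, 5)))


class TestJaccardDice:
    def test_identical_nonempty(self, rng):
        m = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        m[0, 0] = 1
        assert jaccard(m, m) == 1.0
        assert dice(m, m) == 1.0

    def test_disjoint(self):
        a = np.zeros((6, 6), dtype=np.uint8)
        b = np.zeros((6, 6), dtype=np.uint8)
        a[0, 0] = 1
        b[5, 5] = 1
        assert jaccard(a, b) == 0.0
        assert dice(a, b) == 0.0

    def test_shifted_block_values(self):
        pred, truth = _shifted_blocks()
        assert jaccard(pred, truth) == pytest.approx(50 / 150)
        assert dice(pred, truth) == pytest.approx(0.5)

    def test_empty_vs_empty_scores_one(self):
        z = np.zeros((4, 4), dtype=np.uint8)
        assert jaccard(z, z) == 1.0
        assert dice(z, z) == 1.0

    @settings(max_examples=50, deadline=None)
    @given(
        hnp.arrays(np.uint8, (8, 8), elements=st.integers(0, 1)),
        hnp.arrays(np.uint8, (8, 8), elements=st.integers(0, 1)),
    )
    def test_dice_jaccard_identity(self, a, b):
        j = jaccard(a, b)
        d = dice(a, b)
        assert abs(d - 2 * j / (1 + j)) < 1e-12

    def test_rate_metrics_on_shifted_blocks(self):
        pred, truth = _shifted_blocks()
        assert sensitivity(pred, truth) == pytest.approx(0.5)
        assert specificity(pred, truth) == pytest.approx(250 / 300)
        assert pixel_accuracy(pred, truth) == pytest.approx(300 / 400)
        rec = metrics_record(pred, truth)
        assert rec.jaccard == pytest.approx(1 / 3)
        assert rec.dice == pytest.approx(0.5)


class TestRoc:
    def test_perfect_separation(self):
        probs = np.array([[0.9, 0.8, 0.2, 0.1]])
        truth = np.array([[1, 1, 0, 0]])
        curve = roc([probs], [truth])
        assert curve.auc == pytest.approx(1.0)

    def test_worked_example_auc_075(self):
        probs = np.array([[0.9, 0.8, 0.7, 0.1]])
        truth = np.array([[1, 0, 1, 0]])
        curve = roc([probs], [truth])
        assert curve.auc == pytest.approx(0.75)

    def test_all_equal_scores(self):
        probs = np.full((1, 10), 0.4)
        truth = np.array([[1, 0, 1, 0, 1, 0, 1, 0, 1, 0]])
        curve = roc([probs], [truth])
        assert curve.auc == pytest.approx(0.5)

    def test_endpoints_and_monotonicity(self, rng):
        probs = rng.random((3, 50))
        truth = (rng.random((3, 50)) > 0.6).astype(np.uint8)
        curve = roc(list(probs), list(truth))
        assert curve.fpr[0] == 0.0 and curve.tpr[0] == 0.0
        assert curve.fpr[-1] == 1.0 and curve.tpr[-1] == 1.0
        assert np.all(np.diff(curve.fpr) >= 0)
        assert np.all(np.diff(curve.tpr) >= 0)

    def test_matches_concordant_pair_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 50))
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.all() or not labels.any():
                continue
            curve = roc([scores[None]], [labels[None]])
            assert curve.auc == pytest.approx(mann_whitney_auc(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc([np.array([[0.5, 0.6]])], [np.array([[1, 1]])])


class _StubModel:
    """Duck-typed model returning queued probability maps."""

    def __init__(self, maps):
        self.maps = list(maps)

    def forward(self, batch):
        return self.maps.pop(0)[None]


class TestEvaluateDataset:
    def test_perfect_prediction_scores_one(self, rng):
        truth = np.zeros((256, 256), dtype=np.uint8)
        truth[100:150, 80:170] = 1
        img = np.dstack([truth * 100 + 50] * 3).astype(np.uint8)
        model = _StubModel([truth.astype(np.float64) * 0.98 + 0.01])
        per_image, agg, curve = evaluate_dataset(model, [img], [truth])
        assert agg.jaccard == 1.0
        assert curve.auc == 1.0
        assert len(per_image) == 1

    def test_aggregate_is_mean_of_per_image(self, rng):
        truths, imgs, maps = [], [], []
        for k in range(3):
            t = np.zeros((256, 256), dtype=np.uint8)
            t[50 : 100 + 20 * k, 50:150] = 1
            truths.append(t)
            imgs.append(np.dstack([t * 80 + 40] * 3).astype(np.uint8))
            p = t.astype(np.float64) * 0.9 + 0.05
            p[:40, :40] = 0.9  # deliberate false positives
            maps.append(p)
        model = _StubModel(maps)
        per_image, agg, _ = evaluate_dataset(model, imgs, truths)
        assert agg.jaccard == pytest.approx(np.mean([m.jaccard for m in per_image]))
        assert agg.dice == pytest.approx(np.mean([m.dice for m in per_image]))

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            evaluate_dataset(_StubModel([]), [], [])

    def test_dehair_toggle_is_near_noop_on_hair_free_data(self):
        """On hair-free synthetic images the preprocessing A/B switch must
        leave aggregate scores essentially unchanged."""
        from dermoseg import SynthConfig, build_resunet, generate_dataset

        imgs, masks = generate_dataset(2, SynthConfig(seed=17, n_hairs=0))
        model = build_resunet(width_multiplier=0.0625, seed=4)
        _, agg_off, _ = evaluate_dataset(model, imgs, masks, dehair=False)
        _, agg_on, _ = evaluate_dataset(model, imgs, masks, dehair=True)
        for key, off in agg_off.as_dict().items():
            assert abs(off - agg_on.as_dict()[key]) < 0.01, key
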