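"""Loss and evaluation metrics against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.spatial.distance import cdist

from mfsunet.errors import (DegenerateStatisticError, InvalidParameterError,
                            NumericError)
from mfsunet.metrics import (ConfusionCounts, composite_loss, confusion,
                             evaluate_masks, hd95, metric_table,
                             overlap_metrics, paired_t_test)


def _random_mask(rng, shape, p=0.3):
    return rng.uniform(size=shape) < p


class TestCompositeLoss:
    def test_perfect_prediction_is_zero(self, rng):
        Y = _random_mask(rng, (8, 8)).astype(float)
        assert composite_loss(Y, Y) == pytest.approx(0.0, abs=1e-5)

    def test_uniform_half_on_balanced_mask_gives_log2_bce(self):
        Y = np.zeros((4, 4))
        Y[:2] = 1.0
        P = np.full((4, 4), 0.5)
        assert composite_loss(P, Y, w_dice=0.0) == pytest.approx(np.log(2.0))

    def test_matches_scalar_loop_oracle(self, rng):
        P = rng.uniform(0.01, 0.99, size=(8, 8))
        Y = _random_mask(rng, (8, 8)).astype(float)
        got = composite_loss(P, Y, w_dice=2.0, w_bce=0.5, smooth=1.0)
        inter = pd = py = 0.0
        bce = 0.0
        for i in range(8):
            for j in range(8):
                inter += P[i, j] * Y[i, j]
                pd += P[i, j]
                py += Y[i, j]
                bce += -(Y[i, j] * np.log(P[i, j])
                         + (1 - Y[i, j]) * np.log(1 - P[i, j]))
        dice = (2 * inter + 1.0) / (pd + py + 1.0)
        want = 2.0 * (1 - dice) + 0.5 * bce / 64.0
        assert got == pytest.approx(want, rel=1e-10)

    def test_rejects_out_of_range_probabilities(self, rng):
        Y = np.zeros((2, 2))
        with pytest.raises(NumericError):
            composite_loss(np.full((2, 2), 1.5), Y)
        with pytest.raises(InvalidParameterError):
            composite_loss(np.full((2, 2), 0.5), Y, w_dice=-1.0)


class TestOverlap:
    def test_confusion_identical_and_disjoint(self, rng):
        m = _random_mask(rng, (6, 6))
        c = confusion(m, m)
        assert (c.FP, c.FN) == (0, 0) and c.TP == m.sum()
        c = confusion(np.ones((4, 4), bool), np.zeros((4, 4), bool))
        assert (c.TP, c.FP) == (0, 16)

    def test_confusion_on_constructed_fixture(self):
        pred = np.array([[1, 1, 0, 0]] * 4, bool)
        gt = np.array([[1, 0, 1, 0]] * 4, bool)
        c = confusion(pred, gt)
        assert (c.TP, c.FP, c.FN, c.TN) == (4, 4, 4, 4)

    def test_counts_sum_to_pixels(self, rng):
        p, g = _random_mask(rng, (9, 7)), _random_mask(rng, (9, 7))
        c = confusion(p, g)
        assert c.TP + c.FP + c.FN + c.TN == 63

    def test_non_binary_rejected(self):
        with pytest.raises(InvalidParameterError):
            confusion(np.array([[0.5]]), np.array([[1.0]]))

    def test_direct_substitution(self):
        assert overlap_metrics(ConfusionCounts(6, 2, 2, 6)) == \
            (0.75, 0.6, 0.75, 0.75)
        assert overlap_metrics(ConfusionCounts(5, 0, 0, 3)) == (1, 1, 1, 1)

    def test_against_set_arithmetic_oracle(self, rng):
        for _ in range(200):
            p = _random_mask(rng, (12, 12), p=rng.uniform(0.05, 0.9))
            g = _random_mask(rng, (12, 12), p=rng.uniform(0.05, 0.9))
            dice, iou, prec, se = overlap_metrics(confusion(p, g))
            A = {tuple(ij) for ij in np.argwhere(p)}
            B = {tuple(ij) for ij in np.argwhere(g)}
            if not A and not B:
                continue
            inter = len(A & B)
            assert dice == pytest.approx(2 * inter / (len(A) + len(B))
                                         if A or B else 1.0)
            assert iou == pytest.approx(inter / len(A | B))
            if A:
                assert prec == pytest.approx(inter / len(A))
            if B:
                assert se == pytest.approx(inter / len(B))

    def test_dice_iou_identity(self, rng):
        for _ in range(100):
            p = _random_mask(rng, (10, 10), p=rng.uniform(0.1, 0.9))
            g = _random_mask(rng, (10, 10), p=rng.uniform(0.1, 0.9))
            dice, iou, _, _ = overlap_metrics(confusion(p, g))
            assert dice == pytest.approx(2 * iou / (1 + iou), rel=1e-12)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(p=arrays(bool, (7, 7)), g=arrays(bool, (7, 7)))
    def test_dice_iou_identity_property(self, p, g):
        dice, iou, _, _ = overlap_metrics(confusion(p, g))
        assert dice == pytest.approx(2 * iou / (1 + iou), rel=1e-12)
        assert dice >= iou

    def test_empty_mask_conventions(self):
        e = np.zeros((3, 3), bool)
        f = np.ones((3, 3), bool)
        assert overlap_metrics(confusion(e, e)) == (1, 1, 1, 1)
        assert overlap_metrics(confusion(e, f))[0] == 0.0
        assert overlap_metrics(confusion(f, e))[0] == 0.0


def _hd95_oracle(a, b, q=95.0):
    A = np.argwhere(a).astype(float)
    B = np.argwhere(b).astype(float)
    d_ab = cdist(A, B).min(axis=1)
    d_ba = cdist(B, A).min(axis=1)
    return max(np.percentile(d_ab, q), np.percentile(d_ba, q))


class TestHD95:
    def test_identical_masks_zero(self, rng):
        m = _random_mask(rng, (10, 10))
        assert hd95(m, m) == 0.0

    def test_two_single_pixels(self):
        a = np.zeros((8, 8), bool)
        b = np.zeros((8, 8), bool)
        a[0, 0] = True
        b[3, 4] = True
        assert hd95(a, b) == pytest.approx(5.0)

    @pytest.mark.parametrize("points", ["foreground", "boundary"])
    def test_against_brute_force_oracle(self, rng, points):
        from scipy.ndimage import binary_erosion
        for _ in range(50):
            n = int(rng.integers(8, 33))
            a = _random_mask(rng, (n, n), p=rng.uniform(0.1, 0.5))
            b = _random_mask(rng, (n, n), p=rng.uniform(0.1, 0.5))
            if not a.any() or not b.any():
                continue
            got = hd95(a, b, points=points)
            if points == "boundary":
                a = a & ~binary_erosion(a, border_value=0)
                b = b & ~binary_erosion(b, border_value=0)
            assert got == pytest.approx(_hd95_oracle(a, b), rel=1e-10)

    def test_bounded_by_exact_hausdorff_and_small_set_equality(self, rng):
        for _ in range(20):
            a = _random_mask(rng, (16, 16), p=0.2)
            b = _random_mask(rng, (16, 16), p=0.2)
            if not a.any() or not b.any():
                continue
            exact = _hd95_oracle(a, b, q=100.0)
            assert hd95(a, b) <= exact + 1e-12
        # with <= 20 points per direction the 95th percentile interpolates
        # within the top interval but the symmetric max still matches the
        # oracle at the same percentile rule
        a = np.zeros((32, 32), bool)
        b = np.zeros((32, 32), bool)
        a[2, 2:10] = True
        b[5, 2:12] = True
        assert hd95(a, b) == pytest.approx(_hd95_oracle(a, b))

    def test_translation_invariance(self, rng):
        a = np.zeros((20, 20), bool)
        b = np.zeros((20, 20), bool)
        a[4:8, 5:9] = True
        b[6:11, 3:7] = True
        base = hd95(a, b)
        assert hd95(np.roll(a, (4, 3), (0, 1)),
                    np.roll(b, (4, 3), (0, 1))) == pytest.approx(base)

    def test_empty_mask_sentinel_with_warning(self):
        a = np.zeros((6, 8), bool)
        b = np.ones((6, 8), bool)
        with pytest.warns(RuntimeWarning):
            val = hd95(a, b)
        assert val == pytest.approx(np.hypot(6, 8))
        with pytest.warns(RuntimeWarning):
            assert hd95(a, b, empty_value=-1.0) == -1.0


class TestPairedTTest:
    def test_zero_variance_rejected(self):
        a = np.arange(5.0)
        with pytest.raises(DegenerateStatisticError):
            paired_t_test(a, a)

    def test_symmetric_differences_give_null_result(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = a + np.array([-1.0, 1.0, -2.0, 2.0])
        t, p = paired_t_test(a, b)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_closed_form(self, rng):
        """t statistic equals mean(d)/(sd(d)/sqrt(n)) and the p-value the
        survival function of the t distribution (independent route)."""
        from scipy import stats
        a = rng.normal(size=10)
        b = rng.normal(size=10) + 0.4
        t, p = paired_t_test(a, b)
        d = a - b
        t_ref = d.mean() / (d.std(ddof=1) / np.sqrt(10))
        assert t == pytest.approx(t_ref, rel=1e-12)
        assert p == pytest.approx(2 * stats.t.sf(abs(t_ref), df=9), rel=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(InvalidParameterError):
            paired_t_test([1.0, 2.0], [1.0])


class TestReporting:
    def test_perfect_report_and_table(self, rng):
        m = _random_mask(rng, (12, 12))
        r = evaluate_masks(m, m)
        assert (r.dice, r.iou, r.hd95) == (1.0, 1.0, 0.0)
        table = metric_table([r, r], ["s1", "s2"])
        assert table.shape[0] == 3
        assert "±" in table.iloc[-1]["dice"]
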