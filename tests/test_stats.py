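"""Overlap metrics and agreement statistics, cross-checked independently."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exoct.errors import DegenerateInputError
from exoct.stats import (
    agreement_report,
    bland_altman,
    ccc,
    confusion_counts,
    icc,
    overlap_metrics,
    pearson_r,
)


class TestOverlapMetrics:
    def test_identity_masks_all_ones(self):
        m = np.zeros((10, 10), dtype=bool)
        m[2:8, 2:8] = True
        res = overlap_metrics(m, m)
        assert (res.dice, res.iou, res.precision, res.recall) == (1, 1, 1, 1)

    def test_hand_counts_example(self):
        # TP=2, FP=2, FN=2: dice=4/8, iou=2/6, precision=recall=1/2
        pred = np.array([[1, 1, 1, 1, 0, 0]], dtype=bool)
        truth = np.array([[1, 1, 0, 0, 1, 1]], dtype=bool)
        c = confusion_counts(pred, truth)
        assert (c.tp, c.fp, c.fn, c.tn) == (2, 2, 2, 0)
        res = overlap_metrics(pred, truth)
        assert res.dice == pytest.approx(0.5)
        assert res.iou == pytest.approx(1 / 3)
        assert res.precision == pytest.approx(0.5)
        assert res.recall == pytest.approx(0.5)

    def test_empty_prediction_degenerate_with_warning(self):
        truth = np.ones((4, 4), dtype=bool)
        pred = np.zeros((4, 4), dtype=bool)
        with pytest.warns(UserWarning, match="precision"):
            res = overlap_metrics(pred, truth)
        assert (res.dice, res.iou, res.precision, res.recall) == (0, 0, 0, 0)

    def test_counts_partition_the_grid(self):
        rng = np.random.default_rng(0)
        p = rng.random((13, 17)) > 0.5
        t = rng.random((13, 17)) > 0.5
        assert confusion_counts(p, t).total == p.size

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_dice_iou_identity(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random((12, 12)) > rng.uniform(0.2, 0.8)
        t = rng.random((12, 12)) > rng.uniform(0.2, 0.8)
        if not (p | t).any():
            return
        res = overlap_metrics(p, t)
        assert res.dice == pytest.approx(2 * res.iou / (1 + res.iou), abs=1e-12)


class TestCCC:
    def test_perfect_concordance(self):
        x = np.array([1.0, 2.0, 5.0, 7.0])
        assert ccc(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_location_shift_penalized_but_not_correlation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = x + 10
        assert ccc(x, y) < 1.0
        assert pearson_r(x, y) == pytest.approx(1.0, abs=1e-12)

    def test_frozen_example_value(self):
        # direct evaluation of the concordance formula with 1/n moments:
        # 2*1.2625 / (1.25 + 1.286875 + 0.075**2) = 0.99311701...
        x = [1, 2, 3, 4]
        y = [1.1, 2.1, 2.9, 4.2]
        assert ccc(x, y) == pytest.approx(0.9931170108161257, abs=1e-12)

    def test_symmetry_and_common_shift_invariance(self):
        rng = np.random.default_rng(8)
        x = rng.normal(10, 2, 30)
        y = x + rng.normal(0.3, 0.5, 30)
        assert ccc(x, y) == pytest.approx(ccc(y, x), abs=1e-12)
        assert ccc(x + 5, y + 5) == pytest.approx(ccc(x, y), abs=1e-12)

    def test_degenerate_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            ccc([3.0, 3.0, 3.0], [3.0, 3.0, 3.0])

    def test_lin_inequality_against_pearson(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            x = rng.normal(0, rng.uniform(0.5, 3), 20)
            y = rng.uniform(0.5, 2) * x + rng.normal(0, 1, 20)
            assert abs(ccc(x, y)) <= abs(pearson_r(x, y)) + 1e-12


class TestICC:
    def test_perfect_agreement(self):
        x = np.array([1.0, 2.0, 3.0, 7.0])
        assert icc(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_matches_pingouin_absolute_agreement_single(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(10)
        for _ in range(20):
            a = rng.normal(10, 3, 10)
            b = a + rng.normal(0.5, 1.0, 10)
            df = pd.DataFrame(
                {
                    "target": np.r_[np.arange(10), np.arange(10)],
                    "rater": ["x"] * 10 + ["y"] * 10,
                    "score": np.r_[a, b],
                }
            )
            ref = (
                pg.intraclass_corr(df, targets="target", raters="rater", ratings="score")
                .set_index("Type")
                .loc["ICC(A,1)", "ICC"]
            )
            assert icc(a, b) == pytest.approx(ref, abs=1e-8)

    def test_near_zero_under_independence(self):
        rng = np.random.default_rng(11)
        x = rng.normal(0, 1, 1000)
        y = rng.normal(0, 1, 1000)
        assert abs(icc(x, y)) < 0.1

    def test_decreases_with_growing_inter_rater_bias(self):
        rng = np.random.default_rng(12)
        x = rng.normal(20, 4, 200)
        noise = rng.normal(0, 0.5, 200)
        values = [icc(x, x + noise + bias) for bias in (0.0, 1.0, 2.0, 4.0)]
        assert all(b < a for a, b in zip(values, values[1:]))

    def test_degenerate_table_rejected(self):
        with pytest.raises(DegenerateInputError):
            icc([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])


class TestBlandAltman:
    def test_identical_series(self):
        x = np.array([1.0, 2.0, 3.0])
        assert bland_altman(x, x) == (0.0, 0.0, 0.0)

    def test_constant_offset(self):
        x = np.array([1.0, 2.0, 3.0])
        bias, lo, hi = bland_altman(x + 0.5, x)
        assert (bias, lo, hi) == pytest.approx((0.5, 0.5, 0.5))

    def test_hand_example(self):
        bias, lo, hi = bland_altman([1, 2, 3], [0, 2, 4])
        assert bias == pytest.approx(0.0)
        assert lo == pytest.approx(-1.96)
        assert hi == pytest.approx(1.96)

    def test_report_orders_limits_around_bias(self):
        rng = np.random.default_rng(13)
        x = rng.normal(15, 3, 40)
        y = x + rng.normal(0.4, 0.8, 40)
        rep = agreement_report(x, y)
        assert rep.loa_low <= rep.bias <= rep.loa_high
        assert abs(rep.ccc) <= abs(rep.pearson_r) + 1e-12
        assert rep.n_pairs == 40
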