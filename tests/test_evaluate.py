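"""Metrics, Pearson correlation, threshold sweep, per-group reporting."""

import numpy as np
import pandas as pd
import pytest

from fazseg.datatypes import ConfusionCounts
from fazseg.evaluate import (
    confusion_counts,
    dsc,
    group_report,
    pearson_r,
    sensitivity,
    specificity,
    threshold_sweep,
)


def _loop_oracle(pred, gt):
    tp = fp = tn = fn = 0
    for i in range(pred.shape[0]):
        for j in range(pred.shape[1]):
            p, g = bool(pred[i, j]), bool(gt[i, j])
            if p and g:
                tp += 1
            elif p and not g:
                fp += 1
            elif not p and g:
                fn += 1
            else:
                tn += 1
    return tp, fp, tn, fn


class TestConfusion:
    def test_perfect_prediction(self):
        m = np.zeros((10, 10), dtype=np.uint8)
        m[:2, :5] = 1
        c = confusion_counts(m, m)
        assert (c.tp, c.fp, c.fn, c.tn) == (10, 0, 0, 90)

    def test_empty_prediction_counts_misses(self):
        gt = np.zeros((8, 8), dtype=np.uint8)
        gt[2:4, 2:4] = 1
        c = confusion_counts(np.zeros_like(gt), gt)
        assert c.tp == 0 and c.fn == 4

    def test_matches_pixel_loop_oracle(self):
        rng = np.random.default_rng(0)
        pred = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        gt = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        c = confusion_counts(pred, gt)
        assert (c.tp, c.fp, c.tn, c.fn) == tuple(
            _loop_oracle(pred, gt)[i] for i in (0, 1, 2, 3)
        )

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_counts(np.zeros((4, 4)), np.zeros((5, 5)))


class TestMetricFormulas:
    def test_dsc_direct_arithmetic(self):
        assert dsc(ConfusionCounts(tp=2, fp=2, tn=0, fn=2)) == pytest.approx(0.5)

    def test_identical_masks_score_one(self):
        c = ConfusionCounts(tp=50, fp=0, tn=50, fn=0)
        assert dsc(c) == sensitivity(c) == specificity(c) == 1.0

    def test_disjoint_masks_score_zero(self):
        c = ConfusionCounts(tp=0, fp=10, tn=80, fn=10)
        assert dsc(c) == 0.0 and sensitivity(c) == 0.0

    def test_degenerate_both_empty_convention(self):
        c = ConfusionCounts(tp=0, fp=0, tn=100, fn=0)
        assert dsc(c) == 1.0 and sensitivity(c) == 1.0

    def test_dsc_symmetric_in_pred_and_gt(self):
        rng = np.random.default_rng(1)
        a = (rng.random((16, 16)) > 0.6).astype(np.uint8)
        b = (rng.random((16, 16)) > 0.6).astype(np.uint8)
        assert dsc(confusion_counts(a, b)) == dsc(confusion_counts(b, a))

    def test_trio_matches_oracle_on_many_random_pairs(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            pred = (rng.random((16, 16)) > rng.uniform(0.2, 0.8)).astype(np.uint8)
            gt = (rng.random((16, 16)) > rng.uniform(0.2, 0.8)).astype(np.uint8)
            tp, fp, tn, fn = _loop_oracle(pred, gt)
            c = confusion_counts(pred, gt)
            if fp + 2 * tp + fn:
                assert dsc(c) == 2 * tp / (fp + 2 * tp + fn)
            if tp + fn:
                assert sensitivity(c) == tp / (tp + fn)
            if tn + fp:
                assert specificity(c) == tn / (tn + fp)


class TestPearson:
    def test_perfect_positive_linearity(self):
        x = np.array([1.0, 2, 3, 4, 5])
        r, p = pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_perfect_negative_linearity(self):
        x = np.array([1.0, 2, 3, 4])
        r, _ = pearson_r(x, -x)
        assert r == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        r, _ = pearson_r([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(3)
        x = rng.random(20)
        y = 0.5 * x + rng.random(20)
        r, _ = pearson_r(x, y)
        manual = np.cov(x, y, ddof=1)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
        assert r == pytest.approx(manual, rel=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            pearson_r([1, 2], [1, 2])


class TestThresholdSweep:
    def _indicator_fixture(self):
        rng = np.random.default_rng(4)
        gts, probs = [], []
        for _ in range(3):
            g = (rng.random((24, 24)) > 0.8).astype(np.uint8)
            gts.append(g)
            probs.append(g.astype(float))
        return probs, gts

    def test_exact_indicators_score_one_everywhere_interior(self):
        probs, gts = self._indicator_fixture()
        sweep = threshold_sweep(probs, gts, grid=[0.1, 0.5, 0.9], refine_first=False)
        np.testing.assert_allclose(sweep["mean_dsc"], 1.0)

    def test_means_match_direct_metric_calls(self):
        rng = np.random.default_rng(5)
        prob = rng.random((16, 16))
        gt = (rng.random((16, 16)) > 0.7).astype(np.uint8)
        sweep = threshold_sweep([prob], [gt], grid=[0.2, 0.8], refine_first=False)
        from fazseg.postprocess import binarize

        for t, mean in zip(sweep["threshold"], sweep["mean_dsc"]):
            assert mean == pytest.approx(dsc(confusion_counts(binarize(prob, t), gt)))

    def test_order_invariance(self):
        rng = np.random.default_rng(6)
        probs = [rng.random((16, 16)) for _ in range(4)]
        gts = [(rng.random((16, 16)) > 0.7).astype(np.uint8) for _ in range(4)]
        a = threshold_sweep(probs, gts, grid=[0.3, 0.6])
        b = threshold_sweep(probs[::-1], gts[::-1], grid=[0.3, 0.6])
        pd.testing.assert_frame_equal(a, b)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            threshold_sweep([], [], grid=[0.5])


class TestGroupReport:
    def _rows(self, n_subjects=5):
        rng = np.random.default_rng(7)
        rows = []
        for gid in range(1, 10):
            for s in range(n_subjects):
                area = 0.2 + 0.05 * s
                rows.append(
                    {
                        "subject_id": f"S{s}",
                        "bc_group": gid,
                        "dsc": 0.9 + 0.01 * s,
                        "sensitivity": 0.9,
                        "specificity": 0.99,
                        "area_pred": area + rng.normal(0, 0.005),
                        "area_gt": area,
                    }
                )
        return pd.DataFrame(rows)

    def test_nine_groups_plus_pooled_row(self):
        report = group_report(self._rows())
        assert len(report) == 10
        assert list(report["group"]) == [f"G{i}" for i in range(1, 10)] + ["all"]

    def test_duplicated_rows_have_zero_sd(self):
        rows = self._rows(1)
        rows = pd.concat([rows, rows], ignore_index=True)
        report = group_report(rows)
        assert (report["dsc_sd"].abs() <= 1e-12).all()

    def test_pooled_mean_is_mean_of_equal_sized_groups(self):
        report = group_report(self._rows())
        groups = report[report["group"] != "all"]
        pooled = report[report["group"] == "all"].iloc[0]
        assert pooled["dsc_mean"] == pytest.approx(groups["dsc_mean"].mean())

    def test_small_group_reports_nan_correlation(self):
        rows = self._rows(2)
        report = group_report(rows)
        assert report[report["group"] == "G1"]["area_r"].isna().all()

    def test_unknown_group_rejected(self):
        rows = self._rows()
        rows.loc[0, "bc_group"] = 12
        with pytest.raises(ValueError):
            group_report(rows)
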