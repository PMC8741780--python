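"""Overlap-metric identities, overlay conservation, and summary statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from discseg.evaluation import (
    OVERLAY_BLUE,
    OVERLAY_GREEN,
    OVERLAY_RED,
    UndefinedMetricError,
    binarize,
    compute_metrics,
    format_summary_table,
    render_overlay,
    summarize,
)


def random_mask_pair(seed, shape=(16, 16), p=0.3):
    r = np.random.default_rng(seed)
    truth = (r.random(shape) < p).astype(np.uint8)
    if truth.sum() == 0:
        truth[0, 0] = 1
    pred = (r.random(shape) < p).astype(np.uint8)
    return pred, truth


class TestBinarize:
    def test_boundary_is_inclusive(self):
        out = binarize(np.full((4, 4), 0.5), 0.5)
        assert out.all()

    def test_threshold_above_max_gives_empty(self, rng):
        out = binarize(rng.uniform(0, 0.9, (8, 8)), 0.999)
        assert out.sum() == 0

    def test_foreground_count_matches_enumeration(self, rng):
        prob = rng.random((12, 12))
        out = binarize(prob, 0.5)
        ref = sum(1 for i in range(12) for j in range(12) if prob[i, j] >= 0.5)
        assert int(out.sum()) == ref

    def test_threshold_range_enforced(self):
        with pytest.raises(ValueError):
            binarize(np.zeros((2, 2)), 0.0)


class TestComputeMetrics:
    def test_identical_masks_score_one(self):
        m = np.zeros((8, 8), np.uint8)
        m[2:4, 3:8] = 1
        rec = compute_metrics(m, m)
        assert (rec.dice, rec.sensitivity, rec.ppv) == (1.0, 1.0, 1.0)
        assert rec.p_area == rec.t_area == rec.intersection == 10

    def test_disjoint_masks_score_zero(self):
        p = np.zeros((4, 4), np.uint8); p[0, 0] = 1
        t = np.zeros((4, 4), np.uint8); t[3, 3] = 1
        rec = compute_metrics(p, t)
        assert (rec.dice, rec.sensitivity, rec.ppv) == (0.0, 0.0, 0.0)

    def test_hand_enumerated_two_thirds_case(self):
        # |P| = 9, |T| = 9, |P ∩ T| = 6 laid out explicitly
        p = np.zeros((4, 5), np.uint8)
        t = np.zeros((4, 5), np.uint8)
        p.ravel()[:9] = 1          # pixels 0..8
        t.ravel()[3:12] = 1        # pixels 3..11 -> overlap 3..8 = 6 px
        rec = compute_metrics(p, t)
        assert rec.intersection == 6
        assert rec.dice == pytest.approx(2 / 3)
        assert rec.sensitivity == pytest.approx(2 / 3)
        assert rec.ppv == pytest.approx(2 / 3)

    def test_empty_truth_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            compute_metrics(np.ones((3, 3)), np.zeros((3, 3)))

    def test_empty_prediction_flagged_with_zero_ppv(self):
        t = np.zeros((3, 3), np.uint8); t[1, 1] = 1
        rec = compute_metrics(np.zeros((3, 3)), t)
        assert rec.empty_prediction
        assert (rec.dice, rec.sensitivity, rec.ppv) == (0.0, 0.0, 0.0)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_identities_and_symmetry(self, seed):
        """Dice = harmonic mean of sens/PPV; dice symmetric; sens(P,T)=ppv(T,P)."""
        pred, truth = random_mask_pair(seed)
        if pred.sum() == 0:
            pred[0, 0] = 1
        rec = compute_metrics(pred, truth)
        if rec.sensitivity > 0 and rec.ppv > 0:
            hm = 2 * rec.sensitivity * rec.ppv / (rec.sensitivity + rec.ppv)
            assert rec.dice == pytest.approx(hm, abs=1e-12)
        swapped = compute_metrics(truth, pred)
        assert rec.dice == pytest.approx(swapped.dice, abs=1e-12)
        assert rec.sensitivity == pytest.approx(swapped.ppv, abs=1e-12)

    def test_adding_true_positive_never_hurts(self, rng):
        pred, truth = random_mask_pair(7)
        rec = compute_metrics(pred, truth)
        missed = np.argwhere((truth == 1) & (pred == 0))
        assert len(missed)
        pred2 = pred.copy()
        pred2[tuple(missed[0])] = 1
        rec2 = compute_metrics(pred2, truth)
        assert rec2.dice >= rec.dice
        assert rec2.sensitivity >= rec.sensitivity


class TestOverlay:
    def test_equal_masks_render_red_only(self, rng):
        m = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        base = np.full((8, 8), 100, np.uint8)
        out = render_overlay(m, m, base)
        fg = m.astype(bool)
        assert np.all(out[fg] == OVERLAY_RED)
        assert np.all(out[~fg] == 100)

    def test_empty_prediction_renders_truth_blue(self):
        t = np.zeros((6, 6), np.uint8); t[2:4, 2:4] = 1
        out = render_overlay(np.zeros_like(t), t, np.zeros((6, 6), np.uint8))
        assert np.all(out[t.astype(bool)] == OVERLAY_BLUE)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_color_counts_conserve_areas(self, seed):
        """red+blue = |T| and red+green = |P| on every rendered pair."""
        pred, truth = random_mask_pair(seed)
        out = render_overlay(pred, truth, np.zeros(pred.shape, np.uint8))
        red = int(np.all(out == OVERLAY_RED, axis=-1).sum())
        blue = int(np.all(out == OVERLAY_BLUE, axis=-1).sum())
        green = int(np.all(out == OVERLAY_GREEN, axis=-1).sum())
        rec = compute_metrics(pred, truth) if pred.sum() else None
        assert red + blue == int(truth.sum())
        assert red + green == int(pred.sum())
        if rec is not None:
            assert red == rec.intersection

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            render_overlay(np.zeros((4, 4)), np.zeros((4, 5)), np.zeros((4, 4)))


def _frame(groups):
    rows = []
    for (model, dataset), vals in groups.items():
        for v in vals:
            rows.append({"model": model, "dataset": dataset,
                         "dice": v, "sensitivity": v, "ppv": v})
    return pd.DataFrame(rows)


class TestSummarize:
    def test_identical_records_have_zero_sd(self):
        df = _frame({("a", "d"): [0.5, 0.5, 0.5], ("b", "d"): [0.7, 0.7]})
        summary, _ = summarize(df)
        assert (summary["dice_sd"] == 0).all()

    def test_two_value_closed_form(self):
        df = _frame({("a", "d"): [0.6, 0.8], ("b", "d"): [0.1, 0.2]})
        summary, _ = summarize(df)
        row = summary[summary["model"] == "a"].iloc[0]
        assert row["dice_mean"] == pytest.approx(0.7)
        assert row["dice_sd"] == pytest.approx(np.std([0.6, 0.8], ddof=1))
        assert bool(row["dice_best"])

    def test_matches_reference_statistics(self, rng):
        vals = rng.random(20)
        df = _frame({("a", "d"): vals, ("b", "d"): rng.random(20)})
        summary, box = summarize(df)
        row = summary[summary["model"] == "a"].iloc[0]
        assert row["dice_mean"] == pytest.approx(float(np.mean(vals)), abs=1e-12)
        assert row["dice_sd"] == pytest.approx(float(np.std(vals, ddof=1)), abs=1e-12)
        b = box[(box["model"] == "a") & (box["metric"] == "dice")].iloc[0]
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        assert (b["q1"], b["median"], b["q3"]) == pytest.approx((q1, med, q3))

    def test_outliers_use_iqr_fence(self):
        vals = [0.5] * 10 + [0.95]
        df = _frame({("a", "d"): vals, ("b", "d"): [0.1, 0.2]})
        _, box = summarize(df)
        b = box[(box["model"] == "a") & (box["metric"] == "dice")].iloc[0]
        assert b["n_outliers"] == 1

    def test_single_record_group_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            summarize(_frame({("a", "d"): [0.5]}))

    def test_table_marks_best_and_letters(self):
        df = _frame({("a", "d"): [0.8, 0.9], ("b", "d"): [0.2, 0.3]})
        summary, _ = summarize(df)
        txt = format_summary_table(summary, letters={("d", "a"): {"dice": "a"},
                                                     ("d", "b"): {"dice": "b"}})
        assert "**" in txt and "^a" in txt and "^b" in txt
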