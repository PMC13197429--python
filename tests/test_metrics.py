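"""Correctness, entropy confidence, weighted F1, calibration, bootstrap."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import precision_recall_fscore_support

import semioloc as sl
from semioloc.metrics import MAX_ENTROPY_BITS, Prediction, _codes
from semioloc.parsing import RegionLikelihood


def rl(*values):
    return RegionLikelihood.from_array(values)


class TestPredict:
    def test_argmax(self):
        assert sl.predict(rl(40, 30, 5, 5, 5, 10, 5)) == ("Temporal Lobe", 40.0)

    def test_tie_breaks_by_canonical_order(self):
        region, _ = sl.predict(rl(30, 30, 8, 8, 8, 8, 8))
        assert region == "Temporal Lobe"

    def test_all_zero_is_no_prediction(self):
        assert sl.predict(RegionLikelihood.zeros()) == (None, 0.0)


class TestConfidence:
    def test_uniform_vector_has_max_entropy_and_zero_confidence(self):
        score = sl.confidence(rl(*([100 / 7] * 7)))
        assert score.entropy_bits == pytest.approx(2.807, abs=5e-4)
        assert score.entropy_bits == pytest.approx(math.log2(7))
        assert score.confidence == pytest.approx(0.0, abs=1e-12)

    def test_one_hot_vector_has_zero_entropy_and_full_confidence(self):
        score = sl.confidence(rl(0, 0, 0, 100, 0, 0, 0))
        assert score.entropy_bits == 0.0
        assert score.confidence == 1.0

    def test_two_equal_outcomes_give_one_bit(self):
        score = sl.confidence(rl(50, 50, 0, 0, 0, 0, 0))
        assert score.entropy_bits == pytest.approx(1.0)
        assert score.confidence == pytest.approx(1 - 1 / math.log2(7))

    def test_zero_mass_convention(self):
        score = sl.confidence(RegionLikelihood.zeros())
        assert score.confidence == 0.0

    def test_unnormalized_vectors_rescaled(self):
        a = sl.confidence(rl(20, 10, 5, 5, 5, 5, 5))
        b = sl.confidence(rl(40, 20, 10, 10, 10, 10, 10))
        assert a.entropy_bits == pytest.approx(b.entropy_bits)

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(
            st.floats(min_value=0, max_value=100), min_size=7, max_size=7
        ).filter(lambda v: sum(v) > 0)
    )
    def test_identity_and_bounds(self, values):
        score = sl.confidence(rl(*values))
        assert 0.0 <= score.entropy_bits <= MAX_ENTROPY_BITS + 1e-12
        assert score.confidence == pytest.approx(
            1 - score.entropy_bits / MAX_ENTROPY_BITS
        )


def make_predictions(y_true, y_pred, p=0.5):
    """Singleton-truth predictions from integer codes."""
    out = []
    for i, (t, yp) in enumerate(zip(y_true, y_pred)):
        out.append(
            Prediction(
                entry_id=str(i),
                predicted=sl.REGIONS[yp],
                truth=(sl.REGIONS[t],),
                correct=t == yp,
                confidence=p,
                probability=p,
            )
        )
    return out


class TestWeightedPRF1:
    def test_perfect_predictions(self):
        preds = make_predictions([0, 1, 2, 3], [0, 1, 2, 3])
        assert sl.weighted_prf1(preds) == (1.0, 1.0, 1.0)

    def test_constant_predictor_two_classes(self):
        # 6 of class A, 4 of class B, always predicting A:
        # F1(A) = 12/16, weighted F1 = 0.6 * 0.75 = 0.45
        preds = make_predictions([0] * 6 + [1] * 4, [0] * 10)
        _, _, f1 = sl.weighted_prf1(preds)
        assert f1 == pytest.approx(0.45)

    def test_agrees_with_sklearn_on_random_instances(self, rng):
        for _ in range(25):
            n = int(rng.integers(20, 200))
            y_true = rng.integers(0, 7, n)
            y_pred = rng.integers(0, 7, n)
            mine = sl.weighted_prf1(make_predictions(y_true, y_pred))
            ref = precision_recall_fscore_support(
                y_true, y_pred, average="weighted", zero_division=0,
                labels=list(range(7)),
            )[:3]
            assert mine == pytest.approx(ref, abs=1e-12)

    def test_multilabel_crediting_rule(self):
        preds = [
            Prediction("a", "Insula", ("Temporal Lobe", "Insula"), True, 0.5, 0.5),
            Prediction("b", "Frontal Lobe", ("Temporal Lobe", "Insula"), False, 0.5, 0.5),
        ]
        y_true, y_pred = _codes(preds)
        assert y_true.tolist() == [sl.REGION_INDEX["Insula"], sl.REGION_INDEX["Temporal Lobe"]]
        assert y_pred.tolist() == [sl.REGION_INDEX["Insula"], sl.REGION_INDEX["Frontal Lobe"]]

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            sl.weighted_prf1([])


class TestReliabilityAndBrier:
    def test_confident_correct_set(self):
        preds = make_predictions([0, 1], [0, 1], p=1.0)
        report = sl.reliability(preds, 10)
        occupied = [b for b in report.bins if b.size]
        assert len(occupied) == 1 and occupied[0].index == 10
        assert occupied[0].fraction_positive == 1.0
        assert occupied[0].mean_confidence == 1.0
        assert sl.brier(preds) == 0.0

    def test_half_correct_at_half_confidence(self):
        preds = make_predictions([0, 0, 0, 0], [0, 0, 1, 1], p=0.5)
        report = sl.reliability(preds, 10)
        bin5 = report.bins[4]  # (0.4, 0.5]
        assert bin5.size == 4
        assert bin5.fraction_positive == 0.5
        assert bin5.mean_confidence == 0.5
        assert sl.brier(preds) == pytest.approx(0.25)

    def test_bin_intervals_are_open_left_closed_right(self):
        preds = make_predictions([0], [0], p=0.1)
        report = sl.reliability(preds, 10)
        assert report.bins[0].size == 1  # 0.1 lands in (0, 0.1]

    def test_bin_sizes_sum_to_samples(self, rng):
        preds = make_predictions(
            rng.integers(0, 7, 100), rng.integers(0, 7, 100), p=0.5
        )
        # vary probabilities
        preds = [
            Prediction(p.entry_id, p.predicted, p.truth, p.correct, 0.5, float(q))
            for p, q in zip(preds, rng.uniform(0, 1, 100))
        ]
        report = sl.reliability(preds, 10)
        assert sum(b.size for b in report.bins) == 100

    def test_brier_invariant_to_order(self, rng):
        preds = make_predictions(rng.integers(0, 7, 50), rng.integers(0, 7, 50))
        assert sl.brier(preds) == sl.brier(list(reversed(preds)))

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            sl.reliability(make_predictions([0], [0]), 1)


class TestBootstrap:
    def test_constant_scores_have_zero_width(self):
        ci = sl.bootstrap_ci([0.7] * 50, n_resamples=99, seed=1)
        assert ci.upper - ci.lower == pytest.approx(0.0, abs=1e-12)
        assert ci.mean == pytest.approx(0.7)

    def test_deterministic_per_seed(self, rng):
        scores = rng.uniform(0, 1, 100)
        a = sl.bootstrap_ci(scores, n_resamples=199, seed=5)
        b = sl.bootstrap_ci(scores, n_resamples=199, seed=5)
        assert a == b

    def test_width_close_to_normal_approximation(self, rng):
        scores = (rng.random(1000) < 0.5).astype(float)
        ci = sl.bootstrap_ci(scores, n_resamples=999, seed=3)
        expected_width = 2 * 1.96 * np.sqrt(0.25 / 1000)
        assert abs((ci.upper - ci.lower) - expected_width) < 0.2 * expected_width

    def test_empty_scores_rejected(self):
        with pytest.raises(ValueError):
            sl.bootstrap_ci([], n_resamples=10)
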