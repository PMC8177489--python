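"""Metric and significance-test correctness."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from slo_ensemble.evaluation import (
    CONTROL,
    GLAUCOMA,
    ComparisonMatrix,
    ConfusionCounts,
    EvalResult,
    REFERENCE_CONFUSION_MEANS,
    UndefinedMetricError,
    balanced_accuracy,
    build_comparison_matrix,
    confusion,
    sensitivity_specificity,
    wilcoxon_compare,
)


def exact_signflip_pvalue(a, b):
    """Exhaustive 2^n sign-flip null distribution of the signed-rank statistic."""
    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    t_plus = ranks[d > 0].sum()
    dist = np.array(
        [
            sum(r for s, r in zip(signs, ranks) if s)
            for signs in itertools.product([0, 1], repeat=len(d))
        ]
    )
    p = 2 * min((dist <= t_plus).mean(), (dist >= t_plus).mean())
    return min(p, 1.0)


class TestConfusion:
    def test_perfect_prediction(self):
        c = confusion([GLAUCOMA, GLAUCOMA, CONTROL], [GLAUCOMA, GLAUCOMA, CONTROL])
        assert (c.tp, c.tn, c.fp, c.fn) == (2, 1, 0, 0)

    def test_total_error(self):
        y = np.array([GLAUCOMA, CONTROL, GLAUCOMA])
        flipped = np.where(y == GLAUCOMA, CONTROL, GLAUCOMA)
        c = confusion(y, flipped)
        assert c.tp == 0 and c.tn == 0
        assert c.fp + c.fn == 3

    def test_matches_loop_oracle_on_random_labels(self):
        rng = np.random.default_rng(42)
        y_true = rng.choice([CONTROL, GLAUCOMA], size=50)
        y_pred = rng.choice([CONTROL, GLAUCOMA], size=50)
        c = confusion(y_true, y_pred)
        tn = fp = fn = tp = 0
        for t, p in zip(y_true, y_pred):
            if t == GLAUCOMA and p == GLAUCOMA:
                tp += 1
            elif t == GLAUCOMA:
                fn += 1
            elif p == GLAUCOMA:
                fp += 1
            else:
                tn += 1
        assert (c.tn, c.fp, c.fn, c.tp) == (tn, fp, fn, tp)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length mismatch"):
            confusion([CONTROL], [CONTROL, GLAUCOMA])


class TestSensitivitySpecificity:
    @pytest.mark.parametrize(
        "tn,fp,fn,tp,sen,spe",
        [
            (22.7, 1.7, 0.0, 21.0, 1.000, 0.930),
            (11.0, 1.2, 1.2, 9.3, 0.886, 0.902),
            (5, 0, 0, 5, 1.0, 1.0),
        ],
    )
    def test_worked_examples(self, tn, fp, fn, tp, sen, spe):
        got_sen, got_spe = sensitivity_specificity(
            ConfusionCounts(tn=tn, fp=fp, fn=fn, tp=tp)
        )
        assert round(got_sen, 3) == sen
        assert round(got_spe, 3) == spe

    def test_zero_denominator_names_metric(self):
        with pytest.raises(UndefinedMetricError, match="sensitivity"):
            sensitivity_specificity(ConfusionCounts(tn=3, fp=1, fn=0, tp=0))
        with pytest.raises(UndefinedMetricError, match="specificity"):
            sensitivity_specificity(ConfusionCounts(tn=0, fp=0, fn=1, tp=3))


class TestBalancedAccuracy:
    @pytest.mark.parametrize(
        "sen,spe,expected",
        [(1.000, 0.930, 0.965), (0.5, 0.5, 0.5), (0.943, 0.918, 0.9305)],
    )
    def test_mean_of_sen_spe(self, sen, spe, expected):
        assert balanced_accuracy(sen, spe) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            balanced_accuracy(1.2, 0.5)

    @given(
        st.integers(0, 30), st.integers(0, 30), st.integers(0, 30), st.integers(0, 30)
    )
    @settings(max_examples=60, deadline=None)
    def test_metric_identity_on_eval_results(self, tn, fp, fn, tp):
        """balanced accuracy == (sen + spe)/2 to 1e-12 on any valid counts."""
        if tp + fn == 0 or tn + fp == 0:
            return
        res = EvalResult("m", [ConfusionCounts(tn=tn, fp=fp, fn=fn, tp=tp)])
        sen, spe = res.sensitivities[0], res.specificities[0]
        assert abs(res.balanced_accuracies[0] - (sen + spe) / 2) < 1e-12


class TestWilcoxon:
    def test_identical_sequences_not_significant(self):
        p, sig = wilcoxon_compare([0.9] * 6, [0.9] * 6)
        assert p == 1.0 and not sig

    def test_exact_enumeration_example(self):
        a = [0.9, 0.92, 0.95, 0.91, 0.94]
        b = [0.5, 0.52, 0.48, 0.51, 0.5]
        p, sig = wilcoxon_compare(a, b)
        assert p == pytest.approx(exact_signflip_pvalue(a, b))
        assert p == pytest.approx(2 / 32)

    def test_matches_enumeration_on_random_suite(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            n = rng.integers(5, 13)
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            p, _ = wilcoxon_compare(a, b)
            assert p == pytest.approx(exact_signflip_pvalue(a, b), abs=1e-12)

    def test_short_sequences_rejected(self):
        with pytest.raises(ValueError, match=">= 5"):
            wilcoxon_compare([1, 2, 3], [2, 3, 4])


class TestComparisonMatrix:
    @staticmethod
    def _result(model_id, scores):
        # encode balanced accuracies as confusion counts on 10+10 subjects
        counts = [
            ConfusionCounts(tn=10 * s, fp=10 * (1 - s), fn=10 * (1 - s), tp=10 * s)
            for s in scores
        ]
        return EvalResult(model_id, counts)

    def test_identical_results_no_significance(self):
        scores = [0.8, 0.85, 0.9, 0.82, 0.88]
        m = build_comparison_matrix([self._result("a", scores), self._result("b", scores)])
        assert isinstance(m, ComparisonMatrix)
        assert not m.better
        assert np.allclose(m.p_values[0, 1], 1.0)

    def test_dominant_model_is_flagged_for_losers(self):
        rng = np.random.default_rng(1)
        lo1 = 0.5 + 0.05 * rng.random(10)
        lo2 = 0.5 + 0.05 * rng.random(10)
        hi = 0.95 + 0.02 * rng.random(10)
        m = build_comparison_matrix(
            [self._result("weak1", lo1), self._result("weak2", lo2),
             self._result("strong", hi)]
        )
        assert m.annotation_for("weak1") == ["strong"]
        assert m.annotation_for("weak2") == ["strong"]
        # significance agrees with the exhaustive oracle per pair
        assert exact_signflip_pvalue(hi, lo1) < 0.05

    def test_single_result_set_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            build_comparison_matrix([self._result("only", [0.8] * 5)])

    def test_mismatched_fold_counts_rejected(self):
        with pytest.raises(ValueError, match="fold counts"):
            build_comparison_matrix(
                [self._result("a", [0.8] * 5), self._result("b", [0.8] * 10)]
            )


def test_reference_table_symmetry():
    """p-value matrix is symmetric with NaN diagonal."""
    rng = np.random.default_rng(3)
    results = [
        TestComparisonMatrix._result(f"m{i}", 0.7 + 0.2 * rng.random(8))
        for i in range(3)
    ]
    m = build_comparison_matrix(results)
    assert np.allclose(m.p_values, m.p_values.T, equal_nan=True)
    assert np.all(np.isnan(np.diag(m.p_values)))


def test_reference_confusion_means_have_consistent_metrics():
    """The stored reference sen/spe columns match their own mean counts."""
    for _, row in REFERENCE_CONFUSION_MEANS.iterrows():
        sen, spe = sensitivity_specificity(
            ConfusionCounts(tn=row.tn, fp=row.fp, fn=row.fn, tp=row.tp)
        )
        assert round(sen, 3) == row.sen
        assert round(spe, 3) == row.spe
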