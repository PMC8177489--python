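"""Fold plans, combination rules and the CV-ensemble construction."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slo_ensemble.ensemble import (
    CLASSES,
    EnsembleConfig,
    RULES,
    StratificationError,
    build_fold_ensemble,
    collect_eval_results,
    combine_majority,
    combine_support,
    make_fold_plan,
    run_cv_experiment,
)
from slo_ensemble.evaluation import CONTROL, GLAUCOMA

from conftest import linear_support_fn, linear_trainer


def study_labels():
    return np.array([CONTROL] * 122 + [GLAUCOMA] * 105)


# ---------------------------------------------------------------- fold plans


class TestFoldPlan:
    def test_outer_fold_sizes_227_k5(self):
        plan = make_fold_plan(study_labels(), 5, seed=0)
        sizes = sorted(len(plan.test_indices(f)) for f in range(5))
        assert sizes == [45, 45, 45, 46, 46]

    def test_leave_one_out_limit(self):
        labels = np.array([CONTROL, GLAUCOMA] * 5)
        plan = make_fold_plan(labels, 10, seed=0, stratified=False)
        assert all(len(plan.test_indices(f)) == 1 for f in range(10))

    def test_determinism(self):
        labels = study_labels()
        p1 = make_fold_plan(labels, 5, seed=9)
        p2 = make_fold_plan(labels, 5, seed=9)
        assert np.array_equal(p1.outer_assignment, p2.outer_assignment)
        for a, b in zip(p1.inner_assignments, p2.inner_assignments):
            assert np.array_equal(a, b)

    @pytest.mark.parametrize("k", [5, 10])
    def test_partition_and_stratification(self, k):
        labels = study_labels()
        plan = make_fold_plan(labels, k, seed=1)
        # outer folds partition the dataset
        assert np.array_equal(
            np.sort(np.concatenate([plan.test_indices(f) for f in range(k)])),
            np.arange(len(labels)),
        )
        sizes = [len(plan.test_indices(f)) for f in range(k)]
        assert max(sizes) - min(sizes) <= 1
        # per-fold class proportions within one sample of the global share
        for f in range(k):
            fold_labels = labels[plan.test_indices(f)]
            for cls, total in ((CONTROL, 122), (GLAUCOMA, 105)):
                expected = total * len(fold_labels) / len(labels)
                assert abs(np.sum(fold_labels == cls) - expected) <= 1.0

    @pytest.mark.parametrize("k", [5, 10])
    def test_inner_parts_partition_each_training_fold(self, k):
        labels = study_labels()
        plan = make_fold_plan(labels, k, seed=2)
        for f in range(k):
            inner = plan.inner_assignments[f]
            train_idx = plan.train_indices(f)
            assert np.array_equal(np.flatnonzero(inner >= 0), train_idx)
            part_sizes = [len(plan.inner_part_indices(f, p)) for p in range(k - 1)]
            assert sum(part_sizes) == len(train_idx)
            assert max(part_sizes) - min(part_sizes) <= 1

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            make_fold_plan([CONTROL, GLAUCOMA] * 2, 5)

    def test_small_class_under_stratification_rejected(self):
        labels = np.array([CONTROL] * 20 + [GLAUCOMA] * 3)
        with pytest.raises(StratificationError):
            make_fold_plan(labels, 5, stratified=True)


# ----------------------------------------------------------------- combiners


def brute_majority(votes, weights):
    tally = {c: 0.0 for c in CLASSES}
    for v, w in zip(votes, weights):
        tally[v] += w
    best = max(tally.values())
    winners = [c for c in CLASSES if tally[c] == best]
    return winners

def brute_support(supports, weights):
    acc = np.zeros(2)
    for s, w in zip(supports, weights):
        acc += w * np.asarray(s)
    return acc


class TestCombiners:
    def test_strict_majority(self):
        assert combine_majority([GLAUCOMA, GLAUCOMA, GLAUCOMA, CONTROL]) == GLAUCOMA

    def test_weighted_majority(self):
        assert combine_majority([GLAUCOMA, CONTROL], weights=[0.9, 0.1]) == GLAUCOMA

    def test_all_vote_patterns_match_count_oracle(self):
        for pattern in itertools.product(CLASSES, repeat=4):
            got = combine_majority(list(pattern))
            winners = brute_majority(pattern, [1.0] * 4)
            if len(winners) == 1:
                assert got == winners[0]
            else:
                assert got == CONTROL  # tie-break without supports

    def test_support_accumulation_example(self):
        label, acc = combine_support([(0.9, 0.1), (0.4, 0.6)])
        assert label == CONTROL
        assert np.allclose(acc, [1.3, 0.7])

    def test_constructed_tie_predicts_control(self):
        label, acc = combine_support([(0.9, 0.1), (0.4, 0.6)], weights=[0.2, 0.8])
        assert np.allclose(acc, [0.50, 0.50])
        assert label == CONTROL

    def test_majority_tie_falls_back_to_support_accumulation(self):
        supports = [(0.9, 0.1), (0.2, 0.8)]
        votes = [CONTROL, GLAUCOMA]
        # unweighted supports accumulate to (1.1, 0.9) -> control
        assert combine_majority(votes, supports=supports) == CONTROL
        supports = [(0.6, 0.4), (0.1, 0.9)]
        assert combine_majority(votes, supports=supports) == GLAUCOMA

    def test_random_supports_match_weighted_sum_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            m = rng.integers(1, 6)
            p = rng.random(m)
            supports = np.stack([p, 1 - p], axis=1)
            weights = rng.random(m)
            label, acc = combine_support(supports, weights=weights)
            expected = brute_support(supports, weights)
            assert np.allclose(acc, expected)
            assert label == (CONTROL if expected[0] >= expected[1] else GLAUCOMA)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            combine_support([(0.5, 0.5)], weights=[-1.0])

    def test_empty_votes_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            combine_majority([])

    @given(st.lists(st.floats(0.01, 0.99), min_size=1, max_size=5))
    @settings(max_examples=50, deadline=None)
    def test_equal_weights_reproduce_unweighted(self, p_controls):
        supports = [(p, 1 - p) for p in p_controls]
        w = [1.0 / len(supports)] * len(supports)
        assert combine_support(supports)[0] == combine_support(supports, weights=w)[0]
        votes = [CONTROL if p >= 0.5 else GLAUCOMA for p in p_controls]
        assert combine_majority(votes, supports=supports) == combine_majority(
            votes, weights=w, supports=supports
        )


# -------------------------------------------------------- ensemble building


class TestBuildFoldEnsemble:
    def test_k5_yields_four_base_models_with_distinct_validation_parts(
        self, small_separable_images
    ):
        images, labels = small_separable_images
        plan = make_fold_plan(labels, 5, seed=0)
        ens = build_fold_ensemble(
            images, labels, plan, 0, linear_trainer, linear_support_fn
        )
        assert len(ens.models) == 4
        assert ens.weights.shape == (4,)
        assert ens.weights.sum() == pytest.approx(1.0)
        parts = [plan.inner_part_indices(0, p) for p in range(4)]
        for a, b in itertools.combinations(parts, 2):
            assert len(np.intersect1d(a, b)) == 0

    def test_k2_degenerates_to_single_classifier(self, small_separable_images):
        images, labels = small_separable_images
        plan = make_fold_plan(labels, 2, seed=0)
        ens = build_fold_ensemble(
            images, labels, plan, 0, linear_trainer, linear_support_fn
        )
        assert len(ens.models) == 1

    def test_weights_proportional_to_validation_metric(self):
        # two stub models with balanced accuracies 0.8 and 0.2 on their parts
        raw = np.array([0.8, 0.2])
        normalized = raw / raw.sum()
        assert np.allclose(normalized, [0.8, 0.2])


class TestRunCvExperiment:
    def test_separable_data_reaches_perfect_ensemble(self, small_separable_images):
        images, labels = small_separable_images
        frs = run_cv_experiment(
            images, labels, 5, linear_trainer, linear_support_fn, seed=0, rules=RULES
        )
        results = collect_eval_results(frs)
        by_id = {r.model_id: r for r in results}
        assert by_id["mv regular"].balanced_accuracies.mean() == pytest.approx(1.0)

    def test_fold_record_count_and_test_sizes(self):
        labels = study_labels()
        rng = np.random.default_rng(0)
        x = rng.random((len(labels), 8, 10))
        frs = run_cv_experiment(
            x, labels, 5, linear_trainer, linear_support_fn, seed=0
        )
        assert len(frs) == 5
        assert sorted(len(fr.test_indices) for fr in frs) == [45, 45, 45, 46, 46]

    def test_null_labels_stay_at_chance(self):
        """Shuffled labels: mean ensemble balanced accuracy ~ 0.5 over seeds."""
        rng = np.random.default_rng(123)
        scores = []
        for seed in range(10):
            x = rng.random((60, 8, 10))
            labels = np.array([CONTROL] * 30 + [GLAUCOMA] * 30)
            rng.shuffle(labels)
            frs = run_cv_experiment(
                x, labels, 5, linear_trainer, linear_support_fn, seed=seed
            )
            results = collect_eval_results(frs)
            scores.append(results[1].balanced_accuracies.mean())
        assert abs(np.mean(scores) - 0.5) <= 0.1

    def test_single_class_dataset_rejected(self):
        x = np.zeros((10, 4, 4))
        with pytest.raises(ValueError, match="both classes"):
            run_cv_experiment(
                x, np.array([CONTROL] * 10), 2, linear_trainer, linear_support_fn
            )


def test_all_four_rules_available():
    assert set(RULES) == {"mv regular", "mv weighted", "sa regular", "sa weighted"}
    for cfg in RULES.values():
        cfg.validate()


def test_unknown_combiner_rejected():
    with pytest.raises(ValueError, match="combiner"):
        EnsembleConfig(combiner="averaging").validate()
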