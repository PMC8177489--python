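"""k-fold cross-validation ensembles with four combination rules.

For each outer fold the remaining training fold is split into k-1 parts;
k-1 base classifiers are trained, each validating on a different part and
training on the other k-2, so every base model sees a slightly different
dataset.  Their predictions on the held-out fold are combined by majority
voting or support accumulation, optionally weighted by each base model's
own validation performance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .evaluation import (
    CONTROL,
    GLAUCOMA,
    ConfusionCounts,
    EvalResult,
    balanced_accuracy_from_counts,
    confusion,
)

CLASSES = (CONTROL, GLAUCOMA)  # index 0 / 1 everywhere

#: trainer(x_train, y_train, x_val, y_val, seed) -> fitted model
Trainer = Callable[[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int], object]
#: support_fn(model, x) -> (n, 2) array of class supports
SupportFn = Callable[[object, np.ndarray], np.ndarray]


class StratificationError(ValueError):
    """A split would leave a part without both classes."""


@dataclass(frozen=True)
class FoldPlan:
    """Outer fold assignment plus the inner (k-1)-way split of each train fold.

    For k = 2 the training fold is split into two parts so the single base
    model still has a train/validation division.
    ``outer_assignment[i]`` is the outer fold of sample i.
    ``inner_assignments[f][i]`` is the inner part of sample i within outer
    training fold f, or -1 if sample i belongs to test fold f.
    """

    k: int
    outer_assignment: np.ndarray
    inner_assignments: tuple[np.ndarray, ...]
    seed: int
    stratified: bool

    @property
    def n(self) -> int:
        return len(self.outer_assignment)

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.outer_assignment == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.outer_assignment != fold)

    def inner_part_indices(self, fold: int, part: int) -> np.ndarray:
        return np.flatnonzero(self.inner_assignments[fold] == part)


def _balanced_partition(
    labels: np.ndarray,
    n_parts: int,
    rng: np.random.Generator,
    stratified: bool,
) -> np.ndarray:
    """Assign each sample to one of ``n_parts``, sizes differing by <= 1.

    Stratified mode additionally keeps each class's per-part counts within
    one of each other (so per-part class proportions stay within one sample
    of the global proportions), while still balancing total part sizes:
    each class's remainder samples go to the currently least-loaded parts.
    """
    n = len(labels)
    assignment = np.full(n, -1, dtype=int)
    if not stratified:
        order = rng.permutation(n)
        sizes = np.full(n_parts, n // n_parts)
        sizes[: n % n_parts] += 1
        bounds = np.concatenate([[0], np.cumsum(sizes)])
        for p in range(n_parts):
            assignment[order[bounds[p]: bounds[p + 1]]] = p
        return assignment

    loads = np.zeros(n_parts, dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        m = len(idx)
        base, rem = divmod(m, n_parts)
        # least-loaded parts absorb this class's remainder (random tie-break)
        order = np.lexsort((rng.random(n_parts), loads))
        per_part = np.full(n_parts, base)
        per_part[order[:rem]] += 1
        pos = 0
        for p in range(n_parts):
            assignment[idx[pos: pos + per_part[p]]] = p
            pos += per_part[p]
        loads += per_part
    return assignment


def make_fold_plan(
    labels: Sequence,
    k: int,
    seed: int = 0,
    stratified: bool = True,
) -> FoldPlan:
    """Plan the outer k folds and each training fold's inner (k-1) parts."""
    labels = np.asarray(labels)
    n = len(labels)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples ({n})")
    classes, counts = np.unique(labels, return_counts=True)
    if stratified and counts.min() < k:
        raise StratificationError(
            f"class {classes[counts.argmin()]!r} has {counts.min()} members, "
            f"fewer than k={k}"
        )
    rng = np.random.default_rng(seed)
    outer = _balanced_partition(labels, k, rng, stratified)
    # k-1 inner parts, except k=2 where the single base model still needs a
    # train/validation split of its training fold.
    n_parts = max(k - 1, 2)
    inner: list[np.ndarray] = []
    for fold in range(k):
        train_idx = np.flatnonzero(outer != fold)
        part_of_train = _balanced_partition(
            labels[train_idx], n_parts, rng, stratified
        )
        full = np.full(n, -1, dtype=int)
        full[train_idx] = part_of_train
        inner.append(full)
    return FoldPlan(
        k=k,
        outer_assignment=outer,
        inner_assignments=tuple(inner),
        seed=seed,
        stratified=stratified,
    )


@dataclass(frozen=True)
class EnsembleConfig:
    combiner: str = "majority_voting"  # or "support_accumulation"
    weighted: bool = False
    weight_metric: str = "balanced_accuracy"  # or "accuracy"

    def validate(self) -> None:
        if self.combiner not in ("majority_voting", "support_accumulation"):
            raise ValueError(f"unknown combiner {self.combiner!r}")
        if self.weight_metric not in ("balanced_accuracy", "accuracy"):
            raise ValueError(f"unknown weight_metric {self.weight_metric!r}")


def combine_support(
    supports: Sequence,
    weights: Sequence[float] | None = None,
) -> tuple[str, np.ndarray]:
    """Accumulate (optionally weighted) class supports; label = argmax.

    An exact tie in the accumulated pair predicts control — the deterministic
    tie-break used throughout.
    """
    supports = np.atleast_2d(np.asarray(supports, dtype=float))
    if supports.size == 0:
        raise ValueError("empty support list")
    if weights is None:
        weights = np.ones(len(supports))
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (len(supports),):
            raise ValueError("weights must align one-to-one with supports")
        if np.any(weights < 0):
            raise ValueError("weights must be nonnegative")
    accumulated = weights @ supports
    label = CLASSES[0] if accumulated[0] >= accumulated[1] else CLASSES[1]
    return label, accumulated


def combine_majority(
    votes: Sequence[str],
    weights: Sequence[float] | None = None,
    supports: Sequence | None = None,
) -> str:
    """(Weighted) majority vote over class labels.

    A tied vote falls back to unweighted support accumulation when the base
    supports are available; a persistent tie predicts control.
    """
    votes = list(votes)
    if not votes:
        raise ValueError("empty vote list")
    if weights is None:
        weights = np.ones(len(votes))
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (len(votes),):
            raise ValueError("weights must align one-to-one with votes")
    tally = {label: 0.0 for label in CLASSES}
    for vote, w in zip(votes, weights):
        if vote not in tally:
            raise ValueError(f"unknown class label {vote!r}")
        tally[vote] += w
    if tally[CLASSES[0]] > tally[CLASSES[1]]:
        return CLASSES[0]
    if tally[CLASSES[1]] > tally[CLASSES[0]]:
        return CLASSES[1]
    if supports is not None:
        return combine_support(supports, weights=None)[0]
    return CLASSES[0]


@dataclass
class CvEnsemble:
    """k-1 trained base models plus their validation-derived weights."""

    models: list
    weights: np.ndarray  # normalized to sum 1
    config: EnsembleConfig
    support_fn: SupportFn

    def base_supports(self, x: np.ndarray) -> np.ndarray:
        """(n_models, n_samples, 2) support array."""
        return np.stack([np.asarray(self.support_fn(m, x)) for m in self.models])

    def predict_from_supports(self, supports: np.ndarray) -> np.ndarray:
        """Apply the configured combination rule to precomputed supports."""
        self.config.validate()
        weights = self.weights if self.config.weighted else None
        n = supports.shape[1]
        out = np.empty(n, dtype=object)
        for i in range(n):
            s_i = supports[:, i, :]
            if self.config.combiner == "majority_voting":
                votes = [CLASSES[j] for j in s_i.argmax(axis=1)]
                out[i] = combine_majority(votes, weights=weights, supports=s_i)
            else:
                out[i] = combine_support(s_i, weights=weights)[0]
        return out.astype(str)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_from_supports(self.base_supports(x))


def _validation_weight(metric: str, y_true: np.ndarray, y_pred: np.ndarray) -> float:
    if metric == "accuracy":
        return float(np.mean(y_true == y_pred))
    return balanced_accuracy_from_counts(confusion(y_true, y_pred))


def build_fold_ensemble(
    x: np.ndarray,
    y: np.ndarray,
    plan: FoldPlan,
    fold_index: int,
    trainer: Trainer,
    support_fn: SupportFn,
    ensemble_config: EnsembleConfig | None = None,
    base_seed: int = 0,
) -> CvEnsemble:
    """Train the k-1 base models of outer fold ``fold_index``.

    Base model i validates on inner part i and trains on the remaining k-2
    parts; its weight is its own validation performance, normalized across
    models to sum to one.
    """
    ensemble_config = ensemble_config or EnsembleConfig()
    ensemble_config.validate()
    y = np.asarray(y)
    models, raw_weights = [], []
    for part in range(plan.k - 1):
        val_idx = plan.inner_part_indices(fold_index, part)
        train_idx = np.flatnonzero(
            (plan.inner_assignments[fold_index] >= 0)
            & (plan.inner_assignments[fold_index] != part)
        )
        if len(np.unique(y[val_idx])) < 2 and plan.stratified:
            raise StratificationError(
                f"inner part {part} of fold {fold_index} has a single class"
            )
        seed = (base_seed * 10007 + fold_index * 101 + part) % (2**31)
        model = trainer(x[train_idx], y[train_idx], x[val_idx], y[val_idx], seed)
        pred = np.array(
            [CLASSES[j] for j in np.asarray(support_fn(model, x[val_idx])).argmax(axis=1)]
        )
        models.append(model)
        raw_weights.append(
            _validation_weight(ensemble_config.weight_metric, y[val_idx], pred)
        )
    raw = np.asarray(raw_weights, dtype=float)
    weights = raw / raw.sum() if raw.sum() > 0 else np.full(len(raw), 1.0 / len(raw))
    return CvEnsemble(
        models=models, weights=weights, config=ensemble_config, support_fn=support_fn
    )


@dataclass
class FoldResult:
    """Everything measured on one held-out outer fold."""

    fold: int
    test_indices: np.ndarray
    y_test: np.ndarray
    base_supports: np.ndarray  # (k-1, n_test, 2)
    weights: np.ndarray
    single_counts: ConfusionCounts  # mean over the k-1 base models
    base_balanced_accuracies: np.ndarray  # per base model, on this test fold
    ensemble_counts: dict[str, ConfusionCounts]  # rule name -> counts


RULES: dict[str, EnsembleConfig] = {
    "mv regular": EnsembleConfig("majority_voting", weighted=False),
    "mv weighted": EnsembleConfig("majority_voting", weighted=True),
    "sa regular": EnsembleConfig("support_accumulation", weighted=False),
    "sa weighted": EnsembleConfig("support_accumulation", weighted=True),
}


def run_cv_experiment(
    x: np.ndarray,
    y: np.ndarray,
    k: int,
    trainer: Trainer,
    support_fn: SupportFn,
    ensemble_config: EnsembleConfig | None = None,
    seed: int = 0,
    stratified: bool = True,
    rules: dict[str, EnsembleConfig] | None = None,
) -> list[FoldResult]:
    """Full k-fold CV-ensemble experiment.

    Returns one :class:`FoldResult` per outer fold, carrying the mean
    single-model confusion counts and the ensemble counts for the requested
    combination rule(s) (default: the single ``ensemble_config``; pass
    ``rules=RULES`` to evaluate all four from one training pass).
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("dataset must contain both classes")
    plan = make_fold_plan(y, k, seed=seed, stratified=stratified)
    if rules is None:
        cfg = ensemble_config or EnsembleConfig()
        rules = {"ensemble": cfg}
    results = []
    for fold in range(k):
        test_idx = plan.test_indices(fold)
        ensemble = build_fold_ensemble(
            x, y, plan, fold, trainer, support_fn,
            ensemble_config=next(iter(rules.values())), base_seed=seed,
        )
        # Leakage guard: no test sample may appear in any base model's
        # train or validation part.
        train_val = np.flatnonzero(plan.inner_assignments[fold] >= 0)
        assert len(np.intersect1d(test_idx, train_val)) == 0, "fold leakage"

        supports = ensemble.base_supports(x[test_idx])
        y_test = y[test_idx]
        base_counts = [
            confusion(y_test, np.array([CLASSES[j] for j in s.argmax(axis=1)]))
            for s in supports
        ]
        single = ConfusionCounts(
            tn=float(np.mean([c.tn for c in base_counts])),
            fp=float(np.mean([c.fp for c in base_counts])),
            fn=float(np.mean([c.fn for c in base_counts])),
            tp=float(np.mean([c.tp for c in base_counts])),
        )
        ens_counts = {}
        for name, cfg in rules.items():
            ens = CvEnsemble(ensemble.models, ensemble.weights, cfg, support_fn)
            ens_counts[name] = confusion(y_test, ens.predict_from_supports(supports))
        results.append(
            FoldResult(
                fold=fold,
                test_indices=test_idx,
                y_test=y_test,
                base_supports=supports,
                weights=ensemble.weights,
                single_counts=single,
                base_balanced_accuracies=np.array(
                    [balanced_accuracy_from_counts(c) for c in base_counts]
                ),
                ensemble_counts=ens_counts,
            )
        )
    return results


def collect_eval_results(fold_results: list[FoldResult]) -> list[EvalResult]:
    """Assemble per-method :class:`EvalResult`s (single model + each rule)."""
    out = [
        EvalResult(
            model_id="single model",
            fold_counts=[fr.single_counts for fr in fold_results],
        )
    ]
    for name in fold_results[0].ensemble_counts:
        out.append(
            EvalResult(
                model_id=name,
                fold_counts=[fr.ensemble_counts[name] for fr in fold_results],
            )
        )
    return out
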