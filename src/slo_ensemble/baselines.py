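"""Benchmark classifiers: RNFL-thickness models and image-feature + SVM.

RNFL sector thickness is the established structural biomarker, so five
standard classifiers (MLP, kNN, SVM, CART, GNB) on the seven thickness
values provide the clinical reference point.  The hand-crafted image
pipelines (whole image, row/column averages, GLCM texture, PCA, GLCM+PCA,
each feeding an RBF-kernel SVM) represent the traditional machine-learning
alternative to the CNN.  All are evaluated with the same stratified
fold-plan machinery as the CNN ensemble; every fit-dependent step (feature
scaling, PCA) is fitted on the training folds only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.feature import graycomatrix, graycoprops
from sklearn.decomposition import PCA
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .ensemble import make_fold_plan
from .evaluation import balanced_accuracy_from_counts, confusion
from .synthetic_data import RNFL_COLUMNS

RNFL_METHODS = ("mlp", "knn", "svm", "cart", "gnb")


def _make_estimator(method: str, seed: int):
    if method == "mlp":
        clf = MLPClassifier(hidden_layer_sizes=(100,), max_iter=1000, random_state=seed)
    elif method == "knn":
        clf = KNeighborsClassifier(n_neighbors=5)
    elif method == "svm":
        clf = SVC(kernel="rbf")
    elif method == "cart":
        clf = DecisionTreeClassifier(random_state=seed)
    elif method == "gnb":
        clf = GaussianNB()
    else:
        raise ValueError(f"unknown method {method!r}; choose from {RNFL_METHODS}")
    return make_pipeline(StandardScaler(), clf)


def rnfl_classify(
    table: pd.DataFrame,
    k: int,
    method: str,
    seed: int = 0,
) -> np.ndarray:
    """k-fold balanced accuracies of one thickness classifier.

    ``table`` must have the columns rnflav,ts,t,ti,ns,n,ni,label.  Features
    are standardized inside each training fold.
    """
    features = table[RNFL_COLUMNS].to_numpy(dtype=float)
    labels = table["label"].to_numpy()
    return _cv_balanced_accuracies(
        features, labels, k, seed, lambda s: _make_estimator(method, s)
    )


@dataclass(frozen=True)
class FeatureExtractorSpec:
    """Which hand-crafted representation to compute from each ROI."""

    kind: str = "glcm_with_pca"
    glcm_levels: int = 32
    glcm_distances: tuple[int, ...] = (1,)
    glcm_angles_deg: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    pca_explained_variance: float = 0.99

    KINDS = ("whole_image", "averaged_image", "glcm", "pca", "glcm_with_pca")

    def validate(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown extractor kind {self.kind!r}")
        if not 0.0 < self.pca_explained_variance <= 1.0:
            raise ValueError("pca_explained_variance must lie in (0, 1]")
        if self.glcm_levels < 2:
            raise ValueError("glcm_levels must be >= 2")


def glcm_features(image: np.ndarray, spec: FeatureExtractorSpec) -> np.ndarray:
    """GLCM contrast and dissimilarity, averaged over angles per distance.

    The [0, 1] image is quantized to ``glcm_levels`` gray levels; the
    co-occurrence matrix is symmetric and normalized, which makes the
    features invariant to adding a constant before quantization to the same
    level grid.
    """
    q = np.clip(
        (image * spec.glcm_levels).astype(int), 0, spec.glcm_levels - 1
    ).astype(np.uint8)
    glcm = graycomatrix(
        q,
        distances=list(spec.glcm_distances),
        angles=[np.deg2rad(a) for a in spec.glcm_angles_deg],
        levels=spec.glcm_levels,
        symmetric=True,
        normed=True,
    )
    contrast = graycoprops(glcm, "contrast").mean(axis=1)
    dissimilarity = graycoprops(glcm, "dissimilarity").mean(axis=1)
    return np.concatenate([contrast, dissimilarity])


def extract_features(
    images: np.ndarray,
    spec: FeatureExtractorSpec,
    fit_set: np.ndarray | None = None,
) -> np.ndarray:
    """Feature matrix (n_images, n_features) for the configured extractor.

    ``fit_set`` supplies the training images for fit-dependent extractors
    (PCA keeps the smallest number of components whose cumulative explained
    variance reaches the configured fraction, fitted on ``fit_set`` only).
    """
    spec.validate()
    images = np.asarray(images, dtype=float)
    if spec.kind == "whole_image":
        return images.reshape(len(images), -1)
    if spec.kind == "averaged_image":
        row_means = images.mean(axis=2)
        col_means = images.mean(axis=1)
        return np.concatenate([row_means, col_means], axis=1)
    if spec.kind == "glcm":
        return np.stack([glcm_features(im, spec) for im in images])
    if fit_set is None:
        raise ValueError(f"extractor {spec.kind!r} requires a fit_set (training fold)")
    pca = PCA(n_components=spec.pca_explained_variance, svd_solver="full")
    pca.fit(np.asarray(fit_set, dtype=float).reshape(len(fit_set), -1))
    projected = pca.transform(images.reshape(len(images), -1))
    if spec.kind == "pca":
        return projected
    glcm_part = np.stack([glcm_features(im, spec) for im in images])
    return np.concatenate([glcm_part, projected], axis=1)


def feature_classify(
    images: np.ndarray,
    labels: np.ndarray,
    spec: FeatureExtractorSpec,
    k: int,
    seed: int = 0,
) -> np.ndarray:
    """k-fold balanced accuracies of an SVM on the extracted features.

    PCA (when used) and feature standardization are refitted inside every
    training fold, so no information from a test fold leaks into its
    classifier.
    """
    spec.validate()
    images = np.asarray(images, dtype=float)
    labels = np.asarray(labels)
    plan = make_fold_plan(labels, k, seed=seed, stratified=True)
    # Raw-intensity vectors already share the [0, 1] scale; per-feature
    # standardization there only amplifies background-noise pixels.  The
    # heterogeneous GLCM/PCA features do get standardized (per training fold).
    standardize = spec.kind in ("glcm", "pca", "glcm_with_pca")
    scores = np.empty(k)
    for fold in range(k):
        tr, te = plan.train_indices(fold), plan.test_indices(fold)
        x_tr = extract_features(images[tr], spec, fit_set=images[tr])
        x_te = extract_features(images[te], spec, fit_set=images[tr])
        if standardize:
            clf = make_pipeline(StandardScaler(), SVC(kernel="rbf"))
        else:
            clf = SVC(kernel="rbf")
        clf.fit(x_tr, labels[tr])
        scores[fold] = balanced_accuracy_from_counts(
            confusion(labels[te], clf.predict(x_te))
        )
    return scores


def _cv_balanced_accuracies(features, labels, k, seed, estimator_factory) -> np.ndarray:
    plan = make_fold_plan(labels, k, seed=seed, stratified=True)
    scores = np.empty(k)
    for fold in range(k):
        tr, te = plan.train_indices(fold), plan.test_indices(fold)
        clf = estimator_factory(seed)
        clf.fit(features[tr], labels[tr])
        scores[fold] = balanced_accuracy_from_counts(
            confusion(labels[te], clf.predict(features[te]))
        )
    return scores
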