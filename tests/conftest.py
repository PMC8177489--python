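"""Shared fixtures: small synthetic datasets and a fast linear trainer."""

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

from slo_ensemble import SyntheticImageConfig, generate_slo_dataset
from slo_ensemble.synthetic_data import high_effect_config


@pytest.fixture(scope="session")
def small_separable_images():
    """40 + 40 strongly separable 64x80 images with labels."""
    images, labels, _ = generate_slo_dataset(high_effect_config(seed=11), 40, 40)
    return images, labels


@pytest.fixture(scope="session")
def tiny_images():
    """10 + 10 small (32x40) images for cheap feature/classifier tests."""
    config = SyntheticImageConfig(
        image_height=32, image_width=40, disc_radius_mean=8.0,
        cup_to_disc_control=0.30, cup_to_disc_glaucoma=0.75,
        noise_sd=0.02, speckle_sd=0.03, jitter_sd=0.5, vessel_count=2, seed=3,
    )
    images, labels, _ = generate_slo_dataset(config, 10, 10)
    return images, labels


def linear_trainer(x_train, y_train, x_val, y_val, seed):
    """Fast stand-in base classifier: logistic regression on raw pixels."""
    clf = LogisticRegression(max_iter=200, random_state=seed)
    clf.fit(x_train.reshape(len(x_train), -1), y_train)
    return clf


def linear_support_fn(model, x):
    probs = model.predict_proba(x.reshape(len(x), -1))
    # sklearn orders classes alphabetically: control < glaucoma, matching
    # the package's (p_control, p_glaucoma) convention.
    return probs
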