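import dataclasses

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from tomatodetect import (
    train_blob_classifier,
    train_pixel_classifier,
)
from tomatodetect.blob_analysis import blob_features
from tomatodetect.synthetic import (
    SceneConfig,
    generate_blob_training_set,
    generate_pixel_training_set,
)

PIXEL_QUOTAS = {"fruit": 1400, "leaf": 1000, "stem": 1000, "background": 1000}
BLOB_COUNTS = (30, 200, 2000)


@pytest.fixture(scope="session")
def scene_config():
    return SceneConfig()


@pytest.fixture(scope="session")
def pixel_model(scene_config):
    samples = generate_pixel_training_set(scene_config, PIXEL_QUOTAS, seed=7)
    return train_pixel_classifier(samples, seed=7)


@pytest.fixture(scope="session")
def blob_model(scene_config, pixel_model):
    blobs, labels = generate_blob_training_set(
        scene_config, BLOB_COUNTS, seed=8, pixel_classifier=pixel_model
    )
    return train_blob_classifier(
        [blob_features(b) for b in blobs], labels, seed=8
    )


def pool_scenes(det_lists, truth_lists):
    """Shift per-scene detections/truth into disjoint row bands and pool."""
    dets, truth = [], []
    offset = 0.0
    for ds, ts in zip(det_lists, truth_lists):
        dets.extend(
            dataclasses.replace(d, position=(d.position[0] + offset, d.position[1]))
            for d in ds
        )
        truth.extend(
            dataclasses.replace(t, centroid=(t.centroid[0] + offset, t.centroid[1]))
            for t in ts
        )
        offset += 1e6
    return dets, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
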