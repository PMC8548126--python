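"""Shared fixtures: small synthetic datasets and a quickly trained checkpoint.

All fixtures are generated programmatically; the heavier ones (dataset on
disk, trained network) are session-scoped so their cost is paid once.
"""

from __future__ import annotations

import numpy as np
import pytest

import lasermark as lm
from lasermark import pipeline
from lasermark.lwunet import NetworkSpec, TrainConfig

# canonical side used by the fast test pipeline (the production default is 512)
TEST_SIDE = 128
TEST_SYNTH = dict(
    size_range=(140, 180),
    n_laser_marks_range=(35, 55),
    laser_radius_range=(2, 3),
    vessel_count=5,
)


@pytest.fixture(scope="session")
def prp_dataset(tmp_path_factory):
    """Six PRP-pattern synthetic samples (4 train / 2 test) with manifest."""
    out = tmp_path_factory.mktemp("prp_data")
    cfg = lm.SynthConfig(seed=7, n_images=6, pattern="prp", train_fraction=4 / 6,
                         **TEST_SYNTH)
    manifest = lm.generate_dataset(cfg, out)
    return manifest


@pytest.fixture(scope="session")
def prp_samples(prp_dataset):
    return [lm.load_sample(r) for r in prp_dataset.records]


@pytest.fixture(scope="session")
def norm_stats(prp_dataset):
    samples = pipeline.load_split_samples(prp_dataset, "train")
    return pipeline.fit_stats(samples, TEST_SIDE)


@pytest.fixture(scope="session")
def od_checkpoint(prp_dataset, norm_stats):
    """An optic-disc checkpoint (same architecture, OD masks as labels)."""
    samples = pipeline.load_split_samples(prp_dataset, "train")
    pool = pipeline.build_patch_pool(samples, norm_stats, n_per_image=150, seed=4,
                                     label_attr="od_mask")
    return lm.train(pool, TrainConfig(seed=4, max_epochs=1, lr_init=0.03),
                    norm_stats_ref="fitted-in-session")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_spec():
    """A miniature network spec for fast unit tests of the graph itself."""
    return NetworkSpec(block_channels=(4, 6, 8), window=16, dropout_p=0.2)
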