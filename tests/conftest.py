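"""Shared fixtures: synthetic paired datasets and a desk-scale trained model.

The heavy artifacts (64-pair training set, a 5-epoch training run) are
session-scoped so the end-to-end checks share one run.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import scopesr as s

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")

#: study conditions of the desk-scale end-to-end run
TRAIN_SEED = 11
TEST_SEED = 12
MASTER_SEED = 7
FIXTURE_CRAPPIFIER = s.CrappifierSpec(family="poisson", intensity_low=5.0,
                                      intensity_high=15.0)


@pytest.fixture(scope="session")
def fixture_root(tmp_path_factory):
    """64 train + 16 test synthetic pairs, HR 128, scale 4."""
    root = tmp_path_factory.mktemp("fixtures")
    s.generate_paired_dataset(
        s.FixtureSpec(n_images=64, hr_size=128, scale=4, n_structures=6,
                      crappifier=FIXTURE_CRAPPIFIER, seed=TRAIN_SEED),
        root / "train")
    s.generate_paired_dataset(
        s.FixtureSpec(n_images=16, hr_size=128, scale=4, n_structures=6,
                      crappifier=FIXTURE_CRAPPIFIER, seed=TEST_SEED),
        root / "test")
    return root


@pytest.fixture(scope="session")
def train_dataset(fixture_root):
    spec = s.DatasetSpec(mode="train", hr_size=128, scale=4,
                         val_fraction=0.1, split_seed=0,
                         crappifier=FIXTURE_CRAPPIFIER)
    return s.TiledDataset(spec, hr_stacks=s.load_dir(fixture_root / "train/hr_dir"))


@pytest.fixture(scope="session")
def trained_model(train_dataset):
    """Tiny 2-level ResUNet trained for 5 epochs on the fixture set."""
    model = s.build_resunet(
        s.ModelSpec(encoder_blocks=(1, 1), base_width=8, scale=4), seed=0)
    config = s.TrainConfig(epochs=5, batch_size=4, learning_rate=2e-3,
                           seed=MASTER_SEED)
    train_records, val_records = train_dataset.split()
    model, history = s.train(model, train_dataset, train_records,
                             val_records, config)
    return model, history


@pytest.fixture(scope="session")
def benchmark_record(trained_model, fixture_root):
    model, _ = trained_model
    spec = s.DatasetSpec(mode="benchmark", hr_size=128, scale=4)
    ds = s.TiledDataset(spec,
                        hr_stacks=s.load_dir(fixture_root / "test/hr_dir"),
                        lr_stacks=s.load_dir(fixture_root / "test/lr_dir"))
    return s.benchmark(model, ds, 4)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
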