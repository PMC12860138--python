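import numpy as np
import pytest

import histoseg as hs


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """20 tiny (32×32) labelled patches under a grouped layout."""
    root = tmp_path_factory.mktemp("small_data")
    params = hs.SyntheticParams(image_size=32, cluster_spread=(8.0, 14.0))
    records = hs.generate_dataset(params, 10, seed=7, out_dir=root)
    return params, records


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """The 200-patch 64×64 corpus used by the end-to-end training checks."""
    root = tmp_path_factory.mktemp("tiny_data")
    params = hs.SyntheticParams(image_size=64)
    records = hs.generate_dataset(params, 100, seed=1, out_dir=root)
    split = hs.stratified_group_split(records, 0.8, seed=1)
    train_recs = [records[i] for i in split.indices(0)]
    val_recs = [records[i] for i in split.indices(1)]
    return params, records, train_recs, val_recs


@pytest.fixture(scope="session")
def tiny_train_config():
    """Desk-scale training configuration: tiny width, 64×64 inputs, and the
    SGD rate scaled for the ~300-step budget of this run."""
    return hs.TrainConfig(input_size=64, width_multiplier=0.25, max_epochs=30, sgd_lr=0.01)


@pytest.fixture(scope="session")
def trained_tiny_model(tiny_dataset, tiny_train_config):
    """Width-0.25 model trained on the 200-patch corpus (shared; ~2 min)."""
    _, _, train_recs, val_recs = tiny_dataset
    model = hs.build_model(
        hs.EncoderConfig(input_size=64, width_multiplier=0.25), seed=0
    )
    model, history = hs.train(
        model, train_recs, val_recs, tiny_train_config, seed=0
    )
    return model, history
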