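import warnings

import numpy as np
import pytest

from ehmax.presets import fixture_config

# select_top warns when fewer clusters survive than requested; that is routine
# at fixture scale and not a test failure.
warnings.filterwarnings("ignore", message="only .* clusters of size")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def desk_config():
    return fixture_config(seed=0)


@pytest.fixture(scope="session")
def learned_bank():
    """A small learned cluster bank shared by encoding/pipeline tests."""
    from ehmax.fixtures import generate_dataset, scenes_to_records
    from ehmax.io import split_datasets
    from ehmax.learning import run_learning

    cfg = fixture_config(seed=3)
    scenes, nat = generate_dataset(3, 10, seed=3, n_natural=14)
    splits = split_datasets(scenes_to_records(scenes), nat, cfg.seed)
    bank = run_learning(splits, cfg)
    return cfg, scenes, bank
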