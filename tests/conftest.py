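import numpy as np
import pytest

from cervnet.data import SyntheticConfig, generate_synthetic_dataset


@pytest.fixture(autouse=True)
def _seed_global_numpy():
    # layer construction draws initial weights from the global state; pin it so
    # every test sees the same weights regardless of execution order
    np.random.seed(1234)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_records():
    """Small in-memory synthetic dataset: 10 images/class at 48x48, mild noise."""
    cfg = SyntheticConfig(per_class_counts={k: 10 for k in range(5)},
                          image_size=48, noise_sd=0.05, seed=7)
    return generate_synthetic_dataset(cfg)


@pytest.fixture
def image_folder(tmp_path, tiny_records):
    from cervnet.data import write_image_folder
    write_image_folder(tiny_records, tmp_path / "ds")
    return tmp_path / "ds"
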