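import numpy as np
import pytest

from peptox.model import ModelConfig, ToxicityModel
from peptox.simulate import (
    SyntheticDatasetSpec,
    generate_labeled_dataset,
    make_structure_preset,
)
from peptox.train import collate, prepare_samples


def random_rotation(rng):
    """Haar-ish random rotation matrix via QR decomposition."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


@pytest.fixture(scope="session")
def helix12():
    return make_structure_preset("helix", 12, seed=3)


@pytest.fixture(scope="session")
def strand12():
    return make_structure_preset("strand", 12, seed=4)


@pytest.fixture(scope="session")
def small_config():
    return ModelConfig(d_h=16, n_vector_channels=4, d_input=32, L_max=20,
                       seed=0)


@pytest.fixture(scope="session")
def small_dataset():
    spec = SyntheticDatasetSpec(
        n_peptides=12, length_range=(6, 18), n_structures=2,
        signal_scale=4.0, embed_dim=32, L_max=20, seed=11,
    )
    return generate_labeled_dataset(spec)


@pytest.fixture(scope="session")
def small_model_and_batch(small_config, small_dataset):
    samples = prepare_samples(small_dataset[:8], small_config)
    batch = collate(samples[:8], small_config.L_max)
    return ToxicityModel(small_config), batch
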