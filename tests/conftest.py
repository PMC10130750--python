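import numpy as np
import pytest

from kip2traffic.lattice_model import reference_parameters
from kip2traffic.profile_model import align_to_reference_peak, bin_by_length
from kip2traffic.synthetic_data import ProfileGeneratorConfig, generate_profiles


@pytest.fixture(scope="session")
def ref_params():
    return reference_parameters()


@pytest.fixture(scope="session")
def small_profile_dataset():
    """150 synthetic cells at the reference parameters, binned; with truth."""
    cfg = ProfileGeneratorConfig(n_cells=150, seed=42)
    profiles, truth = generate_profiles(cfg)
    dataset = bin_by_length([align_to_reference_peak(p) for p in profiles])
    return dataset, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
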