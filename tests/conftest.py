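import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")

from glycosnog import spectra_io, synth
from glycosnog.glycomass import default_registry


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def synthetic_run(tmp_path_factory):
    """One seed-fixed synthetic run shared across the suite."""
    out = tmp_path_factory.mktemp("run")
    spec = synth.SynthSpec(seed=7)
    mgf_path, csv_path, truth = synth.simulate_run(spec, out)
    return mgf_path, csv_path, truth


@pytest.fixture(scope="session")
def run_spectra(synthetic_run):
    mgf_path, _, _ = synthetic_run
    return spectra_io.read_mgf(mgf_path)


@pytest.fixture(scope="session")
def run_features(synthetic_run):
    _, csv_path, _ = synthetic_run
    return spectra_io.read_feature_csv(csv_path)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
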