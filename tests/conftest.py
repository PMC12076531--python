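import pathlib

import pytest

from absquant import synthetic as syn


@pytest.fixture(scope="session")
def data_dir(tmp_path_factory) -> pathlib.Path:
    return tmp_path_factory.mktemp("synthetic")


@pytest.fixture(scope="session")
def clean_dataset(data_dir):
    """Noiseless MaxQuant-style report: exact log-linear response."""
    spec = syn.SyntheticSpec(n_proteins=60, noise_sigma=0.0, seed=1)
    return syn.make_report(spec, data_dir / "clean", dialect="maxquant"), spec


@pytest.fixture(scope="session")
def noisy_dataset(data_dir):
    """Report with lognormal noise, censoring and dropout."""
    spec = syn.SyntheticSpec(
        n_proteins=300,
        noise_sigma=0.15,
        censor_threshold=2e3,
        dropout_rate=0.1,
        response_intercept=5.0,
        response_slope=1.0,
        seed=42,
    )
    return syn.make_report(spec, data_dir / "noisy", dialect="maxquant"), spec
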