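import numpy as np
import pytest

from cellenergetics import GeneratorConfig, generate_species_table


@pytest.fixture(scope="session")
def eukaryote_table_noiseless():
    """Noise-free eukaryote trait table: every column sits exactly on its law."""
    return generate_species_table(
        GeneratorConfig(seed=7, group="eukaryote", n_species=40, sd_log10=0.0)
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
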