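import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from domfrag import GeneratorConfig, generate_fullrange
from domfrag.chem import ElementalFormula


@pytest.fixture(scope="session")
def c18h22o8():
    return ElementalFormula(c=18, h=22, o=8)


@pytest.fixture(scope="session")
def btc():
    """Benzenetricarboxylic acid, C9H6O6."""
    return ElementalFormula(c=9, h=6, o=6)


@pytest.fixture(scope="session")
def small_scenario():
    """Two-sample synthetic full-range scenario with ground truth."""
    config = GeneratorConfig(
        seed=11,
        sample_ids=("A", "B"),
        n_formulae=80,
        ppm_jitter_sd=0.05,
        intensity_noise_sd=0.05,
    )
    spectra, truth = generate_fullrange(config)
    return config, spectra, truth
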