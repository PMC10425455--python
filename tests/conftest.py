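import numpy as np
import pytest

import hsifruit as hf
from hsifruit.synthetic import SynthSpectraParams


@pytest.fixture(scope="session")
def params() -> SynthSpectraParams:
    return SynthSpectraParams()


@pytest.fixture(scope="session")
def table200():
    return hf.simulate_quality_table(200, seed=1)


@pytest.fixture(scope="session")
def spectra200(table200, params):
    return hf.simulate_spectra(table200, params, seed=3)


@pytest.fixture(scope="session")
def snv200(spectra200):
    return hf.snv(spectra200)


@pytest.fixture(scope="session")
def scene(params):
    """One synthetic fruit scene: (record, raw, white, dark, truth mask)."""
    table = hf.simulate_quality_table(5, seed=2)
    record = table.records[0]
    raw, white, dark, mask = hf.simulate_scene(record, 40, 40, seed=4, params=params)
    return record, raw, white, dark, mask


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
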