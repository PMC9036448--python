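import numpy as np
import pandas as pd
import pytest

from spectraits.spectra_io import SpectraSet, TraitTable
from spectraits.synthetic_data import TrialConfig, generate_field_trial


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_trial():
    """A reduced synthetic trial shared across tests (4 genotypes, 2 years)."""
    config = TrialConfig(n_genotypes=4, n_reps=2, years=("Y1", "Y2"), seed=5)
    return config, generate_field_trial(config)


@pytest.fixture(scope="session")
def default_trial():
    """The full default trial: 11 genotypes x 3 reps x 3 years x 2 x 3."""
    config = TrialConfig(seed=1)
    return config, generate_field_trial(config)


@pytest.fixture
def tiny_spectra(rng):
    """Five 10-band spectra with full metadata, for IO round-trips."""
    wl = np.arange(500, 510)
    refl = rng.uniform(0.05, 0.6, size=(5, wl.size))
    meta = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(5)],
        "genotype": ["G1", "G1", "G2", "G2", "G3"],
        "plot": list("abcde"),
        "replicate": [1, 2, 1, 2, 1],
        "year": ["Y1"] * 5,
        "stage": ["InB", "InB", "A7", "A7", "InB"],
        "layer": ["top", "middle", "bottom", "top", "middle"],
    })
    return SpectraSet(wl, refl, meta)


@pytest.fixture
def tiny_traits():
    rows = []
    for i in range(5):
        rows.append({"sample_id": f"s{i}", "trait": "SPAD", "value": 40.0 + i})
        if i < 3:
            rows.append({"sample_id": f"s{i}", "trait": "Asat", "value": 20.0 + i})
    return TraitTable(pd.DataFrame(rows))
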