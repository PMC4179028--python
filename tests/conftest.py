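import numpy as np
import pandas as pd
import pytest

from nirchem import (
    BandTable,
    ChemistryReference,
    NoiseModel,
    WavenumberGrid,
    generate_spectra,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_grid():
    return WavenumberGrid.default()


@pytest.fixture
def one_band_table():
    """A single lignin band in the middle of the default grid."""
    return BandTable(
        pd.DataFrame(
            {
                "constituent": ["lignin"],
                "center_cm1": [6000.0],
                "width_cm1": [80.0],
                "amplitude": [0.8],
            }
        )
    )


@pytest.fixture
def one_band_dataset(rng, default_grid, one_band_table):
    """Noiseless spectra whose only source of variation is one constituent
    with one absorption band: the ideal case for exact peak recovery."""
    conc = rng.uniform(18, 30, size=12)
    chem = ChemistryReference(
        pd.DataFrame({"lignin": conc}, index=[f"S{i}" for i in range(12)])
    )
    spectra = generate_spectra(
        chem, one_band_table, default_grid, NoiseModel(seed=0).silent()
    )
    return chem, spectra, one_band_table
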