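import numpy as np
import pytest

from lignomap import synth
from lignomap.spectra_io import WavenumberGrid


@pytest.fixture(scope="session")
def fingerprint_grid() -> WavenumberGrid:
    """600-point grid over the 900-1800 cm^-1 fingerprint region."""
    return WavenumberGrid(np.linspace(900.0, 1800.0, 600))


@pytest.fixture(scope="session")
def fingerprint_specs():
    """Default component band lists restricted to the fingerprint region."""
    return synth.restrict_specs(synth.DEFAULT_COMPONENT_SPECS, 900.0, 1800.0)


@pytest.fixture(scope="session")
def fingerprint_pure(fingerprint_specs, fingerprint_grid) -> np.ndarray:
    return synth.gen_pure_spectra(fingerprint_specs, fingerprint_grid)


def small_design(seed: int = 0) -> synth.DesignSpec:
    """24-sample factorial (3 sites x 2 ages x 2 parts x 2 replicates)."""
    return synth.DesignSpec(ages=(1, 2), parts=("middle", "node"),
                            replicates=2, seed=seed)


@pytest.fixture()
def small_dataset(fingerprint_grid, fingerprint_pure):
    """Cheap 24-sample macro dataset on the fingerprint grid."""
    meta, Y = synth.gen_design(small_design(seed=3))
    residue = synth.gen_pure_spectra(
        synth.restrict_specs([synth.RESIDUE_SPEC], 900.0, 1800.0),
        fingerprint_grid)[0]
    return synth.gen_macro_spectra(Y, fingerprint_pure, fingerprint_grid,
                                   snr=500.0, seed=4, residue=residue,
                                   meta=meta)
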