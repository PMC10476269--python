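import pytest

from xlms3.crosslinker import load_spec
from xlms3.synthetic_data import SimulationParams, library_fasta_entries, make_library, simulate_run


@pytest.fixture(scope="session")
def dsso():
    return load_spec("DSSO")


@pytest.fixture(scope="session")
def dsbso():
    return load_spec("DSBSO")


@pytest.fixture(scope="session")
def library():
    """Study-scale groupwise library: 30 peptides in groups of 6-10."""
    return make_library(n_peptides=30, group_size_range=(6, 10), seed=7)


@pytest.fixture(scope="session")
def simulated_run(dsso, library):
    """One simulated acquisition: 20 cross-links, 2 MS3 per doublet, noise."""
    params = SimulationParams(n_crosslinks=20, ms3_per_doublet=2, noise_peaks=30)
    spectra, truth = simulate_run(library, dsso, params, seed=1)
    return spectra, truth


@pytest.fixture(scope="session")
def library_proteins(library):
    return library_fasta_entries(library)
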