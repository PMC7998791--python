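import numpy as np
import pytest

from nmrmetab import preprocess as pp
from nmrmetab import synth


@pytest.fixture(scope="session")
def simulator():
    """One shared cohort simulator (unit spectra rendered once)."""
    return synth.CohortSimulator()


@pytest.fixture(scope="session")
def small_cohort(simulator):
    """A small lactate-effect cohort with its bucket table and truth."""
    spec = synth.CohortSpec(
        n_control=12, n_case=6, fold_changes={"Lactate": 4.19}, seed=11
    )
    spectra, truth = simulator.simulate(spec)
    table = pp.exclude_regions(pp.intelligent_bucket(spectra))
    return spectra, table, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
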