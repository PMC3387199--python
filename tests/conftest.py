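import pytest

from orthoprimer import DesignParams, FixtureSpec, ThermoModel, generate
from orthoprimer.io import read_primer_table
from importlib import resources


@pytest.fixture(scope="session")
def model():
    return ThermoModel()


@pytest.fixture(scope="session")
def params():
    return DesignParams()


@pytest.fixture(scope="session")
def panel_primers():
    """The published, empirically evaluated primer pairs bundled as data."""
    path = resources.files("orthoprimer").joinpath("data/evaluated_primers.tsv")
    return read_primer_table(str(path))


@pytest.fixture(scope="session")
def small_bundle():
    """A compact synthetic bundle: 5 taxa, 3 genes, one with a planted
    exon/intron boundary inside the forward primer window."""
    return generate(
        FixtureSpec(n_taxa=5, n_genes=3, divergence=0.2, seed=11, boundary_genes=(2,))
    )
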