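import pytest

from methexpr import io as mio
from methexpr import simulate


@pytest.fixture(scope="session")
def panel():
    """The bundled 30-cell-line subtype panel."""
    return mio.load_cell_line_panel()


@pytest.fixture(scope="session")
def small_dataset():
    """Small planted dataset shared by read-only tests (seed fixed)."""
    return simulate.simulate_dataset(
        simulate.SimulationConfig(n_genes=40, planted_fraction=0.25, seed=11)
    )
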