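import numpy as np
import pandas as pd
import pytest

from mortmap import ArealPanel, make_lattice_graph, make_srs_graph


@pytest.fixture(scope="session")
def srs_graph():
    return make_srs_graph()


@pytest.fixture
def path3_graph():
    return make_lattice_graph(1, 3)


@pytest.fixture
def toy_panel():
    """2 areas x 2 times with O = [[10, 12], [20, 18]]."""
    return ArealPanel(["a", "b"], [1, 2], np.array([[10, 12], [20, 18]]))


@pytest.fixture
def covariate_panel():
    rng = np.random.default_rng(42)
    O = rng.poisson(80, size=(6, 4))
    X = pd.DataFrame(
        {"anc": rng.normal(70, 8, 6), "health_index": rng.normal(55, 10, 6)},
        index=[f"area{i}" for i in range(6)],
    )
    return ArealPanel([f"area{i}" for i in range(6)], [1, 2, 3, 4], O, X=X)
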