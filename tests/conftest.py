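import numpy as np
import pandas as pd
import pytest

from gsbup import FactorSpec, Panel, datasets


@pytest.fixture(scope="session")
def cluster_panel():
    """The bundled seven-cluster 2013 worked example."""
    return datasets.load_cluster_panel()


@pytest.fixture(scope="session")
def cluster_reference():
    return datasets.load_cluster_reference()


@pytest.fixture
def one_in_one_out_spec():
    return [FactorSpec("x", "DI"), FactorSpec("y", "DO")]


def make_panel(rows, spec, period=0):
    frame = pd.DataFrame(rows)
    if "period" not in frame:
        frame["period"] = period
    return Panel(frame, spec)


@pytest.fixture
def toy_two_dmu(one_in_one_out_spec):
    """A=(1,1) efficient, B=(2,1) dominated: B's optimum is 0.5 via lambda_A=1."""
    return make_panel(
        [{"dmu_id": "A", "x": 1.0, "y": 1.0}, {"dmu_id": "B", "x": 2.0, "y": 1.0}],
        one_in_one_out_spec,
    )


@pytest.fixture
def toy_three_dmu(one_in_one_out_spec):
    """A=(1,1), B=(2,4), C=(4,6): textbook IRS/CRS/DRS pattern."""
    return make_panel(
        [{"dmu_id": "A", "x": 1.0, "y": 1.0},
         {"dmu_id": "B", "x": 2.0, "y": 4.0},
         {"dmu_id": "C", "x": 4.0, "y": 6.0}],
        one_in_one_out_spec,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20130701)
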