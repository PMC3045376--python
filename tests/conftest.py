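import numpy as np
import pytest

import effconn
from effconn import sem


@pytest.fixture(scope="session")
def default_paradigm():
    return effconn.make_paradigm(seed=1)


@pytest.fixture(scope="session")
def default_model():
    return effconn.default_generating_model()


@pytest.fixture(scope="session")
def small_paradigm():
    """Tiny block design with all three modelled conditions."""
    return effconn.make_paradigm(
        {"care": 2, "justice": 2, "neutral": 3}, segment_duration=15.0, tr=2.0, seed=3
    )


@pytest.fixture(scope="session")
def dag_model_3():
    """A 3-node chain x -> y -> z used throughout the SEM tests."""
    B = np.zeros((3, 3))
    B[1, 0] = 0.7
    B[2, 1] = 0.65
    psi = np.ones(3)
    model = sem.PathModel(nodes=("x", "y", "z"), edges=(("x", "y"), ("y", "z")))
    return model, B, psi


@pytest.fixture(scope="session")
def small_generating_model():
    """3-node generating model for pipeline smoke runs."""
    nodes = ("A", "B", "C")
    B = {
        "neutral": np.array([[0, 0, 0], [0.4, 0, 0], [0, 0.3, 0]]),
        "care": np.array([[0, 0, 0], [0.7, 0, 0], [0, 0.5, 0]]),
        "justice": np.array([[0, 0, 0], [0.2, 0, 0], [0.6, 0, 0]]),
    }
    psi = {c: np.ones(3) for c in B}
    return effconn.GeneratingModel(
        nodes=nodes,
        B_by_condition=B,
        Psi_by_condition=psi,
        noise_sd=0.5,
        subject_sd=0.1,
        behavior_link=((("care", "A", "B"), -50.0),),
        score_sd=10.0,
    )
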