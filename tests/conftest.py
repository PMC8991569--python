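import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def pb_fixture():
    """Reference 13-run screening table (design + yields)."""
    from fermopt import datasets

    return datasets.load_pb_table1()


@pytest.fixture(scope="session")
def bb_fixture():
    """Reference 15-run Box-Behnken table (design + yields)."""
    from fermopt import datasets

    return datasets.load_bb_table2()


@pytest.fixture(scope="session")
def ref_model():
    """The published quadratic over coded (CaCl2, trace element, volume)."""
    from fermopt import datasets

    return datasets.reference_polynomial()


def grid_max(model, step=0.01):
    """Brute-force maximum of a quadratic on a regular grid over [-1,1]^k.

    Independent of the package's evaluator: expands the polynomial term
    by term from the raw coefficients using broadcast axes.
    """
    k = model.k
    axes = [np.linspace(-1, 1, int(round(2 / step)) + 1) for _ in range(k)]
    shaped = [a.reshape([-1 if i == j else 1 for i in range(k)]) for j, a in enumerate(axes)]
    total = model.beta0 + sum(model.linear[j] * shaped[j] for j in range(k))
    total = total + sum(model.squared[j] * shaped[j] ** 2 for j in range(k))
    for i in range(k):
        for j in range(i + 1, k):
            total = total + model.interaction[i, j] * shaped[i] * shaped[j]
    return float(total.max())
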