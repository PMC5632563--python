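import numpy as np
import pytest

from swgsd import (
    DesignSpec,
    SpendingSpec,
    VarianceComponents,
    build_sw_layout,
    solve_design,
)


@pytest.fixture(scope="session")
def scenario1():
    """Four hospitals, five periods; variances from the motivating trial."""
    return dict(
        layout=build_sw_layout(4, 5),
        vc=VarianceComponents(0.02, 0.51),
        alpha=0.05,
        beta=0.1,
        delta=0.2,
    )


@pytest.fixture(scope="session")
def scenario2():
    """Twenty clusters, nine periods, near-balanced stepping, ICC 0.1."""
    return dict(
        layout=build_sw_layout(20, 9, (3, 3, 3, 3, 2, 2, 2, 2)),
        vc=VarianceComponents(1.0 / 9.0, 1.0),
        alpha=0.05,
        beta=0.2,
        delta=0.24,
    )


def make_design(sc, analyses, mode, gamma_e=None, gamma_f=None, m="search"):
    return DesignSpec(
        layout=sc["layout"],
        analyses=analyses,
        m=m,
        vc=sc["vc"],
        spending=SpendingSpec(
            alpha=sc["alpha"], beta=sc["beta"], mode=mode, gamma_e=gamma_e, gamma_f=gamma_f
        ),
        delta=sc["delta"],
    )


@pytest.fixture(scope="session")
def design1_s1(scenario1):
    """Scenario 1 flagship sequential design: {2,3,4,5}, E&F, gamma 0.5/0.5."""
    spec = make_design(scenario1, (2, 3, 4, 5), "both", 0.5, 0.5)
    return solve_design(spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
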