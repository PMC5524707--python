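"""Shared fixtures: small-layout synthetic cohorts reused across tests."""

import numpy as np
import pytest

from cardiomorph.synthetic import GeneratorParams, generate_cycle
from cardiomorph.temporal import interpolate_cycle
from cardiomorph.transport import linear_shift

SMALL = dict(n_circles=8, n_per_circle=8)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_params():
    return GeneratorParams(**SMALL)


def make_cohort(n=6, seed0=500, group="Control", **overrides):
    params = GeneratorParams(**{**SMALL, **overrides})
    return [
        interpolate_cycle(
            generate_cycle(params, seed0 + i, f"{group[0]}{i:03d}", group))
        for i in range(n)
    ]


@pytest.fixture(scope="session")
def small_transport():
    """Transported set of 6 Control subjects at the 8x8 layout."""
    return linear_shift(make_cohort(6))


@pytest.fixture(scope="session")
def two_group_transport():
    """5 + 5 subjects with contrasting amplitude and covariation slope."""
    hcs = make_cohort(5, 600, "Control", lv_amplitude=0.12,
                      covariation_slope=1.25)
    hcs += make_cohort(5, 700, "HCM", lv_amplitude=0.08,
                       covariation_slope=0.89)
    return linear_shift(hcs)
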