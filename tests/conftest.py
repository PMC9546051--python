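import numpy as np
import pytest

from triplecens import (
    AnnouncementFunction,
    ParametricFamily,
    SampleData,
    SimulationSetting,
    simulate,
)


@pytest.fixture
def example1_sample() -> SampleData:
    """Four-subject toy sample with one announced and one silent abandonment.

    U=(1,2,3,4), Δ=(0,0,1,1), Y=(0,0,1,0): closed-form estimates are
    γ̂ = 3/10 and θ̂ = 2/3 - 3/10.
    """
    return SampleData(
        u=np.array([1.0, 2.0, 3.0, 4.0]),
        y=np.array([0, 0, 1, 0]),
        delta=np.array([0, 0, 1, 1]),
    )


@pytest.fixture
def unit_exp_setting() -> SimulationSetting:
    """T ~ Exp(1), W ~ Exp(1), q ≡ 0.5 — all category quantities in closed form."""
    return SimulationSetting(
        t_family=ParametricFamily.exponential(rate=1.0),
        w_family=ParametricFamily.exponential(rate=1.0),
        q=AnnouncementFunction.constant(0.5),
        n=1000,
        seed=0,
    )


def make_setting1(n: int, seed: int, q=None) -> SimulationSetting:
    return SimulationSetting.setting1(n=n, seed=seed, q=q)


@pytest.fixture
def setting1_sample():
    """Medium study-condition sample: T Exp(16 h), W Exp(2 h), q=exp(-t)."""
    return simulate(SimulationSetting.setting1(n=2000, seed=11))
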