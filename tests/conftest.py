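import numpy as np
import pytest

from trswitch.model import RegulatorProfile, TargetData
from trswitch.preprocess import attach_target_weights, build_profiles
from trswitch.simulate import SimulationDesign, simulate_repressed_activation


@pytest.fixture
def rng():
    return np.random.default_rng(20231)


@pytest.fixture(scope="session")
def study1():
    """The two-experiment repressed-activation dataset with prepared
    target data and smoothed regulator proxies (one fixed seed)."""
    df, truth = simulate_repressed_activation(SimulationDesign(), rng=11)
    data = TargetData.from_long(df, "target")
    attach_target_weights(data, df, "target")
    profiles = build_profiles(df, truth["candidates"])
    return {"df": df, "truth": truth, "data": data, "profiles": profiles}


@pytest.fixture
def ramp_profile():
    """Single linear ramp from 0 to 1 over [0, 10], one experiment."""
    t = np.linspace(0.0, 10.0, 11)
    return RegulatorProfile("ramp", {"e1": (t, t / 10.0)})


@pytest.fixture
def two_exp_profiles():
    """Hand-built piecewise-linear profiles for two regulators in two
    experiments realizing the canonical repressed-activation pattern:
    A rises through 0.5 at t=2 (exp1) and falls through 0.5 at t=7 (exp2);
    B rises through 0.5 at t=6 (exp1) and t=3 (exp2)."""
    t = np.linspace(0.0, 10.0, 101)

    def rise(t0):
        return np.clip(0.5 + (t - t0) * 0.5, 0.05, 0.95)

    def fall(t0):
        return np.clip(0.5 - (t - t0) * 0.5, 0.05, 0.95)

    A = RegulatorProfile("A", {"exp1": (t, rise(2.0)), "exp2": (t, fall(7.0))})
    B = RegulatorProfile("B", {"exp1": (t, rise(6.0)), "exp2": (t, rise(3.0))})
    return {"A": A, "B": B}
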