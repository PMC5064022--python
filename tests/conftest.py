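import numpy as np
import pytest

from iksgate import (
    GatingScheme,
    PhysConstants,
    RateLaw,
    State,
    Transition,
    iks_scheme,
    preset_protocol,
    simulate_recording,
)


@pytest.fixture(scope="session")
def constants():
    return PhysConstants()


@pytest.fixture(scope="session")
def free_scheme():
    return iks_scheme("free")


@pytest.fixture(scope="session")
def bound_scheme():
    return iks_scheme("bound")


def two_state(rate_ab: float = 2.0, rate_ba: float = 1.0) -> GatingScheme:
    """Minimal A<->B chain with voltage-independent rates."""
    return GatingScheme(
        name="two-state",
        states=(State("A"), State("B", conducting=True)),
        transitions=(
            Transition("A", "B", RateLaw(rate_ab)),
            Transition("B", "A", RateLaw(rate_ba)),
        ),
    )


@pytest.fixture
def toy_scheme():
    return two_state()


@pytest.fixture(scope="session")
def fig9_recordings(free_scheme, bound_scheme):
    """Noiseless six-sweep activation-family recordings, both configurations."""
    proto = preset_protocol("fig9")
    return simulate_recording(free_scheme, proto), simulate_recording(bound_scheme, proto)


def euler_propagate(q: np.ndarray, p0: np.ndarray, duration_s: float, dt: float,
                    sample_every: int) -> np.ndarray:
    """Explicit-Euler master-equation integration (independent oracle)."""
    m = np.eye(len(p0)) + dt * q
    n = int(round(duration_s / dt))
    p = p0.copy()
    out = []
    for k in range(1, n + 1):
        p = p @ m
        if k % sample_every == 0:
            out.append(p.copy())
    return np.array(out)
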