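"""Shared fixtures.

Full-fidelity (500-beat) simulations are memoized per (variant, scalings,
protocol) in a session-scoped cache so independent tests can share the same
paced runs.
"""

import numpy as np
import pytest

from lqtsim import (
    APD_LQT_SCALINGS, MULTIVAR_SCALINGS,
    PacingProtocol, ScalingFactors, measure, pace,
)

FULL = PacingProtocol(record_last=2)  # 500 beats, 1 Hz, record the final two beats
SHORT = PacingProtocol(n_beats=20, record_last=2)


@pytest.fixture(scope="session")
def full_protocol():
    return FULL


@pytest.fixture(scope="session")
def paced():
    """Memoized ``pace``: identical requests reuse one simulation."""
    cache = {}

    def run(variant, scalings=ScalingFactors(), protocol=FULL, start_state=None):
        key = (variant, scalings, protocol)
        if start_state is not None or key not in cache:
            trace = pace(variant, scalings, protocol, start_state=start_state)
            if start_state is not None:
                return trace
            cache[key] = trace
        return cache[key]

    return run


@pytest.fixture(scope="session")
def paced_bm(paced):
    """Memoized biomarkers of a paced run."""
    cache = {}

    def run(variant, scalings=ScalingFactors(), protocol=FULL):
        key = (variant, scalings, protocol)
        if key not in cache:
            cache[key] = measure(paced(variant, scalings, protocol))
        return cache[key]

    return run


@pytest.fixture(scope="session")
def baseline_endo_bm(paced_bm):
    return paced_bm("endocardial")


@pytest.fixture(scope="session")
def multivar():
    return MULTIVAR_SCALINGS


@pytest.fixture(scope="session")
def apd_lqt():
    return APD_LQT_SCALINGS


def _brute_force_min_E(points, theta_steps=2880, offset_steps=1200):
    """Independent oracle: dense exhaustive scan over oriented lines, scoring
    each point by explicit point-line distance."""
    import math

    best = math.inf
    for theta in np.arange(2 * theta_steps) * (math.pi / theta_steps):
        nx, ny = math.cos(theta), math.sin(theta)
        proj = [p.x * nx + p.y * ny for p in points]
        for offset in np.linspace(min(proj) - 0.05, max(proj) + 0.05, offset_steps):
            e = 0.0
            for p in points:
                s = p.x * nx + p.y * ny - offset
                if (p.label and s <= 0) or (not p.label and s > 0):
                    e += s * s
            best = min(best, e)
    return best


@pytest.fixture(scope="session")
def brute_force_min_E():
    return _brute_force_min_E


@pytest.fixture()
def trapezoid_trace():
    """Synthetic beat: rest -85 mV, instant upstroke to +35 mV, 200 ms plateau,
    100 ms linear ramp back to rest; calcium/sodium flat."""
    from lqtsim.pacing import Trace

    t = np.arange(0.0, 500.0, 0.5)
    v = np.full_like(t, -85.0)
    plateau = (t >= 10.0) & (t < 210.0)
    ramp = (t >= 210.0) & (t < 310.0)
    v[plateau] = 35.0
    v[ramp] = 35.0 - (t[ramp] - 210.0) * (120.0 / 100.0)
    return Trace(time=t, v=v, cai=np.full_like(t, 1e-4), nai=np.full_like(t, 8.0),
                 stim_onsets=np.array([0.0]), cycle_length=500.0)
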