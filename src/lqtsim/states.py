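"""Shipped 1 Hz steady-state initial conditions for the two cell variants.

The states are stored as JSON package data and were produced by pacing each
variant at 1 Hz for several thousand beats with this package's integrator
(``scripts/make_steady_states.py`` regenerates them).  All simulations start
from these constants, mirroring the convention of pre-pacing every model
perturbation from the baseline steady state.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

import numpy as np

from .model import N_STATES, STATE_NAMES, CellVariant, _as_variant

__all__ = ["initial_state", "bootstrap_state"]

_GATE_SLICE = slice(9, 38)  # pure gating variables, constrained to [0, 1]


def bootstrap_state() -> np.ndarray:
    """Crude resting-state guess used only to generate the shipped states."""
    y = np.zeros(N_STATES)
    vals = dict(
        v=-87.5, nai=7.0, nass=7.0, ki=145.0, kss=145.0,
        cai=1e-4, cass=1e-4, cansr=1.2, cajsr=1.2,
        m=0.0, hf=1.0, hs=1.0, j=1.0, hsp=1.0, jp=1.0,
        mL=0.0, hL=1.0, hLp=1.0,
        a=0.0, iF=1.0, iS=1.0, ap=0.0, iFp=1.0, iSp=1.0,
        d=0.0, ff=1.0, fs=1.0, fcaf=1.0, fcas=1.0, jca=1.0,
        nca=0.0, ffp=1.0, fcafp=1.0,
        xrf=0.0, xrs=0.0, xs1=0.0, xs2=0.0, xk1=1.0,
        Jrelnp=0.0, Jrelp=0.0, CaMKt=0.0,
    )
    for idx, name in enumerate(STATE_NAMES):
        y[idx] = vals[name]
    return y


@lru_cache(maxsize=None)
def _load(variant: CellVariant) -> np.ndarray:
    stem = "endo" if variant is CellVariant.ENDO else "epi"
    path = resources.files("lqtsim.data").joinpath(f"steady_state_{stem}.json")
    payload = json.loads(path.read_text())
    y = np.array([payload["state"][name] for name in STATE_NAMES], dtype=float)
    _check(y)
    return y


def _check(y: np.ndarray) -> None:
    if y.shape != (N_STATES,):
        raise ValueError("steady-state vector has wrong length")
    conc = y[1:9]
    if np.any(conc <= 0):
        raise ValueError("steady-state concentrations must be positive")
    gates = y[_GATE_SLICE]
    if np.any(gates < -1e-12) or np.any(gates > 1.0 + 1e-12):
        raise ValueError("steady-state gating variables must lie in [0, 1]")


def initial_state(variant) -> np.ndarray:
    """The shipped 1 Hz steady state of ``variant`` (a fresh copy)."""
    return _load(_as_variant(variant)).copy()
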