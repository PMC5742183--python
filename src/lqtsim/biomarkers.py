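"""Scalar biomarkers of the action potential, calcium transient and [Na+]i.

All biomarkers are measured on the final recorded beat of a trace: APD at a
given repolarisation fraction (time from maximum upstroke velocity until the
voltage first falls below ``V_peak - fraction * (V_peak - V_diastolic)``, with
linear interpolation between samples), the diastolic/systolic extremes of the
cytosolic calcium transient, and the maximum [Na+]i (which varies little
within a beat).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pacing import Trace

__all__ = ["Biomarkers", "apd", "calcium_extrema", "sodium_max", "measure", "biomarker_table"]


class IncompleteRepolarizationError(RuntimeError):
    """Voltage never recrossed the repolarisation threshold within the beat."""


@dataclass(frozen=True)
class Biomarkers:
    """Per-condition biomarker set.

    ``apd90``/``apd50`` in ms; ``ca_dia``/``ca_sys`` in uM; ``na_max`` in mM.
    """

    apd90: float
    apd50: float
    ca_dia: float
    ca_sys: float
    na_max: float

    def __post_init__(self):
        if not (0 < self.apd50 <= self.apd90):
            raise ValueError("require 0 < apd50 <= apd90")
        if not (0 < self.ca_dia <= self.ca_sys):
            raise ValueError("require 0 < ca_dia <= ca_sys")
        if self.na_max <= 0:
            raise ValueError("na_max must be positive")

    def as_dict(self) -> dict:
        return {
            "apd90_ms": self.apd90, "apd50_ms": self.apd50,
            "ca_dia_uM": self.ca_dia, "ca_sys_uM": self.ca_sys,
            "na_max_mM": self.na_max,
        }


def _last_beat(trace: Trace):
    mask = trace.beat_mask(-1)
    if mask.sum() < 3:
        raise ValueError("trace does not contain a complete final beat")
    return trace.time[mask], trace.v[mask], trace.cai[mask], trace.nai[mask]


def apd(trace: Trace, fraction: float) -> float:
    """Action potential duration at a repolarisation fraction in (0, 1)."""
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie strictly between 0 and 1")
    t, v, _, _ = _last_beat(trace)
    v_dia = v[0]  # pre-stimulus diastolic voltage at beat onset
    dvdt = np.diff(v) / np.diff(t)
    i_up = int(np.argmax(dvdt))
    t_up = t[i_up]
    i_peak = i_up + int(np.argmax(v[i_up:]))
    v_peak = v[i_peak]
    threshold = v_peak - fraction * (v_peak - v_dia)
    below = np.nonzero(v[i_peak:] < threshold)[0]
    if len(below) == 0:
        raise IncompleteRepolarizationError(
            f"incomplete repolarization: never fell below {threshold:.2f} mV")
    k = i_peak + below[0]
    # linear interpolation across the crossing
    t_cross = t[k - 1] + (threshold - v[k - 1]) * (t[k] - t[k - 1]) / (v[k] - v[k - 1])
    return float(t_cross - t_up)


def calcium_extrema(trace: Trace) -> tuple:
    """(diastolic, systolic) [Ca2+]i in uM over the final recorded cycle."""
    _, _, cai, _ = _last_beat(trace)
    if len(cai) == 0:
        raise ValueError("empty trace")
    return float(cai.min() * 1e3), float(cai.max() * 1e3)


def sodium_max(trace: Trace) -> float:
    """Maximum [Na+]i (mM) over the final recorded cycle."""
    _, _, _, nai = _last_beat(trace)
    return float(nai.max())


def measure(trace: Trace) -> Biomarkers:
    ca_dia, ca_sys = calcium_extrema(trace)
    return Biomarkers(
        apd90=apd(trace, 0.90), apd50=apd(trace, 0.50),
        ca_dia=ca_dia, ca_sys=ca_sys, na_max=sodium_max(trace),
    )


def biomarker_table(rows: dict) -> pd.DataFrame:
    """Assemble ``{condition: Biomarkers}`` into the CSV-ready table."""
    records = []
    for condition, bm in rows.items():
        rec = {"condition": condition}
        rec.update(bm.as_dict())
        records.append(rec)
    return pd.DataFrame.from_records(records)
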