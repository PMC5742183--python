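"""Model perturbations: Hill-equation drug block, congenital LQT subtypes and
conductance sensitivity sweeps; plus drug-table I/O.

A drug blocking channel ``x`` at its effective free therapeutic plasma
concentration (EFTPC) multiplies the channel conductance by
``(1 + EFTPC / IC50_x)^-1`` (Hill coefficient 1).  LQT1 and LQT2 halve G_Ks
and G_Kr; LQT3 multiplies the late-sodium scaling by the dedicated
``nal_lqt3`` factor (so the effective I_NaL multiplier is ``nal * nal_lqt3``).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .biomarkers import Biomarkers, measure
from .model import ScalingFactors, _as_variant
from .pacing import PacingProtocol, pace

__all__ = [
    "DrugRecord", "LQTSubtype", "DrugTableError",
    "hill_scale", "apply_drug", "lqt_variant", "sensitivity_sweep",
    "read_drug_table", "write_drug_table",
]

_SWEEP_PARAMS = ("ks", "kr", "cal", "ncx", "nak", "nal")


@dataclass(frozen=True)
class DrugRecord:
    """One drug-table entry: therapeutic concentration, channel IC50s, TdP label.

    All concentrations must share one unit within a record (only the
    EFTPC/IC50 ratio enters the block equation).  A missing IC50 (``None``)
    means no measured block of that channel.
    """

    drug_name: str
    source: str
    eftpc: float
    ic50_kr: Optional[float]
    ic50_cal: Optional[float]
    ic50_na: Optional[float]
    tdp_label: bool

    def __post_init__(self):
        if not (self.eftpc > 0 and math.isfinite(self.eftpc)):
            raise ValueError(f"{self.drug_name}: eftpc must be positive, got {self.eftpc}")
        for name in ("ic50_kr", "ic50_cal", "ic50_na"):
            value = getattr(self, name)
            if value is not None and not (value > 0 and math.isfinite(value)):
                raise ValueError(f"{self.drug_name}: {name} must be positive if present")


class LQTSubtype(enum.Enum):
    LQT1 = "LQT1"
    LQT2 = "LQT2"
    LQT3 = "LQT3"


def hill_scale(eftpc: float, ic50: Optional[float]) -> float:
    """Fractional conductance remaining under block: (1 + EFTPC/IC50)^-1.

    ``ic50=None`` (no measured block) returns 1.0.
    """
    if not (eftpc > 0):
        raise ValueError("eftpc must be positive")
    if ic50 is None:
        return 1.0
    if not (ic50 > 0):
        raise ValueError("ic50 must be positive if present")
    return 1.0 / (1.0 + eftpc / ic50)


def apply_drug(scalings: ScalingFactors, drug: DrugRecord) -> ScalingFactors:
    """Scale G_Kr, P_CaL and G_Na by the drug's Hill block fractions.

    The fast-sodium fraction lands on the ``na`` multiplier, which is carried
    with :class:`ScalingFactors` but is never a fitted parameter.
    """
    return scalings.with_(
        kr=scalings.kr * hill_scale(drug.eftpc, drug.ic50_kr),
        cal=scalings.cal * hill_scale(drug.eftpc, drug.ic50_cal),
        na=scalings.na * hill_scale(drug.eftpc, drug.ic50_na),
    )


def lqt_variant(scalings: ScalingFactors, subtype: LQTSubtype) -> ScalingFactors:
    """Scalings for a congenital LQT condition applied on top of ``scalings``."""
    subtype = LQTSubtype(subtype)
    if subtype is LQTSubtype.LQT1:
        return scalings.with_(ks=scalings.ks * 0.5)
    if subtype is LQTSubtype.LQT2:
        return scalings.with_(kr=scalings.kr * 0.5)
    # LQT3: the gain-of-function late sodium factor composes multiplicatively
    return scalings.with_(nal=scalings.nal * scalings.nal_lqt3)


def sensitivity_sweep(variant, parameter: str, deltas: Sequence[float],
                      base: ScalingFactors = ScalingFactors(),
                      protocol: PacingProtocol = PacingProtocol()) -> pd.DataFrame:
    """Biomarkers under fractional changes of one conductance scaling.

    ``deltas`` are fractional changes (e.g. ``-0.5`` halves the conductance).
    Returns one row per delta with the full biomarker set.
    """
    if parameter not in _SWEEP_PARAMS:
        raise ValueError(f"parameter must be one of {_SWEEP_PARAMS}, got {parameter!r}")
    variant = _as_variant(variant)
    rows = []
    for delta in deltas:
        factor = 1.0 + delta
        if factor <= 0:
            raise ValueError(f"delta {delta} gives a non-positive scaling")
        scalings = base.with_(**{parameter: getattr(base, parameter) * factor})
        bm = measure(pace(variant, scalings, protocol))
        row = {"parameter": parameter, "delta": delta}
        row.update(bm.as_dict())
        rows.append(row)
    return pd.DataFrame.from_records(rows)


class DrugTableError(ValueError):
    """Raised when a drug-table CSV contains invalid rows; lists each offence."""

    def __init__(self, errors: List[str]):
        self.errors = errors
        super().__init__("invalid drug table:\n" + "\n".join(errors))


_DRUG_COLUMNS = ["drug_name", "source", "eftpc", "ic50_kr", "ic50_cal", "ic50_na", "tdp_label"]


def _parse_label(value) -> bool:
    text = str(value).strip().lower()
    if text in ("true", "1", "yes", "y", "t"):
        return True
    if text in ("false", "0", "no", "n", "f"):
        return False
    raise ValueError(f"unparseable tdp_label: {value!r}")


def read_drug_table(path) -> List[DrugRecord]:
    """Read a drug-table CSV; empty IC50 cells mean 'no measured block'.

    Duplicate (drug_name, source) pairs are allowed.  Malformed rows are
    collected into a single :class:`DrugTableError` naming each row.
    """
    df = pd.read_csv(path, dtype={"drug_name": str, "source": str},
                     float_precision="round_trip")
    missing = set(_DRUG_COLUMNS) - set(df.columns)
    if missing:
        raise DrugTableError([f"missing columns: {sorted(missing)}"])
    records, errors = [], []
    for idx, row in df.iterrows():
        try:
            ic50s = {}
            for col in ("ic50_kr", "ic50_cal", "ic50_na"):
                raw = row[col]
                ic50s[col] = None if pd.isna(raw) else float(raw)
            eftpc = row["eftpc"]
            if pd.isna(eftpc):
                raise ValueError("missing eftpc")
            records.append(DrugRecord(
                drug_name=str(row["drug_name"]), source=str(row["source"]),
                eftpc=float(eftpc), tdp_label=_parse_label(row["tdp_label"]),
                **ic50s,
            ))
        except (ValueError, TypeError) as exc:
            errors.append(f"row {idx}: {exc}")
    if errors:
        raise DrugTableError(errors)
    return records


def write_drug_table(records: Iterable[DrugRecord], path) -> None:
    rows = []
    for r in records:
        rows.append({
            "drug_name": r.drug_name, "source": r.source, "eftpc": r.eftpc,
            "ic50_kr": r.ic50_kr, "ic50_cal": r.ic50_cal, "ic50_na": r.ic50_na,
            "tdp_label": r.tdp_label,
        })
    # %.17g keeps doubles exact through the text round-trip
    pd.DataFrame(rows, columns=_DRUG_COLUMNS).to_csv(path, index=False, float_format="%.17g")
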