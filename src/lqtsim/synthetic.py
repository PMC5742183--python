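"""Seed-deterministic synthetic inputs mirroring the structure of the real data.

The curated multi-channel-block drug table is external; these generators
produce drug records, separable classifier fixtures and optimisation
objectives with the statistical structure the analysis assumes, so the whole
pipeline is testable self-contained.  Torsadogenic records are biased toward
strong hERG (I_Kr) block at therapeutic concentration; non-torsadogenic
records toward balanced I_CaL co-block — the verapamil archetype.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .biomarkers import measure
from .classifier import NormalizedPoint
from .ga import GENE_NAMES, ObjectiveSpec
from .model import ScalingFactors
from .pacing import PacingProtocol, pace
from .perturbations import DrugRecord, LQTSubtype, lqt_variant

__all__ = ["synth_drug_table", "synth_separable_points", "synth_objective", "SeparableSet"]


def _log_uniform(rng: np.random.Generator, lo: float, hi: float, size=None):
    return 10.0 ** rng.uniform(math.log10(lo), math.log10(hi), size=size)


def synth_drug_table(n: int, seed: int, p_tdp: float = 0.5,
                     eftpc_range: Tuple[float, float] = (1e-3, 10.0),
                     ic50_range: Tuple[float, float] = (1e-2, 100.0),
                     duplicate_rate: float = 0.1,
                     p_missing_na: float = 0.3) -> List[DrugRecord]:
    """Generate ``n`` drug records (concentrations in uM, log-uniform draws).

    TdP-positive drugs draw IC50_Kr near or below their EFTPC (strong hERG
    block, Hill fraction ~0.1-0.6) with weak calcium block; TdP-negative drugs
    draw balanced, milder Kr/CaL co-block.  A ``duplicate_rate`` fraction of
    records is re-emitted under a second source with jittered IC50s, mimicking
    the duplicate compounds contributed by the two original datasets.
    """
    rng = np.random.default_rng(seed)
    records: List[DrugRecord] = []
    k = 0
    while len(records) < n:
        name = f"drug{k:03d}"
        k += 1
        eftpc = float(_log_uniform(rng, *eftpc_range))
        positive = rng.random() < p_tdp
        if positive:
            # hERG IC50 within ~[0.1, 3] x EFTPC -> strong Kr block
            ic50_kr = eftpc * float(_log_uniform(rng, 0.1, 3.0))
            ic50_cal = eftpc * float(_log_uniform(rng, 10.0, 300.0))
        else:
            ic50_kr = eftpc * float(_log_uniform(rng, 2.0, 100.0))
            # balanced co-block: CaL IC50 within a decade of the Kr IC50
            ic50_cal = ic50_kr * float(_log_uniform(rng, 0.3, 3.0))
        ic50_na: Optional[float] = None
        if rng.random() > p_missing_na:
            ic50_na = eftpc * float(_log_uniform(rng, 30.0, 3000.0))
        lo, hi = ic50_range
        rec = DrugRecord(
            drug_name=name, source="synthA", eftpc=eftpc,
            ic50_kr=float(np.clip(ic50_kr, lo, hi)),
            ic50_cal=float(np.clip(ic50_cal, lo, hi)),
            ic50_na=None if ic50_na is None else float(np.clip(ic50_na, lo, hi)),
            tdp_label=positive,
        )
        records.append(rec)
        if len(records) < n and rng.random() < duplicate_rate:
            jitter = lambda v: None if v is None else float(np.clip(v * 10 ** rng.normal(0.0, 0.15), lo, hi))
            records.append(DrugRecord(
                drug_name=name, source="synthB", eftpc=eftpc,
                ic50_kr=jitter(rec.ic50_kr), ic50_cal=jitter(rec.ic50_cal),
                ic50_na=jitter(rec.ic50_na), tdp_label=positive,
            ))
    return records


@dataclass(frozen=True)
class SeparableSet:
    """Labelled points plus the ground-truth separating line that made them."""

    points: List[NormalizedPoint]
    true_angle: float   # polar angle of the line normal
    true_offset: float
    margin: float


def synth_separable_points(n: int, seed: int, margin: float = 0.5,
                           spread: float = 0.15) -> SeparableSet:
    """Two Gaussian clouds straddling a known line through (1, 1).

    With ``margin > 0`` every point sits at perpendicular distance
    >= margin/2 from the line (so the gap between classes is >= margin) and a
    fitted boundary must reach E = 0.  ``margin = 0`` allows class overlap.
    """
    if n < 2:
        raise ValueError("need n >= 2 (one point per label)")
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0.0, math.pi)
    normal = np.array([math.cos(theta), math.sin(theta)])
    center = np.array([1.0, 1.0])
    offset = float(normal @ center)
    points: List[NormalizedPoint] = []
    labels = np.zeros(n, dtype=bool)
    labels[: n // 2] = True
    rng.shuffle(labels)
    labels[0], labels[1] = True, False  # guarantee both labels
    tangent = np.array([-normal[1], normal[0]])
    for i in range(n):
        side = 1.0 if labels[i] else -1.0
        while True:
            d = margin / 2.0 + abs(rng.normal(0.0, spread)) if margin > 0 else rng.normal(0.0, spread)
            along = rng.normal(0.0, 2.0 * spread)
            p = center + side * d * normal + along * tangent
            if p[0] > 1e-3 and p[1] > 1e-3:
                break
        points.append(NormalizedPoint(x=float(p[0]), y=float(p[1]),
                                      label=bool(labels[i]), drug_name=f"pt{i}"))
    return SeparableSet(points=points, true_angle=theta, true_offset=offset, margin=margin)


def synth_objective(truth: ScalingFactors, surrogate: bool = True,
                    variant="endocardial", n_beats: int = 50,
                    conditions: Sequence[str] = ("control", "LQT1", "LQT2", "LQT3"),
                    weight: float = 100.0,
                    ) -> Union[Callable[[ScalingFactors], float], ObjectiveSpec]:
    """Optimisation fixture centred on a known parameter truth.

    ``surrogate=True`` returns a simulation-free quadratic error in log10
    parameter space (zero exactly at ``truth``).  ``surrogate=False`` paces
    the truth model (``n_beats`` per condition) and returns an
    :class:`ObjectiveSpec` whose APD90 targets are the truth model's own
    values, enabling closed-loop parameter recovery at reduced scale.
    """
    if surrogate:
        truth_log = np.array([math.log10(getattr(truth, g)) for g in GENE_NAMES])

        def error(candidate: ScalingFactors) -> float:
            cand_log = np.array([math.log10(getattr(candidate, g)) for g in GENE_NAMES])
            return float(weight * np.sum((cand_log - truth_log) ** 2))

        return error

    protocol = PacingProtocol(n_beats=n_beats, record_last=1)
    targets = {}
    for condition in conditions:
        scalings = truth if condition == "control" else lqt_variant(truth, LQTSubtype[condition])
        targets[condition] = measure(pace(variant, scalings, protocol)).apd90
    return ObjectiveSpec(apd_targets=targets, constraints_enabled=False)
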