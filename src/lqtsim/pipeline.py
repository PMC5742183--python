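"""End-to-end drug-panel experiment: block -> pace -> biomarkers -> classify.

For each drug record the model conductances are blocked by the Hill
fractions, the cell is paced to quasi-steady state, biomarkers are extracted
and normalised to the model's own no-drug baseline, and per-model decision
boundaries are fitted and compared through the shared acceptability threshold
E* (twice the lowest fitted E among the compared models).
"""

from __future__ import annotations

import json
import logging
import pathlib
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .biomarkers import Biomarkers, measure
from .classifier import (
    AcceptabilityRegion, DecisionBoundary, NormalizedPoint,
    acceptable_region, confusion_counts, fit_boundary, normalize,
)
from .model import ScalingFactors, _as_variant
from .pacing import PacingProtocol, Trace, pace
from .perturbations import DrugRecord, apply_drug

__all__ = [
    "VERAPAMIL", "evaluate_drug", "run_panel", "compare_models",
    "ModelComparison", "plateau_current_peaks",
]

logger = logging.getLogger(__name__)

#: Verapamil at its therapeutic plasma concentration (uM), curated IC50s for
#: hERG/I_Kr, Cav1.2/I_CaL and Nav1.5/I_Na.  The Hill fractions are
#: G_Kr x 0.64, G_CaL x 0.55, G_Na x 0.998 — the canonical TdP-negative
#: multi-channel blocker.
VERAPAMIL = DrugRecord(
    drug_name="verapamil", source="kramer", eftpc=0.081,
    ic50_kr=0.143, ic50_cal=0.100, ic50_na=40.4, tdp_label=False,
)


def evaluate_drug(variant, scalings: ScalingFactors, drug: DrugRecord,
                  protocol: PacingProtocol = PacingProtocol()) -> Biomarkers:
    """Biomarkers of one model under one drug, paced to quasi-steady state."""
    return measure(pace(_as_variant(variant), apply_drug(scalings, drug), protocol))


def _cache_path(cache_dir, drug: DrugRecord) -> pathlib.Path:
    safe = "".join(c if c.isalnum() or c in "-_" else "_"
                   for c in f"{drug.drug_name}_{drug.source}_{drug.eftpc:g}")
    return pathlib.Path(cache_dir) / f"{safe}.json"


def run_panel(variant, scalings: ScalingFactors, drugs: Sequence[DrugRecord],
              protocol: PacingProtocol = PacingProtocol(),
              cache_dir=None) -> pd.DataFrame:
    """One row per drug record plus the no-drug baseline row.

    The baseline row has ``drug_name='baseline'`` and maps to (1, 1) in the
    normalised plane.  With ``cache_dir`` set, per-drug biomarkers are cached
    as JSON so an interrupted panel resumes where it stopped.
    """
    variant = _as_variant(variant)
    if cache_dir is not None:
        pathlib.Path(cache_dir).mkdir(parents=True, exist_ok=True)
    baseline = measure(pace(variant, scalings, protocol))
    rows = [{
        "drug_name": "baseline", "source": "", "tdp_label": None,
        **baseline.as_dict(), "x_apd50_rel": 1.0, "y_ca_dia_rel": 1.0,
    }]
    for k, drug in enumerate(drugs):
        bm = None
        path = _cache_path(cache_dir, drug) if cache_dir is not None else None
        if path is not None and path.exists():
            payload = json.loads(path.read_text())
            bm = Biomarkers(apd90=payload["apd90_ms"], apd50=payload["apd50_ms"],
                            ca_dia=payload["ca_dia_uM"], ca_sys=payload["ca_sys_uM"],
                            na_max=payload["na_max_mM"])
            logger.info("panel %d/%d %s: cached", k + 1, len(drugs), drug.drug_name)
        if bm is None:
            bm = evaluate_drug(variant, scalings, drug, protocol)
            if path is not None:
                path.write_text(json.dumps(bm.as_dict()))
            logger.info("panel %d/%d %s: apd50=%.2f ms", k + 1, len(drugs),
                        drug.drug_name, bm.apd50)
        point = normalize(bm, baseline, drug.tdp_label, drug.drug_name)
        rows.append({
            "drug_name": drug.drug_name, "source": drug.source,
            "tdp_label": drug.tdp_label, **bm.as_dict(),
            "x_apd50_rel": point.x, "y_ca_dia_rel": point.y,
        })
    return pd.DataFrame.from_records(rows)


def panel_points(panel: pd.DataFrame) -> List[NormalizedPoint]:
    """Extract classifier points (drug rows only) from a panel table."""
    points = []
    for _, row in panel.iterrows():
        if row["drug_name"] == "baseline":
            continue
        points.append(NormalizedPoint(
            x=row["x_apd50_rel"], y=row["y_ca_dia_rel"],
            label=bool(row["tdp_label"]), drug_name=row["drug_name"],
        ))
    return points


@dataclass
class ModelComparison:
    boundary: DecisionBoundary
    error: float
    region: AcceptabilityRegion
    confusion: Dict[str, int]
    e_star_degenerate: bool = False


def compare_models(panels: Dict[str, Sequence[NormalizedPoint]],
                   e_star_floor: float = 1e-4,
                   theta_steps: int = 180, offset_steps: int = 200,
                   ) -> Dict[str, ModelComparison]:
    """Fit per-model boundaries and score regions against the shared E*.

    E* = 2 x min fitted E across models.  If some model separates its panel
    perfectly (min E = 0) the threshold definition degenerates; regions are
    then computed against ``e_star_floor`` and flagged.
    """
    boundaries = {name: fit_boundary(points) for name, points in panels.items()}
    min_e = min(b.error for b in boundaries.values())
    e_star = 2.0 * min_e
    degenerate = e_star <= 0.0
    if degenerate:
        e_star = e_star_floor
        logger.warning("minimum E is 0; using acceptability floor %.2g", e_star_floor)
    out = {}
    for name, points in panels.items():
        b = boundaries[name]
        out[name] = ModelComparison(
            boundary=b, error=b.error,
            region=acceptable_region(points, e_star, theta_steps, offset_steps),
            confusion=confusion_counts(b, points),
            e_star_degenerate=degenerate,
        )
    return out


def plateau_current_peaks(trace: Trace, window_ms: float = 300.0) -> Dict[str, float]:
    """Peak magnitudes of inward I_NCX and I_CaL during the plateau.

    Requires a trace recorded with ``record_currents=True``.  The window
    starts at the last stimulus onset; peaks are reported as positive
    magnitudes of the inward (negative) deflections, the quantities that shrink
    when L-type block collapses the calcium transient.
    """
    if trace.currents is None:
        raise ValueError("trace was recorded without currents")
    onset = trace.stim_onsets[-1]
    mask = (trace.time >= onset + 5.0) & (trace.time <= onset + window_ms)
    incx = trace.currents["INaCa_i"][mask] + trace.currents["INaCa_ss"][mask]
    ical = trace.currents["ICaL"][mask]
    return {
        "peak_inward_INCX": float(np.max(-incx)),
        "peak_inward_ICaL": float(np.max(-ical)),
        "peak_IKr": float(np.max(trace.currents["IKr"][mask])),
        "peak_IKs": float(np.max(trace.currents["IKs"][mask])),
    }
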