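"""Linear TdP/no-TdP decision boundaries in the normalised biomarker plane.

Each drug becomes a point (x, y) = (APD50, diastolic [Ca2+]i) relative to the
no-drug baseline of the same model; a line in that plane separates
torsadogenic from non-torsadogenic drugs.  The line is scored by the
miscategorisation error E: the sum of squared perpendicular (Euclidean)
distances of wrongly-sided points to the line.  Boundary acceptability is
judged against a threshold E* (twice the minimum E among compared models) by
sampling (angle, offset) space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize
from sklearn.svm import SVC

__all__ = [
    "NormalizedPoint", "DecisionBoundary", "AcceptabilityRegion",
    "normalize", "boundary_error", "fit_boundary", "acceptable_region",
    "classify", "confusion_counts",
]


@dataclass(frozen=True)
class NormalizedPoint:
    """A drug in the normalised plane: ``x`` = relative APD50, ``y`` =
    relative diastolic [Ca2+]i; the no-drug control maps to (1, 1)."""

    x: float
    y: float
    label: bool
    drug_name: str = ""

    def __post_init__(self):
        if not (self.x > 0 and self.y > 0):
            raise ValueError("normalized coordinates must be positive")


@dataclass(frozen=True)
class DecisionBoundary:
    """Line ``normal . p = offset`` with unit normal; the positive side
    (``normal . p > offset``) is the TdP-risk side.  ``error`` is E."""

    normal: Tuple[float, float]
    offset: float
    error: float

    def __post_init__(self):
        norm = math.hypot(*self.normal)
        if not math.isclose(norm, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError("boundary normal must have unit length")
        if self.error < 0:
            raise ValueError("boundary error must be >= 0")

    @property
    def angle(self) -> float:
        """Polar angle of the normal in [0, 2*pi)."""
        return math.atan2(self.normal[1], self.normal[0]) % (2 * math.pi)

    def signed_distance(self, point: NormalizedPoint) -> float:
        return self.normal[0] * point.x + self.normal[1] * point.y - self.offset


def normalize(drug_biomarkers, baseline_biomarkers, label: bool,
              drug_name: str = "") -> NormalizedPoint:
    """Map a drug's biomarkers to the normalised plane of its model baseline."""
    return NormalizedPoint(
        x=drug_biomarkers.apd50 / baseline_biomarkers.apd50,
        y=drug_biomarkers.ca_dia / baseline_biomarkers.ca_dia,
        label=label, drug_name=drug_name,
    )


def _point_arrays(points: Sequence[NormalizedPoint]):
    xy = np.array([(p.x, p.y) for p in points], dtype=float).reshape(-1, 2)
    labels = np.array([p.label for p in points], dtype=bool)
    return xy, labels


def _error_for(nx: float, ny: float, offset: float, xy: np.ndarray,
               labels: np.ndarray) -> float:
    s = xy[:, 0] * nx + xy[:, 1] * ny - offset
    wrong_pos = labels & (s <= 0)   # risk drugs on the safe side
    wrong_neg = ~labels & (s > 0)   # safe drugs on the risk side
    return float(np.sum(s[wrong_pos] ** 2) + np.sum(s[wrong_neg] ** 2))


def boundary_error(boundary: DecisionBoundary,
                   points: Sequence[NormalizedPoint]) -> float:
    """E: sum of squared perpendicular distances of miscategorised points."""
    if len(points) == 0:
        return 0.0
    xy, labels = _point_arrays(points)
    return _error_for(boundary.normal[0], boundary.normal[1], boundary.offset, xy, labels)


def classify(boundary: DecisionBoundary, point: NormalizedPoint) -> bool:
    """TdP-risk prediction; points exactly on the line are called negative."""
    return boundary.signed_distance(point) > 0


def confusion_counts(boundary: DecisionBoundary,
                     points: Sequence[NormalizedPoint]) -> dict:
    tp = fp = tn = fn = 0
    for p in points:
        pred = classify(boundary, p)
        if pred and p.label:
            tp += 1
        elif pred and not p.label:
            fp += 1
        elif not pred and not p.label:
            tn += 1
        else:
            fn += 1
    return {"TP": tp, "FP": fp, "TN": tn, "FN": fn}


def _require_both_labels(labels: np.ndarray) -> None:
    if labels.all() or (~labels).all():
        raise ValueError("fit_boundary requires at least one point of each label")


def _max_margin_boundary(xy: np.ndarray, labels: np.ndarray):
    """Hard-margin separating line via a linear SVM, or None if inseparable."""
    svc = SVC(kernel="linear", C=1e9)
    svc.fit(xy, labels.astype(int))
    w = svc.coef_[0]
    b = -svc.intercept_[0]
    norm = np.hypot(w[0], w[1])
    if norm == 0:
        return None
    nx, ny, offset = w[0] / norm, w[1] / norm, b / norm
    if _error_for(nx, ny, offset, xy, labels) > 0:
        return None
    return DecisionBoundary(normal=(float(nx), float(ny)), offset=float(offset), error=0.0)


def _theta_grid(n: int) -> np.ndarray:
    # both orientations of every line direction: theta in [0, 2*pi)
    return np.arange(2 * n) * (math.pi / n)


def fit_boundary(points: Sequence[NormalizedPoint],
                 theta_steps: int = 360, offset_steps: int = 400) -> DecisionBoundary:
    """Line minimising E; deterministic.

    Separable sets return the max-margin separating line (E = 0).  Otherwise
    a coarse (angle, offset) grid scan is refined by Nelder-Mead; the first
    grid optimum in scan order breaks ties.
    """
    if len(points) == 0:
        raise ValueError("fit_boundary requires a non-empty point set")
    xy, labels = _point_arrays(points)
    _require_both_labels(labels)

    mm = _max_margin_boundary(xy, labels)
    if mm is not None:
        return mm

    best = (math.inf, 0.0, 0.0)  # (E, theta, offset)
    for theta in _theta_grid(theta_steps):
        nx, ny = math.cos(theta), math.sin(theta)
        proj = xy[:, 0] * nx + xy[:, 1] * ny
        lo, hi = proj.min(), proj.max()
        pad = 1e-9 + 0.01 * max(hi - lo, 1e-6)
        for offset in np.linspace(lo - pad, hi + pad, offset_steps):
            e = _error_for(nx, ny, offset, xy, labels)
            if e < best[0] - 1e-15:
                best = (e, theta, offset)
    res = minimize(
        lambda z: _error_for(math.cos(z[0]), math.sin(z[0]), z[1], xy, labels),
        x0=np.array([best[1], best[2]]), method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
    )
    e_ref, theta_ref, off_ref = float(res.fun), float(res.x[0]), float(res.x[1])
    if e_ref > best[0]:
        e_ref, theta_ref, off_ref = best
    return DecisionBoundary(
        normal=(math.cos(theta_ref), math.sin(theta_ref)),
        offset=off_ref, error=e_ref,
    )


@dataclass(frozen=True)
class AcceptabilityRegion:
    """(angle, offset) boundary parameters whose E stays below ``e_star``.

    ``samples`` has one row per acceptable grid sample: (theta, offset, E).
    An empty region means no line achieves E < E* — the signature of a model
    whose drug panel cannot be separated acceptably.
    """

    e_star: float
    samples: np.ndarray  # shape (k, 3)
    theta_steps: int
    offset_steps: int

    def __post_init__(self):
        if self.samples.size and np.any(self.samples[:, 2] >= self.e_star):
            raise ValueError("every stored sample must satisfy E < e_star")

    @property
    def is_empty(self) -> bool:
        return self.samples.shape[0] == 0

    @property
    def fraction(self) -> float:
        """Fraction of sampled boundary space that is acceptable."""
        return self.samples.shape[0] / (2 * self.theta_steps * self.offset_steps)


def acceptable_region(points: Sequence[NormalizedPoint], e_star: float,
                      theta_steps: int = 180, offset_steps: int = 200) -> AcceptabilityRegion:
    """Sample boundary space and keep parameters with E < ``e_star``."""
    xy, labels = _point_arrays(points)
    rows: List[Tuple[float, float, float]] = []
    for theta in _theta_grid(theta_steps):
        nx, ny = math.cos(theta), math.sin(theta)
        proj = xy[:, 0] * nx + xy[:, 1] * ny
        lo, hi = proj.min(), proj.max()
        pad = 1e-9 + 0.01 * max(hi - lo, 1e-6)
        for offset in np.linspace(lo - pad, hi + pad, offset_steps):
            e = _error_for(nx, ny, offset, xy, labels)
            if e < e_star:
                rows.append((theta, offset, e))
    samples = np.array(rows, dtype=float).reshape(-1, 3)
    return AcceptabilityRegion(e_star=e_star, samples=samples,
                               theta_steps=theta_steps, offset_steps=offset_steps)
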