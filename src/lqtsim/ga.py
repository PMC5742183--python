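"""Genetic-algorithm optimisation of conductance scalings to long-QT targets.

The objective is a sum-of-squares APD90 error over the control and LQT1-3
conditions; the multi-variable variant adds a fixed penalty for each
control-condition concentration biomarker (diastolic/systolic [Ca2+]i, max
[Na+]i) outside its physiological range.  Seven genes (six conductance
scalings plus the LQT3 late-sodium factor) are searched in log10 space over
[0.1%, 10-fold]; the GA uses tournament selection, two-point crossover,
per-gene Gaussian mutation and single-individual elitism.  Each optimisation
is repeated ``n_runs`` times and the lowest-error run wins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .biomarkers import IncompleteRepolarizationError, measure
from .model import ScalingFactors, _as_variant
from .pacing import PacingProtocol, SimulationError, pace
from .perturbations import LQTSubtype, lqt_variant

__all__ = ["ObjectiveSpec", "GAConfig", "GAResult", "objective_error", "run_ga", "multi_run"]

GENE_NAMES = ("ks", "kr", "cal", "ncx", "nak", "nal", "nal_lqt3")

#: APD90 objective values (ms): clinical QT prolongations of LQT1-3 cohorts
#: mapped onto the baseline model's control APD90.
DEFAULT_APD_TARGETS: Dict[str, float] = {
    "control": 267.97, "LQT1": 301.14, "LQT2": 312.20, "LQT3": 311.55,
}


@dataclass(frozen=True)
class ObjectiveSpec:
    """Optimisation objective: APD90 targets plus optional concentration bounds.

    ``constraints_enabled=False`` reproduces the APD-only objective; with
    constraints each violated control-condition check adds
    ``concentration_penalty`` (ms^2).  ``penalty_per_violation=False`` applies
    the penalty at most once regardless of how many checks fail.
    """

    apd_targets: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_APD_TARGETS))
    ca_dia_range: Tuple[float, float] = (0.05, 0.15)   # uM
    ca_sys_range: Tuple[float, float] = (0.3, 0.7)     # uM
    na_range: Tuple[float, float] = (7.0, 10.0)        # mM
    concentration_penalty: float = 200.0               # ms^2 per violated check
    constraints_enabled: bool = True
    penalty_per_violation: bool = True

    def __post_init__(self):
        for lo, hi in (self.ca_dia_range, self.ca_sys_range, self.na_range):
            if not lo < hi:
                raise ValueError("concentration ranges must be ordered (lo < hi)")
        if self.concentration_penalty < 0:
            raise ValueError("concentration_penalty must be >= 0")
        if not self.apd_targets:
            raise ValueError("apd_targets must contain at least one condition")
        for cond in self.apd_targets:
            if cond != "control" and cond not in LQTSubtype.__members__:
                raise ValueError(f"unknown objective condition: {cond}")


@dataclass(frozen=True)
class GAConfig:
    """GA hyper-parameters; defaults follow the reference optimisation protocol scale."""

    population_size: int = 200
    generations: int = 50
    n_runs: int = 10
    bounds: Tuple[float, float] = (0.001, 10.0)
    seed: int = 0
    fast_beats: int = 500        # beats per condition during evaluation
    tournament_size: int = 2
    crossover_prob: float = 0.9
    mutation_sigma: float = 0.2  # log10 units
    mutation_prob: float = 0.1
    elitism: int = 1
    free_genes: Tuple[str, ...] = GENE_NAMES  # genes evolved; the rest stay at 1.0

    def __post_init__(self):
        unknown = set(self.free_genes) - set(GENE_NAMES)
        if unknown or not self.free_genes:
            raise ValueError(f"free_genes must be a non-empty subset of {GENE_NAMES}")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        lo, hi = self.bounds
        if not (0 < lo < hi):
            raise ValueError("bounds must be positive and ordered")
        if self.generations < 1 or self.n_runs < 1:
            raise ValueError("generations and n_runs must be >= 1")

    @property
    def log_bounds(self) -> Tuple[float, float]:
        return (math.log10(self.bounds[0]), math.log10(self.bounds[1]))


FAILURE_ERROR = 1.0e7  # finite sentinel per failed condition


def _condition_scalings(candidate: ScalingFactors, condition: str) -> ScalingFactors:
    if condition == "control":
        return candidate
    return lqt_variant(candidate, LQTSubtype[condition])


def objective_error(candidate: ScalingFactors, spec: ObjectiveSpec,
                    variant="endocardial",
                    protocol: Optional[PacingProtocol] = None,
                    n_beats: int = 500) -> float:
    """Sum-of-squares APD90 error (ms^2) over the objective conditions.

    Simulation failures (divergence, incomplete repolarisation) contribute a
    large finite sentinel instead of raising, as usual in GA fitness
    evaluation.
    """
    variant = _as_variant(variant)
    if protocol is None:
        protocol = PacingProtocol(n_beats=n_beats, record_last=1)
    error = 0.0
    for condition, target in spec.apd_targets.items():
        try:
            trace = pace(variant, _condition_scalings(candidate, condition), protocol)
            # a beat starting from a depolarised "diastole" is not a valid AP
            if trace.v[trace.beat_mask(-1)][0] > -60.0:
                raise SimulationError("no resting diastolic potential", beat=protocol.n_beats - 1)
            bm = measure(trace)
        except (SimulationError, IncompleteRepolarizationError, ValueError):
            error += FAILURE_ERROR
            continue
        error += (bm.apd90 - target) ** 2
        if condition == "control" and spec.constraints_enabled:
            violations = 0
            for value, (lo, hi) in ((bm.ca_dia, spec.ca_dia_range),
                                    (bm.ca_sys, spec.ca_sys_range),
                                    (bm.na_max, spec.na_range)):
                if not (lo <= value <= hi):
                    violations += 1
            if violations:
                if spec.penalty_per_violation:
                    error += spec.concentration_penalty * violations
                else:
                    error += spec.concentration_penalty
    return error


@dataclass
class GAResult:
    best: ScalingFactors
    best_error: float
    history: pd.DataFrame  # columns: generation, best_error, mean_error
    seed: int

    def to_json_dict(self) -> dict:
        payload = {name: getattr(self.best, name) for name in GENE_NAMES}
        payload.update({"error": self.best_error, "seed": self.seed})
        return payload


Objective = Union[ObjectiveSpec, Callable[[ScalingFactors], float]]


def _genes_to_scalings(genes: np.ndarray,
                       gene_names: Tuple[str, ...] = GENE_NAMES) -> ScalingFactors:
    values = dict(zip(gene_names, 10.0 ** genes))
    return ScalingFactors(**values)


def _make_evaluator(objective: Objective, config: GAConfig,
                    variant, cache: dict) -> Callable[[np.ndarray], float]:
    gene_names = config.free_genes
    if isinstance(objective, ObjectiveSpec):
        protocol = PacingProtocol(n_beats=config.fast_beats, record_last=1)

        def fn(sf: ScalingFactors) -> float:
            return objective_error(sf, objective, variant=variant, protocol=protocol)
    else:
        fn = objective

    def evaluate(genes: np.ndarray) -> float:
        key = genes.tobytes()
        if key not in cache:
            cache[key] = float(fn(_genes_to_scalings(genes, gene_names)))
        return cache[key]

    return evaluate


def run_ga(objective: Objective, config: GAConfig,
           variant="endocardial", seed: Optional[int] = None) -> GAResult:
    """One GA run; deterministic for a given seed.

    ``objective`` is either an :class:`ObjectiveSpec` (evaluated by paced
    simulation) or any callable mapping :class:`ScalingFactors` to an error —
    the hook used by surrogate objectives in tests and parameter-recovery
    studies.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    lo, hi = config.log_bounds
    n_pop, n_genes = config.population_size, len(config.free_genes)
    cache: dict = {}
    evaluate = _make_evaluator(objective, config, variant, cache)

    pop = rng.uniform(lo, hi, size=(n_pop, n_genes))
    best_genes, best_error = None, math.inf
    history: List[dict] = []
    for generation in range(config.generations):
        errors = np.array([evaluate(ind) for ind in pop])
        order = np.argsort(errors, kind="stable")
        if errors[order[0]] < best_error:
            best_error = float(errors[order[0]])
            best_genes = pop[order[0]].copy()
        finite = errors[np.isfinite(errors)]
        history.append({
            "generation": generation,
            "best_error": best_error,
            "mean_error": float(finite.mean()) if len(finite) else math.inf,
        })
        if generation == config.generations - 1:
            break
        # tournament selection
        parents = np.empty_like(pop)
        for i in range(n_pop):
            contenders = rng.integers(0, n_pop, size=config.tournament_size)
            winner = contenders[np.argmin(errors[contenders])]
            parents[i] = pop[winner]
        # two-point crossover on consecutive pairs
        children = parents.copy()
        for i in range(0, n_pop - 1, 2):
            if rng.random() < config.crossover_prob:
                c1, c2 = sorted(rng.integers(0, n_genes + 1, size=2))
                if c1 != c2:
                    seg = children[i, c1:c2].copy()
                    children[i, c1:c2] = children[i + 1, c1:c2]
                    children[i + 1, c1:c2] = seg
        # per-gene Gaussian mutation
        mutate = rng.random(children.shape) < config.mutation_prob
        children = children + mutate * rng.normal(0.0, config.mutation_sigma, children.shape)
        np.clip(children, lo, hi, out=children)
        # elitism: best-ever individual survives unchanged
        for e in range(min(config.elitism, n_pop)):
            children[e] = best_genes
        pop = children

    return GAResult(
        best=_genes_to_scalings(best_genes, config.free_genes), best_error=best_error,
        history=pd.DataFrame(history), seed=seed,
    )


def multi_run(objective: Objective, config: GAConfig,
              variant="endocardial") -> Tuple[GAResult, List[GAResult]]:
    """Best-of-``n_runs`` protocol with seeds ``seed, seed+1, ...``.

    Returns (winning run, all runs); ties go to the lowest run index.
    """
    runs = [run_ga(objective, config, variant=variant, seed=config.seed + k)
            for k in range(config.n_runs)]
    best = min(runs, key=lambda r: r.best_error)  # min() keeps the first of ties
    return best, runs
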