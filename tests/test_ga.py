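"""Objective construction and genetic-algorithm behaviour.

Simulation-dependent objective arithmetic is unit-tested against a stubbed
biomarker oracle; search behaviour is tested on surrogate (simulation-free)
objectives with fixed seeds.
"""

import numpy as np
import pytest

import lqtsim.ga as ga
from lqtsim.biomarkers import Biomarkers
from lqtsim.ga import (
    DEFAULT_APD_TARGETS, GAConfig, ObjectiveSpec, multi_run, objective_error, run_ga,
)
from lqtsim.model import ScalingFactors
from lqtsim.synthetic import synth_objective

TRUTH = ScalingFactors(ks=2.0, kr=0.7, cal=1.5, ncx=0.9, nak=1.2, nal=2.5, nal_lqt3=4.0)


@pytest.fixture()
def stub_simulation(monkeypatch):
    """Replace pace/measure inside the GA module with a condition-keyed oracle.

    The stub recognises the objective condition from the transformed scalings
    of an all-ones candidate (with nal_lqt3=2): LQT1 halves ks, LQT2 halves
    kr, LQT3 doubles nal.  Tests mutate ``table`` to inject deviations.
    """
    table = {
        "control": Biomarkers(apd90=DEFAULT_APD_TARGETS["control"], apd50=200.0,
                              ca_dia=0.10, ca_sys=0.50, na_max=8.0),
        "LQT1": Biomarkers(apd90=DEFAULT_APD_TARGETS["LQT1"], apd50=220.0,
                           ca_dia=0.10, ca_sys=0.50, na_max=8.0),
        "LQT2": Biomarkers(apd90=DEFAULT_APD_TARGETS["LQT2"], apd50=230.0,
                           ca_dia=0.10, ca_sys=0.50, na_max=8.0),
        "LQT3": Biomarkers(apd90=DEFAULT_APD_TARGETS["LQT3"], apd50=230.0,
                           ca_dia=0.10, ca_sys=0.50, na_max=8.0),
    }

    class FakeTrace:
        v = np.array([-87.0])

        def __init__(self, scalings):
            self.scalings = scalings

        def beat_mask(self, k):
            return np.array([True])

    def fake_pace(variant, scalings, protocol, start_state=None):
        return FakeTrace(scalings)

    def fake_measure(trace):
        scalings = trace.scalings
        if scalings.ks == 0.5:
            return table["LQT1"]
        if scalings.kr == 0.5:
            return table["LQT2"]
        if scalings.nal == 2.0:
            return table["LQT3"]
        return table["control"]

    monkeypatch.setattr(ga, "pace", fake_pace)
    monkeypatch.setattr(ga, "measure", fake_measure)
    return table


CANDIDATE = ScalingFactors(nal_lqt3=2.0)


class TestObjectiveError:
    def test_exact_targets_give_zero(self, stub_simulation):
        assert objective_error(CANDIDATE, ObjectiveSpec()) == 0.0

    def test_three_ms_miss_on_one_condition_gives_nine(self, stub_simulation):
        stub_simulation["LQT2"] = Biomarkers(
            apd90=DEFAULT_APD_TARGETS["LQT2"] + 3.0, apd50=230.0,
            ca_dia=0.10, ca_sys=0.50, na_max=8.0)
        assert objective_error(CANDIDATE, ObjectiveSpec()) == pytest.approx(9.0)

    def test_sodium_out_of_range_adds_the_200ms2_penalty(self, stub_simulation):
        stub_simulation["LQT2"] = Biomarkers(
            apd90=DEFAULT_APD_TARGETS["LQT2"] + 3.0, apd50=230.0,
            ca_dia=0.10, ca_sys=0.50, na_max=8.0)
        stub_simulation["control"] = Biomarkers(
            apd90=DEFAULT_APD_TARGETS["control"], apd50=200.0,
            ca_dia=0.10, ca_sys=0.50, na_max=11.0)
        assert objective_error(CANDIDATE, ObjectiveSpec()) == pytest.approx(209.0)

    def test_constraints_disabled_reproduces_apd_only_objective(self, stub_simulation):
        stub_simulation["control"] = Biomarkers(
            apd90=DEFAULT_APD_TARGETS["control"], apd50=200.0,
            ca_dia=0.30, ca_sys=1.50, na_max=11.0)  # three violations
        spec_on = ObjectiveSpec()
        spec_off = ObjectiveSpec(constraints_enabled=False)
        assert objective_error(CANDIDATE, spec_on) == pytest.approx(600.0)
        assert objective_error(CANDIDATE, spec_off) == 0.0

    def test_single_penalty_mode(self, stub_simulation):
        stub_simulation["control"] = Biomarkers(
            apd90=DEFAULT_APD_TARGETS["control"], apd50=200.0,
            ca_dia=0.30, ca_sys=1.50, na_max=11.0)
        spec = ObjectiveSpec(penalty_per_violation=False)
        assert objective_error(CANDIDATE, spec) == pytest.approx(200.0)

    def test_simulation_failure_folded_into_finite_sentinel(self, monkeypatch):
        def broken_pace(*args, **kwargs):
            raise ga.SimulationError("boom", beat=3)
        monkeypatch.setattr(ga, "pace", broken_pace)
        error = objective_error(CANDIDATE, ObjectiveSpec())
        assert np.isfinite(error) and error >= 4 * ga.FAILURE_ERROR


class TestRunGa:
    def test_surrogate_recovery_within_20_percent(self):
        objective = synth_objective(TRUTH, surrogate=True)
        result = run_ga(objective, GAConfig(population_size=50, generations=40,
                                            n_runs=1, seed=1))
        for gene in ga.GENE_NAMES:
            truth, got = getattr(TRUTH, gene), getattr(result.best, gene)
            assert abs(got - truth) / truth < 0.20, gene

    def test_elitism_makes_best_error_non_increasing(self):
        objective = synth_objective(TRUTH, surrogate=True)
        result = run_ga(objective, GAConfig(population_size=20, generations=15,
                                            n_runs=1, seed=3))
        assert (np.diff(result.history["best_error"]) <= 1e-12).all()

    def test_same_seed_same_history(self):
        objective = synth_objective(TRUTH, surrogate=True)
        config = GAConfig(population_size=20, generations=10, n_runs=1, seed=7)
        assert run_ga(objective, config).history.equals(run_ga(objective, config).history)

    def test_free_genes_restricts_the_genome(self):
        objective = synth_objective(ScalingFactors(kr=0.8), surrogate=True)
        result = run_ga(objective, GAConfig(population_size=20, generations=15,
                                            n_runs=1, seed=2, free_genes=("kr",)))
        assert result.best.kr == pytest.approx(0.8, rel=0.2)
        assert result.best.ks == 1.0 and result.best.nal_lqt3 == 1.0


class TestMultiRun:
    def test_single_run_equals_run_ga(self):
        objective = synth_objective(TRUTH, surrogate=True)
        config = GAConfig(population_size=20, generations=8, n_runs=1, seed=5)
        best, runs = multi_run(objective, config)
        assert len(runs) == 1
        assert best.best_error == run_ga(objective, config, seed=5).best_error

    def test_best_of_three_is_min_over_consecutive_seeds(self):
        objective = synth_objective(TRUTH, surrogate=True)
        config = GAConfig(population_size=16, generations=8, n_runs=3, seed=11)
        best, runs = multi_run(objective, config)
        assert [r.seed for r in runs] == [11, 12, 13]
        assert best.best_error == min(r.best_error for r in runs)
        assert all(best.best_error <= r.best_error for r in runs)


class TestClosedLoopRecovery:
    def test_kr_recovered_from_simulated_apd_target(self):
        """Closed loop at reduced scale: the GA recovers a perturbed G_Kr
        scaling from the APD90 it produces (high-sensitivity parameter)."""
        truth = ScalingFactors(kr=0.8)
        spec = synth_objective(truth, surrogate=False, n_beats=20,
                               conditions=("control",))
        config = GAConfig(population_size=16, generations=20, n_runs=1, seed=4,
                          fast_beats=20, free_genes=("kr",))
        result = run_ga(spec, config)
        assert result.best.kr == pytest.approx(0.8, rel=0.20)
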