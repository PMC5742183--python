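"""Decision-boundary fitting against independent geometric oracles."""

import math

import numpy as np
import pytest

from lqtsim.biomarkers import Biomarkers
from lqtsim.classifier import (
    DecisionBoundary, NormalizedPoint, acceptable_region, boundary_error,
    classify, confusion_counts, fit_boundary, normalize,
)
from lqtsim.synthetic import synth_separable_points


def _bm(apd50, ca_dia):
    return Biomarkers(apd90=apd50 + 50.0, apd50=apd50, ca_dia=ca_dia,
                      ca_sys=ca_dia + 0.3, na_max=8.0)


def _pt(x, y, label, name=""):
    return NormalizedPoint(x=x, y=y, label=label, drug_name=name)


class TestNormalize:
    def test_baseline_maps_to_unity(self):
        base = _bm(220.0, 0.10)
        point = normalize(base, base, label=False)
        assert (point.x, point.y) == (1.0, 1.0)

    def test_apd50_doubling(self):
        assert normalize(_bm(440.0, 0.10), _bm(220.0, 0.10), True).x == pytest.approx(2.0)

    def test_five_percent_prolongation(self):
        assert normalize(_bm(231.0, 0.10), _bm(220.0, 0.10), True).x == pytest.approx(1.05)


class TestBoundaryError:
    def test_separating_line_scores_zero(self):
        points = [_pt(1.2, 1.0, True), _pt(1.3, 0.9, True), _pt(0.9, 1.0, False)]
        boundary = DecisionBoundary(normal=(1.0, 0.0), offset=1.05, error=0.0)
        assert boundary_error(boundary, points) == 0.0

    def test_single_miscategorized_point_at_distance(self):
        boundary = DecisionBoundary(normal=(1.0, 0.0), offset=1.0, error=0.0)
        assert boundary_error(boundary, [_pt(0.8, 1.0, True)]) == pytest.approx(0.04)

    def test_empty_point_set_scores_zero(self):
        boundary = DecisionBoundary(normal=(0.0, 1.0), offset=1.0, error=0.0)
        assert boundary_error(boundary, []) == 0.0

    def test_mixed_set_matches_per_point_oracle(self):
        rng = np.random.default_rng(0)
        points = [_pt(x, y, bool(l)) for x, y, l in
                  zip(rng.uniform(0.5, 1.5, 8), rng.uniform(0.5, 1.5, 8),
                      [1, 1, 1, 0, 0, 1, 0, 0])]
        theta = 0.7
        boundary = DecisionBoundary(normal=(math.cos(theta), math.sin(theta)),
                                    offset=1.4, error=0.0)
        expected = 0.0
        for p in points:
            s = p.x * math.cos(theta) + p.y * math.sin(theta) - 1.4
            wrong = (p.label and s <= 0) or (not p.label and s > 0)
            if wrong:
                expected += s ** 2
        assert boundary_error(boundary, points) == pytest.approx(expected, rel=1e-12)

    def test_reflection_with_label_swap_preserves_E(self):
        rng = np.random.default_rng(1)
        points = [_pt(x, y, bool(l)) for x, y, l in
                  zip(rng.uniform(0.5, 1.5, 10), rng.uniform(0.5, 1.5, 10),
                      rng.integers(0, 2, 10))]
        boundary = DecisionBoundary(normal=(0.6, 0.8), offset=1.2, error=0.0)
        flipped = DecisionBoundary(normal=(-0.6, -0.8), offset=-1.2, error=0.0)
        swapped = [_pt(p.x, p.y, not p.label) for p in points]
        assert boundary_error(boundary, points) == pytest.approx(
            boundary_error(flipped, swapped), rel=1e-12)


class TestFitBoundary:
    def test_separable_set_reaches_zero_and_recovers_angle(self):
        fixture = synth_separable_points(30, seed=3, margin=0.5)
        boundary = fit_boundary(fixture.points)
        assert boundary.error == 0.0
        angle_diff = abs(((boundary.angle - fixture.true_angle + math.pi / 2)
                          % math.pi) - math.pi / 2)
        assert math.degrees(angle_diff) < 5.0

    def test_two_points_one_per_label(self):
        fixture = synth_separable_points(2, seed=9, margin=0.5)
        assert fit_boundary(fixture.points).error == 0.0

    def test_matches_brute_force_oracle_on_overlapping_set(self, brute_force_min_E):
        fixture = synth_separable_points(10, seed=5, margin=0.0, spread=0.25)
        boundary = fit_boundary(fixture.points)
        assert boundary.error > 0  # genuinely inseparable draw
        assert boundary.error == pytest.approx(brute_force_min_E(fixture.points), abs=1e-6)

    def test_duplicated_points_double_E_same_boundary(self):
        fixture = synth_separable_points(12, seed=7, margin=0.0, spread=0.3)
        b1 = fit_boundary(fixture.points)
        b2 = fit_boundary(fixture.points + fixture.points)
        assert b2.error == pytest.approx(2.0 * b1.error, rel=1e-4)

    def test_beats_1000_random_lines(self):
        fixture = synth_separable_points(15, seed=11, margin=0.0, spread=0.3)
        fitted = fit_boundary(fixture.points)
        rng = np.random.default_rng(2)
        for theta, offset in zip(rng.uniform(0, 2 * math.pi, 1000),
                                 rng.uniform(-1.0, 3.5, 1000)):
            candidate = DecisionBoundary(normal=(math.cos(theta), math.sin(theta)),
                                         offset=offset, error=0.0)
            assert fitted.error <= boundary_error(candidate, fixture.points) + 1e-12

    def test_single_label_input_rejected(self):
        with pytest.raises(ValueError):
            fit_boundary([_pt(1.1, 1.0, True), _pt(1.2, 1.0, True)])


class TestClassifyAndConfusion:
    def test_side_conventions(self):
        boundary = DecisionBoundary(normal=(1.0, 0.0), offset=1.0, error=0.0)
        assert classify(boundary, _pt(1.5, 1.0, True)) is True
        assert classify(boundary, _pt(1.0, 1.0, True)) is False  # on the line
        assert classify(boundary, _pt(0.5, 1.0, True)) is False

    def test_fitted_separable_set_classifies_all_training_points(self):
        fixture = synth_separable_points(20, seed=13, margin=0.4)
        boundary = fit_boundary(fixture.points)
        counts = confusion_counts(boundary, fixture.points)
        assert counts["FP"] == counts["FN"] == 0
        assert sum(counts.values()) == len(fixture.points)


class TestAcceptableRegion:
    def test_threshold_below_global_minimum_gives_empty_region(self):
        fixture = synth_separable_points(14, seed=5, margin=0.0, spread=0.25)
        min_e = fit_boundary(fixture.points).error
        region = acceptable_region(fixture.points, e_star=min_e * 0.5)
        assert region.is_empty

    def test_infinite_threshold_accepts_every_sample(self):
        fixture = synth_separable_points(10, seed=5, margin=0.0, spread=0.25)
        region = acceptable_region(fixture.points, e_star=math.inf,
                                   theta_steps=36, offset_steps=40)
        assert region.fraction == 1.0

    def test_region_contains_the_fitted_optimum(self):
        fixture = synth_separable_points(20, seed=3, margin=0.4)
        region = acceptable_region(fixture.points, e_star=0.05)
        assert not region.is_empty
        assert np.all(region.samples[:, 2] < 0.05)
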