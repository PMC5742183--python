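"""Hill block, LQT conditions, drug-table I/O and sweep plumbing."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from lqtsim import ScalingFactors
from lqtsim.perturbations import (
    DrugRecord, DrugTableError, LQTSubtype, apply_drug, hill_scale,
    lqt_variant, read_drug_table, sensitivity_sweep, write_drug_table,
)
from lqtsim.pipeline import VERAPAMIL


class TestHillScale:
    def test_midpoint(self):
        assert hill_scale(1.0, 1.0) == pytest.approx(0.5)

    def test_ninefold_excess(self):
        assert hill_scale(9.0, 1.0) == pytest.approx(0.1)

    def test_absent_ic50_means_no_block(self):
        assert hill_scale(5.0, None) == 1.0

    @pytest.mark.parametrize("eftpc,ic50", [(-1.0, 1.0), (0.0, 1.0), (1.0, 0.0), (1.0, -2.0)])
    def test_domain_errors(self, eftpc, ic50):
        with pytest.raises(ValueError):
            hill_scale(eftpc, ic50)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(eftpc=st.floats(1e-6, 1e6), ic50=st.floats(1e-6, 1e6), shrink=st.floats(1.01, 10.0))
    def test_monotone_and_bounded(self, eftpc, ic50, shrink):
        s = hill_scale(eftpc, ic50)
        assert 0.0 < s <= 1.0
        assert hill_scale(eftpc * shrink, ic50) < s       # decreasing in dose
        assert hill_scale(eftpc, ic50 * shrink) > s       # increasing in potency


class TestApplyDrug:
    def test_no_block_drug_leaves_scalings_unchanged(self):
        drug = DrugRecord("inert", "test", 1.0, None, None, None, False)
        assert apply_drug(ScalingFactors(), drug) == ScalingFactors()

    def test_kr_halved_at_its_ic50(self):
        drug = DrugRecord("herg", "test", 2.0, 2.0, None, None, True)
        out = apply_drug(ScalingFactors(), drug)
        assert out.kr == pytest.approx(0.5)
        assert (out.cal, out.na, out.ks) == (1.0, 1.0, 1.0)

    def test_verapamil_block_fractions(self):
        out = apply_drug(ScalingFactors(), VERAPAMIL)
        assert out.kr == pytest.approx(0.64, abs=0.005)
        assert out.cal == pytest.approx(0.55, abs=0.005)
        assert out.na == pytest.approx(0.998, abs=0.0005)

    def test_commutes_with_lqt_variant(self):
        base = ScalingFactors(ks=2.0, nal=1.5, nal_lqt3=3.0)
        for subtype in LQTSubtype:
            a = apply_drug(lqt_variant(base, subtype), VERAPAMIL)
            b = lqt_variant(apply_drug(base, VERAPAMIL), subtype)
            assert a == b


class TestLqtVariant:
    def test_lqt1_halves_ks(self):
        assert lqt_variant(ScalingFactors(), LQTSubtype.LQT1).ks == 0.5

    def test_lqt2_halves_kr(self):
        assert lqt_variant(ScalingFactors(), LQTSubtype.LQT2).kr == 0.5

    def test_lqt3_composes_nal_with_its_dedicated_factor(self, multivar):
        out = lqt_variant(multivar, LQTSubtype.LQT3)
        assert out.nal == pytest.approx(1.70 * 4.17)
        assert out.ks == multivar.ks and out.kr == multivar.kr


class TestDrugTableIO:
    def _write(self, path, body):
        path.write_text("drug_name,source,eftpc,ic50_kr,ic50_cal,ic50_na,tdp_label\n" + body)
        return path

    def test_well_formed_rows(self, tmp_path):
        path = self._write(tmp_path / "t.csv",
                           "a,s1,1.0,2.0,3.0,4.0,true\n"
                           "b,s1,0.5,,1.0,,false\n"
                           "a,s2,1.0,2.5,3.5,4.5,true\n")
        records = read_drug_table(path)
        assert len(records) == 3
        assert records[1].ic50_kr is None and records[1].ic50_na is None
        assert records[0].tdp_label and not records[1].tdp_label

    def test_bad_rows_collected_per_row(self, tmp_path):
        path = self._write(tmp_path / "t.csv",
                           "a,s1,-1.0,2.0,3.0,4.0,true\n"
                           "b,s1,,2.0,3.0,4.0,false\n"
                           "c,s1,1.0,2.0,3.0,4.0,maybe\n")
        with pytest.raises(DrugTableError) as err:
            read_drug_table(path)
        assert len(err.value.errors) == 3

    def test_round_trip(self, tmp_path):
        records = [
            DrugRecord("a", "s1", 1.0, 2.0, None, 4.0, True),
            DrugRecord("b", "s2", 0.25, None, 1.5, None, False),
        ]
        path = tmp_path / "t.csv"
        write_drug_table(records, path)
        assert read_drug_table(path) == records


class TestSensitivitySweep:
    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_sweep("endocardial", "gna", [-0.5])

    def test_table_shape(self):
        from lqtsim.pacing import PacingProtocol
        table = sensitivity_sweep("endocardial", "kr", [-0.2, 0.2],
                                  protocol=PacingProtocol(n_beats=2, record_last=1))
        assert list(table["delta"]) == [-0.2, 0.2]
        assert {"apd90_ms", "ca_dia_uM", "na_max_mM"} <= set(table.columns)
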