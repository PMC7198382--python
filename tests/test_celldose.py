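import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrtkit.celldose import (
    CellGeometry,
    CompartmentTimecourse,
    MEV_TO_J,
    compute_svalue,
    compute_svalue_set,
    electron_range,
    energy_from_range,
    nucleus_dose,
    suspension_cross_dose,
)
from mrtkit.nuclides import NuclideData

from oracles import svalue_quadrature


def _dummy_zero_nuclide():
    return NuclideData(
        "null", 10.0,
        pd.DataFrame(columns=["energy_MeV", "density_per_MeV"]),
        pd.DataFrame({"energy_MeV": [0.1], "yield": [0.0]}),
        pd.DataFrame(columns=["energy_keV", "yield"]))


class TestElectronRange:
    def test_half_mev(self):
        assert electron_range(0.5) == pytest.approx(1.8e3, rel=0.05)

    def test_ten_kev(self):
        assert electron_range(0.01) == pytest.approx(2.5, rel=0.05)

    def test_monotone(self):
        assert electron_range(0.2) < electron_range(0.4)

    @given(st.floats(min_value=0.002, max_value=1.9))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing(self, e):
        assert electron_range(e * 1.05) > electron_range(e)

    def test_nonpositive_energy_rejected(self):
        with pytest.raises(ValueError):
            electron_range(0.0)
        with pytest.raises(ValueError):
            electron_range(-0.1)

    def test_inverse_roundtrip(self):
        e = np.array([0.01, 0.05, 0.134, 0.4, 1.0])
        back = energy_from_range(electron_range(e))
        np.testing.assert_allclose(back, e, rtol=1e-6)

    def test_density_scaling(self):
        assert electron_range(0.1, density_g_cm3=2.0) == pytest.approx(
            electron_range(0.1) / 2.0)


class TestGeometry:
    def test_invalid_radii(self):
        with pytest.raises(ValueError):
            CellGeometry(r_nucleus_um=10, r_cell_um=5)

    def test_masses(self):
        g = CellGeometry(r_nucleus_um=5, r_cell_um=10, density_g_cm3=1.0)
        m_n = 4 / 3 * np.pi * 125e-18 * 1e3
        assert g.mass_kg("nucleus") == pytest.approx(m_n)
        assert g.mass_kg("cytoplasm") == pytest.approx(7 * m_n)


class TestSValue:
    def test_full_absorption_limit(self, lu177):
        # nucleus huge vs electron range: everything stops inside -> af ~ 1
        g = CellGeometry(r_nucleus_um=5e4, r_cell_um=1e5)
        sv = compute_svalue(g, "nucleus", lu177, 50_000, 1)
        assert sv.absorbed_fraction == pytest.approx(1.0, rel=0.02)
        expected = lu177.mean_electron_energy_MeV * MEV_TO_J / g.mass_kg("nucleus")
        assert sv.s_gy_per_bq_s == pytest.approx(expected, rel=0.02)

    def test_zero_yield_nuclide(self):
        sv = compute_svalue(CellGeometry(), "nucleus", _dummy_zero_nuclide(),
                            10_000, 0)
        assert sv.s_gy_per_bq_s == 0.0

    def test_against_quadrature_oracle_default_geometry(self, lu177, csda_table):
        sv = compute_svalue(CellGeometry(), "cytoplasm", lu177, 200_000, 11)
        oracle = svalue_quadrature(5, 10, "cytoplasm", lu177, csda_table)
        assert abs(sv.s_gy_per_bq_s - oracle) < 3 * sv.stderr

    @pytest.mark.parametrize("seed", range(5))
    def test_against_oracle_random_geometries(self, lu177, csda_table, seed):
        rng = np.random.default_rng(100 + seed)
        r_n = rng.uniform(2.0, 6.0)
        r_c = r_n + rng.uniform(2.0, 6.0)
        source = ["nucleus", "cytoplasm", "membrane"][seed % 3]
        g = CellGeometry(r_nucleus_um=r_n, r_cell_um=r_c)
        sv = compute_svalue(g, source, lu177, 200_000, seed)
        oracle = svalue_quadrature(r_n, r_c, source, lu177, csda_table)
        assert abs(sv.s_gy_per_bq_s - oracle) < 3 * sv.stderr + 0.002 * oracle

    def test_source_distance_monotonicity(self, lu177):
        s = compute_svalue_set(CellGeometry(), lu177, 100_000, 3)
        tol = 3 * max(v.stderr for v in s.values.values())
        assert s["nucleus"].s_gy_per_bq_s >= s["cytoplasm"].s_gy_per_bq_s - tol
        assert s["cytoplasm"].s_gy_per_bq_s >= s["membrane"].s_gy_per_bq_s - tol

    def test_absorbed_fraction_bounds(self, lu177):
        for src in ("nucleus", "cytoplasm", "membrane"):
            sv = compute_svalue(CellGeometry(), src, lu177, 50_000, 4)
            assert 0.0 <= sv.absorbed_fraction <= 1.0

    def test_reciprocity_approximate(self, lu177):
        g = CellGeometry()
        s_ncy = compute_svalue(g, "cytoplasm", lu177, 300_000, 5, target="nucleus")
        s_cyn = compute_svalue(g, "nucleus", lu177, 300_000, 6, target="cytoplasm")
        lhs = g.mass_kg("nucleus") * s_ncy.s_gy_per_bq_s
        rhs = g.mass_kg("cytoplasm") * s_cyn.s_gy_per_bq_s
        assert lhs == pytest.approx(rhs, rel=0.05)

    def test_seed_reproducibility(self, lu177):
        a = compute_svalue(CellGeometry(), "membrane", lu177, 20_000, 9)
        b = compute_svalue(CellGeometry(), "membrane", lu177, 20_000, 9)
        assert a.s_gy_per_bq_s == b.s_gy_per_bq_s
        assert a.stderr == b.stderr

    def test_bad_inputs(self, lu177):
        with pytest.raises(ValueError, match="unknown compartment"):
            compute_svalue(CellGeometry(), "mitochondria", lu177, 10_000, 0)
        with pytest.raises(ValueError, match="n_histories"):
            compute_svalue(CellGeometry(), "nucleus", lu177, 100, 0)


def _tc(times, mem, cyt, nuc, med, density=1e6):
    return CompartmentTimecourse(
        times_h=times, membrane_Bq=mem, cytoplasm_Bq=cyt, nucleus_Bq=nuc,
        medium_Bq_per_mL=med, cell_density_per_mL=density)


class TestCrossDose:
    def test_zero_activity(self, lu177):
        tc = _tc([0, 2], [0, 0], [0, 0], [0, 0], [0, 0])
        assert suspension_cross_dose(tc, lu177, 2.0) == 0.0

    def test_constant_medium_closed_form(self, lu177):
        tc = _tc([0, 2], [0, 0], [0, 0], [0, 0], [1e6, 1e6])
        dose = suspension_cross_dose(tc, lu177, 2.0)
        expected = (1e6 * 7200) * lu177.mean_electron_energy_MeV * MEV_TO_J / 1e-3
        assert dose == pytest.approx(expected, rel=1e-9)

    def test_linearity(self, lu177):
        tc1 = _tc([0, 2], [0, 0], [0, 0], [0, 0], [1e6, 1e6])
        tc2 = _tc([0, 2], [0, 0], [0, 0], [0, 0], [2e6, 2e6])
        assert suspension_cross_dose(tc2, lu177, 2.0) == pytest.approx(
            2 * suspension_cross_dose(tc1, lu177, 2.0))

    def test_negative_activity_rejected(self):
        with pytest.raises(ValueError):
            _tc([0, 2], [0, -1], [0, 0], [0, 0], [0, 0])


class TestNucleusDose:
    def test_all_zero(self, lu177):
        tc = _tc([0, 2], [0, 0], [0, 0], [0, 0], [0, 0])
        s = compute_svalue_set(CellGeometry(), lu177, 20_000, 1)
        assert nucleus_dose(tc, s, lu177, 2.0).total == 0.0

    def test_additivity(self, lu177):
        s = compute_svalue_set(CellGeometry(), lu177, 20_000, 1)
        tm = _tc([0, 2], [1, 1], [0, 0], [0, 0], [0, 0], density=0)
        tc_ = _tc([0, 2], [0, 0], [1, 1], [0, 0], [0, 0], density=0)
        both = _tc([0, 2], [1, 1], [1, 1], [0, 0], [0, 0], density=0)
        d = nucleus_dose(both, s, lu177, 2.0).total
        assert d == pytest.approx(nucleus_dose(tm, s, lu177, 2.0).total
                                  + nucleus_dose(tc_, s, lu177, 2.0).total)

    def test_membrane_dominant_distribution_hand_computed(self, lu177):
        # membrane-dominant split: cytoplasm 13%, nucleus 0.1% of cell-bound
        s = compute_svalue_set(CellGeometry(), lu177, 50_000, 2)
        total = 0.057  # Bq/cell
        mem, cyt, nuc = total * 0.869, total * 0.13, total * 0.001
        tc = _tc([0.0, 2.0], [mem, mem], [cyt, cyt], [nuc, nuc], [0, 0], density=0)
        d = nucleus_dose(tc, s, lu177, 2.0)
        # constant activity: cumulated = A * 7200 s
        for src, a in (("membrane", mem), ("cytoplasm", cyt), ("nucleus", nuc)):
            expected = a * 7200 * s[src].s_gy_per_bq_s
            assert getattr(d, src if src != "membrane" else "membrane") == \
                pytest.approx(expected, rel=1e-9)
        # membrane + cross dominate over the nuclear self term
        assert d.membrane + d.cross > 10 * d.nucleus

    def test_decay_tail_beyond_last_sample(self, lu177):
        s = compute_svalue_set(CellGeometry(), lu177, 20_000, 3)
        tc = _tc([0.0, 2.0], [1.0, 1.0], [0, 0], [0, 0], [0, 0], density=0)
        d_short = nucleus_dose(tc, s, lu177, 2.0).total
        d_long = nucleus_dose(tc, s, lu177, 1000.0).total
        lam = lu177.decay_constant_per_h
        expected_tail = (1.0 / lam) * (1 - np.exp(-lam * 998.0)) * 3600 \
            * s["membrane"].s_gy_per_bq_s
        assert d_long - d_short == pytest.approx(expected_tail, rel=1e-6)

    def test_missing_compartment_rejected(self, lu177):
        s = compute_svalue_set(CellGeometry(), lu177, 20_000, 1)
        del s.values["cytoplasm"]
        tc = _tc([0, 2], [1, 1], [0, 0], [0, 0], [0, 0])
        with pytest.raises(ValueError, match="lacks compartments"):
            nucleus_dose(tc, s, lu177, 2.0)


class TestTimecourseIO:
    def test_csv_roundtrip(self, tmp_path):
        tc = _tc([0.0, 1.0, 2.0], [1, 2, 3], [0.1, 0.2, 0.3],
                 [0.0, 0.001, 0.002], [5e5, 4e5, 3e5])
        path = tmp_path / "tc.csv"
        tc.to_csv(path)
        back = CompartmentTimecourse.from_csv(path)
        np.testing.assert_allclose(back.membrane_Bq, tc.membrane_Bq)
        np.testing.assert_allclose(back.medium_Bq_per_mL, tc.medium_Bq_per_mL)

    def test_nonincreasing_times_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            _tc([0, 0], [0, 0], [0, 0], [0, 0], [0, 0])
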