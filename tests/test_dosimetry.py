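import numpy as np
import pytest

from planardose import (
    CompartmentKinetics,
    CumulatedActivitySet,
    bm_cumulated_from_low,
    bm_dose,
    bm_self_dose_concentration,
    dose_table,
    load_sfactor_table,
    mird_dose,
)
from planardose.dosimetry import (
    DoseConfig,
    PhantomMasses,
    SFactorLookupError,
    SFactorTable,
)

SF_CSV = """phantom,source_region,target_region,S_mGy_per_MBq_h
M,red_marrow,red_marrow,0.1
M,high,red_marrow,0.002
M,low,red_marrow,0.001
"""


class TestSFactorTable:
    def test_load_round_trip(self, tmp_path):
        p = tmp_path / "sf.csv"
        p.write_text(SF_CSV)
        table = load_sfactor_table(p)
        assert len(table.entries) == 3
        assert table.s("red_marrow", "high") == pytest.approx(0.002)

    def test_duplicate_pair_rejected(self, tmp_path):
        p = tmp_path / "sf.csv"
        p.write_text(SF_CSV + "M,low,red_marrow,0.005\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_sfactor_table(p)

    def test_missing_pair_is_explicit_error(self, sfactors):
        with pytest.raises(SFactorLookupError):
            sfactors.s("red_marrow", "liver")

    def test_negative_s_rejected(self, tmp_path):
        p = tmp_path / "sf.csv"
        p.write_text("phantom,source_region,target_region,S_mGy_per_MBq_h\nM,a,b,-1\n")
        with pytest.raises(ValueError):
            load_sfactor_table(p)

    def test_unit_column_conversion(self, tmp_path):
        p = tmp_path / "sf.csv"
        p.write_text(
            "phantom,source_region,target_region,S_mGy_per_MBq_h,unit\n"
            "M,a,b,0.0005,Gy_per_MBq_h\n"
        )
        assert load_sfactor_table(p).s("b", "a") == pytest.approx(0.5)


class TestMirdDose:
    def test_unit_conversion_single_source(self, sfactors):
        assert mird_dose({"red_marrow": 1.0}, sfactors, "red_marrow") == pytest.approx(1e-4)

    def test_zero_activities(self, sfactors):
        assert mird_dose({"high": 0.0, "low": 0.0}, sfactors, "red_marrow") == 0.0

    def test_hand_summed_two_sources(self):
        table = SFactorTable(phantom="M", entries={("a", "t"): 2.0, ("b", "t"): 4.0})
        # 10*2 + 5*4 = 40 mGy = 0.040 Gy
        assert mird_dose({"a": 10.0, "b": 5.0}, table, "t") == pytest.approx(0.040)


class TestBmCumulatedFromLow:
    def test_kappa_zero(self, masses):
        assert bm_cumulated_from_low(100.0, 0.0, masses) == 0.0

    def test_identity_when_masses_equal(self):
        m = PhantomMasses(m_BM_g=500.0, m_body_g=1000.0, m_low_g=500.0)
        assert bm_cumulated_from_low(42.0, 1.0, m) == pytest.approx(42.0)

    def test_proportionality(self):
        m = PhantomMasses(m_BM_g=1200.0, m_body_g=70000.0, m_low_g=60000.0)
        assert bm_cumulated_from_low(1000.0, 1.0, m) == pytest.approx(20.0)


class TestConcentrationSelfDose:
    def test_zero_concentration(self):
        assert bm_self_dose_concentration(0.0) == 0.0

    def test_reference_value(self):
        """1 MBq·h/g at 147 keV, φ=1: 3.6e9 decays × 2.355e-14 J over 1e-3 kg."""
        expected = 1e6 * 3600 * 147e3 * 1.602e-19 / 1e-3
        assert bm_self_dose_concentration(1.0, 1.0, 147.0) == pytest.approx(expected)
        assert bm_self_dose_concentration(1.0, 1.0, 147.0) == pytest.approx(0.0848, abs=2e-4)

    def test_phi_linearity(self):
        full = bm_self_dose_concentration(2.0, 1.0, 147.0)
        assert bm_self_dose_concentration(2.0, 0.5, 147.0) == pytest.approx(full / 2)


class TestBmDose:
    def test_components_sum_to_total(self, sfactors, masses):
        cum = CumulatedActivitySet(A_tilde_high=500.0, A_tilde_low=2000.0)
        rep = bm_dose(cum, sfactors, masses)
        assert rep.D_BM_total_Gy == pytest.approx(sum(rep.components.values()), rel=1e-12)

    def test_lesion_term_vanishes_at_zero(self, sfactors, masses):
        cum0 = CumulatedActivitySet(A_tilde_high=500.0, A_tilde_low=2000.0, A_tilde_SL=0.0)
        rep0 = bm_dose(cum0, sfactors, masses)
        assert "from_SL" not in rep0.components
        cum1 = CumulatedActivitySet(A_tilde_high=500.0, A_tilde_low=2000.0, A_tilde_SL=10.0)
        rep1 = bm_dose(cum1, sfactors, masses)
        assert rep1.components["from_SL"] > 0
        for key in ("self", "from_high", "from_low"):
            assert rep1.components[key] == pytest.approx(rep0.components[key])

    def test_uniform_s_table_factorizes(self, masses):
        """With all S equal and the S-matrix self-dose path, the total is
        S·(Ã_BM+Ã_high+Ã_low)·1e-3."""
        s = 0.004
        table = SFactorTable(
            phantom="M",
            entries={(r, "red_marrow"): s for r in ("red_marrow", "high", "low")},
        )
        cum = CumulatedActivitySet(A_tilde_high=100.0, A_tilde_low=300.0)
        cfg = DoseConfig(self_dose_mode="s_matrix", kappa=1.0)
        a_bm = bm_cumulated_from_low(300.0, 1.0, masses)
        rep = bm_dose(cum, table, masses, cfg)
        assert rep.D_BM_total_Gy == pytest.approx(s * (a_bm + 100.0 + 300.0) * 1e-3)

    def test_hand_assembled_four_terms(self, masses):
        """Full assembly matches an independent hand computation."""
        table = SFactorTable(
            phantom="M", entries={("high", "red_marrow"): 0.002, ("low", "red_marrow"): 0.001}
        )
        cfg = DoseConfig(kappa=0.8, delta_keV=147.0, phi=1.0, phi_SL=1.0)
        cum = CumulatedActivitySet(
            A_tilde_high=400.0, A_tilde_low=1500.0, A_tilde_SL=50.0
        )
        rep = bm_dose(cum, table, masses, cfg)
        a_bm = 0.8 * (1500.0 / masses.m_low_g) * masses.m_BM_g
        j_per_decay = 147e3 * 1.602e-19
        d_self = (a_bm / masses.m_BM_g) * 1e6 * 3600 * j_per_decay / 1e-3
        d_high = 400.0 * 0.002 * 1e-3
        d_low = 1500.0 * 0.001 * 1e-3
        d_sl = (50.0 / masses.m_BM_g) * 1e6 * 3600 * j_per_decay / 1e-3
        assert rep.D_BM_total_Gy == pytest.approx(d_self + d_high + d_low + d_sl, rel=1e-12)

    def test_concentration_path_equals_constructed_self_s(self, masses):
        """The Δ-based self-dose equals the S-matrix path when S(BM←BM) is
        the Δ-derived self-S for the configured marrow mass."""
        delta = 147.0
        # S in mGy/(MBq·h): energy rate per unit activity over the BM mass
        s_self = 1e6 * 3600 * delta * 1e3 * 1.602e-19 / (masses.m_BM_g * 1e-3) * 1e3
        table = SFactorTable(
            phantom="M",
            entries={
                ("red_marrow", "red_marrow"): s_self,
                ("high", "red_marrow"): 0.0,
                ("low", "red_marrow"): 0.0,
            },
        )
        cum = CumulatedActivitySet(A_tilde_high=10.0, A_tilde_low=1000.0)
        rep_conc = bm_dose(cum, table, masses, DoseConfig(self_dose_mode="concentration"))
        rep_s = bm_dose(cum, table, masses, DoseConfig(self_dose_mode="s_matrix"))
        assert rep_conc.D_BM_total_Gy == pytest.approx(rep_s.D_BM_total_Gy, rel=1e-12)


class TestDoseTable:
    def make_table(self):
        return SFactorTable(
            phantom="M", entries={("high", "red_marrow"): 0.002, ("low", "red_marrow"): 0.001}
        )

    def test_linear_in_a0_at_fixed_split(self, lu177, masses):
        df = dose_table(
            [5600.0, 8300.0], [(57.0, 43.0)], lu177,
            self.make_table(), self.make_table(), masses, masses,
        )
        m = df[df.phantom == "M"].set_index("A0_MBq")["D_BM_Gy"]
        assert m[8300.0] / m[5600.0] == pytest.approx(8.3 / 5.6, rel=1e-12)

    def test_bad_split_rejected(self, lu177, masses):
        with pytest.raises(ValueError, match="sum to 100"):
            dose_table(
                [5600.0], [(57.0, 44.0)], lu177,
                self.make_table(), self.make_table(), masses, masses,
            )

    def test_zero_s_and_kappa_gives_zero_table(self, lu177, masses):
        table = SFactorTable(
            phantom="M", entries={("high", "red_marrow"): 0.0, ("low", "red_marrow"): 0.0}
        )
        df = dose_table(
            [5600.0], [(60.0, 40.0)], lu177, table, table, masses, masses,
            DoseConfig(kappa=0.0),
        )
        assert (df.D_BM_Gy == 0).all()
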