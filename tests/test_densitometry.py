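import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sempa.densitometry import (
    AhdMeasurement,
    DensityPanel,
    functional_summary,
    glhsa_in_suspension,
    hb_in_particles,
    hb_in_supernatant,
    particle_concentration,
    particle_density,
    relative_nonfunctional,
    solve_composition,
    total_hb_ahd,
)
from sempa.errors import InvalidParameterError, ModelInconsistencyError
from sempa.presets import BETA_HB_SUS, HBMP_PANEL


class TestParticleDensity:
    def test_studied_batch(self):
        assert particle_density(HBMP_PANEL) == pytest.approx(1.0653, abs=5e-5)

    def test_neutral_buoyancy(self):
        p = DensityPanel(1.004, 1.004, 1.003, 0.2, 0.245, 0.2505)
        assert particle_density(p) == pytest.approx(1.004, rel=1e-14)

    def test_unit_ppv_returns_suspension_density(self):
        p = DensityPanel(1.016, 1.004, 1.003, 1 - 1e-12, 0.245, 0.2505)
        assert particle_density(p) == pytest.approx(1.016, rel=1e-9)


class TestCompositionChain:
    def test_glhsa_in_suspension(self):
        assert glhsa_in_suspension(HBMP_PANEL, BETA_HB_SUS) == pytest.approx(
            27.7, abs=0.05
        )

    def test_glhsa_zero_when_density_fully_explained_by_hb(self):
        beta = (HBMP_PANEL.rho_sus - HBMP_PANEL.rho_rac) * 1e3 / HBMP_PANEL.di_hb
        assert glhsa_in_suspension(HBMP_PANEL, beta) == pytest.approx(0.0, abs=1e-9)

    def test_glhsa_scales_inversely_with_increment(self):
        p2 = DensityPanel(
            HBMP_PANEL.rho_sus, HBMP_PANEL.rho_sup, HBMP_PANEL.rho_rac,
            HBMP_PANEL.ppv, HBMP_PANEL.di_hb, 2 * HBMP_PANEL.di_glhsa,
        )
        assert glhsa_in_suspension(p2, BETA_HB_SUS) == pytest.approx(
            glhsa_in_suspension(HBMP_PANEL, BETA_HB_SUS) / 2, rel=1e-12
        )

    def test_hb_in_supernatant(self):
        assert hb_in_supernatant(HBMP_PANEL, 1.0868) == pytest.approx(1.97, abs=0.01)

    def test_supernatant_zero_when_densities_equal(self):
        p = DensityPanel(1.016, HBMP_PANEL.rho_rac, HBMP_PANEL.rho_rac,
                         0.2, 0.245, 0.2505)
        assert hb_in_supernatant(p, 1.0) == 0.0

    def test_single_solute_limit(self):
        expected = (HBMP_PANEL.rho_sup - HBMP_PANEL.rho_rac) * 1e3 / HBMP_PANEL.di_hb
        assert hb_in_supernatant(HBMP_PANEL, 0.0) == pytest.approx(expected, rel=1e-14)

    def test_hb_in_particles_unrounded_chain(self):
        sol = solve_composition(HBMP_PANEL, BETA_HB_SUS)
        assert sol.beta_hb_hbmp == pytest.approx(120.1, abs=0.05)

    def test_homogeneous_suspension(self):
        assert hb_in_particles(25.5, 25.5, 0.1992) == pytest.approx(25.5, rel=1e-12)

    def test_unit_ppv(self):
        assert hb_in_particles(25.5, 2.0, 1.0) == pytest.approx(25.5, rel=1e-12)

    def test_negative_results_raise(self):
        with pytest.raises(ModelInconsistencyError):
            glhsa_in_suspension(HBMP_PANEL, 1000.0)
        with pytest.raises(ModelInconsistencyError):
            hb_in_particles(1.0, 10.0, 0.1992)

    @given(
        hb_frac=st.floats(0.3, 0.95),
        ppv=st.floats(0.05, 0.6),
        drho_sus=st.floats(0.005, 0.02),
        sup_frac=st.floats(0.0, 0.25),
    )
    def test_mass_balance_closure(self, hb_frac, ppv, drho_sus, sup_frac):
        """PPV * beta_HbMP + (1-PPV) * beta_sup reproduces beta_sus exactly."""
        # hb_frac keeps beta_Gl/HSA >= 0; sup_frac < hb_frac keeps the
        # intra-particle Hb non-negative
        panel = DensityPanel(1.0032 + drho_sus, 1.0032 + sup_frac * drho_sus,
                             1.0032, ppv, 0.245, 0.2505)
        beta_hb = hb_frac * drho_sus * 1e3 / panel.di_hb
        sol = solve_composition(panel, beta_hb)
        closure = ppv * sol.beta_hb_hbmp + (1 - ppv) * sol.beta_hb_sup
        assert closure == pytest.approx(beta_hb, rel=1e-12)

    @given(
        hb_frac=st.floats(0.0, 0.99),
        drho=st.floats(0.005, 0.02),
    )
    def test_density_closure(self, hb_frac, drho):
        """Reconstructing rho_sus from the solved concentrations and the
        density increments reproduces the measured value."""
        panel = DensityPanel(1.0032 + drho, 1.0040, 1.0032, 0.1992, 0.245, 0.2505)
        beta_hb = hb_frac * drho * 1e3 / panel.di_hb
        beta_gl = glhsa_in_suspension(panel, beta_hb)
        rho_back = panel.rho_rac + (
            panel.di_hb * beta_hb + panel.di_glhsa * beta_gl
        ) / 1e3
        assert rho_back == pytest.approx(panel.rho_sus, abs=1e-12)


class TestParticleConcentration:
    def test_dls_median(self):
        assert particle_concentration(0.1992, 760.0) == pytest.approx(866.7, abs=0.1)

    def test_ac_median(self):
        assert particle_concentration(0.1992, 996.0) == pytest.approx(385.0, abs=0.1)

    def test_cubic_scaling(self):
        c1 = particle_concentration(0.1992, 500.0)
        c2 = particle_concentration(0.1992, 1000.0)
        assert c2 == pytest.approx(c1 / 8, rel=1e-12)


class TestAhd:
    def test_hand_audited_value(self):
        m = AhdMeasurement(absorbance=0.5, path_length=1.0, dilution=0.116)
        assert total_hb_ahd(m) == pytest.approx(10.0, abs=0.01)

    def test_zero_absorbance(self):
        assert total_hb_ahd(AhdMeasurement(0.0, dilution=0.2)) == 0.0

    def test_halving_dilution_doubles_concentration(self):
        b1 = total_hb_ahd(AhdMeasurement(0.5, dilution=0.2))
        b2 = total_hb_ahd(AhdMeasurement(0.5, dilution=0.1))
        assert b2 == pytest.approx(2 * b1, rel=1e-12)

    def test_weighted_average_of_consistent_dilutions(self):
        # same underlying concentration seen through two dilutions
        beta = 25.5
        ms = [
            AhdMeasurement(beta * 6945 * d / 16114.5, dilution=d)
            for d in (0.116, 0.215)
        ]
        assert total_hb_ahd(ms) == pytest.approx(beta, rel=1e-12)


class TestFunctionalArithmetic:
    def test_studied_batch_summary(self):
        out = functional_summary(120.1, 1.0868, 0.35)
        assert out["functional_hb_gL"] == pytest.approx(78.0, abs=0.1)
        assert out["glhsa_hbmp_gL"] == pytest.approx(130.5, abs=0.1)
        assert out["functional_fraction"] == pytest.approx(0.31, abs=0.005)

    def test_all_met_is_nonfunctional(self):
        assert functional_summary(120.0, 1.0, 1.0)["functional_hb_gL"] == 0.0

    def test_no_glhsa_fraction_reduces_to_one_minus_met(self):
        out = functional_summary(120.0, 0.0, 0.35)
        assert out["functional_fraction"] == pytest.approx(0.65, rel=1e-12)

    @pytest.mark.parametrize(
        "functional, total, expected",
        [(11.8, 25.5, 54.0), (4.8, 25.5, 81.0), (25.5, 25.5, 0.0)],
    )
    def test_relative_nonfunctional(self, functional, total, expected):
        assert relative_nonfunctional(functional, total) == expected

    def test_relative_nonfunctional_bounds(self):
        with pytest.raises(InvalidParameterError):
            relative_nonfunctional(30.0, 25.5)
        with pytest.raises(InvalidParameterError):
            relative_nonfunctional(1.0, 0.0)
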