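import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import lorentz_pair
from sempa.errors import (
    ConfigurationError,
    InvalidParameterError,
    InvalidSpectrumError,
    KKPaddingWarning,
    RangeError,
)
from sempa.ri_model import (
    M_HB_MONOMER,
    HbFractions,
    ParticleComposition,
    epsilon_from_gamma,
    gamma_from_epsilon,
    kk_real_increment,
    particle_complex_ri,
    water_ri,
)
from sempa.spectra import Spectrum


class TestGammaFromEpsilon:
    def test_hand_evaluated_value_at_574nm(self):
        """ln(10)*6945*574nm/(4pi*16114.5 g/mol) in coherent units = 4.533e-3 mL/g."""
        eps = Spectrum([574.0], [6945.0], "molar_extinction")
        gamma = gamma_from_epsilon(eps, M_HB_MONOMER)
        assert gamma.values[0] == pytest.approx(4.533e-3, rel=1e-3)
        assert gamma.kind == "ri_increment_imag"

    def test_zero_epsilon_gives_zero_gamma(self):
        eps = Spectrum(np.linspace(300, 800, 50), np.zeros(50), "molar_extinction")
        assert np.all(gamma_from_epsilon(eps, M_HB_MONOMER).values == 0)

    def test_doubling_molar_mass_halves_gamma(self):
        eps = Spectrum(np.linspace(300, 800, 20), np.linspace(100, 5000, 20),
                       "molar_extinction")
        g1 = gamma_from_epsilon(eps, M_HB_MONOMER).values
        g2 = gamma_from_epsilon(eps, 2 * M_HB_MONOMER).values
        np.testing.assert_allclose(g2, g1 / 2, rtol=1e-14)

    def test_round_trip_with_inverse(self):
        eps = Spectrum(np.linspace(300, 800, 64),
                       np.abs(np.sin(np.linspace(0, 7, 64))) * 1e4,
                       "molar_extinction")
        gamma = gamma_from_epsilon(eps, M_HB_MONOMER)
        back = epsilon_from_gamma(gamma, M_HB_MONOMER)
        np.testing.assert_allclose(back.values, eps.values, rtol=1e-12)

    def test_invalid_inputs(self):
        eps = Spectrum([500.0], [100.0], "molar_extinction")
        with pytest.raises(InvalidParameterError):
            gamma_from_epsilon(eps, 0.0)
        with pytest.raises(InvalidSpectrumError):
            gamma_from_epsilon(Spectrum([500.0], [-1.0]), M_HB_MONOMER)


class TestKramersKronig:
    def test_idempotent_when_target_equals_reference(self):
        lam = np.linspace(250, 850, 601)
        g = Spectrum(lam, np.exp(-(((lam - 430) / 20.0) ** 2)), "ri_increment_imag")
        a_ref = Spectrum(lam, 0.2 + 0.001 * np.sin(lam / 37.0), "ri_increment_real")
        out = kk_real_increment(g, g, a_ref)
        np.testing.assert_array_equal(
            out.values, a_ref.interp(out.wavelengths).values
        )

    def test_matches_analytic_lorentz_pair(self):
        """Numeric transform vs the closed-form oscillator pair, 20 random
        bands, 1e-3 relative (to the dispersion amplitude) two half-widths
        away from the band center."""
        rng = np.random.default_rng(1)
        lam = np.geomspace(60.0, 4000.0, 6000)
        zeros = Spectrum(lam, np.zeros_like(lam), "ri_increment_imag")
        a0 = Spectrum(lam, np.zeros_like(lam), "ri_increment_real")
        for _ in range(20):
            center = rng.uniform(380, 650)
            hw = rng.uniform(0.02, 0.08)
            amp = rng.uniform(0.5, 2.0)
            re, im = lorentz_pair(lam, center, hw, amp)
            out = kk_real_increment(
                Spectrum(lam, im, "ri_increment_imag"), zeros, a0
            )
            expected = np.interp(out.wavelengths, lam, re)
            w = 1.0 / out.wavelengths
            far = np.abs(w - 1.0 / center) >= 2 * hw / center
            err = np.max(np.abs(out.values - expected)[far]) / np.max(np.abs(re))
            assert err < 1e-3

    def test_anomalous_dispersion_sign_change_at_band(self):
        lam = np.linspace(250, 850, 1201)
        dg = 0.01 * np.exp(-(((lam - 430) / 8.0) ** 2) / 2)
        zeros = Spectrum(lam, np.zeros_like(lam), "ri_increment_imag")
        a0 = Spectrum(lam, np.full_like(lam, 0.2), "ri_increment_real")
        out = kk_real_increment(Spectrum(lam, dg, "ri_increment_imag"), zeros, a0)
        delta = out.values - 0.2
        i0 = np.argmin(np.abs(out.wavelengths - 430.0))
        assert delta[i0 - 40] < 0 < delta[i0 + 40]  # lowered blue of, raised red of

    def test_insufficient_padding_warns_then_raises(self):
        lam = np.linspace(280, 820, 400)
        g = Spectrum(lam, np.zeros_like(lam), "ri_increment_imag")
        a = Spectrum(lam, np.zeros_like(lam), "ri_increment_real")
        with pytest.warns(KKPaddingWarning):
            kk_real_increment(g, g, a)
        with pytest.raises(RangeError):
            kk_real_increment(g, g, a, strict=True)


class TestWaterRI:
    def test_sodium_d_line_value(self):
        assert water_ri([589.0]).values[0] == pytest.approx(1.333, abs=0.002)

    def test_normal_dispersion(self):
        n = water_ri(np.linspace(300, 800, 51)).values
        assert np.all(np.diff(n) < 0)

    def test_output_length_and_range_check(self):
        w = np.linspace(300, 800, 17)
        assert len(water_ri(w)) == 17
        with pytest.raises(RangeError):
            water_ri([150.0])


class TestParticleComplexRI:
    def test_oxy_batch_at_488nm(self, optics):
        """n and kappa of the air-saturated batch (65% oxy / 35% met) at the
        flow-cytometer laser line: n approx 1.390, kappa approx 3.6e-4."""
        comp = ParticleComposition(120.0, 130.0, HbFractions(0.65, 0.0, 0.35))
        ri = particle_complex_ri(comp, optics, [488.0])
        assert ri.n[0] == pytest.approx(1.390, abs=0.01)
        assert 3.6e-4 / 2 <= ri.kappa[0] <= 3.6e-4 * 2

    def test_pure_water_limit(self, optics):
        comp = ParticleComposition(0.0, 0.0, HbFractions(1.0, 0.0, 0.0))
        w = np.linspace(300, 800, 21)
        ri = particle_complex_ri(comp, optics, w)
        np.testing.assert_allclose(ri.n, water_ri(w).values, rtol=1e-14)
        assert np.all(ri.kappa == 0)

    def test_single_species_kappa_proportional_to_met_gamma(self, optics):
        comp = ParticleComposition(120.0, 0.0, HbFractions(0.0, 0.0, 1.0))
        w = np.linspace(310, 790, 33)
        ri = particle_complex_ri(comp, optics, w)
        gamma = optics["metHb"].gamma.interp(w).values
        np.testing.assert_allclose(ri.kappa, 0.120 * gamma, rtol=1e-12)

    def test_affine_in_concentrations(self, optics):
        fr = HbFractions(0.5, 0.2, 0.3)
        w = np.linspace(320, 780, 12)
        n_w = water_ri(w).values
        r1 = particle_complex_ri(ParticleComposition(60.0, 65.0, fr), optics, w)
        r2 = particle_complex_ri(ParticleComposition(120.0, 130.0, fr), optics, w)
        np.testing.assert_allclose(r2.n - n_w, 2 * (r1.n - n_w), rtol=1e-10)
        np.testing.assert_allclose(r2.kappa, 2 * r1.kappa, rtol=1e-12)

    @given(
        t=st.floats(0.0, 1.0),
        f1=st.tuples(st.floats(0, 1), st.floats(0, 1)),
        f2=st.tuples(st.floats(0, 1), st.floats(0, 1)),
    )
    def test_kappa_convex_in_fractions(self, t, f1, f2, optics_module):
        """Blending two Hb-state compositions blends kappa exactly linearly."""

        def norm(f):
            d, m = f
            tot = d + m
            if tot > 1:
                d, m = d / tot, m / tot
            return HbFractions(1 - d - m, d, m)

        fa, fb = norm(f1), norm(f2)
        blend = HbFractions(
            t * fa.phi_oxy + (1 - t) * fb.phi_oxy,
            t * fa.phi_deoxy + (1 - t) * fb.phi_deoxy,
            t * fa.phi_met + (1 - t) * fb.phi_met,
        )
        w = np.linspace(350, 750, 9)

        def kappa(fr):
            return particle_complex_ri(
                ParticleComposition(120.0, 130.0, fr), optics_module, w
            ).kappa

        np.testing.assert_allclose(
            kappa(blend), t * kappa(fa) + (1 - t) * kappa(fb), atol=1e-12
        )

    def test_missing_species_table_rejected(self, optics):
        partial = {k: v for k, v in optics.items() if k != "metHb"}
        comp = ParticleComposition(120.0, 130.0, HbFractions(1.0, 0.0, 0.0))
        with pytest.raises(ConfigurationError):
            particle_complex_ri(comp, partial, [500.0])

    def test_fraction_simplex_enforced(self):
        with pytest.raises(InvalidParameterError):
            HbFractions(0.5, 0.5, 0.5)
        with pytest.raises(InvalidParameterError):
            HbFractions(1.2, -0.2, 0.0)


@pytest.fixture(scope="module")
def optics_module(optics):
    # hypothesis needs a non-function-scoped fixture alias
    return optics
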