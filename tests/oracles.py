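"""Independent reference implementations used only as test oracles.

These deliberately avoid the code paths of the package: the Mie series
is evaluated through complex-order Bessel functions (AMOS via
scipy.special) instead of logarithmic-derivative recurrences, the
Kramers-Kronig check uses the closed-form Lorentz-oscillator pair, and
log-normal moments use the analytic formula.
"""

import numpy as np
from scipy.special import jv, yv

from sempa.mie import wiscombe_nmax


def _psi(n, z):
    return np.sqrt(np.pi * z / 2.0) * jv(n + 0.5, z)


def _chi(n, z):
    return -np.sqrt(np.pi * z / 2.0) * yv(n + 0.5, z)


def bessel_mie_cross_sections(diameter_nm, wavelength_nm, m_particle, n_medium):
    """(C_ext, C_sca) in um^2 from direct Riccati-Bessel evaluation."""
    x = np.pi * diameter_nm * n_medium / wavelength_nm
    m = m_particle / n_medium
    z = m * x
    sext = 0.0
    ssca = 0.0
    for n in range(1, wiscombe_nmax(x) + 1):
        pnx, pnx1 = _psi(n, x), _psi(n - 1, x)
        pmx, pmx1 = _psi(n, z), _psi(n - 1, z)
        xin = pnx - 1j * _chi(n, x)
        xin1 = pnx1 - 1j * _chi(n - 1, x)
        dpnx = pnx1 - n / x * pnx
        dpmx = pmx1 - n / z * pmx
        dxin = xin1 - n / x * xin
        a = (m * pmx * dpnx - pnx * dpmx) / (m * pmx * dxin - xin * dpmx)
        b = (pmx * dpnx - m * pnx * dpmx) / (pmx * dxin - m * xin * dpmx)
        sext += (2 * n + 1) * np.real(a + b)
        ssca += (2 * n + 1) * (abs(a) ** 2 + abs(b) ** 2)
    scale = 2 * np.pi / (2 * np.pi * n_medium / wavelength_nm) ** 2 * 1e-6
    return sext * scale, ssca * scale


def rayleigh_cext(diameter_nm, wavelength_nm, m_particle, n_medium):
    """Dipole-limit extinction (absorption + scattering) in um^2."""
    x = np.pi * diameter_nm * n_medium / wavelength_nm
    m = m_particle / n_medium
    lf = (m**2 - 1) / (m**2 + 2)
    q = 4 * x * np.imag(lf) + 8.0 / 3.0 * x**4 * abs(lf) ** 2
    return q * np.pi * (diameter_nm / 2.0 * 1e-3) ** 2


def lorentz_pair(wavelengths_nm, center_nm, rel_halfwidth, amplitude):
    """Real and imaginary parts of a Lorentz oscillator susceptibility.

    f(w) = A w0^2 / (w0^2 - w^2 - i G w) with w ~ 1/lambda and
    G = rel_halfwidth * w0; an exact Kramers-Kronig pair.
    """
    w = 1.0 / np.asarray(wavelengths_nm, dtype=float)
    w0 = 1.0 / center_nm
    g = rel_halfwidth * w0
    f = amplitude * w0**2 / (w0**2 - w**2 - 1j * g * w)
    return np.real(f), np.imag(f)


def lognormal_mean_volume_closed_form(mu_d_nm, sigma_d):
    """(pi/6) mu^3 exp(4.5 sigma^2) in um^3."""
    return np.pi / 6.0 * (mu_d_nm * 1e-3) ** 3 * np.exp(4.5 * sigma_d**2)
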