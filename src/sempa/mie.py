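"""Lorenz-Mie extinction of a homogeneous sphere in a transparent host.

The host (water over 300-800 nm) is treated as non-absorbing, so the
standard formulation in a transparent medium applies: the series is
evaluated with the relative index m = m_particle / n_medium and the
medium-scaled size parameter x = pi D n_medium / lambda,

    C_ext = (2 pi / k^2) sum_n (2n+1) Re(a_n + b_n),   k = 2 pi n_medium / lambda.

Mie coefficients a_n, b_n use logarithmic-derivative downward recurrence
(started 15 orders above the Wiscombe truncation, from zero) and upward
Riccati-Bessel recurrences for psi_n and chi_n -- the standard numerically
stable scheme.  Particle shape is approximated as spherical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GridMismatchError, InvalidParameterError, RangeError
from .spectra import ComplexRI, Spectrum

#: Maximum supported size parameter.
X_MAX = 500.0


@dataclass(frozen=True)
class MieInput:
    """Single-sphere scattering problem definition (lengths in nm)."""

    diameter: float
    wavelength_vacuum: float
    m_particle: complex
    n_medium: float

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.wavelength_vacuum <= 0:
            raise InvalidParameterError("diameter and wavelength must be positive")
        if self.n_medium < 1:
            raise InvalidParameterError("host refractive index must be >= 1")
        if not np.isfinite(self.m_particle):
            raise InvalidParameterError("particle refractive index must be finite")
        if self.m_particle.imag < 0:
            raise InvalidParameterError("Im(m) must be >= 0 (passive particle)")

    @property
    def size_parameter(self) -> float:
        return np.pi * self.diameter * self.n_medium / self.wavelength_vacuum


def wiscombe_nmax(x: float | np.ndarray) -> int:
    """Series truncation order N = ceil(x + 4 x^(1/3) + 2)."""
    x = np.max(np.asarray(x, dtype=float))
    return int(np.ceil(x + 4.0 * np.cbrt(x) + 2.0))


def _mie_q_batch(x: np.ndarray, m: np.ndarray, nmax: int | None = None):
    """Extinction and scattering efficiencies for arrays of (x, m).

    ``x`` and ``m`` are broadcast against each other.  The truncation
    order is the Wiscombe criterion of the largest x in the batch; terms
    beyond an element's own criterion are negligibly small and harmless
    in the size regime handled here (x ratios within a batch < ~100).
    """
    x, m = np.broadcast_arrays(np.asarray(x, float), np.asarray(m, complex))
    shape = x.shape
    x = x.ravel()
    m = m.ravel()
    if np.any(x <= 0) or np.any(x > X_MAX):
        raise RangeError(f"size parameter must lie in (0, {X_MAX:g}]")
    if not np.all(np.isfinite(m)):
        raise InvalidParameterError("refractive index must be finite")

    n_stop = nmax if nmax is not None else wiscombe_nmax(x)
    n_start = n_stop + 15

    z = m * x
    # downward recurrence for the logarithmic derivative D_n(z)
    dn_store: list = [None] * (n_stop + 1)  # dn_store[k] holds D_k, k <= n_stop
    d = np.zeros_like(z)
    for n in range(n_start, 0, -1):
        rn = n / z
        d = rn - 1.0 / (d + rn)  # now D_{n-1}
        if n - 1 <= n_stop:
            dn_store[n - 1] = d

    # upward Riccati-Bessel recurrences: psi_n(x), chi_n(x)
    psi_m1 = np.cos(x)          # psi_{-1}
    psi_0 = np.sin(x)
    chi_m1 = -np.sin(x)         # chi_{-1}
    chi_0 = np.cos(x)

    qext = np.zeros_like(x)
    qsca = np.zeros_like(x)
    psi_nm1, psi_n = psi_m1, psi_0
    chi_nm1, chi_n = chi_m1, chi_0
    for n in range(1, n_stop + 1):
        psi_nm1, psi_n = psi_n, (2 * n - 1) / x * psi_n - psi_nm1
        chi_nm1, chi_n = chi_n, (2 * n - 1) / x * chi_n - chi_nm1
        xi_n = psi_n - 1j * chi_n
        xi_nm1 = psi_nm1 - 1j * chi_nm1
        dn = dn_store[n]
        ta = dn / m + n / x
        tb = dn * m + n / x
        a_n = (ta * psi_n - psi_nm1) / (ta * xi_n - xi_nm1)
        b_n = (tb * psi_n - psi_nm1) / (tb * xi_n - xi_nm1)
        qext += (2 * n + 1) * np.real(a_n + b_n)
        qsca += (2 * n + 1) * (np.abs(a_n) ** 2 + np.abs(b_n) ** 2)

    qext *= 2.0 / x**2
    qsca *= 2.0 / x**2
    return qext.reshape(shape), qsca.reshape(shape)


def mie_cross_sections(inp: MieInput, nmax: int | None = None) -> tuple[float, float]:
    """(C_ext, C_sca) in um^2 for a single sphere."""
    x = inp.size_parameter
    if x <= 0 or x > X_MAX:
        raise RangeError(f"size parameter x = {x:g} outside (0, {X_MAX:g}]")
    m_rel = complex(inp.m_particle) / inp.n_medium
    qext, qsca = _mie_q_batch(np.array([x]), np.array([m_rel]), nmax=nmax)
    geom = np.pi * (inp.diameter / 2.0) ** 2 * 1e-6  # nm^2 -> um^2
    return float(qext[0] * geom), float(qsca[0] * geom)


def mie_extinction(inp: MieInput, nmax: int | None = None) -> float:
    """Extinction cross section C_ext (um^2) of a single sphere."""
    return mie_cross_sections(inp, nmax=nmax)[0]


def mie_extinction_batch(
    diameters_nm: np.ndarray,
    wavelengths_nm: np.ndarray,
    m_particle: np.ndarray,
    n_medium: np.ndarray,
) -> np.ndarray:
    """C_ext (um^2) on the outer product of diameters and wavelengths.

    Returns an array of shape (n_diameters, n_wavelengths).  ``m_particle``
    and ``n_medium`` are per-wavelength.
    """
    d = np.asarray(diameters_nm, float)[:, None]
    lam = np.asarray(wavelengths_nm, float)[None, :]
    n_med = np.asarray(n_medium, float)[None, :]
    m_rel = np.asarray(m_particle, complex)[None, :] / n_med
    x = np.pi * d * n_med / lam
    qext, _ = _mie_q_batch(x, np.broadcast_to(m_rel, x.shape))
    return qext * np.pi * (d / 2.0) ** 2 * 1e-6


def mie_extinction_spectrum(
    diameter_nm: float, ri: ComplexRI, n_medium: Spectrum
) -> Spectrum:
    """Per-wavelength extinction cross section of one sphere (um^2)."""
    if not ri.same_grid(n_medium):
        raise GridMismatchError("particle RI and host RI grids differ")
    cext = mie_extinction_batch(
        np.array([diameter_nm]), ri.wavelengths, ri.m, n_medium.values
    )[0]
    return Spectrum(ri.wavelengths, cext, "extinction_cross_section")
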