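"""Complex refractive index of hemoglobin microparticles.

The particle is modelled as an aqueous protein solution: the host water RI
plus mass-concentration-weighted real and imaginary RI increments of total
hemoglobin (itself a mass-fraction superposition of the oxy, deoxy and met
states) and of the heme-free globin/HSA component,

    n(l) + i*k(l) = n_H2O(l) + b_Hb [a_Hb(l) + i g_Hb(l)]
                             + b_Gl/HSA [a_HSA(l) + i g_HSA(l)],

with b in g/mL when the increments a, g are in mL/g.  The imaginary
increment of each Hb state follows from its molar extinction coefficient,

    g_x(l) = ln(10) * eps_x(l) * l / (4 pi M),

with M the molar mass of the Hb monomer (one heme).  Real increments that
are not directly measured are obtained from the imaginary ones by a
singly subtractive Kramers-Kronig transform anchored to a reference real
increment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import (
    ConfigurationError,
    GridMismatchError,
    InvalidParameterError,
    InvalidSpectrumError,
    KKPaddingWarning,
    RangeError,
)
from .spectra import ComplexRI, Spectrum

LN10 = float(np.log(10.0))

#: Molar mass of the hemoglobin monomer Hb(Fe), g/mol.
M_HB_MONOMER = 16114.5

#: Molar mass of human serum albumin, g/mol (used for the Gl/HSA component).
M_HSA = 66500.0

#: Species recognised by the optics model.
SPECIES = ("oxyHb", "deoxyHb", "metHb", "GlHSA")

#: Reference temperature of the water dispersion formula, deg C.
WATER_RI_TEMPERATURE_C = 20.0

# Sellmeier fit to the refractive index of pure water at 20 deg C
# (Daimon & Masumura 2007), wavelength in um, valid 182-1129 nm.
_WATER_SELLMEIER = (
    (5.684027565e-1, 5.101829712e-3),
    (1.726177391e-1, 1.821153936e-2),
    (2.086189578e-2, 2.620722293e-2),
    (1.130748688e-1, 1.069792721e1),
)
_WATER_VALID_NM = (200.0, 1100.0)


@dataclass(frozen=True)
class HbFractions:
    """Simplex-constrained mass fractions of the three hemoglobin states."""

    phi_oxy: float
    phi_deoxy: float
    phi_met: float

    def __post_init__(self) -> None:
        for name in ("phi_oxy", "phi_deoxy", "phi_met"):
            v = getattr(self, name)
            if not (-1e-12 <= v <= 1 + 1e-12):
                raise InvalidParameterError(f"{name} = {v} outside [0, 1]")
        total = self.phi_oxy + self.phi_deoxy + self.phi_met
        if abs(total - 1.0) > 1e-9:
            raise InvalidParameterError(
                f"mass fractions must sum to 1 (got {total:.12f})"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.phi_oxy, self.phi_deoxy, self.phi_met])


@dataclass
class SpeciesOptics:
    """Per-species optical increment tables.

    ``alpha`` and ``gamma`` are the real and imaginary RI increments in
    mL/g on a common wavelength range covering at least 300-800 nm.
    """

    species: str
    alpha: Spectrum
    gamma: Spectrum
    molar_mass: float

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise InvalidParameterError(f"unknown species {self.species!r}")
        if self.molar_mass <= 0:
            raise InvalidParameterError("molar mass must be positive")
        if np.any(self.gamma.values < 0):
            raise InvalidSpectrumError("gamma (imaginary increment) must be >= 0")
        for spec in (self.alpha, self.gamma):
            if spec.wavelengths[0] > 300 + 1e-9 or spec.wavelengths[-1] < 800 - 1e-9:
                raise InvalidSpectrumError(
                    f"{self.species} increment table must cover 300-800 nm "
                    f"(got {spec.wavelengths[0]:g}-{spec.wavelengths[-1]:g} nm)"
                )


@dataclass(frozen=True)
class ParticleComposition:
    """Intra-particle protein content: total Hb and heme-free Gl/HSA (g/L)."""

    beta_hb: float
    beta_glhsa: float
    fractions: HbFractions

    def __post_init__(self) -> None:
        if self.beta_hb < 0 or self.beta_glhsa < 0:
            raise InvalidParameterError("mass concentrations must be >= 0")


# ----------------------------------------------------------------------
# Operations
# ----------------------------------------------------------------------


def gamma_from_epsilon(epsilon: Spectrum, molar_mass: float) -> Spectrum:
    """Imaginary RI increment (mL/g) from a molar extinction spectrum.

    gamma(l) = ln(10) * eps(l) * l / (4 pi M), with eps in L mol^-1 cm^-1,
    l the vacuum wavelength and M the molar mass in g/mol.  The unit audit
    (eps -> 1000 cm^2/mol per L mol^-1 cm^-1, l -> cm) makes the output
    come out in cm^3/g = mL/g.
    """
    if molar_mass <= 0:
        raise InvalidParameterError("molar mass must be positive")
    if np.any(epsilon.values < 0):
        raise InvalidSpectrumError("molar extinction coefficients must be >= 0")
    lam_cm = epsilon.wavelengths * 1e-7
    gamma = LN10 * epsilon.values * 1000.0 * lam_cm / (4.0 * np.pi * molar_mass)
    return Spectrum(epsilon.wavelengths, gamma, "ri_increment_imag")


def epsilon_from_gamma(gamma: Spectrum, molar_mass: float) -> Spectrum:
    """Inverse of :func:`gamma_from_epsilon` (L mol^-1 cm^-1)."""
    if molar_mass <= 0:
        raise InvalidParameterError("molar mass must be positive")
    lam_cm = gamma.wavelengths * 1e-7
    eps = gamma.values * 4.0 * np.pi * molar_mass / (LN10 * 1000.0 * lam_cm)
    return Spectrum(gamma.wavelengths, eps, "molar_extinction")


def _kk_transform(wavelengths: np.ndarray, dgamma: np.ndarray,
                  out_mask: np.ndarray, chunk: int = 256) -> np.ndarray:
    """Kramers-Kronig transform of an imaginary-increment difference.

    Works in wavenumber space nu = 1/lambda where the dispersion relation
    reads  da(nu) = (2/pi) P-int nu' dg(nu') / (nu'^2 - nu^2) dnu'.
    The principal value is handled by subtracting the pole:  the regular
    part  (g(nu') - g(nu)) / (nu'^2 - nu^2)  with  g = nu * dg  is
    integrated by the trapezoid rule (the on-pole limit g'(nu)/(2 nu) is
    inserted from a finite difference), and the subtracted singular term
    is added back with its closed-form principal-value integral.
    """
    nu = 1.0 / wavelengths[::-1]            # ascending wavenumber grid, nm^-1
    g = (nu * dgamma[::-1]).astype(float)
    n = nu.size
    # local derivative of g for the on-pole limit
    gprime = np.gradient(g, nu)

    idx_out = np.nonzero(out_mask[::-1])[0]
    result = np.zeros(idx_out.size)
    nu2 = nu * nu
    nu_lo, nu_hi = nu[0], nu[-1]

    for start in range(0, idx_out.size, chunk):
        sel = idx_out[start:start + chunk]
        nui = nu[sel][:, None]
        gi = g[sel][:, None]
        denom = nu2[None, :] - nui**2
        with np.errstate(divide="ignore", invalid="ignore"):
            integrand = (g[None, :] - gi) / denom
        # on-pole limit of the regularised integrand
        integrand[np.arange(sel.size), sel] = gprime[sel] / (2.0 * nu[sel])
        regular = np.trapezoid(integrand, nu, axis=1)
        # closed-form PV of the subtracted pole over [nu_lo, nu_hi]
        nui1 = nu[sel]
        log_pv = (1.0 / (2.0 * nui1)) * np.log(
            ((nu_hi - nui1) * (nui1 + nu_lo)) / ((nu_hi + nui1) * (nui1 - nu_lo))
        )
        result[start:start + chunk] = regular + g[sel] * log_pv

    out = np.zeros(n)
    out[idx_out] = (2.0 / np.pi) * result
    return out[::-1][out_mask]


def kk_real_increment(
    gamma_target: Spectrum,
    gamma_ref: Spectrum,
    alpha_ref: Spectrum,
    restrict: tuple[float, float] = (300.0, 800.0),
    min_padding_nm: float = 50.0,
    strict: bool = False,
) -> Spectrum:
    """Real RI increment via a subtractive Kramers-Kronig transform.

    The target's real increment is anchored to a reference species whose
    real increment ``alpha_ref`` is known on the same grid:

        alpha_target(l) = alpha_ref(l) + KK[gamma_target - gamma_ref](l).

    Absorption outside the tabulated window (deep-UV protein and water
    bands) contributes only a smooth background that cancels in the
    difference, which is why the subtractive form is used.  The input
    grids must extend beyond the output window on both sides so the
    principal-value integral sees the band tails.
    """
    gamma_target.require_same_grid(gamma_ref)
    gamma_target.require_same_grid(alpha_ref)
    w = gamma_target.wavelengths
    lo, hi = restrict
    if w[0] > lo - min_padding_nm + 1e-9 or w[-1] < hi + min_padding_nm - 1e-9:
        msg = (
            f"KK input grid [{w[0]:g}, {w[-1]:g}] nm extends less than "
            f"{min_padding_nm:g} nm beyond the output window [{lo:g}, {hi:g}] nm"
        )
        if strict:
            raise RangeError(msg)
        warnings.warn(msg, KKPaddingWarning, stacklevel=2)
    if w[0] >= lo or w[-1] <= hi:
        raise RangeError("KK input grid must strictly contain the output window")

    dgamma = gamma_target.values - gamma_ref.values
    out_mask = (w >= lo - 1e-9) & (w <= hi + 1e-9)
    dalpha = _kk_transform(w, dgamma, out_mask)
    alpha = alpha_ref.values[out_mask] + dalpha
    return Spectrum(w[out_mask], alpha, "ri_increment_real")


def water_ri(wavelengths) -> Spectrum:
    """Refractive index of pure water (Sellmeier fit, 20 deg C).

    Valid for 200-1100 nm; monotonically decreasing over 300-800 nm
    (normal dispersion).  The ~3 K offset from the 23 deg C density
    measurements shifts n by less than 5e-4 and is neglected.
    """
    w = np.atleast_1d(np.asarray(wavelengths, dtype=float))
    if np.any(w < _WATER_VALID_NM[0]) or np.any(w > _WATER_VALID_NM[1]):
        raise RangeError(
            f"water RI model valid for {_WATER_VALID_NM[0]:g}-"
            f"{_WATER_VALID_NM[1]:g} nm"
        )
    lam_um2 = (w * 1e-3) ** 2
    n2 = 1.0 + sum(a * lam_um2 / (lam_um2 - l2) for a, l2 in _WATER_SELLMEIER)
    return Spectrum(w, np.sqrt(n2), "refractive_index")


def particle_complex_ri(
    composition: ParticleComposition,
    optics: dict[str, SpeciesOptics],
    wavelengths,
) -> ComplexRI:
    """Complex RI of a particle from its composition and species tables.

    The Hb increments are the fraction-weighted sums over the three Hb
    states; concentrations enter in g/mL (inputs are g/L) against
    increments in mL/g.
    """
    missing = [s for s in SPECIES if s not in optics]
    if missing:
        raise ConfigurationError(f"missing species optics tables: {missing}")
    w = np.atleast_1d(np.asarray(wavelengths, dtype=float))
    if w.size > 1 and not np.all(np.diff(w) > 0):
        raise GridMismatchError("requested wavelength grid must be increasing")

    f = composition.fractions
    weights = {"oxyHb": f.phi_oxy, "deoxyHb": f.phi_deoxy, "metHb": f.phi_met}
    alpha_hb = np.zeros_like(w)
    gamma_hb = np.zeros_like(w)
    for species, phi in weights.items():
        tab = optics[species]
        alpha_hb += phi * tab.alpha.interp(w).values
        gamma_hb += phi * tab.gamma.interp(w).values
    alpha_hsa = optics["GlHSA"].alpha.interp(w).values
    gamma_hsa = optics["GlHSA"].gamma.interp(w).values

    b_hb = composition.beta_hb / 1000.0      # g/L -> g/mL
    b_gl = composition.beta_glhsa / 1000.0
    n = water_ri(w).values + b_hb * alpha_hb + b_gl * alpha_hsa
    kappa = b_hb * gamma_hb + b_gl * gamma_hsa
    return ComplexRI(w, n, kappa)
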