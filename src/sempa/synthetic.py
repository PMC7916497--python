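"""Synthetic optics tables and transmittance spectra.

No machine-readable extinction tables or raw transmittance spectra are
deposited with the study, so the package generates both: per-species
molar-extinction spectra from Gaussian band models anchored at the known
band positions (oxyHb Soret 413 nm, Q bands 543/578 nm; deoxyHb Soret
430 nm, Q 555 nm; metHb Soret 409 nm plus 500 and 630-640 nm bands;
Gl/HSA featureless above 300 nm), and transmittance measurements by
inverting the Beer-Lambert relation T = exp(-l PPV phi Z) on forward-model
Z spectra, optionally with seeded multiplicative photometric noise.

The band models are stand-ins for the authoritative literature tables:
positions and Soret/Q amplitude ratios (~10:1) are realistic, exact
values are not.  Real analyses should load measured increment tables
through :mod:`sempa.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError, RangeError
from .fitting import ForwardModel
from .pipeline import TransmittanceMeasurement
from .psd import LogNormalPSD
from .ri_model import (
    M_HB_MONOMER,
    M_HSA,
    HbFractions,
    ParticleComposition,
    SpeciesOptics,
    gamma_from_epsilon,
    kk_real_increment,
)
from .spectra import Spectrum

#: Flat real-increment baseline (mL/g) that anchors the KK transform; it
#: stands for the dispersion background of the deep-UV protein bands.
ALPHA_BASELINE = 0.20

#: Default synthesis grid: 250-850 nm with 50 nm padding for the KK integral.
DEFAULT_GRID = np.arange(250.0, 850.0 + 0.5, 1.0)


@dataclass(frozen=True)
class GaussianBand:
    """One absorption band: center (nm), Gaussian sigma (nm), peak molar
    extinction (L mol^-1 cm^-1)."""

    center: float
    width: float
    peak: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise InvalidParameterError("band width must be positive")
        if self.peak < 0:
            raise InvalidParameterError("band peak must be >= 0")


@dataclass(frozen=True)
class BandModel:
    """Gaussian band superposition plus a small positive baseline."""

    bands: tuple[GaussianBand, ...]
    baseline: float = 0.0
    molar_mass: float = M_HB_MONOMER

    def epsilon(self, wavelengths: np.ndarray) -> np.ndarray:
        w = np.asarray(wavelengths, dtype=float)
        eps = np.full_like(w, float(self.baseline))
        for b in self.bands:
            eps += b.peak * np.exp(-((w - b.center) ** 2) / (2.0 * b.width**2))
        return eps


# Band positions from the known spectral signatures; amplitudes per heme
# (monomer) with order-of-magnitude realistic Soret/Q ratios.
DEFAULT_BANDS: dict[str, BandModel] = {
    "oxyHb": BandModel(
        bands=(
            GaussianBand(413.0, 15.0, 125_000.0),
            GaussianBand(543.0, 13.0, 12_500.0),
            GaussianBand(578.0, 10.0, 14_500.0),
        ),
        baseline=800.0,
    ),
    "deoxyHb": BandModel(
        bands=(
            GaussianBand(430.0, 16.0, 133_000.0),
            GaussianBand(555.0, 16.0, 12_500.0),
        ),
        baseline=800.0,
    ),
    "metHb": BandModel(
        bands=(
            GaussianBand(409.0, 13.0, 110_000.0),
            GaussianBand(500.0, 22.0, 10_000.0),
            GaussianBand(632.0, 18.0, 3_900.0),
        ),
        baseline=800.0,
    ),
    # heme-free proteins: only the deep-UV aromatic band, nothing visible
    "GlHSA": BandModel(
        bands=(GaussianBand(280.0, 18.0, 36_000.0),),
        baseline=10.0,
        molar_mass=M_HSA,
    ),
}


def make_species_optics(
    species: str,
    band_model: BandModel | None = None,
    grid: np.ndarray | None = None,
) -> SpeciesOptics:
    """Build a synthetic SpeciesOptics table from a Gaussian band model.

    epsilon comes from the band superposition, gamma from the molar
    extinction, and alpha from the Kramers-Kronig transform of gamma
    anchored to the flat :data:`ALPHA_BASELINE` reference.  The grid must
    cover 250-850 nm so the KK integral sees the band tails.
    """
    if band_model is None:
        if species not in DEFAULT_BANDS:
            raise InvalidParameterError(f"no default band model for {species!r}")
        band_model = DEFAULT_BANDS[species]
    w = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    if w[0] > 250.0 + 1e-9 or w[-1] < 850.0 - 1e-9:
        raise RangeError("synthesis grid must cover 250-850 nm (KK padding)")

    eps = Spectrum(w, band_model.epsilon(w), "molar_extinction")
    gamma = gamma_from_epsilon(eps, band_model.molar_mass)
    flat_ref = Spectrum(w, np.full_like(w, ALPHA_BASELINE), "ri_increment_real")
    zero_gamma = Spectrum(w, np.zeros_like(w), "ri_increment_imag")
    alpha = kk_real_increment(gamma, zero_gamma, flat_ref)
    # restrict gamma to the KK output window so the table grids agree
    gamma_r = gamma.interp(alpha.wavelengths)
    return SpeciesOptics(
        species=species, alpha=alpha, gamma=gamma_r,
        molar_mass=band_model.molar_mass,
    )


def default_species_optics(grid: np.ndarray | None = None) -> dict[str, SpeciesOptics]:
    """Deterministic fixture optics for all four species."""
    return {s: make_species_optics(s, grid=grid) for s in DEFAULT_BANDS}


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative log-normal photometric noise on T."""

    sigma: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise InvalidParameterError("noise sigma must be >= 0")
        if self.sigma > 0 and self.seed is None:
            raise InvalidParameterError("a seed is mandatory when sigma > 0")


@dataclass(frozen=True)
class InstrumentConfig:
    """Cuvette and dilution parameters of a synthetic measurement."""

    path_mm: float = 10.0
    volume_fraction: float = 5e-4
    ppv: float = 0.1992


def synthesize_transmittance(
    fractions: HbFractions,
    psd: LogNormalPSD,
    composition_base: ParticleComposition,
    instrument: InstrumentConfig,
    noise: NoiseModel = NoiseModel(),
    optics: dict[str, SpeciesOptics] | None = None,
    wavelengths: np.ndarray | None = None,
    model: ForwardModel | None = None,
    _rng: np.random.Generator | None = None,
    _stray: float = 0.0,
) -> TransmittanceMeasurement:
    """Forward-model transmittance measurement, optionally noisy.

    Deterministic for a fixed seed; with sigma = 0 the measurement
    round-trips exactly through the VSECS conversion.  ``_stray`` adds a
    constant stray-light floor (a multiple-scattering-like artifact used
    by QC tests).
    """
    if model is None:
        if optics is None:
            optics = default_species_optics()
        w = np.arange(300.0, 800.0 + 1e-9, 5.0) if wavelengths is None else wavelengths
        model = ForwardModel(psd, composition_base, optics, w)
    z = model.vsecs(fractions)
    ell_um = instrument.path_mm * 1e3
    tau = ell_um * instrument.ppv * instrument.volume_fraction * z.values
    t = np.exp(-tau)
    if np.any(t > 1 + 1e-12):
        raise InvalidParameterError("parameters yield transmittance > 1")
    if _stray:
        t = t + _stray * (1.0 - t)
    if noise.sigma > 0:
        rng = _rng if _rng is not None else np.random.default_rng(noise.seed)
        t = t * np.exp(rng.normal(0.0, noise.sigma, size=t.shape))
    t = np.clip(t, 1e-300, 1.0)
    return TransmittanceMeasurement(
        spectrum=Spectrum(z.wavelengths, t, "transmittance"),
        path_length=instrument.path_mm,
        volume_fraction=instrument.volume_fraction,
        ppv=instrument.ppv,
    )


def phi_for_transmittance(
    z_at: float, target_t: float, path_mm: float, ppv: float
) -> float:
    """Volume fraction phi that yields a target transmittance at one point."""
    if not 0 < target_t < 1:
        raise InvalidParameterError("target transmittance must lie in (0, 1)")
    if z_at <= 0:
        raise InvalidParameterError("Z must be positive at the anchor wavelength")
    return -np.log(target_t) / (path_mm * 1e3 * ppv * z_at)


def make_dilution_series(
    base_fractions: HbFractions,
    psd: LogNormalPSD,
    composition_base: ParticleComposition,
    phis: list[float],
    noise: NoiseModel = NoiseModel(),
    optics: dict[str, SpeciesOptics] | None = None,
    wavelengths: np.ndarray | None = None,
    model: ForwardModel | None = None,
    stray_in_densest: float = 0.0,
    path_mm: float = 10.0,
    ppv: float = 0.1992,
) -> list[TransmittanceMeasurement]:
    """One synthetic measurement per volume fraction, shared seed stream.

    ``stray_in_densest`` > 0 injects a stray-light (multiple-scattering
    surrogate) artifact into the densest member only, producing the shape
    distortion the dilution QC is designed to reject.
    """
    phis = list(phis)
    if any(p <= 0 for p in phis) or any(
        b <= a for a, b in zip(phis, phis[1:])
    ):
        raise InvalidParameterError("volume fractions must be positive, increasing")
    if model is None:
        if optics is None:
            optics = default_species_optics()
        w = np.arange(300.0, 800.0 + 1e-9, 5.0) if wavelengths is None else wavelengths
        model = ForwardModel(psd, composition_base, optics, w)
    rng = np.random.default_rng(noise.seed) if noise.sigma > 0 else None
    out = []
    for i, phi in enumerate(phis):
        stray = stray_in_densest if i == len(phis) - 1 else 0.0
        inst = InstrumentConfig(path_mm=path_mm, volume_fraction=phi, ppv=ppv)
        m = synthesize_transmittance(
            base_fractions, psd, composition_base, inst, noise,
            model=model, _rng=rng, _stray=stray,
        )
        m.label = f"phi={phi:g}"
        out.append(m)
    return out
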