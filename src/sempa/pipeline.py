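"""Transmittance -> extinction pipeline with dilution-series QC.

Collimated transmittance T(lambda) of a diluted particle suspension in a
cuvette of path length l obeys Beer-Lambert extinction by single
scattering,

    C_ext(l) = -ln T / (l C0 phi)        (average extinction cross section)
    Z(l)     = -ln T / (l PPV phi)       (volume-specific cross section)

with C0 the stock particle concentration, PPV the stock packed particle
volume and phi the stock volume fraction in the cuvette.  Dense dilutions
suffer multiple scattering; the QC rule keeps the densest member whose
minimum transmittance stays >= 30% over 300-800 nm and whose log-Z curve
agrees with the next-lower dilution up to a constant shift (pipetting
volume error shifts log Z without changing its shape).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ConfigurationError,
    DegenerateInputError,
    GridMismatchError,
    InvalidParameterError,
    QCFailureError,
    SaturationError,
)
from .spectra import Spectrum

#: Default wavelength window for QC and fitting, nm.
FIT_RANGE_NM = (300.0, 800.0)

#: Minimum admissible transmittance before multiple scattering is suspected.
T_MIN_QC = 0.30

#: Default RMS tolerance of the log-Z shape agreement between dilutions.
LOG_SHIFT_RMS_TOL = 0.02


@dataclass
class TransmittanceMeasurement:
    """One transmittance spectrum plus the metadata needed for conversion.

    path_length in mm; ``volume_fraction`` is the stock volume fraction phi
    in the cuvette; ``ppv`` the packed particle volume of the stock;
    ``stock_concentration`` optionally in pL^-1.
    """

    spectrum: Spectrum
    path_length: float
    volume_fraction: float
    ppv: float
    stock_concentration: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.spectrum.kind != "transmittance":
            raise InvalidParameterError("spectrum kind must be 'transmittance'")
        if self.path_length <= 0:
            raise InvalidParameterError("path length must be positive")
        if not 0 < self.volume_fraction < 1:
            raise InvalidParameterError("volume fraction must lie in (0, 1)")
        if not 0 < self.ppv < 1:
            raise InvalidParameterError("PPV must lie in (0, 1)")
        if self.stock_concentration is not None and self.stock_concentration <= 0:
            raise InvalidParameterError("stock concentration must be positive")


def _neg_log_t(m: TransmittanceMeasurement) -> np.ndarray:
    t = m.spectrum.values
    if np.any(t <= 0):
        raise SaturationError("transmittance reached zero; extinction saturated")
    return -np.log(t)


def transmittance_to_cext(m: TransmittanceMeasurement) -> Spectrum:
    """Average extinction cross section (um^2) from one measurement."""
    if m.stock_concentration is None:
        raise ConfigurationError(
            "stock concentration C0 required for the cross-section conversion"
        )
    ell_um = m.path_length * 1e3            # mm -> um
    c0_um3 = m.stock_concentration * 1e-3   # pL^-1 -> um^-3
    cext = _neg_log_t(m) / (ell_um * c0_um3 * m.volume_fraction)
    return Spectrum(m.spectrum.wavelengths, cext, "extinction_cross_section")


def transmittance_to_vsecs(m: TransmittanceMeasurement) -> Spectrum:
    """Volume-specific extinction cross section Z (um^-1) from one measurement."""
    ell_um = m.path_length * 1e3
    z = _neg_log_t(m) / (ell_um * m.ppv * m.volume_fraction)
    return Spectrum(m.spectrum.wavelengths, z, "vsecs")


@dataclass
class DilutionQCReport:
    """Per-member QC diagnostics for a dilution series."""

    labels: list = field(default_factory=list)
    volume_fractions: list = field(default_factory=list)
    t_min: list = field(default_factory=list)
    log_shift_rms: list = field(default_factory=list)
    passed: list = field(default_factory=list)
    selected_index: int | None = None


def select_dilution(
    series: list[TransmittanceMeasurement],
    fit_range: tuple[float, float] = FIT_RANGE_NM,
    t_min: float = T_MIN_QC,
    rms_tol: float = LOG_SHIFT_RMS_TOL,
) -> tuple[TransmittanceMeasurement, DilutionQCReport]:
    """Pick the densest dilution free of multiple-scattering effects.

    Members are ranked by descending volume fraction.  A member passes if
    (a) its transmittance never drops below ``t_min`` inside ``fit_range``
    and (b) after removing the best constant shift, its log-Z curve
    deviates from the next-lower dilution by at most ``rms_tol`` RMS.
    The densest member with no lower neighbour passes (b) trivially.
    """
    if not series:
        raise InvalidParameterError("dilution series is empty")
    order = sorted(range(len(series)),
                   key=lambda i: series[i].volume_fraction, reverse=True)
    report = DilutionQCReport()
    lo, hi = fit_range
    selected = None
    for rank, i in enumerate(order):
        m = series[i]
        t = m.spectrum.restrict(lo, hi)
        tmin_i = float(t.values.min())
        rms = np.nan
        ok = tmin_i >= t_min
        if ok and rank + 1 < len(order):
            nxt = series[order[rank + 1]]
            z_a = transmittance_to_vsecs(m).restrict(lo, hi)
            z_b = transmittance_to_vsecs(nxt).restrict(lo, hi)
            z_a.require_same_grid(z_b)
            with np.errstate(divide="raise"):
                try:
                    r = np.log(z_a.values) - np.log(z_b.values)
                except FloatingPointError as exc:
                    raise DegenerateInputError(
                        "zero Z encountered in the QC comparison"
                    ) from exc
            r -= r.mean()
            rms = float(np.sqrt(np.mean(r**2)))
            ok = rms <= rms_tol
        report.labels.append(m.label or f"#{i}")
        report.volume_fractions.append(m.volume_fraction)
        report.t_min.append(tmin_i)
        report.log_shift_rms.append(rms)
        report.passed.append(bool(ok))
        if ok and selected is None:
            selected = i
            report.selected_index = i
    if selected is None:
        raise QCFailureError(
            "no dilution passed QC; diagnostics: "
            + ", ".join(
                f"{l}(phi={p:g}, Tmin={t:.3f}, rms={r if np.isnan(r) else round(r, 4)})"
                for l, p, t, r in zip(
                    report.labels, report.volume_fractions,
                    report.t_min, report.log_shift_rms,
                )
            )
        )
    return series[selected], report


def rescale_to_reference(
    z: Spectrum, z_ref: Spectrum
) -> tuple[Spectrum, float]:
    """Least-squares rescale of a Z spectrum onto a reference.

    Returns (s*z, s) with s = sum(z z_ref) / sum(z^2), the minimiser of
    sum (s z - z_ref)^2 over 300-800 nm.  Used to correct concentration
    loss (e.g. foaming during deoxygenation) between repeat measurements.
    """
    z.require_same_grid(z_ref)
    denom = float(np.sum(z.values**2))
    if denom == 0:
        raise DegenerateInputError("cannot rescale an all-zero spectrum")
    s = float(np.sum(z.values * z_ref.values) / denom)
    return z.with_values(s * z.values), s
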