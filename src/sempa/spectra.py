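"""Spectral containers.

Every spectral quantity in the package is carried by a :class:`Spectrum`:
a strictly increasing vacuum-wavelength grid (nm) plus real values and a
declared ``kind`` that fixes units and invariants.  Complex refractive
indices, which pair a real part ``n`` with an absorption index ``kappa``
on a common grid, use :class:`ComplexRI`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GridMismatchError, InvalidSpectrumError

#: Recognised spectrum kinds and their conventional units.
KINDS = {
    "transmittance": "dimensionless, (0, 1]",
    "extinction_cross_section": "um^2",
    "vsecs": "um^-1",
    "molar_extinction": "L mol^-1 cm^-1",
    "ri_increment_real": "mL/g",
    "ri_increment_imag": "mL/g",
    "refractive_index": "dimensionless (absolute RI)",
    "absorbance": "dimensionless",
    "generic": "unspecified",
}

_GRID_RTOL = 1e-9


def _as_grid(wavelengths) -> np.ndarray:
    w = np.asarray(wavelengths, dtype=float)
    if w.ndim != 1 or w.size < 1:
        raise InvalidSpectrumError("wavelength grid must be a 1-D array")
    if w.size > 1 and not np.all(np.diff(w) > 0):
        raise InvalidSpectrumError("wavelength grid must be strictly increasing")
    return w


@dataclass
class Spectrum:
    """A real-valued spectrum on a strictly increasing wavelength grid.

    Parameters
    ----------
    wavelengths : array_like
        Vacuum wavelengths in nm, strictly increasing.
    values : array_like
        Same length as ``wavelengths``.
    kind : str
        One of the keys of :data:`KINDS`; fixes the units and, for
        ``transmittance`` and ``molar_extinction``, value-range invariants.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    kind: str = "generic"

    def __post_init__(self) -> None:
        self.wavelengths = _as_grid(self.wavelengths)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.wavelengths.shape:
            raise InvalidSpectrumError(
                f"values shape {self.values.shape} does not match "
                f"grid shape {self.wavelengths.shape}"
            )
        if self.kind not in KINDS:
            raise InvalidSpectrumError(f"unknown spectrum kind {self.kind!r}")
        if not np.all(np.isfinite(self.values)):
            raise InvalidSpectrumError("spectrum values must be finite")
        if self.kind == "transmittance":
            if np.any(self.values <= 0) or np.any(self.values > 1 + 1e-12):
                raise InvalidSpectrumError("transmittance values must lie in (0, 1]")
        if self.kind == "molar_extinction" and np.any(self.values < 0):
            raise InvalidSpectrumError("molar extinction coefficients must be >= 0")

    def __len__(self) -> int:
        return self.wavelengths.size

    # -- grid helpers -------------------------------------------------

    def same_grid(self, other: "Spectrum | ComplexRI") -> bool:
        return self.wavelengths.shape == other.wavelengths.shape and np.allclose(
            self.wavelengths, other.wavelengths, rtol=_GRID_RTOL, atol=0.0
        )

    def require_same_grid(self, other: "Spectrum | ComplexRI") -> None:
        if not self.same_grid(other):
            raise GridMismatchError("spectra are not defined on a common grid")

    def interp(self, wavelengths, kind: str | None = None) -> "Spectrum":
        """Linear interpolation onto a new grid (no extrapolation)."""
        w = _as_grid(wavelengths)
        if w[0] < self.wavelengths[0] - 1e-9 or w[-1] > self.wavelengths[-1] + 1e-9:
            raise GridMismatchError(
                f"requested grid [{w[0]:g}, {w[-1]:g}] nm exceeds the table range "
                f"[{self.wavelengths[0]:g}, {self.wavelengths[-1]:g}] nm"
            )
        v = np.interp(w, self.wavelengths, self.values)
        return Spectrum(w, v, kind or self.kind)

    def restrict(self, lo: float, hi: float) -> "Spectrum":
        """Restrict to wavelengths in [lo, hi] nm (inclusive)."""
        mask = (self.wavelengths >= lo - 1e-9) & (self.wavelengths <= hi + 1e-9)
        if not mask.any():
            raise GridMismatchError(f"no grid points inside [{lo}, {hi}] nm")
        return Spectrum(self.wavelengths[mask], self.values[mask], self.kind)

    def with_values(self, values, kind: str | None = None) -> "Spectrum":
        return Spectrum(self.wavelengths, values, kind or self.kind)


@dataclass
class ComplexRI:
    """Absolute complex refractive index n(lambda) + i*kappa(lambda).

    ``n`` must exceed 1 (aqueous protein systems over 300-800 nm) and the
    absorption index ``kappa`` must be non-negative (passive medium,
    exp(-i omega t) convention).
    """

    wavelengths: np.ndarray
    n: np.ndarray
    kappa: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = _as_grid(self.wavelengths)
        self.n = np.asarray(self.n, dtype=float)
        self.kappa = np.asarray(self.kappa, dtype=float)
        for name, arr in (("n", self.n), ("kappa", self.kappa)):
            if arr.shape != self.wavelengths.shape:
                raise InvalidSpectrumError(f"{name} does not match the grid shape")
            if not np.all(np.isfinite(arr)):
                raise InvalidSpectrumError(f"{name} must be finite")
        if np.any(self.n <= 1.0):
            raise InvalidSpectrumError("real RI must exceed 1 for aqueous systems")
        if np.any(self.kappa < -1e-15):
            raise InvalidSpectrumError("absorption index kappa must be >= 0")
        self.kappa = np.clip(self.kappa, 0.0, None)

    def __len__(self) -> int:
        return self.wavelengths.size

    @property
    def m(self) -> np.ndarray:
        """Complex refractive index as a complex array."""
        return self.n + 1j * self.kappa

    def same_grid(self, other: "Spectrum | ComplexRI") -> bool:
        return self.wavelengths.shape == other.wavelengths.shape and np.allclose(
            self.wavelengths, other.wavelengths, rtol=_GRID_RTOL, atol=0.0
        )
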