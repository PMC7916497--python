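"""Inversion of VSECS spectra to hemoglobin-state mass fractions.

The forward model composes the particle complex RI (superposition of the
oxy/deoxy/met increments), the Lorenz-Mie extinction of a sphere and the
log-normal ensemble average into Z_model(lambda; phi).  The measured
spectrum is inverted by least squares over the mass-fraction simplex,

    min_{phi, s}  sum_lambda (s Z_model(lambda; phi) - Z_meas(lambda))^2,

with an optional free global scale s (closed form per candidate) that
absorbs the systematic offset between measured and modelled Z (particle
loss, agglomeration, trapped packed volume).  A coarse simplex grid
search locates the basin; constrained local refinement (SLSQP) then
polishes the optimum.  The intra-particle concentrations beta_Hb and
beta_Gl/HSA are held fixed: they come from densitometry, not the fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .errors import GridMismatchError, InvalidParameterError
from .psd import LogNormalPSD, ensemble_vsecs
from .ri_model import (
    HbFractions,
    ParticleComposition,
    SpeciesOptics,
    particle_complex_ri,
    water_ri,
)
from .spectra import Spectrum


@dataclass
class FitResult:
    """Outcome of a composition fit."""

    fractions: HbFractions
    scale: float
    rss: float
    uncertainty_met: float
    ill_posed: bool = False

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise InvalidParameterError("scale must be positive")
        if self.rss < 0:
            raise InvalidParameterError("rss must be >= 0")


def simplex_grid(step: float = 0.025) -> np.ndarray:
    """All (phi_oxy, phi_deoxy, phi_met) on a regular simplex lattice."""
    n = int(round(1.0 / step))
    pts = []
    for i in range(n + 1):
        for j in range(n + 1 - i):
            k = n - i - j
            pts.append((i / n, j / n, k / n))
    return np.array(pts)


class ForwardModel:
    """Cached forward VSECS evaluator for fixed PSD, base composition, optics.

    Candidate spectra are memoised by their (rounded) fractions, so a grid
    search or repeated fits against the same configuration reuse every
    Mie evaluation.
    """

    def __init__(
        self,
        psd: LogNormalPSD,
        composition_base: ParticleComposition,
        optics: dict[str, SpeciesOptics],
        wavelengths,
        d_step: float = 10.0,
    ) -> None:
        self.psd = psd
        self.base = composition_base
        self.optics = optics
        self.wavelengths = np.atleast_1d(np.asarray(wavelengths, dtype=float))
        self.d_step = d_step
        self.n_medium = water_ri(self.wavelengths)
        self._cache: dict[tuple[int, int, int], np.ndarray] = {}

    def _key(self, fractions: HbFractions) -> tuple[int, int, int]:
        return tuple(int(round(p * 1e6)) for p in fractions.as_array())

    def vsecs(self, fractions: HbFractions) -> Spectrum:
        key = self._key(fractions)
        if key not in self._cache:
            comp = ParticleComposition(
                beta_hb=self.base.beta_hb,
                beta_glhsa=self.base.beta_glhsa,
                fractions=fractions,
            )
            ri = particle_complex_ri(comp, self.optics, self.wavelengths)
            z = ensemble_vsecs(self.psd, ri, self.n_medium, d_step=self.d_step)
            self._cache[key] = z.values
        return Spectrum(self.wavelengths, self._cache[key], "vsecs")


def forward_vsecs(
    fractions: HbFractions,
    psd: LogNormalPSD,
    composition_base: ParticleComposition,
    optics: dict[str, SpeciesOptics],
    wavelengths,
    d_step: float = 10.0,
) -> Spectrum:
    """Deterministic forward model: fractions -> Z(lambda) in um^-1."""
    model = ForwardModel(psd, composition_base, optics, wavelengths, d_step=d_step)
    return model.vsecs(fractions)


def _objective(z_model: np.ndarray, z_meas: np.ndarray, allow_scale: bool):
    """Return (rss, scale) with the closed-form optimal scale if allowed."""
    if allow_scale:
        denom = float(np.dot(z_model, z_model))
        s = float(np.dot(z_model, z_meas) / denom) if denom > 0 else 1.0
        s = max(s, 1e-12)
    else:
        s = 1.0
    resid = s * z_model - z_meas
    return float(np.dot(resid, resid)), s


def _clip_simplex(phi_d: float, phi_m: float) -> HbFractions:
    phi_d = min(max(phi_d, 0.0), 1.0)
    phi_m = min(max(phi_m, 0.0), 1.0)
    if phi_d + phi_m > 1.0:
        tot = phi_d + phi_m
        phi_d, phi_m = phi_d / tot, phi_m / tot
    return HbFractions(1.0 - phi_d - phi_m, phi_d, phi_m)


def _met_profile_curvature(
    model: ForwardModel, z_meas: np.ndarray, best: HbFractions,
    allow_scale: bool, delta: float = 0.02,
) -> float:
    """Second derivative of the RSS along the metHb direction.

    The probe moves phi_met while scaling the (oxy, deoxy) pair to keep
    their ratio fixed; central second difference over +-delta.
    """
    pm = best.phi_met

    def rss_at(pmx: float) -> float:
        pmx = min(max(pmx, 0.0), 1.0)
        rest = 1.0 - pmx
        tot = best.phi_oxy + best.phi_deoxy
        if tot <= 0:
            fr = HbFractions(rest, 0.0, pmx)
        else:
            fr = HbFractions(rest * best.phi_oxy / tot,
                             rest * best.phi_deoxy / tot, pmx)
        rss, _ = _objective(model.vsecs(fr).values, z_meas, allow_scale)
        return rss

    lo, hi = pm - delta, pm + delta
    if lo < 0:
        lo, pm_c, hi = 0.0, delta, 2 * delta
    elif hi > 1:
        lo, pm_c, hi = 1 - 2 * delta, 1 - delta, 1.0
    else:
        pm_c = pm
    f0, f1, f2 = rss_at(lo), rss_at(pm_c), rss_at(hi)
    return (f0 - 2 * f1 + f2) / delta**2


def fit_fractions(
    z_meas: Spectrum,
    psd: LogNormalPSD,
    composition_base: ParticleComposition,
    optics: dict[str, SpeciesOptics],
    allow_scale: bool = True,
    mode: str = "optimize",
    grid_step: float = 0.025,
    model: ForwardModel | None = None,
) -> FitResult:
    """Recover (phi_oxy, phi_deoxy, phi_met) from a measured Z spectrum.

    mode='grid' evaluates the forward model on a simplex lattice of the
    given step and returns the lattice minimiser; mode='optimize' (the
    default) additionally refines the lattice optimum with SLSQP under
    the simplex constraints.  Pass a shared :class:`ForwardModel` to
    amortise the lattice across repeated fits.

    The reported ``uncertainty_met`` is a local-curvature estimate: with
    sigma^2 estimated from the residuals, u = sqrt(2 sigma^2 / H) where H
    is the second derivative of the RSS along the metHb direction.
    """
    if mode not in ("grid", "optimize"):
        raise InvalidParameterError(f"unknown fit mode {mode!r}")
    if model is None:
        model = ForwardModel(psd, composition_base, optics, z_meas.wavelengths)
    elif not np.allclose(model.wavelengths, z_meas.wavelengths, rtol=1e-9, atol=0):
        raise GridMismatchError("measurement grid differs from the model grid")

    zm = z_meas.values
    candidates = simplex_grid(grid_step)
    best_rss, best_fr, best_scale = np.inf, None, 1.0
    rss_values = []
    for po, pd, pm in candidates:
        fr = HbFractions(po, pd, pm)
        rss, s = _objective(model.vsecs(fr).values, zm, allow_scale)
        rss_values.append(rss)
        if rss < best_rss:
            best_rss, best_fr, best_scale = rss, fr, s

    ill_posed = False
    spread = np.max(rss_values) - best_rss
    if spread <= 1e-12 * max(best_rss, 1.0):
        ill_posed = True  # objective flat over the whole simplex

    if mode == "optimize" and not ill_posed:
        def fun(theta):
            fr = _clip_simplex(theta[0], theta[1])
            rss, _ = _objective(model.vsecs(fr).values, zm, allow_scale)
            return rss

        x0 = np.array([best_fr.phi_deoxy, best_fr.phi_met])
        res = minimize(
            fun, x0, method="SLSQP",
            bounds=[(0.0, 1.0), (0.0, 1.0)],
            constraints=[{"type": "ineq",
                          "fun": lambda t: 1.0 - t[0] - t[1]}],
            # finite-difference step must exceed the forward cache rounding
            options={"maxiter": 60, "ftol": 1e-14, "eps": 1e-3},
        )
        if np.isfinite(res.fun) and res.fun <= best_rss + 1e-15:
            best_fr = _clip_simplex(res.x[0], res.x[1])
            best_rss, best_scale = _objective(
                model.vsecs(best_fr).values, zm, allow_scale
            )

    # curvature-based uncertainty of phi_met
    n_pts = zm.size
    n_par = 2 + (1 if allow_scale else 0)
    sigma2 = best_rss / max(n_pts - n_par, 1)
    curv = _met_profile_curvature(model, zm, best_fr, allow_scale)
    if curv > 0:
        u_met = float(np.sqrt(2.0 * sigma2 / curv))
    else:
        u_met, ill_posed = float("inf"), True

    return FitResult(
        fractions=best_fr,
        scale=best_scale if allow_scale else 1.0,
        rss=best_rss,
        uncertainty_met=u_met,
        ill_posed=ill_posed,
    )
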