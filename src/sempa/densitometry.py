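"""Density/PPV composition solver and concentration calculators.

High-accuracy densities of the stock suspension, its supernatant and the
diluent, together with literature density increments DI = d(rho)/d(beta)
of hemoglobin and of heme-free globin/HSA, decompose the suspension into
protein mass concentrations:

    rho_HbMP      = (rho_sus - rho_sup)/PPV + rho_sup
    beta_Gl/HSA^sus = (rho_sus - rho_RAc - DI_Hb beta_Hb^sus) / DI_Gl/HSA
    beta_Hb^sup   = (rho_sup - rho_RAc) / (DI_Hb + DI_Gl/HSA * ratio)
    beta_Hb^HbMP  = (beta_Hb^sus - (1-PPV) beta_Hb^sup) / PPV

The chain is evaluated without intermediate rounding; printed-table
agreement (e.g. 120.1 g/L Hb in the particles) only holds on the
unrounded chain.  Unit discipline: densities in g/mL, mass
concentrations beta in g/L; the factor 1000 enters exactly once, where a
density difference is converted to g/L.  The assumption that the
Gl/HSA-to-Hb ratio is the same in supernatant and particles is inherited
from the production process (most HSA is co-precipitated) and flagged in
:class:`CompositionResult`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError, ModelInconsistencyError

#: g/mL -> g/L conversion for density differences entering the beta balance.
_DENSITY_TO_GPL = 1000.0


@dataclass(frozen=True)
class DensityPanel:
    """Measured densities (g/mL), PPV and density increments of one batch."""

    rho_sus: float
    rho_sup: float
    rho_rac: float
    ppv: float
    di_hb: float
    di_glhsa: float

    def __post_init__(self) -> None:
        for name in ("rho_sus", "rho_sup", "rho_rac"):
            v = getattr(self, name)
            if not 0.9 < v < 1.2:
                raise InvalidParameterError(
                    f"{name} = {v} g/mL outside the plausible aqueous range"
                )
        if not 0 < self.ppv < 1:
            raise InvalidParameterError("PPV must lie in (0, 1)")
        for name in ("di_hb", "di_glhsa"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise InvalidParameterError(f"{name} must lie in (0, 1)")


@dataclass(frozen=True)
class AhdMeasurement:
    """One alkaline-haematin-detergent photometric reading.

    absorbance at 574 nm, path length in cm, dilution = volume fraction
    of the digested sample in the photometric cuvette.
    """

    absorbance: float
    epsilon_574: float = 6945.0
    molar_mass: float = 16114.5
    path_length: float = 1.0
    dilution: float = 1.0

    def __post_init__(self) -> None:
        if self.absorbance < 0:
            raise InvalidParameterError("absorbance must be >= 0")
        if not 0 < self.dilution <= 1:
            raise InvalidParameterError("dilution must lie in (0, 1]")
        if self.epsilon_574 <= 0 or self.molar_mass <= 0 or self.path_length <= 0:
            raise InvalidParameterError(
                "epsilon, molar mass and path length must be positive"
            )


def particle_density(panel: DensityPanel) -> float:
    """Ensemble density of the particles (g/mL)."""
    return (panel.rho_sus - panel.rho_sup) / panel.ppv + panel.rho_sup


def glhsa_in_suspension(panel: DensityPanel, beta_hb_sus: float) -> float:
    """Heme-free globin/HSA mass concentration in the stock (g/L)."""
    diff = (panel.rho_sus - panel.rho_rac) * _DENSITY_TO_GPL
    beta = (diff - panel.di_hb * beta_hb_sus) / panel.di_glhsa
    if beta < 0:
        raise ModelInconsistencyError(
            "density difference smaller than the Hb contribution alone: "
            f"beta_Gl/HSA would be {beta:.3f} g/L"
        )
    return beta


def hb_in_supernatant(panel: DensityPanel, ratio_glhsa_hb: float) -> float:
    """Hb mass concentration in the supernatant (g/L).

    ``ratio_glhsa_hb`` is the Gl/HSA-to-Hb mass ratio, assumed equal in
    the supernatant and the particles.
    """
    if ratio_glhsa_hb < 0:
        raise InvalidParameterError("Gl/HSA-to-Hb ratio must be >= 0")
    denom = panel.di_hb + panel.di_glhsa * ratio_glhsa_hb
    if denom == 0:
        raise InvalidParameterError("density-increment denominator is zero")
    return (panel.rho_sup - panel.rho_rac) * _DENSITY_TO_GPL / denom


def hb_in_particles(beta_hb_sus: float, beta_hb_sup: float, ppv: float) -> float:
    """Hb mass concentration inside the particles (g/L), from mass balance."""
    if ppv <= 0:
        raise InvalidParameterError("PPV must be positive")
    beta = (beta_hb_sus - (1.0 - ppv) * beta_hb_sup) / ppv
    if beta < 0:
        raise ModelInconsistencyError(
            f"mass balance yields negative intra-particle Hb ({beta:.3f} g/L)"
        )
    return beta


def particle_concentration(ppv: float, median_diameter_nm: float) -> float:
    """Stock particle concentration (pL^-1) from PPV and median diameter.

    C0 = PPV / ((4/3) pi (D/2)^3); 1 pL = 1e12 nm^3.
    """
    if median_diameter_nm <= 0:
        raise InvalidParameterError("diameter must be positive")
    vol_nm3 = 4.0 / 3.0 * np.pi * (median_diameter_nm / 2.0) ** 3
    return ppv / vol_nm3 * 1e12


def total_hb_ahd(measurements: AhdMeasurement | list[AhdMeasurement]) -> float:
    """Total Hb concentration (g/L) from AHD photometry.

    beta = A * M / (l * eps * phi) per dilution; a list of dilutions is
    combined by the uncertainty-weighted average assuming a common
    absorbance uncertainty, i.e. weights proportional to (l eps phi / M)^2.
    """
    if isinstance(measurements, AhdMeasurement):
        measurements = [measurements]
    if not measurements:
        raise InvalidParameterError("at least one AHD measurement is required")
    betas, weights = [], []
    for m in measurements:
        k = m.path_length * m.epsilon_574 * m.dilution / m.molar_mass
        betas.append(m.absorbance / k)
        weights.append(k * k)
    return float(np.average(betas, weights=weights))


@dataclass
class CompositionResult:
    """Full density-chain solution for one batch.

    ``assumes_equal_ratio`` flags the inherited assumption that the
    Gl/HSA-to-Hb ratio in the supernatant equals that in the particles.
    """

    rho_hbmp: float
    beta_glhsa_sus: float
    ratio_glhsa_hb: float
    beta_hb_sup: float
    beta_hb_hbmp: float
    beta_glhsa_hbmp: float
    assumes_equal_ratio: bool = True


def solve_composition(panel: DensityPanel, beta_hb_sus: float) -> CompositionResult:
    """Chained density-increment solve, all intermediates unrounded."""
    if beta_hb_sus <= 0:
        raise InvalidParameterError("total Hb concentration must be positive")
    beta_gl_sus = glhsa_in_suspension(panel, beta_hb_sus)
    ratio = beta_gl_sus / beta_hb_sus
    beta_hb_sup = hb_in_supernatant(panel, ratio)
    beta_hb_hbmp = hb_in_particles(beta_hb_sus, beta_hb_sup, panel.ppv)
    return CompositionResult(
        rho_hbmp=particle_density(panel),
        beta_glhsa_sus=beta_gl_sus,
        ratio_glhsa_hb=ratio,
        beta_hb_sup=beta_hb_sup,
        beta_hb_hbmp=beta_hb_hbmp,
        beta_glhsa_hbmp=ratio * beta_hb_hbmp,
    )


def functional_summary(
    beta_hb_hbmp: float, ratio_glhsa_hb: float, phi_met: float
) -> dict[str, float]:
    """Functional-Hb arithmetic for one batch.

    functional = (1 - phi_met) * beta_Hb^HbMP; the functional fraction is
    taken relative to the total protein content (Hb + Gl/HSA).
    """
    if not 0 <= phi_met <= 1:
        raise InvalidParameterError("phi_met must lie in [0, 1]")
    if ratio_glhsa_hb < 0 or beta_hb_hbmp < 0:
        raise InvalidParameterError("concentrations and ratio must be >= 0")
    functional = (1.0 - phi_met) * beta_hb_hbmp
    glhsa = ratio_glhsa_hb * beta_hb_hbmp
    total = beta_hb_hbmp + glhsa
    fraction = functional / total if total > 0 else 0.0
    return {
        "functional_hb_gL": functional,
        "functional_fraction": fraction,
        "glhsa_hbmp_gL": glhsa,
    }


def relative_nonfunctional(functional_meas: float, total_hb: float) -> float:
    """Relative non-functional Hb content in percent (reporting-rounded).

    100 * (1 - functional/total), rounded to the nearest integer percent
    as in the tabulated comparisons.
    """
    if total_hb == 0:
        raise InvalidParameterError("total Hb concentration is zero")
    if not 0 <= functional_meas <= total_hb:
        raise InvalidParameterError("functional Hb must lie in [0, total]")
    return float(round(100.0 * (1.0 - functional_meas / total_hb)))
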