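# sempa

**S**pectral **e**xtinction **m**easurement in **p**article suspensions and
**a**nalysis — quantifying the hemoglobin-state composition of hemoglobin
microparticles (HbMPs) from collimated transmittance spectra.

## The problem

HbMPs are ~750 nm cross-linked hemoglobin/albumin particles under development
as artificial oxygen carriers. Their clinical usefulness hinges on how much of
the hemoglobin is *functional* (ferrous oxyHb/deoxyHb, able to bind oxygen)
versus *non-functional* ferric metHb — but the standard blood-gas assays fail
for HbMPs: the particles cannot be lysed, and their light scattering corrupts
ordinary photometry. `sempa` implements an all-optical alternative for
scientists characterizing particle-based oxygen carriers: measure the
collimated transmittance T(λ) of a dilute suspension over 300–800 nm, convert
it to a volume-specific extinction cross section, and invert a Lorenz–Mie
forward model to obtain the mass fractions of oxyHb, deoxyHb and metHb.

## The model

From a transmittance measurement with cuvette path length ℓ, stock volume
fraction φ and packed particle volume PPV, the concentration-independent
**volume-specific extinction cross section** (VSECS) is

    Z(λ) = C̄_ext(λ) / V̄ = −ln T(λ) / (ℓ · PPV · φ)   [µm⁻¹]

The forward model predicts Z(λ) for any composition:

1. **Complex refractive index** of the particle as an aqueous protein
   solution:
   `n + iκ = n_H2O + β_Hb (α_Hb + iγ_Hb) + β_Gl/HSA (α_HSA + iγ_HSA)`,
   where the Hb increments are mass-fraction superpositions over the three
   states, γ_x(λ) = ln(10)·ε_x(λ)·λ/(4πM) links absorption to the imaginary
   increment, and real increments follow from subtractive Kramers–Kronig
   transforms.
2. **Lorenz–Mie extinction** C_ext(λ; D) of a homogeneous sphere in water
   (log-derivative downward recurrence, Wiscombe truncation).
3. **Ensemble average** over a log-normal size distribution p(D) with median
   μ_D and log-width σ_D, giving Z = ⟨C_ext⟩/⟨V⟩.

The inverse fit minimizes Σ_λ (s·Z_model − Z_meas)² over the
(φ_oxy, φ_deoxy, φ_met) simplex, with an optional free scale s absorbing the
systematic offset between measured and modelled spectra.

A companion **densitometry** module decomposes high-accuracy density
measurements (suspension, supernatant, diluent, density increments DI) into
the hemoglobin and heme-free globin/HSA content of the suspension and the
particles, and derives particle density and concentration from the PPV.

## Worked example

Solve the density-increment composition chain for the characterized batch
(densities in g/mL, β in g/L) and attach the functional-Hb summary for a
35 % metHb fraction:

```bash
sempa compose --beta-hb-sus 25.5 --phi-met 0.35
```

```json
{
  "result": {
    "rho_hbmp_g_per_mL": 1.0653143775100402,
    "beta_glhsa_sus_g_per_L": 27.714570858282688,
    "ratio_glhsa_hb": 1.0868459160110857,
    "beta_hb_sup_g_per_L": 1.971948445791906,
    "beta_hb_hbmp_g_per_L": 120.08465705125423,
    "beta_glhsa_hbmp_g_per_L": 130.51351909174747,
    "functional": {
      "functional_hb_gL": 78.05502708331525,
      "functional_fraction": 0.31147484105699885,
      "glhsa_hbmp_gL": 130.51351909174747
    }
  }
}
```

Reading the numbers: the particles have density 1.0653 g/mL; the stock
suspension carries 27.7 g/L heme-free globin/HSA against 25.5 g/L total Hb
(ratio 1.087); only 2.0 g/L of Hb sits in the supernatant, so the particles
themselves hold 120.1 g/L Hb — of which 78 g/L (31 % of the total particle
protein) is functional when 35 % of the Hb is metHb.

The optical pipeline runs the same way from files:

```bash
sempa synth --phi-met 0.35 --noise 0.01 --seed 42 --out run/   # synthetic T(λ)
sempa vsecs --series run/ --out run/z.csv                      # QC + Z(λ)
sempa fit --spectrum run/z.csv --allow-scale                   # φ_oxy/φ_deoxy/φ_met
```

or from Python:

```python
import numpy as np
from sempa import (HbFractions, ParticleComposition, fit_fractions,
                   forward_vsecs, lognormal_from_summary, SizeSummary,
                   default_species_optics)

psd = lognormal_from_summary(SizeSummary(median=760, width_16_84=395))
base = ParticleComposition(120.0, 130.0, HbFractions(1, 0, 0))
optics = default_species_optics()
w = np.arange(300.0, 801.0, 5.0)
z = forward_vsecs(HbFractions(0.65, 0.0, 0.35), psd, base, optics, w)
result = fit_fractions(z, psd, base, optics)
print(result.fractions.phi_met)   # 0.35
```

## Scope and caveats

- Particles are treated as optically homogeneous spheres; the host is pure
  water. The bundled species optics are Gaussian-band stand-ins for
  literature extinction tables (see `docs/methods.md`); real analyses should
  load measured increment tables via `sempa.io`.
- The PSD is an input (from DLS or analytical centrifugation), never fitted
  from the spectrum.
- β_Hb and β_Gl/HSA are fixed by densitometry during the spectral fit.
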