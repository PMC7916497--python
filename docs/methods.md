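# Methods

This note documents the model, the numerical choices and the limits of
validity of `sempa`, in the order data flows through the package.

## 1. Optical model of a hemoglobin microparticle

A particle is modelled as a homogeneous sphere of an aqueous protein
solution. Its complex refractive index is the host water RI plus linear
mass-concentration terms:

    n(λ) + iκ(λ) = n_H2O(λ) + β_Hb [α_Hb(λ) + iγ_Hb(λ)]
                            + β_Gl/HSA [α_HSA(λ) + iγ_HSA(λ)]

with β in g/mL against increments in mL/g (the package stores β in g/L and
converts at exactly one boundary). The hemoglobin increments are mass-
fraction superpositions of the oxy, deoxy and met states (simplex
constraint φ_oxy + φ_deoxy + φ_met = 1, enforced to 1e-9). The heme-free
component is modelled with HSA optics for both globin and HSA: the two
globular proteins have similar molar mass and no heme, so their increments
are expected to be nearly identical; the package keeps them as a single
`GlHSA` species.

**Imaginary increments.** γ_x(λ) = ln(10)·ε_x(λ)·λ/(4π·M) with ε in
L mol⁻¹ cm⁻¹ and M the monomer (per-heme) molar mass, 16114.5 g/mol for
hemoglobin. Unit audit: ε → 10³ cm²/mol, λ → cm gives γ in cm³/g = mL/g.
This is the only dimensionally consistent reading of the relation and it
reproduces the hand value γ(574 nm) = 4.533·10⁻³ mL/g for
ε = 6945 L mol⁻¹ cm⁻¹.

**Real increments by Kramers–Kronig.** Real increments that are not
directly measured are computed from imaginary ones by a *singly
subtractive* KK transform anchored to a reference:
α_target = α_ref + (2/π) P∫ ν′Δγ(ν′)/(ν′² − ν²) dν′ with Δγ = γ_target −
γ_ref and ν = 1/λ. The subtractive form makes the deep-UV/IR absorption
outside the tabulated window (which the integral cannot see) cancel
between target and reference. Numerics: trapezoid quadrature on the
wavenumber grid with pole subtraction — the regularized integrand
(g(ν′) − g(ν))/(ν′² − ν²), g = ν·Δγ, is finite at the pole (limit
g′(ν)/2ν, taken from a central difference) and the subtracted singular
term has a closed-form principal value. Inputs must extend ≥ 50 nm beyond
the 300–800 nm output window on both sides (warning, escalatable to an
error). Against the analytic Lorentz-oscillator pair the transform is
accurate to ~10⁻⁵ of the dispersion amplitude away from band centers on a
6000-point grid — three orders better than the 10⁻³ the tests require.

**Water RI.** One fixed empirical dispersion formula is used package-wide:
the four-term Sellmeier fit of Daimon & Masumura (2007) at 20 °C, valid
200–1100 nm. The density panel was measured at 23 °C; the 3 K offset
changes n by < 5·10⁻⁴, far below the sensitivity of the fit, so no
temperature correction is applied. The temperature is recorded as a module
constant, not a parameter.

## 2. Lorenz–Mie engine

Single-sphere extinction in a non-absorbing host (water over 300–800 nm):
relative index m = m_particle/n_medium, size parameter
x = πDn_medium/λ, C_ext = (2π/k²)Σ(2n+1)Re(aₙ+bₙ). Numerics follow the
standard stable scheme: Wiscombe truncation N = ⌈x + 4x^⅓ + 2⌉,
logarithmic derivative by downward recurrence started at N+15 from 0,
ψ/χ by upward recurrence. Supported size parameters: 0 < x ≤ 500.
Batched evaluation vectorizes over a (diameter × wavelength) grid with the
largest x in the batch setting the truncation; extra orders for smaller x
are negligible and numerically harmless in the regime the package handles
(in-batch x ratios well under 100 — beyond that the χ recurrence could
overflow, which is why the ensemble code batches per size-distribution
grid). The engine is verified against an independently coded series
(direct complex-order Bessel evaluation) to 10⁻⁸ relative and against the
Rayleigh dipole limit at x ≤ 0.01 to 1 %. Non-spherical particle shape is
deliberately ignored: for these particles its influence on extinction
spectra is negligible compared to composition effects.

## 3. Size distribution and ensemble averaging

Diameters follow a log-normal distribution with median μ_D and log-width
σ_D. Sizing instruments report (median, w) with w = Q(84 %) − Q(16 %);
the conversion uses the *exact* normal quantile z(0.84) = 0.994458, giving
σ_D = asinh(w/2μ_D)/z₈₄. This convention — not the common z = 1
approximation — is what reproduces the characterization values of the
studied batch (σ_D = 25.8 % from 760/395 nm DLS, 15.1 % from 996/300 nm
AC). DLS is the default size source; the AC preset is selectable.

⟨C_ext⟩ and ⟨V⟩ are computed on one shared equidistant diameter grid
spanning Q(0.1 %)–Q(99.9 %) at a 10 nm step (hard limit 20 nm), composite
trapezoid; using the same nodes for both integrals makes the PSD
truncation cancel in Z = ⟨C_ext⟩/⟨V⟩. Halving the step changes Z by less
than 10⁻⁴ relative. σ_D = 0 falls back to the single-sphere ratio.
⟨V⟩ agrees with the closed-form moment (π/6)μ³exp(4.5σ²) to 10⁻⁶.

Caveat: the DLS median is intensity-weighted but enters a number-weighted
PSD model unchanged. This follows the measurement protocol the package
mirrors, and is flagged here because it biases the effective size for
broad distributions.

## 4. Transmittance pipeline and QC

Conversions are exact Beer–Lambert forms (see README). Dilution-series
QC implements two rules: transmittance must stay ≥ 30 % over 300–800 nm
(below that, multiple scattering inflates the apparent transmission), and
the log-Z curve of a candidate must agree with the next-lower dilution up
to a constant shift — a pure shift corresponds to a pipetting volume
error, a shape change to multiple scattering. The shift-agreement
tolerance (2 % RMS after removing the mean log offset) is a package
choice; the underlying criterion is qualitative. Both thresholds are
configurable. The densest passing member is selected for its
signal-to-noise ratio. `rescale_to_reference` provides the closed-form
least-squares scale (in linear Z, over 300–800 nm) used to splice
measurements between which particle concentration changed (e.g. foaming
during gas exchange).

## 5. Composition fit

The fit minimizes the unweighted linear-Z residual over the fraction
simplex. Design choices, where the procedure was genuinely open:

- **Free global scale** (default on): measured Z sits systematically below
  the model (particle adhesion loss, agglomeration, trapped volume in the
  PPV), so a per-candidate closed-form scale s = Σ(Z_m Z)/ΣZ_m² absorbs
  the offset without touching the spectral shape that carries the
  composition information.
- **Grid-then-refine**: global search on a simplex lattice (step 0.025,
  861 candidates, memoised per model configuration) followed by SLSQP
  refinement of (φ_deoxy, φ_met) under bounds and φ_deoxy + φ_met ≤ 1.
  The SLSQP finite-difference step is 10⁻³, deliberately larger than the
  10⁻⁶ rounding of the forward-model cache keys.
- **β held fixed** at the densitometry values (default 120/130 g/L):
  jointly fitting concentrations and fractions is ill-conditioned against
  a free scale.
- **u(φ_met)**: local-curvature estimate u = √(2σ̂²/H) with σ̂² = RSS/(N−p)
  and H the second difference of the RSS profile along the metHb
  direction (±0.02, ratio of the other two fractions held). A degenerate
  flat objective or non-positive curvature sets `ill_posed` instead of
  fabricating a number. Monte-Carlo replication on synthetic data is the
  recommended check and is what the test suite does.

On noiseless synthetic spectra the fit recovers generating fractions to
< 0.01; with 1 % multiplicative photometric noise the recovered metHb
fraction scatters with a standard deviation ≈ 0.035, consistent with the
0.05 standard uncertainty quoted for the method on real spectra.

## 6. Densitometry

Closed-form solvers as listed in the README, with two commitments:

- **No intermediate rounding.** The chain Gl/HSA-in-suspension →
  Hb-in-supernatant → Hb-in-particles uses full-precision intermediates;
  rounding is applied only at the reporting layer. (The printed
  intra-particle value 120.1 g/L is only reproduced this way; rounding
  the supernatant step to 2.0 g/L first gives 120.0.)
- **Stated assumption carried in the result object**: the Gl/HSA-to-Hb
  ratio is taken to be equal in supernatant and particles, justified by
  the production process (most HSA is co-precipitated and cross-linked).
  `CompositionResult.assumes_equal_ratio` flags it.

The AHD total-Hb calculator combines dilutions by an uncertainty-weighted
average assuming a common absorbance uncertainty (weights ∝ (ℓεφ/M)²).
First-order uncertainty propagation of the printed standard uncertainties
is not implemented; the solvers are exact forms and the dominant
uncertainties enter through their inputs.

## 7. Synthetic data

The generator exists because neither extinction tables nor raw
transmittance spectra are deposited; it makes every stage testable and
defines the study conditions of the statistical tests.

- **Species optics**: Gaussian bands on a 250–850 nm grid (1 nm step).
  Band centers sit at the known signatures — oxyHb 413 (Soret), 543, 578;
  deoxyHb 430, 555; metHb 409, 500, 632; Gl/HSA only the 280 nm aromatic
  band. The deoxyHb 555 nm and metHb 500 nm bands are real features of
  those spectra and are included beyond the minimal signature set because
  the inter-band region (≈ 460–520 nm) otherwise carries almost no
  absorption: with them, the model reproduces the independently reported
  complex RI of the oxygenated batch at 488 nm (n ≈ 1.390,
  κ ≈ 3.6·10⁻⁴) within its tolerance. Amplitudes are per-heme with
  Soret ≈ 10× the Q bands; a flat 800 L mol⁻¹ cm⁻¹ baseline stands in for
  unresolved background absorption. α comes from the package's own KK
  transform anchored to a flat 0.20 mL/g reference — a typical protein
  refraction increment. These tables are *clearly non-authoritative*:
  band shapes are Gaussian rather than measured, so inter-band values are
  only order-of-magnitude correct. They are generated deterministically
  at run time (pure functions of the constants above, byte-reproducible)
  rather than shipped as files; `sempa.io` round-trips them as CSV for
  users who want to substitute literature tables.
- **Transmittance synthesis**: T = exp(−ℓ·PPV·φ·Z) with multiplicative
  log-normal noise on T (photometric noise; seed mandatory when σ > 0),
  clipped into (0, 1]. Noiseless synthesis round-trips through the VSECS
  conversion to 10⁻¹². Dilution series share one seeded stream; an
  optional constant stray-light term in the densest member emulates the
  shape distortion of multiple scattering for QC tests.

**What passing tests do and do not show.** Round-trip recovery on
synthetic spectra demonstrates the identifiability and conditioning of the
inversion *under the model's own assumptions* (homogeneous spheres, exact
PSD, Gaussian bands, multiplicative noise). It does not validate the
literature increment data, the sphericity approximation, or instrument
systematics on real cuvette spectra — those enter real analyses through
the user-supplied tables and the free scale factor.

## 8. Problem sizes and defaults

| Quantity | Default | Notes |
|---|---|---|
| Fit wavelength grid | 300–800 nm, 5 nm step | 101 points |
| Optics synthesis grid | 250–850 nm, 1 nm step | KK padding 50 nm |
| Diameter quadrature | Q(0.1 %)–Q(99.9 %), 10 nm step | ≤ 20 nm enforced |
| Simplex lattice step | 0.025 | 861 candidates, memoised |
| PSD (DLS preset) | μ_D = 760 nm, σ_D = 0.2585 | from (760, 395) nm |
| β_Hb / β_Gl/HSA | 120 / 130 g/L | densitometry values |
| Noise replicates in tests | 100 at σ = 1 % | sd(φ_met) ≤ 0.05 |

## 9. Known limitations

- Gaussian band models cannot reproduce true line shapes; fits of *real*
  spectra against the bundled fixtures would be biased. Use measured
  increment tables.
- The log-shift QC tolerance is calibrated for low-noise spectra; at 1 %
  photometric noise the red end of Z is noisy enough (δZ/Z ≈ σ/|ln T|)
  that the 2 % RMS rule would reject consistent dilutions. Raise the
  tolerance or restrict the QC window for noisy data.
- No carboxy- or sulf-hemoglobin species; no coated-sphere or T-matrix
  options; no PSD inference from spectra; no propagation of the density
  panel uncertainties.
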