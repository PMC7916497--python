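"""Characterization constants of the studied HbMP batch.

These are measured inputs of the analysis (densities, density
increments, packed particle volume, size-distribution summaries, total
Hb by AHD photometry), not fitted quantities.  They define the default
study conditions throughout the package; every function also accepts
user-supplied values.
"""

from .densitometry import DensityPanel
from .psd import SizeSummary

#: Density panel of the HbMP stock suspension at 23 deg C.
HBMP_PANEL = DensityPanel(
    rho_sus=1.01639,   # g/mL, stock suspension
    rho_sup=1.00422,   # g/mL, supernatant
    rho_rac=1.00320,   # g/mL, acetated Ringer's solution (diluent)
    ppv=0.1992,        # packed particle volume (solid fraction)
    di_hb=0.2450,      # density increment of bovine Hb
    di_glhsa=0.2505,   # density increment of the 1:1 Hb/HSA mixture proxy
)

#: Total Hb in the stock suspension by AHD photometry, g/L.
BETA_HB_SUS = 25.5

#: Size summaries (median, 16-84% width) in nm.
DLS_SUMMARY = SizeSummary(median=760.0, width_16_84=395.0)
AC_SUMMARY = SizeSummary(median=996.0, width_16_84=300.0)

#: Intra-particle protein concentrations used in the optical model, g/L.
BETA_HB_HBMP = 120.0
BETA_GLHSA_HBMP = 130.0

#: Cuvette path length of the transmittance setup, mm.
PATH_LENGTH_MM = 10.0

#: metHb mass fraction of the air-saturated batch from the spectral fit.
PHI_MET_OXY_BATCH = 0.35

SIZE_SUMMARIES = {"dls": DLS_SUMMARY, "ac": AC_SUMMARY}
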