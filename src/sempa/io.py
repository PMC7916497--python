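"""CSV/JSON readers and writers for spectra, optics tables and panels.

Dialects:

* transmittance CSV: columns ``wavelength_nm, transmittance``, with a
  JSON sidecar (same stem, ``.json``) carrying ``path_length_mm``,
  ``volume_fraction``, ``ppv`` and optionally
  ``stock_concentration_per_pL``;
* generic spectrum CSV: ``wavelength_nm, <value column>`` where the
  value column name encodes the kind (e.g. ``vsecs_per_um``);
* species optics CSV: ``wavelength_nm, alpha_ml_per_g, gamma_ml_per_g``;
* molar extinction CSV: ``wavelength_nm, epsilon_L_per_mol_cm``;
* density panel JSON: keys mirroring :class:`sempa.densitometry.DensityPanel`.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .densitometry import DensityPanel
from .errors import ConfigurationError
from .pipeline import TransmittanceMeasurement
from .ri_model import SpeciesOptics
from .spectra import Spectrum

_VALUE_COLUMNS = {
    "transmittance": "transmittance",
    "vsecs": "vsecs_per_um",
    "extinction_cross_section": "cext_um2",
    "molar_extinction": "epsilon_L_per_mol_cm",
    "ri_increment_real": "alpha_ml_per_g",
    "ri_increment_imag": "gamma_ml_per_g",
    "refractive_index": "n",
    "absorbance": "absorbance",
    "generic": "value",
}
_KIND_BY_COLUMN = {v: k for k, v in _VALUE_COLUMNS.items()}


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    col = _VALUE_COLUMNS[spectrum.kind]
    pd.DataFrame(
        {"wavelength_nm": spectrum.wavelengths, col: spectrum.values}
    ).to_csv(path, index=False)


def read_spectrum(path: str | Path, kind: str | None = None) -> Spectrum:
    df = pd.read_csv(path)
    if "wavelength_nm" not in df.columns:
        raise ConfigurationError(f"{path}: missing 'wavelength_nm' column")
    value_cols = [c for c in df.columns if c != "wavelength_nm"]
    if len(value_cols) != 1:
        raise ConfigurationError(f"{path}: expected exactly one value column")
    col = value_cols[0]
    inferred = kind or _KIND_BY_COLUMN.get(col, "generic")
    return Spectrum(df["wavelength_nm"].to_numpy(), df[col].to_numpy(), inferred)


def write_species_optics(optics: SpeciesOptics, path: str | Path) -> None:
    pd.DataFrame(
        {
            "wavelength_nm": optics.alpha.wavelengths,
            "alpha_ml_per_g": optics.alpha.values,
            "gamma_ml_per_g": optics.gamma.interp(optics.alpha.wavelengths).values,
        }
    ).to_csv(path, index=False)


def read_species_optics(
    path: str | Path, species: str, molar_mass: float
) -> SpeciesOptics:
    df = pd.read_csv(path)
    required = {"wavelength_nm", "alpha_ml_per_g", "gamma_ml_per_g"}
    if not required.issubset(df.columns):
        raise ConfigurationError(
            f"{path}: species optics CSV needs columns {sorted(required)}"
        )
    w = df["wavelength_nm"].to_numpy()
    return SpeciesOptics(
        species=species,
        alpha=Spectrum(w, df["alpha_ml_per_g"].to_numpy(), "ri_increment_real"),
        gamma=Spectrum(w, df["gamma_ml_per_g"].to_numpy(), "ri_increment_imag"),
        molar_mass=molar_mass,
    )


def write_measurement(
    m: TransmittanceMeasurement, csv_path: str | Path
) -> None:
    csv_path = Path(csv_path)
    write_spectrum(m.spectrum, csv_path)
    meta = {
        "path_length_mm": m.path_length,
        "volume_fraction": m.volume_fraction,
        "ppv": m.ppv,
    }
    if m.stock_concentration is not None:
        meta["stock_concentration_per_pL"] = m.stock_concentration
    csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_measurement(csv_path: str | Path) -> TransmittanceMeasurement:
    csv_path = Path(csv_path)
    sidecar = csv_path.with_suffix(".json")
    if not sidecar.exists():
        raise ConfigurationError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("path_length_mm", "volume_fraction", "ppv"):
        if key not in meta:
            raise ConfigurationError(f"{sidecar}: missing key {key!r}")
    return TransmittanceMeasurement(
        spectrum=read_spectrum(csv_path, kind="transmittance"),
        path_length=meta["path_length_mm"],
        volume_fraction=meta["volume_fraction"],
        ppv=meta["ppv"],
        stock_concentration=meta.get("stock_concentration_per_pL"),
        label=csv_path.stem,
    )


def read_density_panel(path: str | Path) -> DensityPanel:
    data = json.loads(Path(path).read_text())
    try:
        return DensityPanel(
            rho_sus=data["rho_sus"],
            rho_sup=data["rho_sup"],
            rho_rac=data["rho_rac"],
            ppv=data["ppv"],
            di_hb=data["di_hb"],
            di_glhsa=data["di_glhsa"],
        )
    except KeyError as exc:
        raise ConfigurationError(f"{path}: missing panel key {exc}") from exc


def write_density_panel(panel: DensityPanel, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "rho_sus": panel.rho_sus,
                "rho_sup": panel.rho_sup,
                "rho_rac": panel.rho_rac,
                "ppv": panel.ppv,
                "di_hb": panel.di_hb,
                "di_glhsa": panel.di_glhsa,
            },
            indent=2,
        )
    )
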