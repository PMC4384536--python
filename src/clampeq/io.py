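"""CSV dialects for thermograms, DLS series and emission spectra.

All files are UTF-8 with a mandatory header row:

* thermogram (observed): ``injection,volume_uL,heat_ucal``; emitted files
  additionally carry ``molar_ratio,ndh_kcal_per_mol``;
* DLS: ``conc_uM,radius_nm[,radius_sd_nm]``;
* spectrum: ``wavelength_nm,intensity``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dls import DLSSeries
from .fret import EmissionSpectrum
from .itc import Thermogram, TitrationExperiment, _all_concentrations

__all__ = [
    "SchemaError",
    "read_thermogram",
    "write_thermogram",
    "read_dls_series",
    "write_dls_series",
    "read_spectrum",
    "write_spectrum",
]


class SchemaError(ValueError):
    """An input CSV is missing a required column or holds bad values."""


def _require(df: pd.DataFrame, columns: list[str], path) -> None:
    for col in columns:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column '{col}'")


def read_thermogram(path, experiment: TitrationExperiment) -> Thermogram:
    """Load observed heats; molar ratios and NDH are derived from the
    experiment geometry (the file's injection volumes must match it)."""
    df = pd.read_csv(path)
    _require(df, ["injection", "volume_uL", "heat_ucal"], path)
    df = df.sort_values("injection")
    vols = df["volume_uL"].to_numpy(float) * 1e-6
    if len(vols) != experiment.n_injections or not np.allclose(
        vols, experiment.injection_volumes, rtol=1e-6
    ):
        raise SchemaError(
            f"{path}: column 'volume_uL' disagrees with the experiment's "
            "injection schedule"
        )
    heats = df["heat_ucal"].to_numpy(float)
    if not np.all(np.isfinite(heats)):
        raise SchemaError(f"{path}: column 'heat_ucal' contains non-finite values")
    mt, xt = _all_concentrations(experiment)
    moles = experiment.syringe_concentration * vols
    return Thermogram(
        molar_ratios=xt / mt,
        injection_heats=heats,
        normalized_heats=(heats / 1e9) / moles,
    )


def write_thermogram(path, thermogram: Thermogram, experiment: TitrationExperiment) -> None:
    df = pd.DataFrame(
        {
            "injection": np.arange(1, len(thermogram) + 1),
            "volume_uL": np.asarray(experiment.injection_volumes) * 1e6,
            "heat_ucal": thermogram.injection_heats,
            "molar_ratio": thermogram.molar_ratios,
            "ndh_kcal_per_mol": thermogram.normalized_heats,
        }
    )
    df.to_csv(path, index=False)


def read_dls_series(path) -> DLSSeries:
    df = pd.read_csv(path)
    _require(df, ["conc_uM", "radius_nm"], path)
    sd = df["radius_sd_nm"].to_numpy(float) if "radius_sd_nm" in df.columns else None
    return DLSSeries(
        concentrations=df["conc_uM"].to_numpy(float) * 1e-6,
        radii=df["radius_nm"].to_numpy(float),
        radius_sd=sd,
    )


def write_dls_series(path, series: DLSSeries) -> None:
    series.to_frame().to_csv(path, index=False)


def read_spectrum(path) -> EmissionSpectrum:
    df = pd.read_csv(path)
    _require(df, ["wavelength_nm", "intensity"], path)
    return EmissionSpectrum(
        wavelengths=df["wavelength_nm"].to_numpy(float),
        intensities=df["intensity"].to_numpy(float),
    )


def write_spectrum(path, spectrum: EmissionSpectrum) -> None:
    pd.DataFrame(
        {"wavelength_nm": spectrum.wavelengths, "intensity": spectrum.intensities}
    ).to_csv(path, index=False)
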