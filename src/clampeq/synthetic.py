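"""Seeded synthetic-data generators emulating the three instruments.

Each generator forward-simulates the corresponding physical model and adds
instrument-like noise:

* ``gen_itc`` — one- or two-site titration thermograms with additive
  Gaussian noise on normalized heats (sd expressed as a fraction of |dH|),
  the dominant error of integrated injection peaks;
* ``gen_dls`` — radius-vs-concentration series with multiplicative Gaussian
  noise on radii;
* ``gen_spectra`` — a Gaussian donor emission band on a 410-600 nm grid and
  its acceptor-quenched counterpart at a target FRET efficiency.

Determinism: every call derives its random stream from (seed, operation
name), so generators never share or consume each other's state and the same
config reproduces the same data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dls import DLSSeries, OligomerModel, predict_radius_curve
from .equilibria import BindingParameters, InvalidParameterError
from .fret import EmissionSpectrum
from .itc import (
    Thermogram,
    TitrationExperiment,
    TwoSiteParameters,
    simulate_thermogram,
    simulate_two_site_thermogram,
)

__all__ = ["GeneratorConfig", "gen_itc", "gen_dls", "gen_spectra"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Seeded noise configuration shared by all generators."""

    seed: int = 0
    noise_fraction: float = 0.02
    replicate_count: int = 1

    def __post_init__(self) -> None:
        if self.noise_fraction < 0:
            raise InvalidParameterError("noise_fraction must be >= 0")
        if self.replicate_count < 1:
            raise InvalidParameterError("replicate_count must be >= 1")

    def rng(self, operation: str) -> np.random.Generator:
        """Independent stream per (seed, operation)."""
        digest = int.from_bytes(operation.encode(), "little") % (2**32)
        return np.random.default_rng([int(self.seed) % (2**31), digest])


def gen_itc(
    exp: TitrationExperiment,
    params: BindingParameters | TwoSiteParameters,
    cfg: GeneratorConfig,
) -> list[Thermogram]:
    """Simulated thermogram replicates with noise on normalized heats.

    The noise sd is ``noise_fraction * |dH|`` in kcal/mol of injectant
    (for a two-site model, the larger |dH| of the two classes).  Injection
    heats are back-computed from the noisy normalized heats so the two
    representations stay consistent.
    """
    if isinstance(params, TwoSiteParameters):
        clean = simulate_two_site_thermogram(exp, params)
        dh_scale = max(abs(params.site_cen.enthalpy), abs(params.site_acc.enthalpy))
    else:
        clean = simulate_thermogram(exp, params)
        dh_scale = abs(params.enthalpy)
    rng = cfg.rng("gen_itc")
    sd = cfg.noise_fraction * dh_scale
    moles = exp.syringe_concentration * np.asarray(exp.injection_volumes, float)
    out = []
    for _ in range(cfg.replicate_count):
        ndh = clean.normalized_heats + rng.normal(0.0, sd, size=len(clean))
        out.append(
            Thermogram(
                molar_ratios=clean.molar_ratios,
                injection_heats=ndh * moles * 1e9,
                normalized_heats=ndh,
            )
        )
    return out


def gen_dls(
    model: OligomerModel,
    concentrations,
    cfg: GeneratorConfig,
) -> list[DLSSeries]:
    """Radius series replicates with multiplicative Gaussian noise on radii."""
    clean = predict_radius_curve(model, np.asarray(concentrations, float))
    rng = cfg.rng("gen_dls")
    out = []
    for _ in range(cfg.replicate_count):
        factor = 1.0 + rng.normal(0.0, cfg.noise_fraction, size=len(clean))
        out.append(
            DLSSeries(
                concentrations=clean.concentrations,
                radii=clean.radii * factor,
            )
        )
    return out


#: Default concentration panel (M): spans the 25-50 uM oligomerization regime.
DEFAULT_DLS_CONCENTRATIONS = (5e-6, 10e-6, 25e-6, 50e-6, 100e-6)


def gen_spectra(
    target_efficiency: float,
    cfg: GeneratorConfig,
    band_center: float = 440.0,
    band_width: float = 18.0,
    amplitude: float = 1000.0,
) -> tuple[EmissionSpectrum, EmissionSpectrum]:
    """Donor-only and donor-acceptor emission spectra at a target efficiency.

    A Gaussian donor band (default centered at 440 nm, sd 18 nm) is laid on
    a 1-nm grid over 410-600 nm; the donor-acceptor trace is the same band
    scaled by (1 - E), so the band-integral ratio encodes the efficiency
    exactly.  Additive noise sd is ``noise_fraction * amplitude``.
    """
    if not 0.0 <= target_efficiency < 1.0:
        raise InvalidParameterError("target_efficiency must lie in [0, 1)")
    rng = cfg.rng("gen_spectra")
    wl = np.arange(410.0, 600.0 + 1.0, 1.0)
    band = amplitude * np.exp(-0.5 * ((wl - band_center) / band_width) ** 2)
    noise_sd = cfg.noise_fraction * amplitude
    donor = band + rng.normal(0.0, noise_sd, size=len(wl))
    quenched = (1.0 - target_efficiency) * band + rng.normal(
        0.0, noise_sd, size=len(wl)
    )
    return (
        EmissionSpectrum(wavelengths=wl, intensities=donor),
        EmissionSpectrum(wavelengths=wl, intensities=quenched),
    )
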