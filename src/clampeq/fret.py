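"""FRET efficiency and distance from donor-quenching fluorescence.

The energy-transfer efficiency is measured as the fractional loss of donor
emission when the acceptor is present,

    E = 1 - integral(F_DA) / integral(F_D)

over a wavelength window covering the donor band, and converted into the
donor-acceptor distance through the Forster relation

    E = 1 / (1 + (r/R0)^6)   <=>   r = R0 * (1/E - 1)^(1/6),

where R0 is the 50%-efficiency distance of the dye pair (e.g. ~27 A for
stilbene/bimane, ~38 A for bimane/Oregon Green).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .equilibria import InvalidParameterError

__all__ = [
    "FretPair",
    "EmissionSpectrum",
    "efficiency_from_donor_quenching",
    "distance_from_efficiency",
    "efficiency_from_distance",
    "DEFAULT_INTEGRATION_WINDOW",
]

#: Default donor-band window (nm): the bimane emission band inside a
#: 410-600 nm scan.
DEFAULT_INTEGRATION_WINDOW = (410.0, 470.0)


@dataclass(frozen=True)
class FretPair:
    """A donor/acceptor dye pair characterized by its Forster radius (A)."""

    forster_radius: float
    donor_name: str = "donor"
    acceptor_name: str = "acceptor"

    def __post_init__(self) -> None:
        if self.forster_radius <= 0:
            raise InvalidParameterError("forster_radius must be positive")


@dataclass(frozen=True)
class EmissionSpectrum:
    """Fluorescence emission trace: wavelengths (nm, ascending) vs intensity."""

    wavelengths: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, float)
        it = np.asarray(self.intensities, float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensities", it)
        if len(wl) != len(it):
            raise InvalidParameterError("wavelengths/intensities length mismatch")
        if np.any(np.diff(wl) <= 0):
            raise InvalidParameterError("wavelengths must be strictly increasing")

    def integrate(self, window: tuple[float, float]) -> float:
        """Trapezoidal band area within [window[0], window[1]] nm."""
        lo, hi = window
        mask = (self.wavelengths >= lo) & (self.wavelengths <= hi)
        if mask.sum() < 2:
            raise InvalidParameterError("integration window contains <2 samples")
        return float(np.trapezoid(self.intensities[mask], self.wavelengths[mask]))


def efficiency_from_donor_quenching(
    donor_only: EmissionSpectrum,
    donor_acceptor: EmissionSpectrum,
    integration_window: tuple[float, float] = DEFAULT_INTEGRATION_WINDOW,
) -> float:
    """FRET efficiency from the quenching of the donor band.

    Both spectra must share the wavelength grid inside the window
    (resampling is refused rather than silently interpolated).  The
    reported value is clamped to [0, 1]; raw values outside that range
    (noise) are clamped without error.
    """
    lo, hi = integration_window
    m1 = (donor_only.wavelengths >= lo) & (donor_only.wavelengths <= hi)
    m2 = (donor_acceptor.wavelengths >= lo) & (donor_acceptor.wavelengths <= hi)
    if m1.sum() != m2.sum() or not np.allclose(
        donor_only.wavelengths[m1], donor_acceptor.wavelengths[m2]
    ):
        raise InvalidParameterError(
            "spectra are on different wavelength grids within the window; "
            "resample before computing an efficiency"
        )
    fd = donor_only.integrate(integration_window)
    if fd <= 0:
        raise InvalidParameterError("donor-only band integral must be positive")
    fda = donor_acceptor.integrate(integration_window)
    return float(np.clip(1.0 - fda / fd, 0.0, 1.0))


def distance_from_efficiency(e: float, pair: FretPair) -> float:
    """Donor-acceptor distance (A) from efficiency: r = R0 (1/E - 1)^(1/6)."""
    if not 0.0 < e < 1.0:
        raise InvalidParameterError(
            f"efficiency must lie strictly in (0, 1); got {e}"
        )
    return pair.forster_radius * (1.0 / e - 1.0) ** (1.0 / 6.0)


def efficiency_from_distance(r: float, pair: FretPair) -> float:
    """Inverse of :func:`distance_from_efficiency`: E = 1/(1 + (r/R0)^6)."""
    if r <= 0:
        raise InvalidParameterError("distance must be positive")
    return 1.0 / (1.0 + (r / pair.forster_radius) ** 6)
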