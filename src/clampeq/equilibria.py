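"""Closed-form binding equilibria and thermodynamic conversions.

Every other analysis in the package (ITC isotherms, the DLS oligomer model,
saturation arguments) reduces to one of two mass-balance problems solved
here in closed form:

* the heterodimerization quadratic for a receptor R and ligand L forming a
  1:1 complex with dissociation constant ``Kd``, and
* the self-association quadratic for a species whose associable interface
  binds an identical partner (``[free]^2 = Kd * [bound]``).

Energies follow the calorimetric convention: kcal/mol throughout, with the
gas constant R = 1.987e-3 kcal mol^-1 K^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GAS_CONSTANT_KCAL",
    "DEFAULT_TEMPERATURE",
    "BindingParameters",
    "ThermodynamicState",
    "thermodynamics_from_affinity",
    "hetero_bound_concentration",
    "saturation_percent",
    "self_association_bound",
]

#: Gas constant in kcal mol^-1 K^-1 (Origin/Microcal convention).
GAS_CONSTANT_KCAL = 1.987e-3

#: Default temperature (25 degC) used wherever an experiment does not state one.
DEFAULT_TEMPERATURE = 298.15


class InvalidParameterError(ValueError):
    """A physically meaningless parameter (non-positive Kd, negative total...)."""


@dataclass(frozen=True)
class BindingParameters:
    """Thermodynamic description of one class of binding sites.

    Parameters
    ----------
    dissociation_constant : float
        Kd in molar units; must be positive.
    enthalpy : float
        Molar binding enthalpy dH in kcal/mol (exothermic binding is negative).
    stoichiometry : float
        Sites per macromolecule, n.
    temperature : float
        Kelvin.
    """

    dissociation_constant: float
    enthalpy: float = 0.0
    stoichiometry: float = 1.0
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if not self.dissociation_constant > 0:
            raise InvalidParameterError(
                f"dissociation_constant must be > 0, got {self.dissociation_constant}"
            )
        if not self.stoichiometry > 0:
            raise InvalidParameterError(
                f"stoichiometry must be > 0, got {self.stoichiometry}"
            )
        if not self.temperature > 0:
            raise InvalidParameterError(
                f"temperature must be > 0 K, got {self.temperature}"
            )

    @property
    def association_constant(self) -> float:
        """Ka = 1/Kd in M^-1."""
        return 1.0 / self.dissociation_constant


@dataclass(frozen=True)
class ThermodynamicState:
    """Free energy decomposition dG = dH - TdS, all in kcal/mol."""

    free_energy: float
    enthalpy: float
    entropy_term: float = field(default=0.0)

    def __post_init__(self) -> None:
        # dG = dH - TdS holds by construction; recompute to guard callers
        # building the state by hand.
        if not math.isclose(
            self.free_energy, self.enthalpy - self.entropy_term, rel_tol=1e-9, abs_tol=1e-12
        ):
            raise InvalidParameterError(
                "free_energy must equal enthalpy - entropy_term"
            )


def thermodynamics_from_affinity(params: BindingParameters) -> ThermodynamicState:
    """Convert an affinity into the free-energy decomposition.

    dG = -R*T*ln(Ka) and TdS = dH - dG, with R = 1.987e-3 kcal/mol/K.

    Examples
    --------
    >>> st = thermodynamics_from_affinity(BindingParameters(1e-6))
    >>> round(st.free_energy, 2)
    -8.18
    """
    dg = -GAS_CONSTANT_KCAL * params.temperature * math.log(params.association_constant)
    return ThermodynamicState(
        free_energy=dg, enthalpy=params.enthalpy, entropy_term=params.enthalpy - dg
    )


def hetero_bound_concentration(receptor_total, ligand_total, kd):
    """Equilibrium 1:1 complex concentration [RL] from total R, L and Kd.

    Solves [RL]^2 - (R+L+Kd)[RL] + R*L = 0 on the physical branch using the
    conjugate (citardauq) form, which is numerically stable when
    (R+L+Kd)^2 >> 4RL.

    All concentrations in M. Accepts scalars or arrays (broadcast).
    """
    r = np.asarray(receptor_total, dtype=float)
    l = np.asarray(ligand_total, dtype=float)
    k = np.asarray(kd, dtype=float)
    if np.any(r < 0) or np.any(l < 0):
        raise InvalidParameterError("totals must be non-negative")
    if np.any(k <= 0):
        raise InvalidParameterError("kd must be positive")
    s = r + l + k
    disc = np.sqrt(np.maximum(s * s - 4.0 * r * l, 0.0))
    # conjugate form: 2RL / (s + sqrt(disc)) avoids cancellation for RL << s^2
    with np.errstate(invalid="ignore", divide="ignore"):
        bound = np.where(s + disc > 0, 2.0 * r * l / (s + disc), 0.0)
    if bound.ndim == 0:
        return float(bound)
    return bound


def saturation_percent(receptor_total, excess_fold, kd):
    """Percent receptor occupancy when the ligand is an ``excess_fold`` molar excess.

    100 * [RL]/R with L = excess_fold * R.  Strictly increasing in
    ``excess_fold`` and in R/Kd; 0 at zero excess, -> 100 as Kd -> 0.
    """
    ex = np.asarray(excess_fold, dtype=float)
    if np.any(ex < 0):
        raise InvalidParameterError("excess_fold must be non-negative")
    r = np.asarray(receptor_total, dtype=float)
    bound = hetero_bound_concentration(r, ex * r, kd)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(r > 0, bound / np.where(r > 0, r, 1.0), 0.0)
    out = 100.0 * frac
    if np.ndim(out) == 0:
        return float(out)
    return out


def self_association_bound(c_initial, kd):
    """Split a total concentration into (unbound, bound) for self-association.

    The associable unit obeys [unbound]^2 = Kd*[bound] with
    [unbound] + [bound] = C, giving

        unbound = Kd*(sqrt(1 + 4C/Kd) - 1)/2,  bound = C - unbound.

    Returns a pair (unbound, bound); conservation unbound + bound = C is
    exact by construction.
    """
    c = np.asarray(c_initial, dtype=float)
    k = np.asarray(kd, dtype=float)
    if np.any(c < 0):
        raise InvalidParameterError("c_initial must be non-negative")
    if np.any(k <= 0):
        raise InvalidParameterError("kd must be positive")
    unbound = 0.5 * k * (np.sqrt(1.0 + 4.0 * c / k) - 1.0)
    unbound = np.minimum(unbound, c)
    bound = c - unbound
    if c.ndim == 0 and k.ndim == 0:
        return float(unbound), float(bound)
    return unbound, bound
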