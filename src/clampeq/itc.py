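"""Isothermal titration calorimetry: thermogram simulation and fitting.

The forward model is the classical single-class-of-sites (Wiseman) isotherm
used by the Microcal Origin software: after injection *i* the cumulative
heat in the cell is

    Q(i) = n Mt dH V0 / 2 * [ 1 + Xt/(n Mt) + 1/(n Ka Mt)
                              - sqrt((1 + Xt/(n Mt) + 1/(n Ka Mt))^2
                                     - 4 Xt/(n Mt)) ]

with Mt, Xt the macromolecule and titrant totals in the cell after the
standard perfusion displacement correction, and the per-injection heat

    dQ(i) = Q(i) + (dVi/V0) * (Q(i) + Q(i-1))/2 - Q(i-1).

A two-independent-site-classes generalization (free-ligand mass balance
solved numerically per injection) models bivalent titrants such as a
complexin engaging both its central- and accessory-helix sites.

Fitting follows the statsmodels convention: build a model object from a
``Thermogram`` plus its ``TitrationExperiment``, call :meth:`fit`, and read
estimates, standard errors and derived thermodynamics off the results
object.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .equilibria import (
    DEFAULT_TEMPERATURE,
    BindingParameters,
    InvalidParameterError,
    ThermodynamicState,
    thermodynamics_from_affinity,
)

__all__ = [
    "TitrationExperiment",
    "Thermogram",
    "TwoSiteParameters",
    "concentrations_after_injection",
    "one_site_cumulative_heat",
    "simulate_thermogram",
    "simulate_two_site_thermogram",
    "fit_one_site",
    "fold_change",
    "OneSiteBindingModel",
    "TwoSiteBindingModel",
    "BindingFitResults",
]

KCAL_TO_UCAL = 1e9


@dataclass(frozen=True)
class TitrationExperiment:
    """Geometry of a titration: cell, syringe and injection schedule.

    Volumes in litres, concentrations in M.  ``discard_first`` marks the
    customary small pre-injection whose heat is excluded from fits.
    """

    cell_volume: float
    cell_concentration_initial: float
    syringe_concentration: float
    injection_volumes: tuple = ()
    temperature: float = DEFAULT_TEMPERATURE
    discard_first: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "injection_volumes", tuple(self.injection_volumes))
        if self.cell_volume <= 0:
            raise InvalidParameterError("cell_volume must be positive")
        if self.cell_concentration_initial <= 0 or self.syringe_concentration <= 0:
            raise InvalidParameterError("concentrations must be positive")
        if any(v <= 0 for v in self.injection_volumes):
            raise InvalidParameterError("injection volumes must be positive")
        if sum(self.injection_volumes) >= self.cell_volume:
            warnings.warn(
                "cumulative injected volume reaches the cell volume; the "
                "perfusion correction is unreliable in this regime",
                stacklevel=2,
            )

    @classmethod
    def standard(
        cls,
        cell_concentration: float,
        syringe_concentration: float,
        n_injections: int = 20,
        injection_volume: float = 2e-6,
        cell_volume: float = 200e-6,
        first_injection_volume: float | None = 0.4e-6,
        temperature: float = DEFAULT_TEMPERATURE,
    ) -> "TitrationExperiment":
        """A typical ITC200 run: 200 uL cell, 20 x 2 uL injections after an
        optional small discarded first injection."""
        vols = [injection_volume] * n_injections
        discard = first_injection_volume is not None
        if discard:
            vols = [first_injection_volume] + vols
        return cls(
            cell_volume=cell_volume,
            cell_concentration_initial=cell_concentration,
            syringe_concentration=syringe_concentration,
            injection_volumes=tuple(vols),
            temperature=temperature,
            discard_first=discard,
        )

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes)

    def cumulative_volumes(self) -> np.ndarray:
        return np.cumsum(np.asarray(self.injection_volumes, dtype=float))


@dataclass(frozen=True)
class Thermogram:
    """Per-injection integrated heats of a titration.

    ``injection_heats`` are in ucal; ``normalized_heats`` (NDH) are
    kcal per mole of injectant, the quantity plotted against
    ``molar_ratios`` (cumulative titrant over macromolecule in the cell).
    """

    molar_ratios: np.ndarray
    injection_heats: np.ndarray
    normalized_heats: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "molar_ratios", np.asarray(self.molar_ratios, float))
        object.__setattr__(self, "injection_heats", np.asarray(self.injection_heats, float))
        object.__setattr__(self, "normalized_heats", np.asarray(self.normalized_heats, float))
        n = len(self.molar_ratios)
        if len(self.injection_heats) != n or len(self.normalized_heats) != n:
            raise InvalidParameterError("thermogram arrays must have equal length")

    def __len__(self) -> int:
        return len(self.molar_ratios)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "injection": np.arange(1, len(self) + 1),
                "molar_ratio": self.molar_ratios,
                "heat_ucal": self.injection_heats,
                "ndh_kcal_per_mol": self.normalized_heats,
            }
        )


@dataclass(frozen=True)
class TwoSiteParameters:
    """Two independent classes of sites, e.g. central- and accessory-helix
    interactions of a bivalent complexin with a bivalent SNARE complex."""

    site_cen: BindingParameters
    site_acc: BindingParameters


def concentrations_after_injection(exp: TitrationExperiment, index: int):
    """Totals (Mt, Xt) in the cell after injection ``index`` (0-based).

    Applies the Origin perfusion displacement correction with v the
    cumulative injected volume:

        Mt = M0 (1 - v/2V0)/(1 + v/2V0),   Xt = X0 (v/V0)/(1 + v/2V0).
    """
    if not 0 <= index < exp.n_injections:
        raise IndexError(f"injection index {index} out of range")
    v = float(exp.cumulative_volumes()[index])
    v0 = exp.cell_volume
    d = 1.0 + v / (2.0 * v0)
    mt = exp.cell_concentration_initial * (1.0 - v / (2.0 * v0)) / d
    xt = exp.syringe_concentration * (v / v0) / d
    return mt, xt


def _all_concentrations(exp: TitrationExperiment):
    v = exp.cumulative_volumes()
    v0 = exp.cell_volume
    d = 1.0 + v / (2.0 * v0)
    mt = exp.cell_concentration_initial * (1.0 - v / (2.0 * v0)) / d
    xt = exp.syringe_concentration * (v / v0) / d
    return mt, xt


def one_site_cumulative_heat(
    params: BindingParameters, mt: float, xt: float, cell_volume: float
):
    """Cumulative heat Q (ucal) in the cell for the one-set-of-sites model."""
    if np.any(np.asarray(mt) <= 0) or np.any(np.asarray(xt) < 0) or cell_volume <= 0:
        raise InvalidParameterError("mt, cell_volume must be positive; xt non-negative")
    n = params.stoichiometry
    ka = params.association_constant
    mt = np.asarray(mt, float)
    xt = np.asarray(xt, float)
    a = 1.0 + xt / (n * mt) + 1.0 / (n * ka * mt)
    disc = a * a - 4.0 * xt / (n * mt)
    if np.any(disc < -1e-12):
        raise ArithmeticError("negative discriminant in one-site isotherm")
    q_kcal = (
        n * mt * params.enthalpy * cell_volume / 2.0
        * (a - np.sqrt(np.maximum(disc, 0.0)))
    )
    out = q_kcal * KCAL_TO_UCAL
    if out.ndim == 0:
        return float(out)
    return out


def _differential_heats(q: np.ndarray, exp: TitrationExperiment) -> np.ndarray:
    """Per-injection heats from cumulative heats, with the displacement term
    dQ(i) = Q(i) + (dVi/V0)(Q(i)+Q(i-1))/2 - Q(i-1)."""
    dvi = np.asarray(exp.injection_volumes, float)
    q_prev = np.concatenate([[0.0], q[:-1]])
    return q + (dvi / exp.cell_volume) * (q + q_prev) / 2.0 - q_prev


def _assemble_thermogram(q_ucal: np.ndarray, exp: TitrationExperiment) -> Thermogram:
    mt, xt = _all_concentrations(exp)
    dq = _differential_heats(q_ucal, exp)
    moles_injected = exp.syringe_concentration * np.asarray(exp.injection_volumes, float)
    ndh = (dq / KCAL_TO_UCAL) / moles_injected  # kcal per mole of injectant
    return Thermogram(molar_ratios=xt / mt, injection_heats=dq, normalized_heats=ndh)


def simulate_thermogram(
    exp: TitrationExperiment, params: BindingParameters
) -> Thermogram:
    """Forward-simulate a noise-free one-set-of-sites thermogram."""
    mt, xt = _all_concentrations(exp)
    q = one_site_cumulative_heat(params, mt, xt, exp.cell_volume)
    return _assemble_thermogram(np.asarray(q, float), exp)


def _active_sites(params: TwoSiteParameters):
    # a calorimetrically silent class (dH == 0) or a non-binding class
    # (Ka == 0, i.e. Kd = inf) is treated as absent, so the model reduces
    # exactly to the single-class isotherm in those limits
    return tuple(
        p
        for p in (params.site_cen, params.site_acc)
        if p.enthalpy != 0.0 and p.association_constant > 0.0
    )


def _two_site_free_ligand(mt: float, xt: float, sites) -> float:
    """Free titrant L from Xt = L + Mt * sum_j n_j K_j L/(1+K_j L)."""
    if xt == 0.0:
        return 0.0

    def f(l):
        bound = sum(
            p.stoichiometry * p.association_constant * l
            / (1.0 + p.association_constant * l)
            for p in sites
        )
        return l + mt * bound - xt

    # f(0) = -xt < 0, f(xt) >= 0: monotone bracket
    return optimize.brentq(f, 0.0, xt, xtol=1e-18, rtol=1e-14)


def simulate_two_site_thermogram(
    exp: TitrationExperiment, params: TwoSiteParameters
) -> Thermogram:
    """Thermogram for two independent site classes on the macromolecule.

    Per injection the free-ligand concentration is solved from the mass
    balance by bracketed root finding and the cumulative heat is

        Q = V0 Mt sum_j n_j dH_j K_j L / (1 + K_j L).

    Reduces exactly to :func:`simulate_thermogram` when one class has
    dH = 0 (its binding is silent) or Ka -> 0.
    """
    mt, xt = _all_concentrations(exp)
    sites = _active_sites(params)
    q = np.empty(exp.n_injections)
    for i in range(exp.n_injections):
        l = _two_site_free_ligand(mt[i], xt[i], sites)
        q_kcal = exp.cell_volume * mt[i] * sum(
            p.stoichiometry * p.enthalpy * p.association_constant * l
            / (1.0 + p.association_constant * l)
            for p in sites
        )
        q[i] = q_kcal * KCAL_TO_UCAL
    return _assemble_thermogram(q, exp)


def fold_change(kd_a: float, kd_b: float) -> float:
    """Affinity ratio kd_a/kd_b (e.g. wild-type over mutant)."""
    if kd_a <= 0 or kd_b <= 0:
        raise InvalidParameterError("dissociation constants must be positive")
    return kd_a / kd_b


# --------------------------------------------------------------------------
# model/results objects


class OneSiteBindingModel:
    """One-set-of-sites calorimetric binding model for an observed thermogram.

    Parameters
    ----------
    thermogram : Thermogram
        Observed (or simulated) per-injection heats.
    experiment : TitrationExperiment
        The titration geometry that produced them.

    fix_stoichiometry : float, optional
        Hold n at a known value instead of fitting it.  In the low-c
        regime (c = n Ka M0 below ~5) the triple (n, dH, Ka) is poorly
        identified and the standard protocol is to fix the stoichiometry
        at its known value and fit only (Ka, dH).

    Notes
    -----
    The fit is ordinary least squares on normalized heats over
    ``(log Ka, dH, log n)``; log parameterizations keep Ka and n positive.
    The dimensionless c-value ``n Ka M0`` governs identifiability: far
    outside ~1-1000 the affinity is poorly determined and the results
    carry a warning flag rather than failing.
    """

    param_names = ("log_ka", "enthalpy", "log_n")

    def __init__(
        self,
        thermogram: Thermogram,
        experiment: TitrationExperiment,
        fix_stoichiometry: float | None = None,
    ):
        if len(thermogram) != experiment.n_injections:
            raise InvalidParameterError("thermogram length must match injections")
        self.thermogram = thermogram
        self.experiment = experiment
        self.fix_stoichiometry = fix_stoichiometry
        if fix_stoichiometry is not None:
            if fix_stoichiometry <= 0:
                raise InvalidParameterError("fix_stoichiometry must be positive")
            self.param_names = ("log_ka", "enthalpy")
        self._mask = np.ones(experiment.n_injections, dtype=bool)
        if experiment.discard_first:
            self._mask[0] = False
        if int(self._mask.sum()) < 6:
            raise InvalidParameterError("need at least 6 retained injections to fit")
        if not np.all(np.isfinite(thermogram.normalized_heats)):
            raise InvalidParameterError("observed heats must be finite")

    # -- forward model ---------------------------------------------------
    def predict(self, params: BindingParameters) -> Thermogram:
        return simulate_thermogram(self.experiment, params)

    def _theta_to_params(self, theta: np.ndarray) -> BindingParameters:
        if self.fix_stoichiometry is not None:
            log_ka, dh = theta
            n = self.fix_stoichiometry
        else:
            log_ka, dh, log_n = theta
            n = math.exp(log_n)
        return BindingParameters(
            dissociation_constant=math.exp(-log_ka),
            enthalpy=dh,
            stoichiometry=n,
            temperature=self.experiment.temperature,
        )

    def _ndh(self, theta: np.ndarray) -> np.ndarray:
        return self.predict(self._theta_to_params(theta)).normalized_heats[self._mask]

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        return self._ndh(theta) - self.thermogram.normalized_heats[self._mask]

    # -- starting values -------------------------------------------------
    def start_params(self) -> np.ndarray:
        ndh = self.thermogram.normalized_heats[self._mask]
        ratio = self.thermogram.molar_ratios[self._mask]
        dh0 = float(ndh[0])
        if dh0 == 0.0:
            dh0 = float(ndh[np.argmax(np.abs(ndh))]) or -1.0
        # inflection heuristic: steepest NDH drop marks ratio ~ n; curve
        # half-width in ratio units ~ 1/sqrt(c) gives a Ka scale
        d = np.diff(ndh)
        i = int(np.argmax(np.abs(d))) if len(d) else 0
        n0 = float(np.clip(ratio[i], 0.2, 5.0)) if len(d) else 1.0
        m0 = self.experiment.cell_concentration_initial
        width = max(float(np.ptp(ratio[np.abs(ndh) > 0.5 * np.abs(dh0)])), 1e-3) \
            if np.any(np.abs(ndh) > 0.5 * abs(dh0)) else 1.0
        c0 = float(np.clip((2.0 / width) ** 2, 1.0, 1e4))
        ka0 = c0 / (n0 * m0)
        if self.fix_stoichiometry is not None:
            return np.array([math.log(ka0), dh0])
        return np.array([math.log(ka0), dh0, math.log(n0)])

    # -- fit -------------------------------------------------------------
    def fit(self, start_params=None) -> "BindingFitResults":
        """Nonlinear least squares fit; returns a :class:`BindingFitResults`."""
        theta0 = np.asarray(start_params, float) if start_params is not None \
            else self.start_params()
        sol = optimize.least_squares(
            self._residuals, theta0, method="lm", xtol=1e-12, ftol=1e-12, gtol=1e-12,
            max_nfev=20000,
        )
        if not sol.success:
            raise RuntimeError(f"one-site fit did not converge: {sol.message}")
        return BindingFitResults(self, sol)


class TwoSiteBindingModel(OneSiteBindingModel):
    """Two-independent-site-classes fit (six free parameters).

    Site classes are exchangeable; the reported ordering follows the
    starting values.  Identifiability requires well-separated affinities or
    enthalpies.
    """

    param_names = (
        "log_ka_1", "enthalpy_1", "stoichiometry_1",
        "log_ka_2", "enthalpy_2", "stoichiometry_2",
    )

    def predict(self, params: TwoSiteParameters) -> Thermogram:  # type: ignore[override]
        return simulate_two_site_thermogram(self.experiment, params)

    def _ndh(self, theta: np.ndarray) -> np.ndarray:
        p = TwoSiteParameters(
            site_cen=BindingParameters(
                math.exp(-theta[0]), theta[1], theta[2], self.experiment.temperature
            ),
            site_acc=BindingParameters(
                math.exp(-theta[3]), theta[4], theta[5], self.experiment.temperature
            ),
        )
        return self.predict(p).normalized_heats[self._mask]

    def start_params(self) -> np.ndarray:
        one = super().start_params()
        # split the single-site guess into a tighter and a weaker class
        return np.array([one[0] + 2.0, one[1], one[2], one[0] - 2.0, one[1] / 2.0, one[2]])

    def fit(self, start_params=None) -> "BindingFitResults":
        theta0 = np.asarray(start_params, float) if start_params is not None \
            else self.start_params()
        sol = optimize.least_squares(
            self._residuals, theta0, method="lm", xtol=1e-12, ftol=1e-12, gtol=1e-12,
            max_nfev=50000,
        )
        if not sol.success:
            raise RuntimeError(f"two-site fit did not converge: {sol.message}")
        return BindingFitResults(self, sol)


class BindingFitResults:
    """Estimates, uncertainties and derived thermodynamics of an ITC fit.

    Attributes
    ----------
    params : ndarray
        Fitted parameter vector in the model's internal parameterization.
    bse : ndarray
        Standard errors from the Gauss-Newton covariance of the fit.
    """

    def __init__(self, model: OneSiteBindingModel, sol) -> None:
        self.model = model
        self.params = sol.x
        self._sol = sol
        resid = sol.fun
        self.ssr = float(resid @ resid)
        self.nobs = len(resid)
        self.df_resid = max(self.nobs - len(sol.x), 1)
        self.scale = self.ssr / self.df_resid
        jtj = sol.jac.T @ sol.jac
        try:
            self.cov_params = np.linalg.inv(jtj) * self.scale
        except np.linalg.LinAlgError:
            self.cov_params = np.full_like(jtj, np.nan)
        self.bse = np.sqrt(np.maximum(np.diag(self.cov_params), 0.0))
        self.warnings: list[str] = []
        if isinstance(model, TwoSiteBindingModel):
            return
        c = self.c_value
        if not 0.5 <= c <= 2000.0:
            self.warnings.append(
                f"c-value {c:.3g} outside ~1-1000: affinity poorly determined"
            )

    # -- one-site accessors ---------------------------------------------
    @property
    def binding_parameters(self) -> BindingParameters:
        if isinstance(self.model, TwoSiteBindingModel):
            raise AttributeError("use site_parameters for a two-site fit")
        return self.model._theta_to_params(self.params)

    @property
    def stoichiometry_se(self) -> float:
        """SE of n (delta method from log n); 0 when n was held fixed."""
        if self.model.fix_stoichiometry is not None:
            return 0.0
        return self.binding_parameters.stoichiometry * float(self.bse[2])

    @property
    def site_parameters(self) -> TwoSiteParameters:
        t = self.params
        temp = self.model.experiment.temperature
        return TwoSiteParameters(
            BindingParameters(math.exp(-t[0]), t[1], t[2], temp),
            BindingParameters(math.exp(-t[3]), t[4], t[5], temp),
        )

    @property
    def kd(self) -> float:
        return self.binding_parameters.dissociation_constant

    @property
    def ka(self) -> float:
        return self.binding_parameters.association_constant

    @property
    def kd_se(self) -> float:
        """Delta-method standard error of Kd from the log-Ka error."""
        return self.kd * float(self.bse[0])

    @property
    def c_value(self) -> float:
        p = self.binding_parameters
        return (
            p.stoichiometry * p.association_constant
            * self.model.experiment.cell_concentration_initial
        )

    @property
    def thermodynamics(self) -> ThermodynamicState:
        return thermodynamics_from_affinity(self.binding_parameters)

    def predicted(self) -> Thermogram:
        if isinstance(self.model, TwoSiteBindingModel):
            return self.model.predict(self.site_parameters)
        return self.model.predict(self.binding_parameters)

    def summary(self) -> str:
        lines = [
            "Calorimetric binding fit",
            "=" * 58,
            f"Model:              {type(self.model).__name__}",
            f"Injections fitted:  {self.nobs}",
            f"SSR (kcal/mol)^2:   {self.ssr:.6g}",
        ]
        if isinstance(self.model, TwoSiteBindingModel):
            p = self.site_parameters
            for label, s in (("site 1", p.site_cen), ("site 2", p.site_acc)):
                lines += [
                    f"{label}: Kd = {s.dissociation_constant:.4g} M, "
                    f"dH = {s.enthalpy:.4g} kcal/mol, n = {s.stoichiometry:.4g}",
                ]
        else:
            p = self.binding_parameters
            th = self.thermodynamics
            lines += [
                f"n  = {p.stoichiometry:.4g} +/- {self.stoichiometry_se:.2g}"
                + (" (fixed)" if self.model.fix_stoichiometry is not None else ""),
                f"Kd = {p.dissociation_constant:.4g} M +/- {self.kd_se:.2g}",
                f"Ka = {p.association_constant:.4g} 1/M",
                f"dH = {p.enthalpy:.4g} +/- {self.bse[1]:.2g} kcal/mol",
                f"dG = {th.free_energy:.4g} kcal/mol",
                f"TdS = {th.entropy_term:.4g} kcal/mol",
                f"c-value = {self.c_value:.4g}",
            ]
        for w in self.warnings:
            lines.append(f"WARNING: {w}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Observed vs fitted normalized heats against molar ratio."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tg = self.model.thermogram
        ax.plot(tg.molar_ratios, tg.normalized_heats, "o", label="observed")
        pred = self.predicted()
        ax.plot(pred.molar_ratios, pred.normalized_heats, "-", label="fit")
        ax.set_xlabel("molar ratio")
        ax.set_ylabel("NDH (kcal/mol of injectant)")
        ax.legend()
        return ax


def fit_one_site(
    observed: Thermogram,
    exp: TitrationExperiment,
    initial_guess: BindingParameters | None = None,
    fix_stoichiometry: float | None = None,
) -> tuple[BindingParameters, BindingFitResults]:
    """Functional wrapper over :class:`OneSiteBindingModel`.

    Returns the fitted :class:`BindingParameters` together with the full
    results object (standard errors, diagnostics, warnings).
    """
    model = OneSiteBindingModel(observed, exp, fix_stoichiometry=fix_stoichiometry)
    theta0 = None
    if initial_guess is not None:
        theta0 = [math.log(initial_guess.association_constant), initial_guess.enthalpy]
        if fix_stoichiometry is None:
            theta0.append(math.log(initial_guess.stoichiometry))
        theta0 = np.array(theta0)
    res = model.fit(start_params=theta0)
    return res.binding_parameters, res
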