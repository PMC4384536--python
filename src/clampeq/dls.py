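"""Semi-quantitative oligomerization model for DLS radius-vs-concentration data.

Complexin/SNAREΔ60 units carrying a free accessory helix can cross-link
into chains.  Treating each cross-link as an independent association with
dissociation constant Kd, the fraction of units engaged at total
concentration C follows the self-association quadratic, the mean chain
length is N = 1/(1-p), and the measured average radius is modelled as the
gyration radius of an N-mer,

    r(C) = sqrt(N) * r0,   N = (1 + sqrt(1 + 4C/Kd)) / 2,

with r0 the spacing between adjacent units (monomer size).  The mapping is
quantitative for long ideal chains and semi-quantitative for the small
oligomers relevant here.

Fitting is statsmodels-style: ``OligomerSizeModel(series).fit()`` returns an
:class:`OligomerFitResults` with estimates, standard errors and a
low-affinity (non-specific aggregation) flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .equilibria import InvalidParameterError

__all__ = [
    "OligomerModel",
    "DLSSeries",
    "bound_probability",
    "mean_oligomer_size",
    "gyration_radius",
    "predict_radius_curve",
    "fit_dls",
    "OligomerSizeModel",
    "OligomerFitResults",
]


@dataclass(frozen=True)
class OligomerModel:
    """(Kd, r0) pair parameterizing the self-association radius model.

    kd: cross-link dissociation constant (M); monomer_radius: r0 (nm).
    """

    kd: float
    monomer_radius: float

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise InvalidParameterError("kd must be positive")
        if self.monomer_radius <= 0:
            raise InvalidParameterError("monomer_radius must be positive")


@dataclass(frozen=True)
class DLSSeries:
    """Average particle radius (nm) versus total complex concentration (M)."""

    concentrations: np.ndarray
    radii: np.ndarray
    radius_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, float)
        r = np.asarray(self.radii, float)
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "radii", r)
        if len(c) != len(r):
            raise InvalidParameterError("concentrations and radii length mismatch")
        if np.any(c <= 0):
            raise InvalidParameterError("concentrations must be positive")
        if np.any(np.diff(c) <= 0):
            raise InvalidParameterError("concentrations must be strictly ascending")
        if self.radius_sd is not None:
            sd = np.asarray(self.radius_sd, float)
            if len(sd) != len(c):
                raise InvalidParameterError("radius_sd length mismatch")
            object.__setattr__(self, "radius_sd", sd)

    def __len__(self) -> int:
        return len(self.concentrations)

    def to_frame(self) -> pd.DataFrame:
        d = {"conc_uM": self.concentrations * 1e6, "radius_nm": self.radii}
        if self.radius_sd is not None:
            d["radius_sd_nm"] = self.radius_sd
        return pd.DataFrame(d)


def bound_probability(c_initial, kd):
    """Probability that an accessory-helix interface is engaged at total C.

    p = 1 - [unbound]/C with [unbound] from the self-association quadratic,
    evaluated in the cancellation-free conjugate form

        p = 4x / (1 + sqrt(1 + 4x))^2,   x = C/Kd,

    so both the C << Kd and C >> Kd tails keep full precision.  p(0) = 0 by
    continuity and p -> 1 as C -> infinity.
    """
    c = np.asarray(c_initial, float)
    k = np.asarray(kd, float)
    if np.any(c < 0):
        raise InvalidParameterError("c_initial must be non-negative")
    if np.any(k <= 0):
        raise InvalidParameterError("kd must be positive")
    x = c / k
    s = np.sqrt(1.0 + 4.0 * x)
    p = 4.0 * x / (1.0 + s) ** 2
    return float(p) if p.ndim == 0 else p


def mean_oligomer_size(p):
    """Mean number of monomers per particle: N = p/(1-p) + 1 = 1/(1-p)."""
    p_arr = np.asarray(p, float)
    if np.any(p_arr < 0) or np.any(p_arr >= 1):
        raise InvalidParameterError("p must lie in [0, 1)")
    out = 1.0 / (1.0 - p_arr)
    return float(out) if out.ndim == 0 else out


def gyration_radius(n_mer, model: OligomerModel):
    """Gyration radius of an N-mer: r = sqrt(N) * r0 (nm)."""
    n = np.asarray(n_mer, float)
    if np.any(n < 1):
        raise InvalidParameterError("n_mer must be >= 1")
    out = np.sqrt(n) * model.monomer_radius
    return float(out) if out.ndim == 0 else out


def predict_radius_curve(model: OligomerModel, concentrations) -> DLSSeries:
    """Model radius at each concentration (composition p -> N -> r)."""
    c = np.asarray(concentrations, float)
    p = bound_probability(c, model.kd)
    r = gyration_radius(mean_oligomer_size(p), model)
    return DLSSeries(concentrations=c, radii=np.atleast_1d(r))


class OligomerSizeModel:
    """Least-squares fit of (Kd, r0) to a radius-vs-concentration series.

    Residuals are on radii, weighted by ``radius_sd`` when present.  Kd is
    fitted in log space with an upper bound of ``kd_max`` (default 1 mM);
    r0 is bounded to (0.5, 20) nm.  A fitted Kd at or above the largest
    measured concentration means the association never develops within the
    sampled range, which the results flag as the non-specific-aggregation
    (low-affinity) regime.
    """

    param_names = ("log_kd", "monomer_radius")

    def __init__(self, series: DLSSeries, kd_max: float = 1e-3):
        if len(series) < 4:
            raise InvalidParameterError("need at least 4 concentration points")
        c = series.concentrations
        if c[-1] / c[0] < 4.0:
            raise InvalidParameterError(
                "concentrations must span at least a 4-fold range"
            )
        self.series = series
        self.kd_max = kd_max

    def predict(self, model: OligomerModel) -> DLSSeries:
        return predict_radius_curve(model, self.series.concentrations)

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        m = OligomerModel(kd=math.exp(theta[0]), monomer_radius=theta[1])
        r = self.predict(m).radii - self.series.radii
        if self.series.radius_sd is not None:
            r = r / self.series.radius_sd
        return r

    def start_params(self) -> np.ndarray:
        # smallest-C radius approximates r0; Kd scale from the concentration
        # at which the radius grows ~25% over the first point
        r0 = float(np.clip(self.series.radii[0], 0.6, 19.0))
        grown = self.series.radii > 1.25 * self.series.radii[0]
        kd0 = float(self.series.concentrations[np.argmax(grown)]) if grown.any() \
            else float(self.series.concentrations[-1])
        kd0 = min(kd0, 0.5 * self.kd_max)
        return np.array([math.log(kd0), r0])

    def fit(self, start_params=None) -> "OligomerFitResults":
        theta0 = np.asarray(start_params, float) if start_params is not None \
            else self.start_params()
        sol = optimize.least_squares(
            self._residuals,
            theta0,
            bounds=([math.log(1e-9), 0.5], [math.log(self.kd_max), 20.0]),
            xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=20000,
        )
        if not sol.success:
            raise RuntimeError(f"DLS fit did not converge: {sol.message}")
        return OligomerFitResults(self, sol)


class OligomerFitResults:
    """Fitted oligomerization model with uncertainties and regime flags."""

    def __init__(self, model: OligomerSizeModel, sol) -> None:
        self.model = model
        self.params = sol.x
        resid = sol.fun
        self.ssr = float(resid @ resid)
        self.nobs = len(resid)
        self.df_resid = max(self.nobs - 2, 1)
        self.scale = self.ssr / self.df_resid
        jtj = sol.jac.T @ sol.jac
        try:
            self.cov_params = np.linalg.inv(jtj) * self.scale
        except np.linalg.LinAlgError:
            self.cov_params = np.full_like(jtj, np.nan)
        self.bse = np.sqrt(np.maximum(np.diag(self.cov_params), 0.0))
        self.low_affinity = bool(
            self.kd >= float(model.series.concentrations[-1])
            or self.kd >= 0.999 * model.kd_max
        )
        self.warnings: list[str] = []
        if self.low_affinity:
            self.warnings.append(
                "fitted Kd is at/above the sampled concentration range: "
                "non-specific aggregation regime"
            )

    @property
    def oligomer_model(self) -> OligomerModel:
        return OligomerModel(kd=math.exp(self.params[0]), monomer_radius=self.params[1])

    @property
    def kd(self) -> float:
        return math.exp(self.params[0])

    @property
    def kd_se(self) -> float:
        return self.kd * float(self.bse[0])

    @property
    def monomer_radius(self) -> float:
        return float(self.params[1])

    @property
    def monomer_radius_se(self) -> float:
        return float(self.bse[1])

    def predicted(self) -> DLSSeries:
        return self.model.predict(self.oligomer_model)

    def summary(self) -> str:
        lines = [
            "DLS oligomerization fit",
            "=" * 58,
            f"Points fitted:  {self.nobs}",
            f"SSR (nm^2):     {self.ssr:.6g}",
            f"Kd = {self.kd:.4g} M +/- {self.kd_se:.2g}",
            f"r0 = {self.monomer_radius:.4g} nm +/- {self.monomer_radius_se:.2g}",
            f"low-affinity regime: {self.low_affinity}",
        ]
        for w in self.warnings:
            lines.append(f"WARNING: {w}")
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = self.model.series
        ax.plot(s.concentrations * 1e6, s.radii, "o", label="observed")
        grid = np.geomspace(s.concentrations[0], s.concentrations[-1], 100)
        pred = predict_radius_curve(self.oligomer_model, grid)
        ax.plot(grid * 1e6, pred.radii, "-", label="model")
        ax.set_xlabel("concentration (uM)")
        ax.set_ylabel("average radius (nm)")
        ax.legend()
        return ax


def fit_dls(
    series: DLSSeries, initial_guess: OligomerModel | None = None, kd_max: float = 1e-3
) -> tuple[OligomerModel, OligomerFitResults]:
    """Functional wrapper over :class:`OligomerSizeModel`."""
    model = OligomerSizeModel(series, kd_max=kd_max)
    theta0 = None
    if initial_guess is not None:
        theta0 = np.array([math.log(initial_guess.kd), initial_guess.monomer_radius])
    res = model.fit(start_params=theta0)
    return res.oligomer_model, res
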