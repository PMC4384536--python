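import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from clampeq import BindingParameters, TitrationExperiment


@pytest.fixture
def pre_fusion_experiment() -> TitrationExperiment:
    """210 uM titrant into 14 uM cell, 20 x 2 uL into 200 uL."""
    return TitrationExperiment(
        cell_volume=200e-6,
        cell_concentration_initial=14e-6,
        syringe_concentration=210e-6,
        injection_volumes=(2e-6,) * 20,
    )


@pytest.fixture
def pre_fusion_params() -> BindingParameters:
    return BindingParameters(dissociation_constant=457e-9, enthalpy=-10.0, stoichiometry=1.0)


def bisect_hetero_bound(r: float, l: float, kd: float) -> float:
    """Independent oracle: bisection on the untransformed 1:1 mass balance
    (r - x)(l - x) = kd * x for the bound complex x."""
    lo, hi = 0.0, min(r, l)
    if hi == 0.0:
        return 0.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f = (r - mid) * (l - mid) - kd * mid
        if f > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def bisect_self_unbound(c: float, kd: float) -> float:
    """Independent oracle: bisection on x^2 = kd (c - x) for the unbound pool."""
    lo, hi = 0.0, c
    if c == 0.0:
        return 0.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f = mid * mid - kd * (c - mid)
        if f < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
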