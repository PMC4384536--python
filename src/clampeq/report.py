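"""Report assembly: orchestrate the ITC, DLS, FRET and saturation analyses.

Each ``run_*`` function takes parsed inputs, runs the corresponding model
and returns a JSON-serializable dict plus a human-readable text block.
Warnings (poor c-value, aggregation regime) are carried in the report and
never turn into errors.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from . import dls as dls_mod
from . import fret as fret_mod
from .equilibria import DEFAULT_TEMPERATURE, saturation_percent
from .itc import OneSiteBindingModel, Thermogram, TitrationExperiment, TwoSiteBindingModel

__all__ = [
    "RunConfig",
    "run_itc_analysis",
    "run_saturation_report",
    "run_dls_analysis",
    "run_fret_analysis",
    "format_report",
]


@dataclass
class RunConfig:
    """Run-wide settings; round-trips losslessly through YAML."""

    temperature: float = DEFAULT_TEMPERATURE
    concentration_unit: str = "uM"
    output_dir: str = "."
    seed: int = 0
    verbosity: int = 1

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls(**yaml.safe_load(text))


def run_itc_analysis(
    thermogram: Thermogram,
    experiment: TitrationExperiment,
    model: str = "one-site",
) -> dict:
    """Fit a thermogram and tabulate N, dH, Kd, dG, TdS with uncertainties."""
    if model == "one-site":
        res = OneSiteBindingModel(thermogram, experiment).fit()
        p = res.binding_parameters
        th = res.thermodynamics
        table = {
            "stoichiometry": p.stoichiometry,
            "stoichiometry_se": res.stoichiometry_se,
            "enthalpy_kcal_per_mol": p.enthalpy,
            "enthalpy_se": float(res.bse[1]),
            "kd_M": p.dissociation_constant,
            "kd_se_M": res.kd_se,
            "ka_per_M": p.association_constant,
            "free_energy_kcal_per_mol": th.free_energy,
            "entropy_term_kcal_per_mol": th.entropy_term,
            "c_value": res.c_value,
        }
    elif model == "two-site":
        res = TwoSiteBindingModel(thermogram, experiment).fit()
        sp = res.site_parameters
        table = {}
        for name, s in (("site_1", sp.site_cen), ("site_2", sp.site_acc)):
            table[name] = {
                "stoichiometry": s.stoichiometry,
                "enthalpy_kcal_per_mol": s.enthalpy,
                "kd_M": s.dissociation_constant,
            }
    else:
        raise ValueError(f"unknown model '{model}'")
    return {
        "analysis": "itc",
        "model": model,
        "n_injections": experiment.n_injections,
        "parameters": table,
        "ssr": res.ssr,
        "warnings": list(res.warnings),
        "summary": res.summary(),
    }


def run_saturation_report(receptor: float, excess_folds, kd: float) -> dict:
    """Tabulate percent receptor occupancy per molar-excess fold."""
    rows = [
        {"excess_fold": float(x), "saturation_percent": float(saturation_percent(receptor, x, kd))}
        for x in excess_folds
    ]
    return {
        "analysis": "saturation",
        "receptor_M": receptor,
        "kd_M": kd,
        "rows": rows,
        "warnings": [],
    }


def run_dls_analysis(series: dls_mod.DLSSeries, kd_max: float = 1e-3) -> dict:
    """Fit the oligomerization model to a radius series."""
    res = dls_mod.OligomerSizeModel(series, kd_max=kd_max).fit()
    return {
        "analysis": "dls",
        "n_points": res.nobs,
        "parameters": {
            "kd_M": res.kd,
            "kd_se_M": res.kd_se,
            "monomer_radius_nm": res.monomer_radius,
            "monomer_radius_se_nm": res.monomer_radius_se,
        },
        "low_affinity_regime": res.low_affinity,
        "ssr": res.ssr,
        "warnings": list(res.warnings),
        "summary": res.summary(),
    }


def run_fret_analysis(
    donor_only: fret_mod.EmissionSpectrum,
    donor_acceptor: fret_mod.EmissionSpectrum,
    forster_radius: float,
    integration_window=fret_mod.DEFAULT_INTEGRATION_WINDOW,
    labeling_efficiency: float | None = None,
) -> dict:
    """Efficiency from donor quenching and the implied dye-pair distance."""
    e = fret_mod.efficiency_from_donor_quenching(
        donor_only, donor_acceptor, integration_window
    )
    warnings = []
    if labeling_efficiency is not None:
        e = min(e / labeling_efficiency, 1.0)
    if 0.0 < e < 1.0:
        distance = fret_mod.distance_from_efficiency(
            e, fret_mod.FretPair(forster_radius)
        )
    else:
        distance = None
        warnings.append("efficiency at 0 or 1: distance undefined")
    return {
        "analysis": "fret",
        "efficiency": e,
        "forster_radius_A": forster_radius,
        "distance_A": distance,
        "integration_window_nm": list(integration_window),
        "warnings": warnings,
    }


def format_report(report: dict) -> str:
    """Human-readable rendering of any run_* report dict."""
    lines = [f"clampeq {report['analysis']} report", "-" * 40]
    if "summary" in report:
        lines.append(report["summary"])
    elif report["analysis"] == "saturation":
        lines.append(f"receptor = {report['receptor_M']:.4g} M, Kd = {report['kd_M']:.4g} M")
        lines.append(f"{'excess':>8}  {'saturation %':>12}")
        for row in report["rows"]:
            lines.append(f"{row['excess_fold']:>8.2f}  {row['saturation_percent']:>12.1f}")
    elif report["analysis"] == "fret":
        lines.append(f"efficiency = {report['efficiency']:.4f}")
        if report["distance_A"] is not None:
            lines.append(f"distance  = {report['distance_A']:.1f} A (R0 = {report['forster_radius_A']:.1f} A)")
    for w in report.get("warnings", []):
        lines.append(f"WARNING: {w}")
    return "\n".join(lines)
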