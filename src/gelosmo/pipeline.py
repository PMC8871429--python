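"""End-to-end analysis pipeline: decompose, fit, solve, check.

The pipeline ties the stages together on file inputs:

1. read osmotic tables; subtract the elastic (and optionally ionic) terms;
2. fit (A2, A3) per condition;
3. build gel models, solve equilibrium swelling and scan for a volume
   transition over the condition grid;
4. evaluate the longitudinal osmotic modulus M_os at each equilibrium;
5. fit any SANS profiles and, when contrast and phi are known, compare the
   fitted dynamic amplitude with the osmotic prediction phi^2-over-M_os.

Stages whose inputs are absent are recorded as "skipped".  Given the same
config and seed the report is deterministic.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .elasticity import ElasticScalingModel
from .gelio import read_osmotic_table, read_sans_profile, write_json_report
from .osmotics import (GelModel, SolventSpec, WATER_25C,
                       decompose_swelling_pressure, detect_volume_transition,
                       fit_virial_coefficients, longitudinal_modulus)
from .scattering import consistency_check, fit_sans_profile, osmotic_amplitude

__all__ = ["RunConfig", "AnalysisReport", "run_pipeline"]

logger = logging.getLogger("gelosmo")


@dataclass
class RunConfig:
    """Configuration of one reproducible pipeline run."""

    osmotic_table: Optional[Path] = None
    sans_profiles: tuple[Path, ...] = ()
    out_dir: Optional[Path] = None
    solvent: SolventSpec = WATER_25C
    # conventions
    sans_variant: str = "rod"                    # "rod" or "oz"
    include_elastic_derivative: bool = False     # M_os convention
    consistency_tolerance: float = 0.5
    jump_threshold: float = 2.0
    # physics inputs not derivable from the tables
    contrast: Optional[float] = None             # Delta-rho^2, 1/cm^4
    sans_phi: Optional[float] = None             # phi of the SANS specimen
    phi_ref: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sans_variant not in ("rod", "oz"):
            raise ValueError("sans_variant must be 'rod' or 'oz'")
        if self.osmotic_table is not None:
            self.osmotic_table = Path(self.osmotic_table)
        self.sans_profiles = tuple(Path(p) for p in self.sans_profiles)
        if self.out_dir is not None:
            self.out_dir = Path(self.out_dir)

    def to_dict(self) -> dict:
        return {
            "osmotic_table": str(self.osmotic_table) if self.osmotic_table else None,
            "sans_profiles": [str(p) for p in self.sans_profiles],
            "out_dir": str(self.out_dir) if self.out_dir else None,
            "solvent": {"V1_m3_per_mol": self.solvent.V1, "T_K": self.solvent.T},
            "sans_variant": self.sans_variant,
            "include_elastic_derivative": self.include_elastic_derivative,
            "consistency_tolerance": self.consistency_tolerance,
            "jump_threshold": self.jump_threshold,
            "contrast_invcm4": self.contrast,
            "sans_phi": self.sans_phi,
            "phi_ref": self.phi_ref,
            "seed": self.seed,
        }


@dataclass
class AnalysisReport:
    """Serializable record of every stage of one pipeline run."""

    config: dict
    provenance: dict
    stages: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"config": self.config, "provenance": self.provenance,
                "stages": self.stages, "warnings": self.warnings}

    def summary(self) -> str:
        lines = [f"gelosmo pipeline report (v{self.provenance.get('version')})"]
        for name, stage in self.stages.items():
            status = stage.get("status", "?")
            lines.append(f"  [{status:>7s}] {name}")
        for w in self.warnings:
            lines.append(f"  warning: {w}")
        return "\n".join(lines)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _condition_control(condition: dict) -> Optional[float]:
    for key in ("c_CaCl2_mM", "T_K", "c_NaCl_mM"):
        if key in condition:
            return float(condition[key])
    return None


def run_pipeline(config: RunConfig) -> AnalysisReport:
    """Execute all stages configured in ``config``; see module docstring."""
    provenance = {"version": __version__, "input_hashes": {}}
    for p in ([config.osmotic_table] if config.osmotic_table else []) + list(config.sans_profiles):
        if p is not None and Path(p).exists():
            provenance["input_hashes"][str(p)] = _sha256(Path(p))
    report = AnalysisReport(config=config.to_dict(), provenance=provenance)

    virial_by_condition: list[dict] = []
    models: list[GelModel] = []
    controls: list[float] = []

    # --- osmotic stages ---------------------------------------------------
    if config.osmotic_table is None:
        report.stages["osmotics"] = {"status": "skipped", "reason": "no osmotic table"}
    else:
        curves = read_osmotic_table(config.osmotic_table)
        if not curves:
            report.stages["osmotics"] = {"status": "skipped", "reason": "empty table"}
        else:
            for curve in curves:
                g = curve.metadata.get("G_s_Pa")
                if curve.pressure_kind in ("total", "swelling"):
                    if g is None:
                        raise ValueError(
                            f"curve at condition {curve.condition} has kind "
                            f"{curve.pressure_kind!r} but no G_s column")
                    mixing = decompose_swelling_pressure(curve, g, solvent=config.solvent)
                else:
                    mixing = curve
                fit = fit_virial_coefficients(mixing, solvent=config.solvent)
                entry = {"condition": curve.condition, "virials": fit.to_dict()}
                control = _condition_control(curve.condition)
                if g is not None and len(np.unique(curve.phi)) >= 3:
                    scaling = ElasticScalingModel(curve.phi, np.asarray(g, float)).fit()
                    C_ref = float(scaling.predict(config.phi_ref))
                    entry["elastic_scaling"] = scaling.to_dict()
                elif g is not None:
                    C_ref = float(np.median(g))
                else:
                    C_ref = 0.0
                model = GelModel(A2=fit.A2, A3=fit.A3, elastic_C=C_ref,
                                 phi_ref=config.phi_ref, solvent=config.solvent)
                roots = model.equilibrium()
                stable = [r for r in roots if r.stable]
                entry["equilibrium"] = {
                    "roots": [{"phi": r.phi, "stable": r.stable} for r in roots],
                    "status": "ok" if stable else "fully-swollen/no-equilibrium",
                }
                if stable:
                    phi_eq = min(r.phi for r in stable)
                    m_os = longitudinal_modulus(
                        phi_eq, (fit.A2, fit.A3), model.shear_modulus(phi_eq),
                        config.solvent,
                        include_elastic_derivative=config.include_elastic_derivative)
                    entry["M_os_Pa"] = float(m_os)
                    entry["phi_eq"] = float(phi_eq)
                virial_by_condition.append(entry)
                if control is not None:
                    controls.append(control)
                    models.append(model)
            report.stages["osmotics"] = {"status": "ok",
                                         "conditions": virial_by_condition}
            # transition scan over the condition grid
            if len(controls) >= 4 and np.all(np.diff(controls) > 0):
                tr = detect_volume_transition(controls, models,
                                              jump_threshold=config.jump_threshold)
                report.stages["transition"] = {
                    "status": "ok",
                    "control_grid": list(tr.control_grid),
                    "phi_eq": [None if np.isnan(p) else float(p) for p in tr.phi_eq],
                    "c_critical": tr.c_critical,
                    "jump_ratio": (None if tr.jump_ratio is None
                                   else (tr.jump_ratio if np.isfinite(tr.jump_ratio)
                                         else "inf")),
                    "detected": tr.transition_detected,
                }
            else:
                report.stages["transition"] = {
                    "status": "skipped",
                    "reason": "fewer than 4 monotone control values",
                }

    # --- scattering stages ------------------------------------------------
    if not config.sans_profiles:
        report.stages["scattering"] = {"status": "skipped", "reason": "no SANS input"}
        report.stages["consistency"] = {"status": "skipped", "reason": "no SANS input"}
    else:
        fits = []
        for p in config.sans_profiles:
            profile = read_sans_profile(p)
            fit = fit_sans_profile(profile, variant=config.sans_variant)
            fits.append({"path": str(p), "fit": fit.to_dict()})
        report.stages["scattering"] = {"status": "ok", "fits": fits}
        can_compare = (config.contrast is not None and config.sans_phi is not None
                       and virial_by_condition
                       and "M_os_Pa" in virial_by_condition[0])
        if can_compare:
            first = virial_by_condition[0]
            v = first["virials"]
            model = GelModel(A2=v["A2"], A3=v["A3"],
                             elastic_C=first.get("elastic_scaling", {}).get("prefactor_Pa", 0.0),
                             phi_ref=config.phi_ref, solvent=config.solvent)
            phi = config.sans_phi
            g = models[0].shear_modulus(phi) if models else 0.0
            m_os = longitudinal_modulus(
                phi, (v["A2"], v["A3"]), g, config.solvent,
                include_elastic_derivative=config.include_elastic_derivative)
            osm = osmotic_amplitude(phi, float(m_os), config.contrast, config.solvent)
            first_fit = fits[0]["fit"]
            check = consistency_check(first_fit["dyn_amplitude"], osm,
                                      tolerance=config.consistency_tolerance)
            report.stages["consistency"] = {"status": "ok", **check.to_dict()}
        else:
            report.stages["consistency"] = {
                "status": "skipped",
                "reason": "needs contrast, sans_phi and an osmotic M_os",
            }

    if config.out_dir is not None:
        config.out_dir.mkdir(parents=True, exist_ok=True)
        write_json_report(report.to_dict(), config.out_dir / "report.json")
        (config.out_dir / "report.txt").write_text(report.summary() + "\n")
    return report
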