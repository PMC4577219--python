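"""Tissue material parameters and conductivity dependence rules.

All electrical/thermal parameters of the model live here, together with
the field-dependence of conductivity (the electroporation effect) and its
temperature coefficient.  Internally everything is SI (m, S/m, K); field
thresholds are exposed in V/cm at the interfaces with an explicit
conversion factor of 100 V/m per V/cm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal

import numpy as np

__all__ = [
    "V_PER_CM",
    "TissueMaterial",
    "BloodProperties",
    "ArrheniusParams",
    "MaterialTable",
    "default_material_table",
    "sigma_of_field",
    "sigma_of_temperature",
]

#: 1 V/cm expressed in V/m.
V_PER_CM = 100.0

SigmaShape = Literal["linear", "smoothstep"]


@dataclass(frozen=True)
class TissueMaterial:
    """Electrical and thermal parameters of one tissue type."""

    name: str
    sigma0: float  # S/m, baseline conductivity
    sigma_f: float  # S/m, fully electroporated conductivity
    E_rev: float  # V/cm, onset of the conductivity rise
    E_irr: float  # V/cm, saturation of the rise / irreversible threshold
    alphaT: float  # 1/K, thermal coefficient of conductivity
    k: float  # W/(m K), thermal conductivity
    rho: float  # kg/m^3
    c: float  # J/(kg K)
    perfusion: float  # 1/s, volumetric blood perfusion rate
    metabolic_q: float  # W/m^3

    def __post_init__(self) -> None:
        if not (self.sigma_f >= self.sigma0 > 0):
            raise ValueError(
                f"{self.name}: require sigma_f >= sigma0 > 0, got "
                f"sigma0={self.sigma0}, sigma_f={self.sigma_f}"
            )
        if not (0 < self.E_rev <= self.E_irr):
            raise ValueError(
                f"{self.name}: require 0 < E_rev <= E_irr, got "
                f"E_rev={self.E_rev}, E_irr={self.E_irr}"
            )
        if min(self.k, self.rho, self.c) <= 0:
            raise ValueError(f"{self.name}: thermal parameters must be positive")
        if self.perfusion < 0:
            raise ValueError(f"{self.name}: perfusion must be >= 0")


@dataclass(frozen=True)
class BloodProperties:
    """Blood parameters of the perfusion heat sink."""

    rho_b: float = 1060.0  # kg/m^3
    c_b: float = 3840.0  # J/(kg K)
    T_b: float = 310.0  # K, arterial = initial tissue temperature

    def __post_init__(self) -> None:
        if min(self.rho_b, self.c_b, self.T_b) <= 0:
            raise ValueError("blood properties must be positive")


@dataclass(frozen=True)
class ArrheniusParams:
    """First-order thermal damage kinetics parameters."""

    Ea: float = 5.06e5  # J/mol, activation energy
    zeta: float = 2.984e80  # 1/s, frequency factor
    R: float = 8.314  # J/(mol K)

    def __post_init__(self) -> None:
        if min(self.Ea, self.zeta, self.R) <= 0:
            raise ValueError("Arrhenius parameters must be positive")


@dataclass
class MaterialTable:
    """Full parameter set: per-tissue materials plus blood and damage kinetics.

    ``tissues`` must contain at least ``liver``, ``tumor``, ``vessel`` and
    ``electrode``.  Voxels labeled ``background`` fall back to the liver
    entry unless an explicit ``background`` entry is present.
    """

    tissues: dict[str, TissueMaterial] = field(default_factory=dict)
    blood: BloodProperties = field(default_factory=BloodProperties)
    arrhenius: ArrheniusParams = field(default_factory=ArrheniusParams)
    sigma_shape: SigmaShape = "linear"
    #: conductivity of the insulated electrode shaft, S/m
    sigma_insulation: float = 1e-6

    def material_for(self, tissue: str) -> TissueMaterial:
        if tissue == "background" and "background" not in self.tissues:
            return self.tissues["liver"]
        if tissue == "electrode_insulated":
            tissue = "electrode"
        if tissue == "electrode_active":
            tissue = "electrode"
        return self.tissues[tissue]

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "sigma_shape": self.sigma_shape,
            "sigma_insulation_S_per_m": self.sigma_insulation,
            "tissues": {
                name: {
                    "name": m.name,
                    "sigma0_S_per_m": m.sigma0,
                    "sigma_f_S_per_m": m.sigma_f,
                    "E_rev_V_per_cm": m.E_rev,
                    "E_irr_V_per_cm": m.E_irr,
                    "alphaT_per_K": m.alphaT,
                    "k_W_per_mK": m.k,
                    "rho_kg_per_m3": m.rho,
                    "c_J_per_kgK": m.c,
                    "perfusion_per_s": m.perfusion,
                    "metabolic_q_W_per_m3": m.metabolic_q,
                }
                for name, m in self.tissues.items()
            },
            "blood": {
                "rho_b_kg_per_m3": self.blood.rho_b,
                "c_b_J_per_kgK": self.blood.c_b,
                "T_b_K": self.blood.T_b,
            },
            "arrhenius": {
                "Ea_J_per_mol": self.arrhenius.Ea,
                "zeta_per_s": self.arrhenius.zeta,
                "R_J_per_molK": self.arrhenius.R,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MaterialTable":
        tissues = {
            name: TissueMaterial(
                name=t["name"],
                sigma0=t["sigma0_S_per_m"],
                sigma_f=t["sigma_f_S_per_m"],
                E_rev=t["E_rev_V_per_cm"],
                E_irr=t["E_irr_V_per_cm"],
                alphaT=t["alphaT_per_K"],
                k=t["k_W_per_mK"],
                rho=t["rho_kg_per_m3"],
                c=t["c_J_per_kgK"],
                perfusion=t["perfusion_per_s"],
                metabolic_q=t["metabolic_q_W_per_m3"],
            )
            for name, t in d["tissues"].items()
        }
        b = d["blood"]
        a = d["arrhenius"]
        return cls(
            tissues=tissues,
            blood=BloodProperties(b["rho_b_kg_per_m3"], b["c_b_J_per_kgK"], b["T_b_K"]),
            arrhenius=ArrheniusParams(a["Ea_J_per_mol"], a["zeta_per_s"], a["R_J_per_molK"]),
            sigma_shape=d.get("sigma_shape", "linear"),
            sigma_insulation=d.get("sigma_insulation_S_per_m", 1e-6),
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            if path.suffix in (".yaml", ".yml"):
                import yaml

                yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
            else:
                json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "MaterialTable":
        path = Path(path)
        with open(path) as fh:
            if path.suffix in (".yaml", ".yml"):
                import yaml

                d = yaml.safe_load(fh)
            else:
                d = json.load(fh)
        return cls.from_dict(d)


def default_material_table() -> MaterialTable:
    """Load the default parameter set shipped with the package.

    Liver 0.091 -> 0.45 S/m, tumor 0.4 -> 1.6 S/m, vessel 0.7 -> 1.05 S/m,
    thermal coefficient 1.5 %/K, tissue c = 3540 J/(kg K), rho = 1079 kg/m^3,
    k = 0.52 W/(m K), perfusion 1.8 mL/s/100 mL = 0.018 1/s, blood
    c = 3840 J/(kg K), rho = 1060 kg/m^3, baseline temperature 310 K,
    metabolic heat 10740 W/m^3, Ea = 5.06e5 J/mol, zeta = 2.984e80 1/s.

    The reversible-onset thresholds ``E_rev`` are not part of the published
    parameter set; the defaults use ``E_irr / 2`` (liver 350, tumor 400,
    vessel 350 V/cm) and are configurable.  Tumor perfusion defaults to half
    the liver value (the source only states that it is lower).
    """
    text = resources.files("ireplan.data").joinpath("materials_default.json").read_text()
    return MaterialTable.from_dict(json.loads(text))


def sigma_of_field(
    E: np.ndarray | float,
    m: TissueMaterial,
    shape: SigmaShape = "linear",
) -> np.ndarray | float:
    """Field-dependent conductivity sigma(E).

    Parameters
    ----------
    E
        Electric-field magnitude in V/cm (scalar or array), >= 0.
    m
        Material supplying ``sigma0``, ``sigma_f`` and the two thresholds.
    shape
        ``"linear"``: linear ramp between (E_rev, sigma0) and
        (E_irr, sigma_f).  ``"smoothstep"``: C1 cubic smoothstep between the
        same endpoints.

    Returns
    -------
    Conductivity in S/m, bounded in [sigma0, sigma_f], monotone
    non-decreasing in E.
    """
    E = np.asarray(E, dtype=float)
    if np.any(E < 0):
        raise ValueError("field magnitude must be non-negative")
    if m.E_irr == m.E_rev:
        t = (E >= m.E_irr).astype(float)
    else:
        t = np.clip((E - m.E_rev) / (m.E_irr - m.E_rev), 0.0, 1.0)
    if shape == "smoothstep":
        t = t * t * (3.0 - 2.0 * t)
    elif shape != "linear":
        raise ValueError(f"unknown sigma(E) shape: {shape!r}")
    out = m.sigma0 + (m.sigma_f - m.sigma0) * t
    return float(out) if out.ndim == 0 else out


def sigma_of_temperature(
    sigma: np.ndarray | float,
    T: np.ndarray | float,
    alphaT: float,
    T_ref: float,
) -> np.ndarray | float:
    """Apply the linear thermal coefficient: sigma * (1 + alphaT (T - T_ref)).

    The result is clamped below at zero (the linear model would otherwise
    go negative for a large temperature drop).
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("absolute temperature must be positive")
    out = np.maximum(np.asarray(sigma, float) * (1.0 + alphaT * (T - T_ref)), 0.0)
    return float(out) if out.ndim == 0 else out
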