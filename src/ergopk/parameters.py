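"""Model parameterization for the whole-body ergothioneine PBPK model.

The model describes the disposition of ergothioneine (EGT), a diet-derived
thiol-amino acid that enters cells exclusively through the carnitine/organic
cation transporter OCTN1 (SLC22A4).  The physiology is a fixed 70-kg adult:
plasma, circulating red blood cells plus a marrow precursor pool, a
five-unit tandem liver (flow-limited hepatic uptake), three large
OCTN1-expressing peripheral tissues (adipose, skin, muscle) each split into
extracellular and intracellular spaces, and a renal proximal duct receiving
the glomerular filtrate with saturable OCTN1 reabsorption.  Urine is the
only elimination route.

:class:`ModelParameters` holds every primitive constant (volumes, plasma
flows, rate constants, transporter kinetics, tissue-to-plasma ratios,
OCTN1 mRNA expression weights, hematocrit).  :func:`derive_parameters`
computes the secondary quantities that the mass balances actually use:
peripheral maximum uptake rates scaled from the hepatic anchor by relative
mRNA expression per unit tissue mass, and intrinsic efflux clearances
PS_eff = (V_max/K_m)/K_p fixed by the steady-state, linear-condition
tissue-to-plasma concentration ratios.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "ModelParameters",
    "DerivedParameters",
    "ParameterError",
    "derive_parameters",
    "default_parameter_file",
]

#: Tissues with explicit extracellular/intracellular sub-compartments.
TISSUES = ("liver", "adipose", "skin", "muscle")

#: Peripheral (non-hepatic) tissues whose V_max is scaled from the liver.
PERIPHERAL_TISSUES = ("adipose", "skin", "muscle")


class ParameterError(ValueError):
    """Raised for invalid, inconsistent, or unknown model parameters."""


@dataclass(frozen=True)
class ModelParameters:
    """Primitive parameters of the EGT PBPK model (70-kg adult defaults).

    Units: volumes L, flows L/h, rate constants /h, transport maxima
    ``V_max*`` μmol/h, concentrations μM, ``R`` μmol/h.  ``Hct`` is the
    hematocrit volume fraction; the default is the ratio of the RBC volume
    (2.29 L) to total blood volume (5.20 L).
    """

    # dietary intake and absorption
    R: float = 1.36           # dietary EGT ingestion rate, μmol/h (optimized)
    k_a: float = 6.00         # first-order absorption rate constant, /h

    # volumes, L
    V_p: float = 3.00         # plasma
    V_RBC: float = 2.29       # circulating red blood cells
    V_a: float = 10.0         # adipose intracellular
    V_ae: float = 2.00        # adipose extracellular
    V_h: float = 1.69         # liver intracellular
    V_he: float = 0.338       # liver extracellular
    V_s: float = 7.8          # skin intracellular
    V_se: float = 1.56        # skin extracellular
    V_m: float = 35.0         # muscle intracellular
    V_me: float = 7.00        # muscle extracellular
    V_d: float = 0.127        # renal tubular duct

    # plasma flows, L/h
    Q_a: float = 8.74
    Q_h: float = 48.7
    Q_s: float = 18.0
    Q_m: float = 45.0
    Q_u: float = 0.0583       # urinary flow
    GFR: float = 7.50         # glomerular filtration rate

    # red-blood-cell turnover, /h
    k_1: float = 0.0104       # precursor differentiation into circulating RBC
    k_b: float = 0.000963     # circulating RBC degradation

    # OCTN1 transport
    V_maxH: float = 10227.0   # hepatic maximum uptake, μmol/h (= 10·Q_h·K_m)
    V_maxD: float = 121.0     # renal duct reabsorption maximum, μmol/h (optimized)
    V_maxP: float = 11.1      # RBC-precursor uptake maximum, μmol/h (optimized)
    K_m: float = 21.0         # Michaelis constant of human OCTN1, μM

    # steady-state tissue-to-plasma concentration ratios (mouse)
    K_pH: float = 80.1
    K_pM: float = 5.06
    K_pA: float = 17.5
    K_pS: float = 20.8

    # OCTN1 mRNA expression weights per gram of tissue
    e_H: float = 0.147
    e_M: float = 0.464
    e_A: float = 0.209
    e_S: float = 0.131

    Hct: float = 2.29 / 5.20  # hematocrit fraction
    n_liver_units: int = 5    # tandem liver sub-compartments

    #: Route for absorbed gut flux: "portal" feeds liver unit 1 (default),
    #: "systemic" feeds central plasma directly.
    absorption_route: str = "portal"

    def __post_init__(self) -> None:
        if not (isinstance(self.R, (int, float)) and self.R >= 0):
            raise ParameterError(f"R must be non-negative, got {self.R!r}")
        positive = [
            "k_a", "V_p", "V_RBC", "V_a", "V_ae", "V_h", "V_he",
            "V_s", "V_se", "V_m", "V_me", "V_d", "Q_a", "Q_h", "Q_s",
            "Q_m", "Q_u", "GFR", "k_1", "k_b", "V_maxH", "V_maxD",
            "V_maxP", "K_m", "K_pH", "K_pM", "K_pA", "K_pS",
            "e_H", "e_M", "e_A", "e_S",
        ]
        for name in positive:
            value = getattr(self, name)
            if not (isinstance(value, (int, float)) and value > 0):
                raise ParameterError(f"parameter {name!r} must be strictly positive, got {value!r}")
        if not 0.0 < self.Hct < 1.0:
            raise ParameterError(f"Hct must lie in (0, 1), got {self.Hct!r}")
        if self.n_liver_units != 5:
            raise ParameterError("the tandem liver is modelled with exactly 5 sub-units")
        if self.absorption_route not in ("portal", "systemic"):
            raise ParameterError(f"absorption_route must be 'portal' or 'systemic', got {self.absorption_route!r}")

    def replace(self, **changes: object) -> "ModelParameters":
        """Return a copy with the given fields replaced (validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, mapping: Mapping[str, object]) -> "ModelParameters":
        """Build parameters from a mapping; unknown keys are rejected."""
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(mapping) - known)
        if unknown:
            raise ParameterError(f"unknown parameter key(s): {', '.join(unknown)}")
        return cls(**dict(mapping))

    @classmethod
    def from_file(cls, path: str | Path) -> "ModelParameters":
        """Load parameters from a YAML or JSON config file."""
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ParameterError(f"parameter file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        data = self.to_dict()
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(data, indent=2) + "\n", encoding="utf-8")
        else:
            path.write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")

    # convenience views -------------------------------------------------
    def intracellular_volume(self, tissue: str) -> float:
        return {"liver": self.V_h, "adipose": self.V_a, "skin": self.V_s, "muscle": self.V_m}[tissue]

    def extracellular_volume(self, tissue: str) -> float:
        return {"liver": self.V_he, "adipose": self.V_ae, "skin": self.V_se, "muscle": self.V_me}[tissue]

    def plasma_flow(self, tissue: str) -> float:
        return {"liver": self.Q_h, "adipose": self.Q_a, "skin": self.Q_s, "muscle": self.Q_m}[tissue]

    def kp(self, tissue: str) -> float:
        return {"liver": self.K_pH, "adipose": self.K_pA, "skin": self.K_pS, "muscle": self.K_pM}[tissue]

    def expression_weight(self, tissue: str) -> float:
        return {"liver": self.e_H, "adipose": self.e_A, "skin": self.e_S, "muscle": self.e_M}[tissue]


@dataclass(frozen=True)
class DerivedParameters:
    """Secondary transport parameters computed from :class:`ModelParameters`.

    ``V_max`` maps tissue name to its maximum uptake rate (μmol/h; the liver
    entry is ``V_maxH`` itself) and ``PS_eff`` maps tissue name to the
    intrinsic efflux clearance (L/h) fixed by PS_eff = (V_max/K_m)/K_p.
    """

    V_max: Mapping[str, float]
    PS_eff: Mapping[str, float]

    def replace_liver(self, V_maxH: float, K_m: float, K_pH: float) -> "DerivedParameters":
        """Copy with only the hepatic entries recomputed from ``V_maxH``.

        Used by the sensitivity analysis, where rescaling the hepatic anchor
        must not propagate to the peripheral V_max values (those are tied to
        independent mRNA-expression measurements).
        """
        vmax = dict(self.V_max)
        ps = dict(self.PS_eff)
        vmax["liver"] = V_maxH
        ps["liver"] = (V_maxH / K_m) / K_pH
        return DerivedParameters(V_max=vmax, PS_eff=ps)


def derive_parameters(params: ModelParameters) -> DerivedParameters:
    """Scale peripheral V_max from the hepatic anchor and fix efflux clearances.

    Peripheral maxima follow V_maxT / V_maxH = (e_T · W_T)/(e_H · W_H) with
    organ mass W approximated by intracellular volume at unit density; every
    tissue's efflux clearance is PS_eff = (V_max/K_m)/K_p, the value that
    makes the steady-state, linear-condition intracellular-to-plasma ratio
    equal K_p.
    """
    vmax: dict[str, float] = {"liver": params.V_maxH}
    for tissue in PERIPHERAL_TISSUES:
        w = params.intracellular_volume(tissue)
        vmax[tissue] = params.V_maxH * (
            params.expression_weight(tissue) * w
        ) / (params.e_H * params.V_h)
    ps = {t: (vmax[t] / params.K_m) / params.kp(t) for t in TISSUES}
    return DerivedParameters(V_max=vmax, PS_eff=ps)


def default_parameter_file() -> Path:
    """Path to the shipped all-defaults YAML config."""
    return Path(__file__).parent / "data" / "default_params.yaml"
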