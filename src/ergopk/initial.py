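"""Steady-state initialization of the PBPK system.

Baseline plasma and RBC concentrations are measured quantities and are
pinned to their observed blank values; every other compartment is set to
the value that zeroes its own mass balance given that plasma level and the
dietary throughput ``R``:

* gut lumen:           A_g = R / k_a
* liver extracellular: C_he,j = C_p0 + R / Q_h  (dietary flux in transit)
* tissue intracellular: C_i = K_p · K_m · C_e / (K_m + C_e)
  (uptake = efflux at the local extracellular level)
* peripheral extracellular: C_e = C_p0
* renal duct: positive root of the filtration/reabsorption/urine balance
  Q_u·C_d² + (V_maxD + Q_u·K_m − GFR·C_p0)·C_d − GFR·C_p0·K_m = 0
* RBC precursor: A_pre = v_up,P(C_p0) / k_1

No global steady state is imposed — under the fitted dietary rate the
observed blanks are not an exact whole-system equilibrium, so plasma and
circulating RBC retain non-zero derivatives (they are data, not solved).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import N_STATE, SystemState, michaelis_menten_flux
from .parameters import DerivedParameters, ModelParameters, derive_parameters

__all__ = ["InitialCondition", "InitializationError", "duct_steady_state", "initialize"]


class InitializationError(RuntimeError):
    """No valid steady-state initial condition exists for the inputs."""


@dataclass(frozen=True)
class InitialCondition:
    """Full system state at t = 0 with provenance flags.

    ``fixed`` names the entries pinned to observed values (plasma and
    circulating RBC); everything else was solved from the compartment-local
    steady-state balances.
    """

    y: np.ndarray
    fixed: tuple[str, ...] = ("C_p", "C_RBC")

    @property
    def state(self) -> SystemState:
        return SystemState.from_vector(self.y)

    @property
    def C_p(self) -> float:
        return float(self.y[1])

    @property
    def C_RBC(self) -> float:
        return float(self.y[20])


def duct_steady_state(C_p: float, params: ModelParameters) -> float:
    """Duct concentration balancing filtration, reabsorption, and urine flow.

    Solves GFR·C_p = V_maxD·C_d/(K_m + C_d) + Q_u·C_d for C_d ≥ 0.  The
    quadratic has exactly one positive root for positive inputs (the product
    of the roots is negative).
    """
    if C_p <= 0:
        raise InitializationError("plasma concentration must be positive")
    a = params.Q_u
    b = params.V_maxD + params.Q_u * params.K_m - params.GFR * C_p
    c = -params.GFR * C_p * params.K_m
    disc = b * b - 4.0 * a * c
    if disc < 0:  # impossible for positive inputs; defensive
        raise InitializationError("duct steady-state quadratic has no real root")
    # numerically stable form of the positive root: c < 0, so with b ≥ 0 the
    # naive (−b+√disc)/(2a) cancels catastrophically when reabsorption
    # capacity dwarfs the filtered load
    sqrt_disc = np.sqrt(disc)
    if b >= 0:
        root = -2.0 * c / (b + sqrt_disc)
    else:
        root = (-b + sqrt_disc) / (2.0 * a)
    if root <= 0:
        raise InitializationError("duct steady-state root is non-positive")
    return float(root)


def initialize(
    C_p0: float,
    C_RBC0: float,
    params: ModelParameters,
    derived: DerivedParameters | None = None,
) -> InitialCondition:
    """Initial condition with plasma/RBC pinned and all else at local balance."""
    if C_p0 <= 0:
        raise InitializationError("C_p0 must be strictly positive")
    if C_RBC0 < 0:
        raise InitializationError("C_RBC0 must be non-negative")
    if derived is None:
        derived = derive_parameters(params)

    y = np.empty(N_STATE)
    y[0] = params.R / params.k_a
    y[1] = C_p0

    # dietary flux raises the liver extracellular level by R/Q_h in transit;
    # with systemic absorption the liver sees plain plasma.
    C_he = C_p0 + (params.R / params.Q_h if params.absorption_route == "portal" else 0.0)
    y[2:7] = C_he
    y[7:12] = params.K_pH * params.K_m * C_he / (params.K_m + C_he)

    for k, tissue in enumerate(("adipose", "skin", "muscle")):
        i = 12 + 2 * k
        y[i] = C_p0
        y[i + 1] = params.kp(tissue) * params.K_m * C_p0 / (params.K_m + C_p0)

    y[18] = duct_steady_state(C_p0, params)
    y[19] = michaelis_menten_flux(params.V_maxP, params.K_m, C_p0) / params.k_1
    y[20] = C_RBC0
    return InitialCondition(y=y)
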