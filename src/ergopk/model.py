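"""Mass balances of the EGT PBPK system.

State layout (21 entries; amounts in μmol, concentrations in μM, time in h):

====  ==========  ====================================================
idx   name        meaning
====  ==========  ====================================================
0     A_g         gut lumen amount
1     C_p         plasma concentration
2-6   C_he[1..5]  liver extracellular, tandem units 1..5
7-11  C_h[1..5]   liver intracellular, tandem units 1..5
12    C_ae        adipose extracellular
13    C_a         adipose intracellular
14    C_se        skin extracellular
15    C_s         skin intracellular
16    C_me        muscle extracellular
17    C_m         muscle intracellular
18    C_d         renal proximal duct
19    A_pre       RBC-precursor amount
20    C_RBC       circulating-RBC concentration
====  ==========  ====================================================

Every cellular uptake is Michaelis–Menten in the local extracellular
concentration with the shared OCTN1 ``K_m``; efflux back to the
extracellular space is linear with clearance ``PS_eff``.  Plasma flow
``Q_h`` runs through the five liver units in series (dispersion
approximation of flow-limited hepatic uptake); each unit carries one fifth
of the hepatic volumes, uptake maximum, and efflux clearance.  The
glomerular filtrate (``GFR·C_p``) enters the duct, is reabsorbed by a
saturable carrier (``V_maxD``), and the residue leaves in urine at ``Q_u``.
The marrow precursor pool takes EGT up from plasma (``V_maxP``), matures
into circulating RBC at ``k_1``, and RBC degradation (``k_b``) returns EGT
to plasma, so urine is the only route out of the body.

The right-hand side is numba-compiled against a packed parameter vector;
:func:`rhs` is the validated public wrapper operating on
:class:`SystemState`-compatible vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .parameters import DerivedParameters, ModelParameters, derive_parameters

__all__ = [
    "STATE_NAMES",
    "N_STATE",
    "SystemState",
    "NumericalStateError",
    "michaelis_menten_flux",
    "pack_parameters",
    "rhs",
    "rhs_packed",
    "total_amount",
    "amount_derivative",
    "rk4_integrate",
]

STATE_NAMES = (
    "A_g", "C_p",
    "C_he1", "C_he2", "C_he3", "C_he4", "C_he5",
    "C_h1", "C_h2", "C_h3", "C_h4", "C_h5",
    "C_ae", "C_a", "C_se", "C_s", "C_me", "C_m",
    "C_d", "A_pre", "C_RBC",
)
N_STATE = len(STATE_NAMES)

# indices into the packed parameter vector used by the compiled RHS
_P_FIELDS = (
    "R", "k_a", "V_p", "V_RBC", "V_he", "V_h", "Q_h", "Q_u", "GFR",
    "k_1", "k_b", "V_maxH", "V_maxD", "V_maxP", "K_m", "PS_H",
    "Q_a", "V_ae", "V_a", "V_maxA", "PS_A",
    "Q_s", "V_se", "V_s", "V_maxS", "PS_S",
    "Q_m", "V_me", "V_m", "V_maxM", "PS_M",
    "V_d", "portal",
)
N_PACKED = len(_P_FIELDS)


class NumericalStateError(RuntimeError):
    """A state vector contains NaN/Inf; the message names the compartment."""


@dataclass
class SystemState:
    """Named view of one time point of the 21-compartment system."""

    A_g: float = 0.0
    C_p: float = 0.0
    C_he: np.ndarray = field(default_factory=lambda: np.zeros(5))
    C_h: np.ndarray = field(default_factory=lambda: np.zeros(5))
    C_ae: float = 0.0
    C_a: float = 0.0
    C_se: float = 0.0
    C_s: float = 0.0
    C_me: float = 0.0
    C_m: float = 0.0
    C_d: float = 0.0
    A_pre: float = 0.0
    C_RBC: float = 0.0

    def to_vector(self) -> np.ndarray:
        y = np.empty(N_STATE)
        y[0], y[1] = self.A_g, self.C_p
        y[2:7] = self.C_he
        y[7:12] = self.C_h
        y[12:18] = (self.C_ae, self.C_a, self.C_se, self.C_s, self.C_me, self.C_m)
        y[18], y[19], y[20] = self.C_d, self.A_pre, self.C_RBC
        return y

    @classmethod
    def from_vector(cls, y: np.ndarray) -> "SystemState":
        y = np.asarray(y, dtype=float)
        if y.shape != (N_STATE,):
            raise ValueError(f"state vector must have shape ({N_STATE},), got {y.shape}")
        return cls(
            A_g=float(y[0]), C_p=float(y[1]),
            C_he=y[2:7].copy(), C_h=y[7:12].copy(),
            C_ae=float(y[12]), C_a=float(y[13]),
            C_se=float(y[14]), C_s=float(y[15]),
            C_me=float(y[16]), C_m=float(y[17]),
            C_d=float(y[18]), A_pre=float(y[19]), C_RBC=float(y[20]),
        )


def michaelis_menten_flux(V_max: float, K_m: float, C) -> float | np.ndarray:
    """Saturable OCTN1 transport rate ``V_max·C/(K_m + C)`` in μmol/h.

    Monotone non-decreasing in ``C`` and bounded above by ``V_max``.
    """
    if V_max <= 0 or K_m <= 0:
        raise ValueError("V_max and K_m must be strictly positive")
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("substrate concentration must be non-negative")
    out = V_max * C / (K_m + C)
    return float(out) if out.ndim == 0 else out


def pack_parameters(
    params: ModelParameters, derived: DerivedParameters | None = None
) -> np.ndarray:
    """Flatten parameters into the vector consumed by the compiled RHS."""
    if derived is None:
        derived = derive_parameters(params)
    values = {
        "R": params.R, "k_a": params.k_a, "V_p": params.V_p,
        "V_RBC": params.V_RBC, "V_he": params.V_he, "V_h": params.V_h,
        "Q_h": params.Q_h, "Q_u": params.Q_u, "GFR": params.GFR,
        "k_1": params.k_1, "k_b": params.k_b,
        "V_maxH": derived.V_max["liver"], "V_maxD": params.V_maxD,
        "V_maxP": params.V_maxP, "K_m": params.K_m,
        "PS_H": derived.PS_eff["liver"],
        "Q_a": params.Q_a, "V_ae": params.V_ae, "V_a": params.V_a,
        "V_maxA": derived.V_max["adipose"], "PS_A": derived.PS_eff["adipose"],
        "Q_s": params.Q_s, "V_se": params.V_se, "V_s": params.V_s,
        "V_maxS": derived.V_max["skin"], "PS_S": derived.PS_eff["skin"],
        "Q_m": params.Q_m, "V_me": params.V_me, "V_m": params.V_m,
        "V_maxM": derived.V_max["muscle"], "PS_M": derived.PS_eff["muscle"],
        "V_d": params.V_d,
        "portal": 1.0 if params.absorption_route == "portal" else 0.0,
    }
    return np.array([values[k] for k in _P_FIELDS], dtype=float)


@njit(cache=True)
def rhs_packed(t: float, y: np.ndarray, p: np.ndarray) -> np.ndarray:  # pragma: no cover - compiled
    R = p[0]; k_a = p[1]; V_p = p[2]; V_RBC = p[3]
    V_he = p[4]; V_h = p[5]; Q_h = p[6]; Q_u = p[7]; GFR = p[8]
    k_1 = p[9]; k_b = p[10]
    V_maxH = p[11]; V_maxD = p[12]; V_maxP = p[13]; K_m = p[14]; PS_H = p[15]
    V_d = p[31]; portal = p[32]

    d = np.empty(21)
    A_g = y[0]; C_p = y[1]
    absorbed = k_a * A_g
    d[0] = R - absorbed

    # tandem liver: per-unit volumes, uptake maximum and efflux clearance
    V_he_u = V_he / 5.0
    V_h_u = V_h / 5.0
    V_maxH_u = V_maxH / 5.0
    PS_H_u = PS_H / 5.0
    upstream = C_p
    for j in range(5):
        C_e = y[2 + j]
        C_i = y[7 + j]
        uptake = V_maxH_u * C_e / (K_m + C_e)
        efflux = PS_H_u * C_i
        inflow = Q_h * (upstream - C_e)
        if j == 0 and portal == 1.0:
            inflow += absorbed
        d[2 + j] = (inflow - uptake + efflux) / V_he_u
        d[7 + j] = (uptake - efflux) / V_h_u
        upstream = C_e

    # peripheral tissues: adipose (16), skin (21), muscle (26) parameter blocks
    peripheral_return = 0.0
    for k in range(3):
        base = 16 + 5 * k
        Q_t = p[base]; V_e = p[base + 1]; V_i = p[base + 2]
        V_max_t = p[base + 3]; PS_t = p[base + 4]
        i = 12 + 2 * k
        C_e = y[i]; C_i = y[i + 1]
        uptake = V_max_t * C_e / (K_m + C_e)
        efflux = PS_t * C_i
        d[i] = (Q_t * (C_p - C_e) - uptake + efflux) / V_e
        d[i + 1] = (uptake - efflux) / V_i
        peripheral_return += Q_t * (C_e - C_p)

    # renal duct: filtration in, saturable reabsorption back, urine out
    C_d = y[18]
    reabsorption = V_maxD * C_d / (K_m + C_d)
    d[18] = (GFR * C_p - reabsorption - Q_u * C_d) / V_d

    # RBC precursor pool and circulating RBC
    A_pre = y[19]; C_RBC = y[20]
    precursor_uptake = V_maxP * C_p / (K_m + C_p)
    d[19] = precursor_uptake - k_1 * A_pre
    rbc_return = k_b * V_RBC * C_RBC
    d[20] = (k_1 * A_pre - rbc_return) / V_RBC

    d[1] = (
        Q_h * (y[6] - C_p)
        + peripheral_return
        - GFR * C_p
        + reabsorption
        - precursor_uptake
        + rbc_return
        + (0.0 if portal == 1.0 else absorbed)
    ) / V_p
    return d


def rhs(
    t: float,
    state: np.ndarray | SystemState,
    params: ModelParameters,
    derived: DerivedParameters | None = None,
) -> np.ndarray:
    """Time derivative of the 21-compartment state (validated wrapper)."""
    if isinstance(state, SystemState):
        y = state.to_vector()
    else:
        y = np.asarray(state, dtype=float)
    bad = ~np.isfinite(y)
    if bad.any():
        names = [STATE_NAMES[i] for i in np.flatnonzero(bad)]
        raise NumericalStateError(f"non-finite state in compartment(s): {', '.join(names)}")
    return rhs_packed(float(t), y, pack_parameters(params, derived))


def total_amount(y: np.ndarray, params: ModelParameters) -> float:
    """Total EGT amount in the body, μmol."""
    y = np.asarray(y, dtype=float)
    amount = y[0] + params.V_p * y[1]
    amount += (params.V_he / 5.0) * y[2:7].sum() + (params.V_h / 5.0) * y[7:12].sum()
    amount += params.V_ae * y[12] + params.V_a * y[13]
    amount += params.V_se * y[14] + params.V_s * y[15]
    amount += params.V_me * y[16] + params.V_m * y[17]
    amount += params.V_d * y[18] + y[19] + params.V_RBC * y[20]
    return float(amount)


def amount_derivative(dydt: np.ndarray, params: ModelParameters) -> float:
    """d/dt of the total body amount implied by a derivative vector, μmol/h.

    By construction of the mass balances this equals ``R − Q_u·C_d`` for any
    state: only dietary input and urine cross the system boundary.
    """
    return total_amount(dydt, params)


@njit(cache=True)
def _rk4_loop(y0, p, t_span, dt):  # pragma: no cover - compiled
    y = y0.copy()
    t = t_span[0]
    n = int(np.ceil((t_span[1] - t_span[0]) / dt))
    h = (t_span[1] - t_span[0]) / n
    for _ in range(n):
        k1 = rhs_packed(t, y, p)
        k2 = rhs_packed(t + 0.5 * h, y + 0.5 * h * k1, p)
        k3 = rhs_packed(t + 0.5 * h, y + 0.5 * h * k2, p)
        k4 = rhs_packed(t + h, y + h * k3, p)
        y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        t += h
    return y


def rk4_integrate(
    y0: np.ndarray,
    params: ModelParameters,
    t_span: tuple[float, float],
    dt: float = 2e-4,
    derived: DerivedParameters | None = None,
) -> np.ndarray:
    """Fixed-step classical Runge–Kutta integration (brute-force oracle).

    The liver extracellular sub-units relax at ≈1.4e3 /h, so the explicit
    step must satisfy dt ≲ 2e-3 h for stability; the default 2e-4 h leaves
    an order-of-magnitude margin and resolves the fast transients.
    """
    p = pack_parameters(params, derived)
    return _rk4_loop(np.asarray(y0, dtype=float), p, np.asarray(t_span, dtype=float), dt)
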