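"""Matrix and unit conversions.

Whole blood is a volume-weighted mixture of red cells and plasma, so
``C_Blood = Hct·C_RBC + (1 − Hct)·C_Plasma``; :func:`blood_to_rbc` is the
rearrangement used to recover the RBC concentration from the two measured
matrices.  Dose conversions use the molar mass of L-ergothioneine
(C9H15N3O2S, 229.30 g/mol).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "MOLAR_MASS_EGT",
    "blood_to_rbc",
    "rbc_plasma_to_blood",
    "dose_mg_to_umol",
    "umol_to_mg",
    "rate_umol_per_h_to_mg_per_day",
]

#: Molar mass of L-ergothioneine, g/mol.
MOLAR_MASS_EGT = 229.30


def _check_hct(Hct: float) -> None:
    if not 0.0 < Hct < 1.0:
        raise ValueError(f"hematocrit must lie strictly in (0, 1), got {Hct!r}")


def blood_to_rbc(C_Blood, C_Plasma, Hct: float):
    """RBC concentration from whole-blood and plasma concentrations (μM).

    Returns ``(C_Blood − C_Plasma·(1 − Hct)) / Hct``.  A negative result
    means the measured pair is physically impossible at this hematocrit and
    raises ``ValueError``.
    """
    _check_hct(Hct)
    C_Blood = np.asarray(C_Blood, dtype=float)
    C_Plasma = np.asarray(C_Plasma, dtype=float)
    if np.any(C_Blood < 0) or np.any(C_Plasma < 0):
        raise ValueError("concentrations must be non-negative")
    out = (C_Blood - C_Plasma * (1.0 - Hct)) / Hct
    if np.any(out < 0):
        raise ValueError(
            "blood/plasma pair implies a negative RBC concentration "
            "(physically impossible at this hematocrit)"
        )
    return float(out) if out.ndim == 0 else out


def rbc_plasma_to_blood(C_RBC, C_Plasma, Hct: float):
    """Whole-blood concentration ``Hct·C_RBC + (1 − Hct)·C_Plasma`` (μM)."""
    _check_hct(Hct)
    C_RBC = np.asarray(C_RBC, dtype=float)
    C_Plasma = np.asarray(C_Plasma, dtype=float)
    out = Hct * C_RBC + (1.0 - Hct) * C_Plasma
    return float(out) if out.ndim == 0 else out


def dose_mg_to_umol(mg: float) -> float:
    """Convert an EGT dose in mg to μmol."""
    if mg < 0:
        raise ValueError("dose must be non-negative")
    return mg * 1000.0 / MOLAR_MASS_EGT


def umol_to_mg(umol: float) -> float:
    """Convert an EGT amount in μmol to mg."""
    if umol < 0:
        raise ValueError("amount must be non-negative")
    return umol * MOLAR_MASS_EGT / 1000.0


def rate_umol_per_h_to_mg_per_day(rate: float) -> float:
    """Convert an intake rate in μmol/h to mg/day (e.g. 1.36 → 7.48)."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    return umol_to_mg(rate) * 24.0
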