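"""Nonlinear least-squares calibration of the PBPK model.

Three parameters are identifiable from mean plasma and RBC profiles alone:
the dietary ingestion rate ``R``, the renal reabsorption maximum
``V_maxD``, and the RBC-precursor uptake maximum ``V_maxP``.  They are
estimated jointly across all dose arms and both matrices by trust-region
least squares on log-parameters (which enforces positivity), each arm
simulated from its own pinned baseline initial values.

Weighting schemes (for residual r = obs − pred):

* ``relative`` (default): r/pred — squared residuals weighted 1/pred².
  Needed for plasma (~5 μM) and RBC (~600 μM) data to contribute
  comparably in a joint fit.
* ``sqrt``: r/√pred — 1/pred weighting of squared residuals.
* ``uniform``: r unweighted.

Parameter uncertainty is the Gauss–Newton approximation at the optimum:
cov(log θ) = s²·(JᵀJ)⁻¹ with s² = RSS/(n − p), whose diagonal square roots
are (to first order) the coefficients of variation of the estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .initial import initialize
from .parameters import ModelParameters, derive_parameters
from .simulate import DoseRegimen, run_simulation

__all__ = ["ArmData", "ErgothioneinePBPK", "PBPKResults", "FitError", "blushup_refit"]

FREE_DEFAULT = ("R", "V_maxD", "V_maxP")
_WEIGHTINGS = ("relative", "sqrt", "uniform")


class FitError(RuntimeError):
    """Optimizer failure; carries the last iterate in ``last_params``."""

    def __init__(self, message: str, last_params: dict | None = None):
        super().__init__(message)
        self.last_params = last_params or {}


@dataclass(frozen=True)
class ArmData:
    """One dose arm: regimen, pinned baselines, observed mean profiles.

    ``observations`` columns: ``time_h``, ``matrix`` (plasma|rbc),
    ``concentration_uM`` — arm-level means at the sampling times.
    """

    dose_mg: float
    init_plasma: float
    init_rbc: float
    observations: pd.DataFrame
    interval_h: float = 24.0

    def __post_init__(self) -> None:
        required = {"time_h", "matrix", "concentration_uM"}
        missing = required - set(self.observations.columns)
        if missing:
            raise ValueError(f"observations missing column(s): {sorted(missing)}")
        bad = set(self.observations["matrix"]) - {"plasma", "rbc"}
        if bad:
            raise ValueError(f"observations contain unknown matrix label(s): {sorted(bad)}")

    @property
    def duration_weeks(self) -> float:
        return float(self.observations["time_h"].max()) / 168.0


class ErgothioneinePBPK:
    """PBPK model of oral ergothioneine bound to concentration data.

    Parameters
    ----------
    arms
        Dose arms with observed mean plasma/RBC profiles.  At least two
        dose levels with three or more time points per matrix are required
        to identify the three free parameters.
    params
        Fixed physiological parameterization; free parameters start from
        the values carried here.
    free
        Names of the parameters to estimate (default R, V_maxD, V_maxP).
    weighting
        Residual weighting scheme: relative | sqrt | uniform.
    rtol
        Integrator relative tolerance used during fitting.
    """

    def __init__(
        self,
        arms: list[ArmData],
        params: ModelParameters | None = None,
        free: tuple[str, ...] = FREE_DEFAULT,
        weighting: str = "relative",
        rtol: float = 1e-6,
    ):
        if len({a.dose_mg for a in arms}) < 2:
            raise ValueError("at least two distinct dose levels are required")
        for a in arms:
            counts = a.observations.groupby("matrix")["time_h"].nunique()
            if (counts < 3).any() or len(counts) < 2:
                raise ValueError(
                    f"arm {a.dose_mg} mg/day needs ≥3 time points in both plasma and rbc"
                )
        if weighting not in _WEIGHTINGS:
            raise ValueError(f"weighting must be one of {_WEIGHTINGS}")
        self.arms = list(arms)
        self.params = params if params is not None else ModelParameters()
        self.free = tuple(free)
        self.weighting = weighting
        self.rtol = rtol
        self._obs = self._stack_observations()

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        inits: dict[float, tuple[float, float]],
        **kwargs,
    ) -> "ErgothioneinePBPK":
        """Build from a tidy frame with columns ``dose_mg_per_day``,
        ``time_h``, ``matrix``, ``mean_concentration_uM``; ``inits`` maps
        dose → (baseline plasma μM, baseline RBC μM)."""
        arms = []
        for dose, sub in data.groupby("dose_mg_per_day"):
            if dose not in inits:
                raise ValueError(f"no initial values supplied for the {dose} mg/day arm")
            cp0, crbc0 = inits[dose]
            obs = sub.rename(columns={"mean_concentration_uM": "concentration_uM"})[
                ["time_h", "matrix", "concentration_uM"]
            ].reset_index(drop=True)
            arms.append(ArmData(float(dose), cp0, crbc0, obs))
        return cls(arms, **kwargs)

    # ------------------------------------------------------------------
    def _stack_observations(self) -> pd.DataFrame:
        frames = []
        for a in self.arms:
            f = a.observations.copy()
            f["dose_mg"] = a.dose_mg
            frames.append(f)
        obs = pd.concat(frames, ignore_index=True)
        obs = obs.sort_values(["dose_mg", "matrix", "time_h"]).reset_index(drop=True)
        return obs

    def predict(self, params: ModelParameters | None = None) -> pd.DataFrame:
        """Model predictions at every observation point (columns of the
        stacked observation frame plus ``predicted_uM``)."""
        params = params if params is not None else self.params
        derived = derive_parameters(params)
        out = self._obs.copy()
        out["predicted_uM"] = np.nan
        for a in self.arms:
            times = np.unique(a.observations["time_h"])
            init = initialize(a.init_plasma, a.init_rbc, params, derived)
            regimen = DoseRegimen(
                dose_mg=a.dose_mg,
                duration_weeks=max(a.duration_weeks, 1e-6),
                interval_h=a.interval_h,
            )
            series = run_simulation(
                regimen, init, params, output_times=times,
                derived=derived, rtol=self.rtol,
            )
            for m in ("plasma", "rbc"):
                sim = series.matrix(m).set_index("time_h")["concentration_uM"]
                mask = (out["dose_mg"] == a.dose_mg) & (out["matrix"] == m)
                out.loc[mask, "predicted_uM"] = sim.reindex(out.loc[mask, "time_h"]).values
        return out

    def _make_params(self, theta_log: np.ndarray) -> ModelParameters:
        changes = {name: float(np.exp(v)) for name, v in zip(self.free, theta_log)}
        return self.params.replace(**changes)

    def _residuals(self, theta_log: np.ndarray) -> np.ndarray:
        pred = self.predict(self._make_params(theta_log))
        obs = pred["concentration_uM"].to_numpy()
        mu = pred["predicted_uM"].to_numpy()
        mu = np.maximum(mu, 1e-12)
        r = obs - mu
        if self.weighting == "relative":
            return r / mu
        if self.weighting == "sqrt":
            return r / np.sqrt(mu)
        return r

    def fit(
        self,
        start: dict[str, float] | None = None,
        multistart: int = 1,
        xtol: float = 1e-8,
        ftol: float = 1e-8,
        diff_step: float = 1e-3,
    ) -> "PBPKResults":
        """Estimate the free parameters by trust-region least squares.

        ``multistart > 1`` additionally starts from geometric perturbations
        of the base values spanning ×0.25…×4 and keeps the best optimum (a
        guard against local minima).  ``diff_step`` is the relative
        finite-difference step for the Jacobian; it must stay well above
        the adaptive integrator's noise floor (``rtol``), otherwise the
        gradient estimates are dominated by integration noise.
        """
        base = {name: getattr(self.params, name) for name in self.free}
        if start:
            base.update(start)
        theta0 = np.log([base[name] for name in self.free])

        starts = [theta0]
        if multistart > 1:
            rng = np.random.default_rng(0)  # fixed: multistart pattern is part of the method
            for _ in range(multistart - 1):
                starts.append(theta0 + rng.uniform(np.log(0.25), np.log(4.0), size=len(theta0)))

        best = None
        last = theta0
        for s in starts:
            sol = least_squares(
                self._residuals, s, method="trf", xtol=xtol, ftol=ftol, gtol=1e-10,
                diff_step=diff_step,
            )
            last = sol.x
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None or not best.success:
            raise FitError(
                f"least-squares did not converge: {getattr(best, 'message', 'no solution')}",
                last_params=dict(zip(self.free, np.exp(last))),
            )
        return PBPKResults._from_solution(self, best)


@dataclass
class PBPKResults:
    """Calibration results: estimates, precision, residual diagnostics."""

    model: ErgothioneinePBPK
    params: pd.Series            # point estimates on the natural scale
    cv_percent: pd.Series        # Gauss–Newton CVs of the estimates, %
    bse_log: pd.Series           # standard errors on the log scale
    rss: float                   # weighted residual sum of squares
    nobs: int
    residuals: pd.DataFrame      # per-point observed/predicted/weighted residual
    success: bool
    message: str
    nfev: int
    fitted_params: ModelParameters = field(repr=False, default=None)

    @classmethod
    def _from_solution(cls, model: ErgothioneinePBPK, sol) -> "PBPKResults":
        theta = sol.x
        estimates = pd.Series(np.exp(theta), index=list(model.free))
        n, p = sol.fun.size, theta.size
        dof = max(n - p, 1)
        s2 = 2.0 * sol.cost / dof
        J = sol.jac
        JtJ = J.T @ J
        try:
            cov_log = s2 * np.linalg.inv(JtJ)
            bse_log = np.sqrt(np.maximum(np.diag(cov_log), 0.0))
            cv = 100.0 * bse_log  # log-scale SE ≈ relative SE of the natural estimate
        except np.linalg.LinAlgError:
            bse_log = np.full(p, np.nan)
            cv = np.full(p, np.nan)
        fitted = model._make_params(theta)
        resid = model.predict(fitted)
        resid["weighted_residual"] = sol.fun
        return cls(
            model=model,
            params=estimates,
            cv_percent=pd.Series(cv, index=list(model.free)),
            bse_log=pd.Series(bse_log, index=list(model.free)),
            rss=float(2.0 * sol.cost),
            nobs=int(n),
            residuals=resid,
            success=bool(sol.success),
            message=str(sol.message),
            nfev=int(sol.nfev),
            fitted_params=fitted,
        )

    def summary(self) -> str:
        lines = [
            "Ergothioneine PBPK calibration (nonlinear least squares)",
            "=" * 60,
            f"arms: {[a.dose_mg for a in self.model.arms]} mg/day   "
            f"observations: {self.nobs}   weighting: {self.model.weighting}",
            f"weighted RSS: {self.rss:.6g}   function evals: {self.nfev}",
            "-" * 60,
            f"{'parameter':<10}{'estimate':>14}{'CV %':>10}",
        ]
        for name in self.params.index:
            lines.append(
                f"{name:<10}{self.params[name]:>14.4g}{self.cv_percent[name]:>10.3g}"
            )
        lines.append("=" * 60)
        return "\n".join(lines)


def blushup_refit(
    fitted: PBPKResults,
    extra_arms: list[ArmData],
    **fit_kwargs,
) -> PBPKResults:
    """Refit after adding dose arms (e.g. folding a later trial's arm in).

    Builds a new model with the combined arms, starting from the previous
    estimates, and returns the new results; the ratio new/old estimates
    quantifies how the added data shift the calibration.
    """
    model = fitted.model
    new = ErgothioneinePBPK(
        model.arms + list(extra_arms),
        params=model.params,
        free=model.free,
        weighting=model.weighting,
        rtol=model.rtol,
    )
    start = {name: float(fitted.params[name]) for name in model.free}
    return new.fit(start=start, **fit_kwargs)
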