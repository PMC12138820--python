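import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ergopk

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def params() -> ergopk.ModelParameters:
    return ergopk.ModelParameters()


@pytest.fixture(scope="session")
def derived(params) -> ergopk.DerivedParameters:
    return ergopk.derive_parameters(params)


@pytest.fixture(scope="session")
def init_316(params) -> ergopk.InitialCondition:
    """Dose-projection initial condition: plasma 3.16 μM, RBC 594 μM."""
    return ergopk.initialize(3.16, 594.0, params)


@pytest.fixture(scope="session")
def study1_times() -> np.ndarray:
    """Sampling times of the 8-week PK study (days 0/8/14/21/28/56), h."""
    return np.array([0.0, 8.0, 14.0, 21.0, 28.0, 56.0]) * 24.0


@pytest.fixture(scope="session")
def study1_inits() -> dict:
    """Printed per-arm baseline (blank) values used to pin initial states."""
    return {5.0: (3.42, 624.0), 10.0: (3.51, 562.0), 20.0: (2.97, 594.0)}


@pytest.fixture(scope="session")
def noise_free_arm_means(params, study1_times, study1_inits):
    """Mean plasma/RBC profiles simulated at the default (generating) values.

    Used as exact calibration targets: fitting these must recover the
    generating parameters.
    """
    import pandas as pd

    rows = []
    for dose, (cp0, crbc0) in study1_inits.items():
        init = ergopk.initialize(cp0, crbc0, params)
        regimen = ergopk.DoseRegimen(dose_mg=dose, duration_weeks=study1_times[-1] / 168.0)
        series = ergopk.run_simulation(
            regimen, init, params, output_times=study1_times, rtol=1e-8
        )
        for m in ("plasma", "rbc"):
            for t in study1_times:
                rows.append(
                    {"dose_mg_per_day": dose, "time_h": t, "matrix": m,
                     "mean_concentration_uM": series.value(t, m)}
                )
    return pd.DataFrame(rows)
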