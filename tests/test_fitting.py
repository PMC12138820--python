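"""Calibration behavior: fixed points, refits, directional shifts, CVs."""

import numpy as np
import pandas as pd
import pytest

import ergopk
from ergopk.fitting import ArmData, ErgothioneinePBPK, blushup_refit

TRUTH = {"R": 1.36, "V_maxD": 121.0, "V_maxP": 11.1}


def _make_model(means, inits, params, **kw):
    kw.setdefault("rtol", 1e-6)
    return ErgothioneinePBPK.from_dataframe(means, inits, params=params, **kw)


def _extra_arm(params, dose=8.0, cp0=4.07, crbc0=594.0, inflate=1.0):
    """Noise-free arm simulated at the default parameters."""
    times = np.array([0.0, 8, 14, 21, 28, 56]) * 24.0
    init = ergopk.initialize(cp0, crbc0, params)
    series = ergopk.run_simulation(
        ergopk.DoseRegimen(dose_mg=dose, duration_weeks=8), init, params,
        output_times=times, rtol=1e-8,
    )
    rows = []
    for m in ("plasma", "rbc"):
        for t in times:
            c = series.value(t, m)
            rows.append({"time_h": t, "matrix": m,
                         "concentration_uM": c * (inflate if m == "plasma" else 1.0)})
    return ArmData(dose, cp0 * inflate, crbc0, pd.DataFrame(rows))


class TestModelConstruction:
    def test_requires_two_dose_levels(self, noise_free_arm_means, study1_inits, params):
        one_arm = noise_free_arm_means[noise_free_arm_means.dose_mg_per_day == 5.0]
        with pytest.raises(ValueError, match="two distinct dose levels"):
            _make_model(one_arm, study1_inits, params)

    def test_requires_three_points_per_matrix(self, noise_free_arm_means, study1_inits, params):
        sparse = noise_free_arm_means[noise_free_arm_means.time_h <= 200.0]
        with pytest.raises(ValueError, match="3 time points"):
            _make_model(sparse, study1_inits, params)

    def test_missing_inits_rejected(self, noise_free_arm_means, params):
        with pytest.raises(ValueError, match="initial values"):
            _make_model(noise_free_arm_means, {5.0: (3.42, 624.0)}, params)

    def test_unknown_weighting_rejected(self, noise_free_arm_means, study1_inits, params):
        with pytest.raises(ValueError, match="weighting"):
            _make_model(noise_free_arm_means, study1_inits, params, weighting="huber")


class TestFixedPoint:
    def test_truth_start_converges_immediately_with_zero_rss(
        self, noise_free_arm_means, study1_inits, params
    ):
        """Starting at the generating values on self-generated data the
        optimizer has nothing to improve: the solution is a fixed point."""
        model = _make_model(noise_free_arm_means, study1_inits, params, rtol=1e-8)
        res = model.fit()
        assert res.success
        assert res.rss < 1e-10
        for name, value in TRUTH.items():
            assert res.params[name] == pytest.approx(value, rel=1e-4)

    def test_refit_from_solution_is_stable(self, noise_free_arm_means, study1_inits, params):
        model = _make_model(noise_free_arm_means, study1_inits, params, rtol=1e-8)
        first = model.fit()
        second = model.fit(start={k: float(v) for k, v in first.params.items()})
        for name in TRUTH:
            assert second.params[name] == pytest.approx(first.params[name], rel=1e-6)


class TestBlushupRefit:
    def test_redundant_consistent_arm_leaves_estimates_unchanged(
        self, noise_free_arm_means, study1_inits, params
    ):
        model = _make_model(noise_free_arm_means, study1_inits, params, rtol=1e-8)
        base = model.fit()
        refit = blushup_refit(base, [_extra_arm(params)])
        for name in TRUTH:
            ratio = refit.params[name] / base.params[name]
            assert ratio == pytest.approx(1.0, abs=5e-3)

    def test_inflated_plasma_arm_pulls_dietary_rate_up(
        self, noise_free_arm_means, study1_inits, params
    ):
        """A fourth arm whose plasma runs 10% high demands more dietary
        input: R must move upward (matching its positive plasma
        sensitivity)."""
        model = _make_model(noise_free_arm_means, study1_inits, params, rtol=1e-8)
        base = model.fit()
        refit = blushup_refit(base, [_extra_arm(params, inflate=1.10)])
        assert refit.params["R"] > base.params["R"] * 1.01


class TestUncertainty:
    @pytest.fixture(scope="class")
    def perturbed_fit(self, noise_free_arm_means, study1_inits, params):
        """Fit to data with a small deterministic ±2% ripple so the RSS,
        and hence the covariance estimate, is non-degenerate."""
        noisy = noise_free_arm_means.copy()
        ripple = 1.0 + 0.02 * np.where(np.arange(len(noisy)) % 2 == 0, 1.0, -1.0)
        noisy["mean_concentration_uM"] *= ripple
        model = _make_model(noisy, study1_inits, params)
        return model, model.fit()

    def test_cvs_are_positive_and_finite(self, perturbed_fit):
        _, res = perturbed_fit
        assert (res.cv_percent > 0).all()
        assert np.isfinite(res.cv_percent).all()

    def test_cvs_shrink_as_sqrt_of_replication(
        self, perturbed_fit, study1_inits, params
    ):
        """Quadruplicating every observation halves the standard errors
        (1/√n scaling of the Gauss–Newton covariance)."""
        model, res = perturbed_fit
        rep = pd.concat([model._obs] * 4, ignore_index=True).rename(
            columns={"concentration_uM": "mean_concentration_uM"}
        )[["dose_mg", "time_h", "matrix", "mean_concentration_uM"]].rename(
            columns={"dose_mg": "dose_mg_per_day"}
        )
        model4 = _make_model(rep, study1_inits, params)
        res4 = model4.fit(start={k: float(v) for k, v in res.params.items()})
        ratio = (res4.cv_percent / res.cv_percent).to_numpy()
        assert np.allclose(ratio, 0.5, atol=0.12)

    def test_summary_mentions_every_free_parameter(self, perturbed_fit):
        _, res = perturbed_fit
        text = res.summary()
        for name in TRUTH:
            assert name in text
        assert "CV %" in text
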