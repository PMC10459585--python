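"""Kinetics model fits: exact recovery, oracle equivalence, windows."""

import numpy as np
import pytest

import gridrelease as gr
from gridrelease.exceptions import DomainError, InsufficientDataError
from gridrelease.kinetics import evaluate_model

from conftest import power_law_profile


def normal_equations(x, y):
    """Independent closed-form least squares: slope and intercept."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx, sxy = sum(v * v for v in x), sum(a * b for a, b in zip(x, y))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept


class TestPowerLawFit:
    def test_exact_recovery_of_noiseless_power_law(self):
        profile = power_law_profile(k=0.05, n=0.65, times=np.arange(1.0, 40.0))
        fit = gr.kp_fit(profile)
        assert fit.params["n"] == pytest.approx(0.65, abs=1e-6)
        assert fit.params["k"] == pytest.approx(0.05, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_square_root_data_gives_half(self):
        t = np.arange(1.0, 50.0)
        profile = gr.ReleaseProfile("h", t, 20.0 * 0.07 * np.sqrt(t), 20.0)
        assert gr.kp_fit(profile).params["n"] == pytest.approx(0.5, abs=1e-9)

    def test_anomalous_regime_exponents_recovered(self, implant_names):
        # burst-free power-law runs of the nine study implants: the fitted
        # exponent stays in the anomalous-transport band
        for i, name in enumerate(implant_names):
            spec = gr.implant_spec(name, seed=50 + i, burst_fraction=0.0)
            profile = gr.cumulative_release(gr.simulate_study(spec),
                                            spec.dose_mg, name)
            n = gr.kp_fit(profile).params["n"]
            assert 0.45 <= n <= 1.0, f"{name}: fitted n={n:.3f}"

    def test_insufficient_points_raise(self):
        profile = power_law_profile(times=np.array([1.0, 2.0]))
        with pytest.raises(InsufficientDataError):
            gr.kp_fit(profile)

    def test_oracle_equivalence_on_five_point_toy(self):
        t = np.array([1.0, 3.0, 7.0, 15.0, 40.0])
        rel = np.array([0.06, 0.11, 0.18, 0.27, 0.45])
        profile = gr.ReleaseProfile("toy", t, rel * 10.0, 10.0)
        fit = gr.kp_fit(profile, window=(0.0, 1.0))
        slope, intercept = normal_equations(np.log10(t).tolist(),
                                            np.log10(rel).tolist())
        assert fit.params["n"] == pytest.approx(slope, abs=1e-10)
        assert fit.params["k"] == pytest.approx(10**intercept, abs=1e-10)

    def test_window_discipline_outside_points_inert(self):
        t = np.arange(1.0, 30.0)
        rel = 0.05 * t**0.6
        base = gr.ReleaseProfile("a", t, rel * 10, 10.0)
        perturbed_rel = rel.copy()
        perturbed_rel[rel >= 0.60] += 0.2   # outside the window
        perturbed_rel[rel <= 0.05] *= 0.5
        pert = gr.ReleaseProfile("b", t, perturbed_rel * 10, 10.0)
        fa, fb = gr.kp_fit(base), gr.kp_fit(pert)
        assert fa.params == fb.params
        assert fa.n_points == fb.n_points

    def test_window_matters_on_burst_profile(self, noiseless_profile):
        narrow = gr.kp_fit(noiseless_profile, window=(0.05, 0.60))
        wide = gr.kp_fit(noiseless_profile, window=(0.0, 1.0))
        assert narrow.params["n"] != wide.params["n"]


class TestMechanismClassification:
    @pytest.mark.parametrize("n,label", [
        (0.65, "anomalous"), (0.45, "fickian"), (1.20, "super_case_II"),
        (1.0, "case_II"), (0.30, "sub_fickian"), (0.46, "fickian"),
    ])
    def test_thresholds(self, n, label):
        mech = gr.classify_mechanism(n, tolerance=0.02)
        assert mech.label == label
        assert "cylindrical" in mech.geometry_caveat

    def test_non_finite_rejected(self):
        with pytest.raises(DomainError):
            gr.classify_mechanism(float("nan"))


class TestHiguchiFit:
    def test_exact_sqrt_profile(self):
        t = np.linspace(1.0, 16.0, 20)
        area = 10.0
        q = 0.14 * np.sqrt(t)
        profile = gr.ReleaseProfile("h", t, q * area, dose_mg=10.0)
        fit = gr.higuchi_fit(profile, area)
        assert fit.params["dk"] == pytest.approx(0.14, abs=1e-12)
        assert fit.params["intercept"] == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_generator_round_trip_dk(self):
        # truth M_t = 0.1371·15.30·√t; the fit must return the constant
        t = np.linspace(2.0, 60.0, 25)
        dose = 24.1
        profile = gr.ReleaseProfile("g", t, 0.1371 * 15.30 * np.sqrt(t), dose)
        fit = gr.higuchi_fit(profile, 15.30)
        assert fit.params["dk"] == pytest.approx(0.1371, abs=1e-10)

    def test_scale_invariance(self):
        t = np.linspace(1.0, 30.0, 15)
        mass = 0.1 * 12.0 * np.sqrt(t)
        p1 = gr.ReleaseProfile("a", t, mass, 20.0)
        p2 = gr.ReleaseProfile("b", t, 2 * mass, 40.0)
        f1 = gr.higuchi_fit(p1, 12.0)
        f2 = gr.higuchi_fit(p2, 24.0)
        assert f2.params["dk"] == pytest.approx(f1.params["dk"], rel=1e-12)

    def test_oracle_equivalence_on_five_point_toy(self):
        t = np.array([1.0, 4.0, 9.0, 25.0, 49.0])
        q = np.array([0.15, 0.29, 0.44, 0.73, 1.02])
        area, dose = 8.0, 12.0
        profile = gr.ReleaseProfile("toy", t, q * area, dose)
        fit = gr.higuchi_fit(profile, area, window=(0.0, 1.0))
        slope, intercept = normal_equations(np.sqrt(t).tolist(), q.tolist())
        assert fit.params["dk"] == pytest.approx(slope, abs=1e-10)
        assert fit.params["intercept"] == pytest.approx(intercept, abs=1e-10)

    def test_rejects_nonpositive_area(self):
        profile = power_law_profile()
        with pytest.raises(DomainError):
            gr.higuchi_fit(profile, 0.0)


class TestNonlinearFits:
    def test_weibull_parameter_recovery(self):
        t = np.linspace(0.5, 40.0, 40)
        rel = 1.0 - np.exp(-0.05 * t**0.8)
        profile = gr.ReleaseProfile("w", t, rel * 20, 20.0)
        fit = gr.nonlinear_fit(profile, "weibull")
        assert fit.converged
        assert fit.params["a"] == pytest.approx(0.05, abs=1e-4)
        assert fit.params["b"] == pytest.approx(0.8, abs=1e-4)

    def test_weibull_first_order_special_case(self):
        t = np.linspace(0.5, 9.0, 25)
        rel = 1.0 - np.exp(-0.1 * t)
        profile = gr.ReleaseProfile("w1", t, rel * 6, 6.0)
        fit = gr.nonlinear_fit(profile, "weibull")
        assert fit.params["a"] == pytest.approx(0.1, abs=1e-6)
        assert fit.params["b"] == pytest.approx(1.0, abs=1e-6)

    def test_peppas_sahlin_parameter_recovery(self):
        t = np.linspace(0.5, 30.0, 40)
        rel = 0.04 * t**0.45 + 0.002 * t**0.9
        profile = gr.ReleaseProfile("ps", t, rel * 30, 30.0)
        fit = gr.nonlinear_fit(profile, "peppas_sahlin")
        assert fit.converged
        assert fit.params["k1"] == pytest.approx(0.04, abs=1e-3)
        assert fit.params["k2"] == pytest.approx(0.002, abs=1e-3)
        assert fit.params["m"] == pytest.approx(0.45, abs=1e-3)

    def test_model_evaluation_matches_fit(self):
        t = np.linspace(0.5, 40.0, 30)
        rel = 1.0 - np.exp(-0.05 * t**0.8)
        profile = gr.ReleaseProfile("w", t, rel * 20, 20.0)
        fit = gr.nonlinear_fit(profile, "weibull")
        pred = evaluate_model("weibull", fit.params, t)
        assert np.max(np.abs(pred - rel)) < 1e-4

    def test_unknown_model_rejected(self):
        with pytest.raises(DomainError):
            gr.nonlinear_fit(power_law_profile(), "zero_order")

    def test_fits_on_study_fixture_converge(self, study_profiles):
        for name, profile in study_profiles.items():
            for model in ("peppas_sahlin", "weibull"):
                fit = gr.nonlinear_fit(profile, model)
                assert fit.converged, f"{name}/{model}"
                assert fit.r_squared > 0.9, f"{name}/{model}: r2={fit.r_squared:.3f}"
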