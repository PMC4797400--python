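import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mobydose.biokinetics import (
    BiexponentialFit,
    DegenerateFitError,
    DivergentIntegralError,
    InsufficientDataError,
    MARROW_TO_BLOOD_RATIO,
    TimeActivityCurve,
    UnitMismatchError,
    cumulated_activity,
    cumulated_activity_quadrature,
    decays_per_mbq_administered,
    fit_biexponential,
    marrow_curve_from_blood,
    read_tacs,
    write_tacs,
)

from conftest import LAMBDA_PHYS


def make_tac(times, values, kind="per_gram", region="r"):
    return TimeActivityCurve(region, np.asarray(times, float), np.asarray(values, float), kind)


class TestTimeActivityCurve:
    def test_rejects_nonincreasing_times(self):
        with pytest.raises(ValueError):
            make_tac([0, 10, 10], [1, 1, 1])

    def test_rejects_negative_values(self):
        with pytest.raises(ValueError):
            make_tac([0, 10, 20], [1, -1, 1])

    def test_csv_round_trip(self, tmp_path):
        tacs = {"blood": make_tac([4, 24, 72], [30, 20, 13], region="blood")}
        path = tmp_path / "tacs.csv"
        write_tacs(tacs, path)
        back = read_tacs(path)
        np.testing.assert_allclose(back["blood"].values, [30, 20, 13])
        assert back["blood"].value_kind == "per_gram"

    def test_strict_header_validation(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("organ,hours,val\na,1,2\n")
        with pytest.raises(ValueError, match="expected columns"):
            read_tacs(path)


class TestFit:
    def test_single_exponential_recovered_exactly(self):
        t = np.array([1.0, 24.0, 72.0, 168.0])
        fit = fit_biexponential(make_tac(t, 10 * np.exp(-0.01 * t)), LAMBDA_PHYS)
        assert fit.a1 == pytest.approx(10.0, rel=1e-6)
        assert fit.lambda1 == pytest.approx(0.01, rel=1e-6)
        assert abs(fit.a2) < 1e-6 * 10.0

    def test_uptake_curve_with_negative_amplitude(self):
        # rise-then-fall tumor kinetics: one negative amplitude
        t = np.array([1.0, 4.0, 8.0, 24.0, 48.0, 72.0, 120.0, 168.0])
        y = -20 * np.exp(-0.05 * t) + 30 * np.exp(-0.004 * t)
        fit = fit_biexponential(make_tac(t, y), LAMBDA_PHYS)
        assert fit.a1 == pytest.approx(-20.0, rel=1e-4)
        assert fit.lambda1 == pytest.approx(0.05, rel=1e-4)
        assert fit.a2 == pytest.approx(30.0, rel=1e-4)
        assert fit.lambda2 == pytest.approx(0.004, rel=1e-4)

    def test_constant_curve(self):
        fit = fit_biexponential(make_tac([1, 24, 72, 168], [5, 5, 5, 5]), LAMBDA_PHYS)
        total0 = fit(0.0)
        assert total0 == pytest.approx(5.0, rel=1e-6)
        assert fit(200.0) == pytest.approx(5.0, rel=1e-4)

    def test_insufficient_points(self):
        with pytest.raises(InsufficientDataError):
            fit_biexponential(make_tac([1, 24, 72], [1, 2, 3]), LAMBDA_PHYS)

    def test_all_zero_curve(self):
        with pytest.raises(DegenerateFitError):
            fit_biexponential(make_tac([1, 24, 72, 168], [0, 0, 0, 0]), LAMBDA_PHYS)

    def test_deterministic(self):
        t = np.array([1.0, 24.0, 72.0, 168.0])
        y = 7 * np.exp(-0.02 * t) + 2 * np.exp(-0.001 * t)
        f1 = fit_biexponential(make_tac(t, y), LAMBDA_PHYS)
        f2 = fit_biexponential(make_tac(t, y), LAMBDA_PHYS)
        assert (f1.a1, f1.lambda1, f1.a2, f1.lambda2) == (f2.a1, f2.lambda1, f2.a2, f2.lambda2)

    @given(scale=st.floats(min_value=0.1, max_value=50.0))
    @settings(deadline=None, max_examples=20, derandomize=True)
    def test_scale_equivariance(self, scale):
        # multiplying values by c scales amplitudes by c, leaves rates alone
        t = np.array([1.0, 24.0, 72.0, 168.0])
        y = 8 * np.exp(-0.03 * t) + 3 * np.exp(-0.002 * t)
        base = fit_biexponential(make_tac(t, y), LAMBDA_PHYS)
        scaled = fit_biexponential(make_tac(t, scale * y), LAMBDA_PHYS)
        assert scaled.a1 == pytest.approx(scale * base.a1, rel=1e-4)
        assert scaled.a2 == pytest.approx(scale * base.a2, rel=1e-4)
        assert scaled.lambda1 == pytest.approx(base.lambda1, rel=1e-4)
        assert scaled.lambda2 == pytest.approx(base.lambda2, rel=1e-4)


class TestCumulatedActivity:
    def test_zero_amplitudes(self):
        fit = BiexponentialFit("r", 0, 0.01, 0, 0.001, LAMBDA_PHYS, 0.0)
        assert cumulated_activity(fit) == 0.0

    def test_pure_physical_decay(self):
        # A(t)=100 with no biological clearance: integral = 100 / lambda_phys
        fit = BiexponentialFit("r", 100.0, 0.0, 0.0, 0.0, 4.345e-3, 0.0)
        assert cumulated_activity(fit) == pytest.approx(100 / 4.345e-3, rel=1e-12)
        assert cumulated_activity(fit) == pytest.approx(2.301e4, rel=1e-3)

    def test_matches_quadrature(self):
        fit = BiexponentialFit("r", 50.0, 0.01, 25.0, 0.001, 4.345e-3, 0.0)
        assert cumulated_activity(fit) == pytest.approx(
            cumulated_activity_quadrature(fit), rel=1e-6
        )

    def test_divergent_integral_rejected(self):
        with pytest.raises(DivergentIntegralError):
            BiexponentialFit("r", 10.0, -0.01, 0.0, 0.0, 4.345e-3, 0.0)

    def test_closed_form_vs_quadrature_random_parameters(self, rng):
        # property over 100 random integrable parameter sets
        for _ in range(100):
            a1, a2 = rng.uniform(-30, 50, 2)
            if a1 + a2 <= 0:
                a1, a2 = abs(a1), abs(a2) + 0.1
            l1, l2 = rng.uniform(1e-4, 0.5, 2)
            fit = BiexponentialFit("r", a1, max(l1, l2), a2, min(l1, l2), LAMBDA_PHYS, 0.0)
            assert cumulated_activity(fit) == pytest.approx(
                cumulated_activity_quadrature(fit), rel=1e-6
            )


class TestMarrowFromBlood:
    def test_fixed_ratio(self):
        blood = make_tac([24.0], [10.0], region="blood")
        # needs >=1 point; single-point curve is fine for the ratio rule
        marrow = marrow_curve_from_blood(blood)
        assert marrow.values[0] == pytest.approx(0.36 * 10.0)
        assert marrow.region == "marrow"

    def test_linearity_and_times_preserved(self):
        blood = make_tac([4, 24, 72], [1.0, 2.0, 3.0], region="blood")
        marrow = marrow_curve_from_blood(blood)
        np.testing.assert_allclose(marrow.values, [0.36, 0.72, 1.08])
        np.testing.assert_array_equal(marrow.times, blood.times)

    def test_zero_blood_gives_zero_marrow(self):
        marrow = marrow_curve_from_blood(make_tac([4, 24], [0.0, 0.0], region="blood"))
        assert np.all(marrow.values == 0)

    def test_per_organ_input_rejected(self):
        with pytest.raises(UnitMismatchError):
            marrow_curve_from_blood(make_tac([4.0], [10.0], kind="per_organ"))

    def test_ratio_constant_is_the_documented_value(self):
        assert MARROW_TO_BLOOD_RATIO == 0.36


class TestDecaysPerMBq:
    def _flat_fit(self, kind):
        # cumulated activity exactly 100 %IA.h: A1=100*lam, lam1=lam-lphys... simpler:
        # use A1 such that A1/(l1+lphys) = 100
        l1 = 0.01
        return BiexponentialFit("r", 100 * (l1 + LAMBDA_PHYS), l1, 0.0, 0.0, LAMBDA_PHYS, 0.0, kind)

    def test_per_organ_definition(self):
        fit = self._flat_fit("per_organ")
        # 100 %IA.h == 1 MBq.h per MBq administered == 3.6e9 decays
        assert decays_per_mbq_administered(fit) == pytest.approx(3.6e9, rel=1e-9)

    def test_per_gram_mass_scaling(self):
        fit = self._flat_fit("per_gram")
        # 100 %IA/g.h at 0.5 g -> 0.5 MBq.h -> 1.8e9 decays
        assert decays_per_mbq_administered(fit, region_mass_g=0.5) == pytest.approx(
            1.8e9, rel=1e-9
        )

    def test_per_gram_requires_mass(self):
        with pytest.raises(UnitMismatchError):
            decays_per_mbq_administered(self._flat_fit("per_gram"))


class TestParameterRecoveryUnderNoise:
    def test_median_cumulated_activity_error_under_noise(self):
        """Log-normal CV 20 %, n=4 animals/point: median Atilde error < 15 %."""
        t = np.array([4.0, 24.0, 48.0, 72.0, 168.0])
        a1, l1, a2, l2 = -20.0, 0.05, 30.0, 0.004
        truth = BiexponentialFit("r", a1, l1, a2, l2, LAMBDA_PHYS, 0.0)
        true_atilde = cumulated_activity(truth)
        clean = truth(t)
        rng = np.random.default_rng(2024)
        sigma = np.sqrt(np.log(1 + 0.2**2))
        errs = []
        for _ in range(200):
            noise = np.exp(sigma * rng.standard_normal((4, t.size)) - sigma**2 / 2)
            y = clean * noise.mean(axis=0)
            fit = fit_biexponential(make_tac(t, y), LAMBDA_PHYS)
            errs.append(abs(cumulated_activity(fit) - true_atilde) / true_atilde)
        assert np.median(errs) < 0.15
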