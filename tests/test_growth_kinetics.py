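"""Rate estimation: exactness on clean curves, noise recovery, plate effects."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cbsvar.data_model import AssayCondition
from cbsvar.growth_kinetics import (
    GrowthCurve,
    InvalidCurveError,
    NormalizationError,
    default_window,
    estimate_rate,
    normalize_curve,
    plate_normalize,
    relative_rate,
)
from cbsvar.synthetic_data import (
    CurveSimConfig,
    logistic_log_slope,
    simulate_curve,
)

COND = AssayCondition(pyridoxine=400.0)


def exp_curve(rate, start=0.01, hours=84.0, step=0.5, cap=None):
    t = np.arange(0.0, hours, step)
    od = start * 10 ** (rate * t)
    if cap is not None:
        od = np.minimum(od, cap)
    return GrowthCurve("w1", "major", "P1", COND, t, od, endpoint_od=float(od[-1]))


class TestNormalize:
    def test_identity_when_already_scaled(self):
        c = exp_curve(0.05, cap=1.0)
        out = normalize_curve(c)
        np.testing.assert_allclose(out.od, c.od)

    def test_halves_doubled_signal(self):
        c = exp_curve(0.05, cap=1.0)
        doubled = GrowthCurve("w1", "major", "P1", COND, c.times, 2 * c.od,
                              endpoint_od=c.endpoint_od)
        np.testing.assert_allclose(normalize_curve(doubled).od, c.od)

    def test_all_zero_od_rejected(self):
        c = GrowthCurve("w1", "major", "P1", COND, np.arange(5.0),
                        np.zeros(5), endpoint_od=1.0)
        with pytest.raises(InvalidCurveError):
            normalize_curve(c)


class TestEstimateRate:
    def test_exact_on_clean_exponential(self):
        est = estimate_rate(exp_curve(0.05), (0.05, 0.1))
        assert est.attained_window
        assert est.rate == pytest.approx(0.05, abs=1e-9)

    @pytest.mark.parametrize("window", [(0.05, 0.1), (0.1, 0.2), (0.02, 0.5)])
    @pytest.mark.parametrize("rate", [0.02, 0.05, 0.11])
    def test_window_choice_irrelevant_on_clean_curves(self, rate, window):
        est = estimate_rate(exp_curve(rate), window)
        assert est.rate == pytest.approx(rate, abs=1e-9)

    def test_flat_curve_never_attains_window(self):
        t = np.arange(0.0, 84.0, 0.5)
        c = GrowthCurve("w1", "x", "P1", COND, t, np.full_like(t, 0.01),
                        endpoint_od=0.01)
        est = estimate_rate(c, (0.05, 0.1))
        assert not est.attained_window
        assert est.rate is None

    def test_two_points_give_exact_two_point_slope(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        od = np.array([0.01, 0.06, 0.09, 0.5])
        c = GrowthCurve("w1", "x", "P1", COND, t, od, endpoint_od=0.5)
        est = estimate_rate(c, (0.05, 0.1))
        assert est.n_points_used == 2
        expected = (np.log10(0.09) - np.log10(0.06)) / 1.0
        assert est.rate == pytest.approx(expected, abs=1e-12)

    def test_default_window_switches_on_background(self):
        assert default_window(COND) == (0.05, 0.1)
        hem1d = AssayCondition(pyridoxine=400.0, dala=50.0, hem1_deleted=True)
        assert default_window(hem1d) == (0.1, 0.2)

    @given(gain=st.floats(min_value=0.2, max_value=5.0),
           rate=st.floats(min_value=0.02, max_value=0.1))
    @settings(derandomize=True, max_examples=30)
    def test_invariant_under_uniform_od_scaling(self, gain, rate):
        """Endpoint normalization + log-slope cancel any multiplicative gain."""
        cfg = CurveSimConfig(noise_sd=0.0)
        base = simulate_curve(cfg, rate, seed=0)
        gained = simulate_curve(
            CurveSimConfig(noise_sd=0.0, plate_gain=gain), rate, seed=0)
        r1 = estimate_rate(normalize_curve(base), (0.05, 0.1)).rate
        r2 = estimate_rate(normalize_curve(gained), (0.05, 0.1)).rate
        assert r2 == pytest.approx(r1, rel=1e-9)

    def test_logistic_recovery_close_to_window_midpoint_slope(self):
        """On a noisy logistic curve the estimate tracks the closed-form
        log-slope at the window midpoint within 5%."""
        cfg = CurveSimConfig()
        rng = np.random.default_rng(1)
        ests = [
            estimate_rate(normalize_curve(simulate_curve(cfg, 0.05, rng)),
                          (0.05, 0.1)).rate
            for _ in range(50)
        ]
        expected = logistic_log_slope(0.075, cfg, 0.05)
        assert np.mean(ests) == pytest.approx(expected, rel=0.15)
        assert np.median(ests) == pytest.approx(expected, rel=0.15)


class TestPlateNormalize:
    def test_single_plate_factor_one(self):
        rates = {"P1": [("major", 0.05), ("v1", 0.03)]}
        normalized, factors = plate_normalize(rates)
        assert factors["P1"].factor == pytest.approx(1.0)
        assert normalized == rates

    def test_two_plate_factors_forced_by_definition(self):
        rates = {"A": [("major", 0.04)], "B": [("major", 0.06)]}
        _, factors = plate_normalize(rates)
        assert factors["A"].factor == pytest.approx(1.25)
        assert factors["B"].factor == pytest.approx(0.05 / 0.06)

    def test_reference_means_equal_after_normalization(self):
        rates = {"A": [("major", 0.04), ("major", 0.05), ("v", 0.02)],
                 "B": [("major", 0.07), ("v", 0.03)]}
        normalized, _ = plate_normalize(rates)
        means = [np.mean([r for s, r in pairs if s == "major"])
                 for pairs in normalized.values()]
        assert means[0] == pytest.approx(means[1])

    def test_plate_without_reference_rejected(self):
        with pytest.raises(NormalizationError, match="B"):
            plate_normalize({"A": [("major", 0.05)], "B": [("v", 0.03)]})

    def test_rate_level_plate_effect_cancels_in_ratios(self):
        """A 1.2x rate effect on plate B leaves variant/reference ratios
        identical across plates after normalization (exponential curves
        isolate the normalization algebra from logistic attenuation)."""
        cfg = CurveSimConfig(noise_sd=0.0, carrying_capacity=float("inf"))
        per_plate = {}
        for plate, mult in (("A", 1.0), ("B", 1.2)):
            pairs = []
            for strain, ratio in (("major", 1.0), ("v", 0.6)):
                c = simulate_curve(cfg, 0.05 * ratio * mult, seed=0)
                pairs.append((strain,
                              estimate_rate(normalize_curve(c), (0.05, 0.1)).rate))
            per_plate[plate] = pairs
        normalized, _ = plate_normalize(per_plate)
        ratios = {}
        for plate, pairs in normalized.items():
            d = dict(pairs)
            ratios[plate] = relative_rate(d["v"], d["major"])
        assert ratios["A"] == pytest.approx(ratios["B"], rel=1e-9)
        assert ratios["A"] == pytest.approx(0.6, rel=1e-6)


class TestRelativeRate:
    def test_arithmetic(self):
        assert relative_rate(0.04, 0.04) == pytest.approx(1.0)
        assert relative_rate(0.02, 0.04) == pytest.approx(0.5)

    def test_failed_reference_rejected(self):
        with pytest.raises(ValueError):
            relative_rate(0.02, 0.0)
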