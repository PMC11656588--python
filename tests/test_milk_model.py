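import math

import numpy as np
import pytest

from herdspace.errors import ConfigError, InvalidSpanError
from herdspace.milk_model import (
    MilkModelConfig,
    WilminkCurve,
    daily_yield,
    draw_cow_coefficients,
    gestation_category,
    lactation_milk,
)

from conftest import ZERO_SDS, deterministic_milk_config


class Span:
    def __init__(self, end, conception=None):
        self.end = end
        self.conception = conception


def flat_config(scale, ramp=0.0, ramp_rate=0.0, persistency=0.0, **overrides):
    curve = WilminkCurve(scale, ramp, ramp_rate, persistency)
    return deterministic_milk_config(
        curves={"primiparous": curve, "multiparous": curve},
        scenario_effect=overrides.pop("scenario_effect", 0.0),
        gestation_effects=overrides.pop("gestation_effects", (0.0, 0.0, 0.0, 0.0, 0.0)),
        **overrides,
    )


def test_wilmink_closed_form_evaluation(rng):
    # y(1) = 35 - 15 e^{-0.05} - 0.03, checked against a hand calculation
    config = flat_config(35.0, -15.0, 0.05, -0.03)
    coeffs = draw_cow_coefficients(config, rng)
    expected = 35.0 - 15.0 * math.exp(-0.05) - 0.03
    assert daily_yield(coeffs, "control", "multiparous", 1, 0) == pytest.approx(expected, abs=1e-12)
    assert expected == pytest.approx(20.7016, abs=5e-5)


def test_zero_sds_reproduce_means(milk_config, rng):
    config = deterministic_milk_config()
    coeffs = draw_cow_coefficients(config, rng)
    for cls in ("primiparous", "multiparous"):
        assert coeffs.curves[cls] == milk_config.curves[cls]
    assert coeffs.scenario_effect == milk_config.scenario_effect
    assert coeffs.deviation == 0.0


def test_same_seed_same_coefficients(milk_config):
    first = draw_cow_coefficients(milk_config, np.random.default_rng(77))
    second = draw_cow_coefficients(milk_config, np.random.default_rng(77))
    assert first == second


def test_coefficient_draw_sampling_mean():
    # 10,000 draws of a Normal(30, 2) coefficient: mean within ~3 standard errors
    curve = WilminkCurve(30.0, 0.0, 0.0, 0.0)
    config = MilkModelConfig(
        curves={"primiparous": curve, "multiparous": curve},
        curve_sds={
            "primiparous": WilminkCurve(2.0, 0.0, 0.0, 0.0),
            "multiparous": WilminkCurve(0.0, 0.0, 0.0, 0.0),
        },
        scenario_effect=0.0,
        scenario_effect_sd=0.0,
        gestation_effects=(0.0,) * 5,
    )
    gen = np.random.default_rng(2024)
    draws = [draw_cow_coefficients(config, gen).curves["primiparous"].scale for _ in range(10_000)]
    assert np.mean(draws) == pytest.approx(30.0, abs=0.07)
    assert all(
        d.deviation >= 0 for d in [draw_cow_coefficients(config, gen) for _ in range(10)]
    )


def test_deviation_summary_is_rms_of_standardized_draws(milk_config):
    coeffs = draw_cow_coefficients(milk_config, np.random.default_rng(5))
    zs = []
    for cls in ("primiparous", "multiparous"):
        for name in ("scale", "ramp", "ramp_rate", "persistency"):
            sd = getattr(milk_config.curve_sds[cls], name)
            if sd > 0:
                delta = getattr(coeffs.curves[cls], name) - getattr(milk_config.curves[cls], name)
                zs.append(delta / sd)
    if milk_config.scenario_effect_sd > 0:
        zs.append((coeffs.scenario_effect - milk_config.scenario_effect) / milk_config.scenario_effect_sd)
    assert coeffs.deviation == pytest.approx(np.sqrt(np.mean(np.square(zs))), rel=1e-12)


@pytest.mark.parametrize(
    "days_pregnant, category",
    [(0, 0), (1, 1), (56, 1), (57, 2), (112, 2), (113, 3), (168, 3), (169, 4),
     (224, 4), (225, 5), (280, 5), (400, 5)],
)
def test_gestation_category_default_bins(milk_config, days_pregnant, category):
    assert gestation_category(days_pregnant, milk_config) == category


def test_gestation_category_rejects_negative(milk_config):
    with pytest.raises(ConfigError):
        gestation_category(-1, milk_config)


def test_scenario_effect_is_additive(rng):
    config = flat_config(30.0, -5.0, 0.04, -0.02, scenario_effect=1.8)
    coeffs = draw_cow_coefficients(config, rng)
    control = daily_yield(coeffs, "control", "multiparous", 120, 0)
    high = daily_yield(coeffs, "high", "multiparous", 120, 0)
    assert high - control == pytest.approx(1.8, abs=1e-12)


def test_gestation_effect_is_additive(rng):
    config = flat_config(30.0, gestation_effects=(-1.0, -2.0, -3.0, -4.0, -5.0))
    coeffs = draw_cow_coefficients(config, rng)
    open_yield = daily_yield(coeffs, "control", "primiparous", 200, 0)
    late = daily_yield(coeffs, "control", "primiparous", 200, 5)
    assert open_yield - late == pytest.approx(5.0, abs=1e-12)


def test_negative_predictions_floored_at_zero(rng):
    config = flat_config(1.0, gestation_effects=(-10.0,) * 5)
    coeffs = draw_cow_coefficients(config, rng)
    assert daily_yield(coeffs, "control", "multiparous", 100, 5) == 0.0


def test_default_mean_yield_nonnegative_over_milking_range(milk_config, rng):
    coeffs = draw_cow_coefficients(deterministic_milk_config(), rng)
    dims = np.arange(1, 501)
    for cls in ("primiparous", "multiparous"):
        for cat in range(6):
            y = daily_yield(coeffs, "control", cls, dims, np.full(dims.shape, cat))
            assert np.all(y >= 0)


def test_vectorized_matches_scalar(milk_config, rng):
    coeffs = draw_cow_coefficients(milk_config, rng)
    dims = np.arange(1, 400)
    cats = np.minimum(dims // 60, 5)
    vector = daily_yield(coeffs, "high", "multiparous", dims, cats)
    scalars = [daily_yield(coeffs, "high", "multiparous", int(d), int(c)) for d, c in zip(dims, cats)]
    np.testing.assert_allclose(vector, scalars, rtol=1e-9)


def test_lactation_milk_single_day_equals_daily_yield(milk_config, rng):
    coeffs = draw_cow_coefficients(milk_config, rng)
    assert lactation_milk(coeffs, "control", "primiparous", Span(1)) == pytest.approx(
        daily_yield(coeffs, "control", "primiparous", 1, 0)
    )


def test_constant_curve_sums_exactly(rng):
    coeffs = draw_cow_coefficients(flat_config(24.0), rng)
    assert lactation_milk(coeffs, "control", "multiparous", Span(100)) == pytest.approx(2400.0)


def test_lactation_milk_matches_day_loop_oracle(rng):
    # independent day-by-day evaluation with manual gestation binning
    config = deterministic_milk_config(
        curves={
            "primiparous": WilminkCurve(27.0, -9.0, 0.06, -0.02),
            "multiparous": WilminkCurve(33.0, -12.0, 0.05, -0.04),
        },
        scenario_effect=1.5,
        gestation_effects=(-0.5, -1.0, -2.0, -3.0, -4.5),
    )
    coeffs = draw_cow_coefficients(config, rng)
    conception, end = 100, 305
    expected = 0.0
    for t in range(1, end + 1):
        y = 33.0 - 12.0 * math.exp(-0.05 * t) - 0.04 * t + 1.5
        dp = t - conception
        if dp > 0:
            for upper, effect in zip((56, 112, 168, 224, float("inf")), config.gestation_effects):
                if dp <= upper:
                    y += effect
                    break
        expected += max(y, 0.0)
    result = lactation_milk(coeffs, "high", "multiparous", Span(end, conception))
    assert result == pytest.approx(expected, rel=1e-12)


def test_lactation_milk_monotone_in_span_length(milk_config, rng):
    coeffs = draw_cow_coefficients(milk_config, rng)
    totals = [lactation_milk(coeffs, "high", "multiparous", Span(end, 90)) for end in (50, 150, 250, 350)]
    assert all(b >= a for a, b in zip(totals, totals[1:]))


def test_invalid_span_raises(milk_config, rng):
    coeffs = draw_cow_coefficients(milk_config, rng)
    with pytest.raises(InvalidSpanError):
        lactation_milk(coeffs, "control", "primiparous", Span(0))


@pytest.mark.parametrize(
    "overrides",
    [
        dict(scenario_effect_sd=-0.1),
        dict(gestation_effects=(-1.0, -2.0)),
        dict(gestation_bin_edges=(56.0, 40.0, 168.0, 224.0)),
        dict(curve_sds={"primiparous": WilminkCurve(-1.0, 0, 0, 0), "multiparous": ZERO_SDS["multiparous"]}),
    ],
)
def test_invalid_configuration_rejected(overrides):
    with pytest.raises(ConfigError):
        MilkModelConfig(**overrides)
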