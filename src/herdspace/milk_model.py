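"""Daily milk-yield model for the two living-space scenarios.

The yield surface is a Wilmink lactation curve per parity class,

    y(t) = a + b * exp(-k * t) + c * t,

where ``t`` is days in milk (t >= 1), ``a`` the curve scale (liters),
``b`` the (negative) early-lactation ramp (liters), ``k`` the ramp rate
(per day) and ``c`` the persistency slope (liters/day, negative for a
declining tail).  On top of the curve sit two additive terms: a
living-space effect applied only to the high-space scenario, and a
gestation-stage effect for pregnant cows (five categories of days
pregnant; category 0 is the non-pregnant state, category effects are
typically negative and grow with stage).  Negative predicted yields are
floored at zero.

Per-cow heterogeneity enters as independent normal perturbations of each
curve coefficient and of the living-space effect; the root-mean-square of
the standardized perturbations is recorded per cow as a single
coefficient-deviation covariate for the downstream regression.

The coefficients of the mixed-effects model that motivated this structure
are not public; the shipped defaults are illustrative of a UK-average
housed Holstein herd (roughly 7,700 L per 305-day primiparous lactation
and 8,000 L multiparous, with a flat persistent heifer curve and a
steeply declining multiparous tail) and are configuration, not ground
truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Tuple

import numpy as np

from .errors import ConfigError, InvalidSpanError

PARITY_CLASSES = ("primiparous", "multiparous")
SCENARIOS = ("control", "high")
CURVE_FIELDS = ("scale", "ramp", "ramp_rate", "persistency")

#: Number of gestation-stage categories (excluding the non-pregnant state 0).
N_GESTATION_CATEGORIES = 5


@dataclass(frozen=True)
class WilminkCurve:
    """Coefficients of one Wilmink lactation curve."""

    scale: float
    ramp: float
    ramp_rate: float
    persistency: float

    def __call__(self, dim):
        t = np.asarray(dim, dtype=float)
        return self.scale + self.ramp * np.exp(-self.ramp_rate * t) + self.persistency * t

    def as_tuple(self) -> Tuple[float, float, float, float]:
        return (self.scale, self.ramp, self.ramp_rate, self.persistency)


def _default_curves() -> Mapping[str, WilminkCurve]:
    return {
        "primiparous": WilminkCurve(29.0, -8.0, 0.050, -0.022),
        "multiparous": WilminkCurve(44.0, -16.0, 0.060, -0.110),
    }


def _default_curve_sds() -> Mapping[str, WilminkCurve]:
    sds = WilminkCurve(2.0, 1.5, 0.004, 0.006)
    return {"primiparous": sds, "multiparous": sds}


@dataclass(frozen=True)
class MilkModelConfig:
    """Configuration of the milk-yield model (see module docstring).

    ``gestation_bin_edges`` are the upper bounds (days pregnant, inclusive)
    of the first four gestation categories; category 5 is open above the
    last edge.  ``scenario_effect`` is the additive liters/day advantage of
    the high-space scenario, perturbed per cow with sd
    ``scenario_effect_sd``.
    """

    curves: Mapping[str, WilminkCurve] = field(default_factory=_default_curves)
    curve_sds: Mapping[str, WilminkCurve] = field(default_factory=_default_curve_sds)
    scenario_effect: float = 1.8
    scenario_effect_sd: float = 0.35
    gestation_effects: Tuple[float, ...] = (-1.5, -1.5, -2.0, -2.0, -2.5)
    gestation_bin_edges: Tuple[float, ...] = (56.0, 112.0, 168.0, 224.0)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self, path: str = "milk_model") -> None:
        for cls in PARITY_CLASSES:
            if cls not in self.curves:
                raise ConfigError(f"{path}.curves: missing parity class '{cls}'")
            if cls not in self.curve_sds:
                raise ConfigError(f"{path}.curve_sds: missing parity class '{cls}'")
            for name in CURVE_FIELDS:
                if getattr(self.curve_sds[cls], name) < 0:
                    raise ConfigError(f"{path}.curve_sds.{cls}.{name}: standard deviation must be >= 0")
        if self.scenario_effect_sd < 0:
            raise ConfigError(f"{path}.scenario_effect_sd: standard deviation must be >= 0")
        if len(self.gestation_effects) != N_GESTATION_CATEGORIES:
            raise ConfigError(f"{path}.gestation_effects: exactly {N_GESTATION_CATEGORIES} values required")
        edges = self.gestation_bin_edges
        if len(edges) != N_GESTATION_CATEGORIES - 1:
            raise ConfigError(f"{path}.gestation_bin_edges: exactly {N_GESTATION_CATEGORIES - 1} edges required")
        if any(b <= a for a, b in zip(edges, edges[1:])) or edges[0] < 1:
            raise ConfigError(f"{path}.gestation_bin_edges: edges must be >= 1 and strictly increasing")


@dataclass(frozen=True)
class MilkCoefficients:
    """One cow's realized yield model.

    ``deviation`` is the root-mean-square of the standardized coefficient
    perturbations (0 when every configured sd is 0); it is carried through
    the simulation as a regression covariate.
    """

    curves: Mapping[str, WilminkCurve]
    scenario_effect: float
    gestation_effects: Tuple[float, ...]
    gestation_bin_edges: Tuple[float, ...]
    deviation: float

    def __post_init__(self) -> None:
        if self.deviation < 0:
            raise ConfigError("MilkCoefficients.deviation must be >= 0")


def draw_cow_coefficients(config: MilkModelConfig, rng: np.random.Generator) -> MilkCoefficients:
    """Draw one cow's coefficient set from the configured normals.

    Each curve coefficient (per parity class) and the living-space effect
    is drawn independently as Normal(mean, sd).  The same generator state
    always yields the same coefficients.
    """
    config.validate()
    zs_used = []
    curves = {}
    for cls in PARITY_CLASSES:
        means = config.curves[cls]
        sds = config.curve_sds[cls]
        realized = {}
        for name in CURVE_FIELDS:
            z = rng.standard_normal()
            s = getattr(sds, name)
            realized[name] = getattr(means, name) + s * z
            if s > 0:
                zs_used.append(z)
        curves[cls] = WilminkCurve(**realized)
    z = rng.standard_normal()
    scenario_effect = config.scenario_effect + config.scenario_effect_sd * z
    if config.scenario_effect_sd > 0:
        zs_used.append(z)
    deviation = float(np.sqrt(np.mean(np.square(zs_used)))) if zs_used else 0.0
    return MilkCoefficients(
        curves=curves,
        scenario_effect=scenario_effect,
        gestation_effects=tuple(config.gestation_effects),
        gestation_bin_edges=tuple(config.gestation_bin_edges),
        deviation=deviation,
    )


def gestation_category(days_pregnant: float, config) -> int:
    """Map days pregnant to a reproductive-status category.

    0 means non-pregnant; 1-5 index the gestation stage.  Days beyond the
    last bin edge clamp to category 5.  ``config`` may be a
    :class:`MilkModelConfig` or :class:`MilkCoefficients` (anything with
    ``gestation_bin_edges``).
    """
    if days_pregnant < 0:
        raise ConfigError("days_pregnant must be >= 0")
    if days_pregnant == 0:
        return 0
    edges = np.asarray(config.gestation_bin_edges, dtype=float)
    return int(min(np.searchsorted(edges, days_pregnant, side="left"), len(edges))) + 1


def _gestation_categories(days_pregnant: np.ndarray, edges: Tuple[float, ...]) -> np.ndarray:
    """Vectorized :func:`gestation_category` (0 stays 0, values clamp to 5)."""
    dp = np.asarray(days_pregnant, dtype=float)
    cats = np.searchsorted(np.asarray(edges, dtype=float), dp, side="left")
    cats = np.minimum(cats, len(edges)) + 1
    return np.where(dp > 0, cats, 0)


def daily_yield(coeffs: MilkCoefficients, scenario: str, parity_class: str, dim, gest_cat) -> float | np.ndarray:
    """Predicted daily yield (liters) at days-in-milk ``dim``.

    Curve value plus scenario effect (high-space scenario only) plus the
    gestation-category effect, floored at 0.  ``dim`` and ``gest_cat``
    may be scalars or matching arrays.
    """
    if scenario not in SCENARIOS:
        raise ConfigError(f"unknown scenario '{scenario}'")
    if parity_class not in PARITY_CLASSES:
        raise ConfigError(f"unknown parity class '{parity_class}'")
    t = np.asarray(dim, dtype=float)
    if np.any(t < 1):
        raise ConfigError("days in milk must be >= 1")
    y = coeffs.curves[parity_class](t)
    if scenario == "high":
        y = y + coeffs.scenario_effect
    effects = np.concatenate(([0.0], np.asarray(coeffs.gestation_effects, dtype=float)))
    y = y + effects[np.asarray(gest_cat, dtype=int)]
    y = np.maximum(y, 0.0)
    return float(y) if np.isscalar(dim) else y


def lactation_milk(coeffs: MilkCoefficients, scenario: str, parity_class: str, span) -> float:
    """Total milk (liters) over one lactation span.

    Sums :func:`daily_yield` over whole days in milk 1..span.end, deriving
    the gestation category each day from days since the span's conception
    (if any).  ``span`` needs only ``end`` and ``conception`` attributes.
    """
    end = int(span.end)
    if end < 1:
        raise InvalidSpanError("lactation span must cover at least one day")
    t = np.arange(1, end + 1)
    conception = getattr(span, "conception", None)
    if conception is None:
        cats = np.zeros(end, dtype=int)
    else:
        dp = np.maximum(t - int(conception), 0)
        cats = _gestation_categories(dp, coeffs.gestation_bin_edges)
    return float(np.sum(daily_yield(coeffs, scenario, parity_class, t, cats)))
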