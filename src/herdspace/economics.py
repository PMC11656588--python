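"""Partial budget for one paired comparison.

Only items that differ between the two living-space scenarios enter the
budget: milk income over purchased feed (lifetime milk x margin per
liter) and the disease-risk cost attached to each dry/transition period
(one cost per calving event, by parity class).  The financial-return
difference is

    (HS milk x margin - HS transition costs) - (CS milk x margin - CS transition costs),

expressed both as a lifetime total and per cow per year over the shared
(post-replacement) horizon.  The margin and the two transition costs are
drawn once per paired comparison and shared by both scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np

from .errors import ConfigError, SimulationError
from .lifetime import ScenarioTimeline

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class EconomicConfig:
    """Uniform bounds for the per-simulation economic draws (GBP)."""

    margin_bounds: tuple[float, float] = (0.17, 0.23)
    primiparous_cost_bounds: tuple[float, float] = (32.43, 129.72)
    multiparous_cost_bounds: tuple[float, float] = (49.54, 198.16)
    days_per_year: float = DAYS_PER_YEAR

    def __post_init__(self) -> None:
        self.validate()

    def validate(self, path: str = "economics") -> None:
        for name in ("margin_bounds", "primiparous_cost_bounds", "multiparous_cost_bounds"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigError(f"{path}.{name}: bounds must satisfy low <= high")
            if lo < 0:
                raise ConfigError(f"{path}.{name}: monetary values must be >= 0")
        if self.days_per_year <= 0:
            raise ConfigError(f"{path}.days_per_year: must be > 0")


@dataclass(frozen=True)
class EconomicDraws:
    margin: float            # GBP per liter
    primiparous_cost: float  # GBP per first-calving transition
    multiparous_cost: float  # GBP per later-calving transition


def draw_economics(config: EconomicConfig, rng: np.random.Generator) -> EconomicDraws:
    """One margin and one transition cost per parity class, uniform within bounds."""
    config.validate()
    return EconomicDraws(
        margin=float(rng.uniform(*config.margin_bounds)),
        primiparous_cost=float(rng.uniform(*config.primiparous_cost_bounds)),
        multiparous_cost=float(rng.uniform(*config.multiparous_cost_bounds)),
    )


def transition_total(timeline: ScenarioTimeline, draws: EconomicDraws) -> float:
    """Total transition cost (GBP): one cost per calving, including replacements."""
    return (
        draws.primiparous_cost * timeline.primiparous_calvings
        + draws.multiparous_cost * timeline.multiparous_calvings
    )


def financial_return_difference(
    hs_milk: float,
    cs_milk: float,
    hs_transition_cost: float,
    cs_transition_cost: float,
    margin: float,
    span_days: float,
    days_per_year: float = DAYS_PER_YEAR,
) -> tuple[float, float]:
    """Partial-budget difference, total GBP and GBP per cow per year.

    ``span_days`` is the shared horizon of the equalized pair.
    """
    if span_days <= 0:
        raise SimulationError("paired span must be positive")
    total = (hs_milk * margin - hs_transition_cost) - (cs_milk * margin - cs_transition_cost)
    per_year = total / (span_days / days_per_year)
    return total, per_year


@dataclass(frozen=True)
class SimulationRecord:
    """One paired comparison's outputs and regression covariates."""

    cow: int
    exit_parity: int
    exit_dim: int
    span_days: int
    hs_milk: float
    cs_milk: float
    hs_transition_cost: float
    cs_transition_cost: float
    margin: float
    cost_primiparous: float
    cost_multiparous: float
    ttc_primiparous_high: float
    ttc_primiparous_control: float
    ttc_multiparous_high: float
    ttc_multiparous_control: float
    gestation: float
    dry_period: float
    milk_deviation: float
    return_total: float
    return_per_year: float


RECORD_COLUMNS = tuple(f.name for f in fields(SimulationRecord))

#: Human-readable dictionary for the flat records CSV.
RECORD_DICTIONARY = {
    "cow": "cow index within the run",
    "exit_parity": "number of calvings before herd exit (1-10)",
    "exit_dim": "days in milk at exit in the final lactation",
    "span_days": "shared horizon of the equalized pair, days",
    "hs_milk": "high-space lifetime milk incl. replacements, liters",
    "cs_milk": "control-space lifetime milk incl. replacements, liters",
    "hs_transition_cost": "high-space transition costs, GBP",
    "cs_transition_cost": "control-space transition costs, GBP",
    "margin": "margin over purchased feed, GBP/liter",
    "cost_primiparous": "transition cost per first calving, GBP",
    "cost_multiparous": "transition cost per later calving, GBP",
    "ttc_primiparous_high": "time to conception, high space parity 1, days",
    "ttc_primiparous_control": "time to conception, control space parity 1, days",
    "ttc_multiparous_high": "time to conception, high space parity >= 2, days",
    "ttc_multiparous_control": "time to conception, control space parity >= 2, days",
    "gestation": "gestation length, days",
    "dry_period": "dry-period length, days",
    "milk_deviation": "RMS standardized milk-coefficient perturbation",
    "return_total": "financial-return difference, GBP over the lifetime",
    "return_per_year": "financial-return difference, GBP per cow per year",
}
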