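"""Reproductive and timing draws for one simulated cow.

Time to conception (days from calving) is normal per living-space
scenario x parity class; gestation length, dry-period length and the
final-lactation exit time are uniform.  One gestation and one dry-period
value is drawn per cow and reused for every lactation in both scenarios,
and the multiparous conception value is reused for every parity >= 2.

The two scenarios share the underlying standard-normal deviate within a
parity class (common random numbers): marginally each cell is exactly its
configured Normal(mean, sd), while scenarios with identical configurations
receive identical draws, which keeps the paired comparison free of
spurious between-scenario sampling noise.

Normal draws are truncated below at a configurable floor (default 21
days, the earliest plausible post-calving conception) by moving to the
next deviate in the shared stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Tuple

import numpy as np

from .errors import ConfigError
from .milk_model import PARITY_CLASSES, SCENARIOS

_MAX_REDRAWS = 10_000


def _default_conception() -> Mapping[Tuple[str, str], Tuple[float, float]]:
    return {
        ("control", "primiparous"): (82.0, 10.0),
        ("high", "primiparous"): (155.0, 25.0),
        ("control", "multiparous"): (108.0, 15.0),
        ("high", "multiparous"): (133.0, 25.0),
    }


@dataclass(frozen=True)
class ReproductionConfig:
    """(mean, sd) per scenario x parity class plus uniform timing bounds (days)."""

    conception: Mapping[Tuple[str, str], Tuple[float, float]] = field(default_factory=_default_conception)
    gestation_bounds: Tuple[float, float] = (275.0, 285.0)
    dry_period_bounds: Tuple[float, float] = (42.0, 60.0)
    exit_dim_bounds: Tuple[float, float] = (1.0, 305.0)
    conception_floor: float = 21.0
    n_exit_draws: int = 5

    def __post_init__(self) -> None:
        self.validate()

    def cell(self, scenario: str, parity_class: str) -> Tuple[float, float]:
        return self.conception[(scenario, parity_class)]

    def validate(self, path: str = "reproduction") -> None:
        for scenario in SCENARIOS:
            for cls in PARITY_CLASSES:
                if (scenario, cls) not in self.conception:
                    raise ConfigError(f"{path}.conception: missing cell ({scenario}, {cls})")
                mean, sd = self.conception[(scenario, cls)]
                if sd < 0:
                    raise ConfigError(f"{path}.conception.{scenario}_{cls}: sd must be >= 0")
        for name in ("gestation_bounds", "dry_period_bounds", "exit_dim_bounds"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigError(f"{path}.{name}: bounds must satisfy low <= high")
        if self.conception_floor < 1:
            raise ConfigError(f"{path}.conception_floor: must be >= 1 day")
        if self.n_exit_draws < 1:
            raise ConfigError(f"{path}.n_exit_draws: must be >= 1")


@dataclass(frozen=True)
class ReproductiveDraws:
    """One cow's realized timings, rounded to whole days."""

    conception: Mapping[Tuple[str, str], int]
    gestation: int
    dry_period: int
    exit_dims: Tuple[int, ...]


def truncate_positive(value: float, floor: float, redraw) -> float:
    """First value >= ``floor`` from ``value`` followed by the ``redraw`` stream.

    Raises :class:`ConfigError` after 10,000 consecutive rejections (the
    configured distribution puts too much mass below the floor).
    """
    if floor < 1:
        raise ConfigError("truncation floor must be >= 1")
    stream = iter(redraw)
    rejections = 0
    while value < floor:
        rejections += 1
        if rejections > _MAX_REDRAWS:
            raise ConfigError(
                f"more than {_MAX_REDRAWS} draws below the truncation floor {floor}"
            )
        value = next(stream)
    return value


def _conception_draws(config: ReproductionConfig, rng: np.random.Generator) -> dict:
    """Truncated conception draws sharing one z stream per parity class."""
    values = {}
    for cls in PARITY_CLASSES:
        zs: list[float] = []
        for scenario in SCENARIOS:
            mean, sd = config.cell(scenario, cls)
            i = 0
            while True:
                if i >= len(zs):
                    zs.append(rng.standard_normal())
                v = mean + sd * zs[i]
                if v >= config.conception_floor:
                    break
                i += 1
                if i > _MAX_REDRAWS:
                    raise ConfigError(
                        f"conception cell ({scenario}, {cls}) rarely exceeds the floor "
                        f"{config.conception_floor}"
                    )
            values[(scenario, cls)] = int(np.rint(v))
    return values


def draw_reproduction(config: ReproductionConfig, rng: np.random.Generator) -> ReproductiveDraws:
    """Draw all reproductive timings for one cow (whole days).

    One conception value per scenario x parity class, one gestation and
    one dry-period length shared by the whole lifetime, and
    ``n_exit_draws`` final-lactation exit times.
    """
    config.validate()
    conception = _conception_draws(config, rng)
    gestation = int(np.rint(rng.uniform(*config.gestation_bounds)))
    dry_period = int(np.rint(rng.uniform(*config.dry_period_bounds)))
    lo, hi = config.exit_dim_bounds
    exit_dims = tuple(int(np.rint(x)) for x in rng.uniform(lo, hi, size=config.n_exit_draws))
    return ReproductiveDraws(
        conception=conception,
        gestation=gestation,
        dry_period=dry_period,
        exit_dims=exit_dims,
    )
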