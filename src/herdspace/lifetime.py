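"""Paired cow-lifetime timelines and lifetime milk totals.

A cow enters at first calving and is simulated simultaneously through the
control-space and high-space scenarios from the same set of stochastic
draws.  Each lifetime is defined up front by its exit parity (1-10) and
the days in milk at exit in the final lactation; for every earlier parity
the next calving follows conception + gestation, with dry-off at next
calving minus the dry-period length.  Calving day is day 0 of its
lactation and the first milking day is days-in-milk 1.

Because conception is slower in the high-space scenario, the two
scenarios' exits rarely coincide; the scenario that exits first is
immediately backfilled with a replacement heifer carrying the same
coefficient and draw set (parity restarting at 1) until the later exit
day, so that each paired comparison covers an equal horizon per cow place.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import InvalidSpanError, SimulationError
from .milk_model import MilkCoefficients, lactation_milk
from .repro_model import ReproductiveDraws

EXIT_PARITIES = range(1, 11)
EXIT_SLOTS = range(5)


def parity_class(parity: int) -> str:
    return "primiparous" if parity == 1 else "multiparous"


@dataclass(frozen=True)
class LactationSpan:
    """One lactation: parity, calendar calving day, and key days in milk.

    ``conception`` and ``dry_off`` are days in milk (None if absent);
    ``end`` is the last milking day (dry-off for completed lactations,
    exit day for final ones).
    """

    parity: int
    calving_day: int
    conception: int | None
    dry_off: int | None
    end: int

    def __post_init__(self) -> None:
        if self.end < 1:
            raise InvalidSpanError("span ends before its first milking day")
        if self.conception is not None and self.dry_off is not None and self.conception >= self.dry_off:
            raise InvalidSpanError("conception at or after dry-off")


@dataclass(frozen=True)
class ScenarioTimeline:
    """One cow's dated lifetime under one scenario, plus any replacement tail."""

    scenario: str
    spans: tuple[LactationSpan, ...]
    total_span: int
    replacement_spans: tuple[LactationSpan, ...] = ()

    @property
    def all_spans(self) -> tuple[LactationSpan, ...]:
        return self.spans + self.replacement_spans

    @property
    def primiparous_calvings(self) -> int:
        return sum(1 for s in self.all_spans if s.parity == 1)

    @property
    def multiparous_calvings(self) -> int:
        return sum(1 for s in self.all_spans if s.parity > 1)


def build_timeline(
    draws: ReproductiveDraws, scenario: str, exit_parity: int, exit_dim: int
) -> ScenarioTimeline:
    """Focal-cow timeline for one scenario, exit parity, and exit day.

    The final lactation ends at ``exit_dim`` with no dry-off; its
    conception is recorded only when the conception draw falls before the
    exit day (it then affects yield through the gestation category).
    """
    if exit_parity not in EXIT_PARITIES:
        raise SimulationError(f"exit parity must be in 1-10, got {exit_parity}")
    if exit_dim < 1:
        raise SimulationError("exit day in milk must be >= 1")
    spans = []
    calving_day = 0
    for parity in range(1, exit_parity + 1):
        conception = draws.conception[(scenario, parity_class(parity))]
        if parity < exit_parity:
            interval = conception + draws.gestation
            dry_off = interval - draws.dry_period
            if dry_off <= conception:
                raise SimulationError(
                    "calving interval shorter than conception + dry period"
                )
            spans.append(LactationSpan(parity, calving_day, conception, dry_off, dry_off))
            calving_day += interval
        else:
            marked = conception if conception < exit_dim else None
            spans.append(LactationSpan(parity, calving_day, marked, None, exit_dim))
    return ScenarioTimeline(scenario=scenario, spans=tuple(spans), total_span=calving_day + exit_dim)


def _replacement_tail(
    timeline: ScenarioTimeline, draws: ReproductiveDraws, horizon: int
) -> ScenarioTimeline:
    """Extend a timeline with replacement-heifer lactations up to ``horizon``."""
    day = timeline.total_span
    spans = []
    parity = 0
    while day < horizon:
        parity += 1
        conception = draws.conception[(timeline.scenario, parity_class(parity))]
        interval = conception + draws.gestation
        dry_off = interval - draws.dry_period
        if day + interval <= horizon:
            spans.append(LactationSpan(parity, day, conception, dry_off, dry_off))
            day += interval
        else:
            remaining = horizon - day
            end = min(remaining, dry_off)
            marked = conception if conception < end else None
            reached_dry = dry_off if remaining > dry_off else None
            spans.append(LactationSpan(parity, day, marked, reached_dry, end))
            day = horizon
    return replace(
        timeline,
        replacement_spans=timeline.replacement_spans + tuple(spans),
        total_span=horizon,
    )


def pair_and_replace(
    timeline_hs: ScenarioTimeline,
    timeline_cs: ScenarioTimeline,
    draws: ReproductiveDraws,
) -> tuple[ScenarioTimeline, ScenarioTimeline]:
    """Equalize the paired horizons via immediate replacement.

    The earlier-exiting scenario is extended with a replacement heifer
    (same draws, parity restarting at 1, further lactations as needed,
    final one truncated at the horizon) so both timelines span the later
    exit day.
    """
    horizon = max(timeline_hs.total_span, timeline_cs.total_span)
    if timeline_hs.total_span < horizon:
        timeline_hs = _replacement_tail(timeline_hs, draws, horizon)
    if timeline_cs.total_span < horizon:
        timeline_cs = _replacement_tail(timeline_cs, draws, horizon)
    return timeline_hs, timeline_cs


def lifetime_milk(
    timeline: ScenarioTimeline,
    coeffs: MilkCoefficients,
    scenario: str | None = None,
    cache: dict | None = None,
) -> float:
    """Lifetime milk (liters): sum of lactation milk over all spans.

    ``cache`` (optional, per cow) memoizes span totals keyed by the span
    features that determine yield; it must not be shared across cows.
    """
    scenario = timeline.scenario if scenario is None else scenario
    total = 0.0
    for span in timeline.all_spans:
        cls = parity_class(span.parity)
        if cache is None:
            total += lactation_milk(coeffs, scenario, cls, span)
        else:
            key = (scenario, cls, span.conception, span.end)
            if key not in cache:
                cache[key] = lactation_milk(coeffs, scenario, cls, span)
            total += cache[key]
    return total


def milking_days(timeline: ScenarioTimeline) -> int:
    """Total days with milk recorded (used in conservation checks)."""
    return sum(span.end for span in timeline.all_spans)


def enumerate_design(n_cows: int):
    """Yield the (cow, exit parity, exit slot) grid: 50 comparisons per cow."""
    if n_cows < 1:
        raise SimulationError("n_cows must be >= 1")
    for cow in range(n_cows):
        for exit_parity in EXIT_PARITIES:
            for slot in EXIT_SLOTS:
                yield cow, exit_parity, slot
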