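"""Capital costing, loan amortization, and net return on investment.

Three ways of providing the extra 3.5 m² of living space per cow are
costed for a 100-cow herd: a new build (total space 14 vs 9 m² per cow at
£182/m², the option cost being the difference), an indoor loafing-area
extension (£248/m² x 3.5 m²) and an outdoor loafing-area extension
(£100.75/m² x 3.5 m²).

The default repayment model is equal annual principal installments with
interest charged on the outstanding balance, whose total repayment has
the closed form

    total = P * (1 + r * (n + 1) / 2)

for principal P, annual rate r and term n years.  An annuity
(equal-payment) schedule is available as an alternative; it produces
higher totals at the same rate and does not match the equal-principal
figures.  All arithmetic is carried at full precision; currency is
rounded half-up to pennies for display only.

Net return on infrastructure investment subtracts the annualized
per-cow-per-year cost from a sample of simulated financial-return
differences and summarizes the result (10th/50th/90th percentiles by
linear interpolation, plus the share of strictly positive net returns).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .errors import ConfigError

#: Sensitivity grid defaults: percent APR and loan terms in years.
SENSITIVITY_RATES = (0.0, 3.74, 4.00, 5.30, 8.00)
SENSITIVITY_TERMS = (12, 20)


def round_pennies(value: float) -> float:
    """Round half-up to two decimal places (display rounding for GBP)."""
    return float(Decimal(repr(float(value))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class BuildOption:
    """One way of providing the extra living space.

    ``area_high`` / ``area_control`` are the m² per cow being compared;
    extensions compare added area against nothing (``area_control`` 0).
    """

    name: str
    unit_cost: float       # GBP per m²
    area_high: float       # m² per cow
    area_control: float = 0.0
    herd_size: int = 100

    def __post_init__(self) -> None:
        if self.unit_cost <= 0:
            raise ConfigError(f"{self.name}: unit cost must be > 0")
        if self.herd_size < 0:
            raise ConfigError(f"{self.name}: herd size must be >= 0")
        if self.area_high <= self.area_control:
            raise ConfigError(f"{self.name}: compared area must exceed the baseline")

    @property
    def principal(self) -> float:
        """Herd-level capital cost difference between the compared areas (GBP)."""
        return self.unit_cost * (self.area_high - self.area_control) * self.herd_size


def default_build_options() -> tuple[BuildOption, BuildOption, BuildOption]:
    return (
        BuildOption("new-build", 182.00, 14.0, 9.0),
        BuildOption("indoor-extension", 248.00, 3.5),
        BuildOption("outdoor-extension", 100.75, 3.5),
    )


@dataclass(frozen=True)
class LoanTerms:
    """Annual interest rate (fraction), term in years, and repayment model."""

    rate: float
    years: int
    model: str = "equal_principal"

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ConfigError("interest rate must be >= 0")
        if self.years <= 0:
            raise ConfigError("loan term must be > 0 years")
        if self.model not in ("equal_principal", "annuity"):
            raise ConfigError(f"unknown repayment model '{self.model}'")


@dataclass(frozen=True)
class AmortizationResult:
    principal: float          # GBP
    total_repayment: float    # GBP
    total_per_cow: float      # GBP
    per_cow_per_year: float   # GBP/cow/year


@dataclass(frozen=True)
class NetReturnSummary:
    cost_per_cow_per_year: float
    p10: float
    median: float
    p90: float
    probability_positive: float


def capital_cost(option: BuildOption, area_per_cow: float) -> float:
    """Herd capital cost (GBP) of building ``area_per_cow`` m² per cow."""
    if area_per_cow <= 0:
        raise ConfigError("area per cow must be > 0")
    return option.unit_cost * area_per_cow * option.herd_size


def total_repayment(principal: float, terms: LoanTerms) -> float:
    """Total repaid (GBP) over the loan's life under the chosen model."""
    r, n = terms.rate, terms.years
    if terms.model == "equal_principal":
        return principal * (1.0 + r * (n + 1) / 2.0)
    # annuity: n equal payments of P r / (1 - (1+r)^-n)
    if r == 0:
        return float(principal)
    payment = principal * r / (1.0 - (1.0 + r) ** -n)
    return payment * n


def annualized_cost_per_cow(option: BuildOption, terms: LoanTerms) -> AmortizationResult:
    """Amortize the option's capital-cost difference and annualize per cow."""
    principal = option.principal
    total = total_repayment(principal, terms)
    per_cow = total / option.herd_size
    return AmortizationResult(
        principal=principal,
        total_repayment=total,
        total_per_cow=per_cow,
        per_cow_per_year=per_cow / terms.years,
    )


def net_return_summary(samples, cost_per_cow_per_year: float) -> NetReturnSummary:
    """Summarize net returns: sample minus annualized cost (GBP/cow/year)."""
    values = np.asarray(samples, dtype=float)
    if values.size == 0:
        raise ConfigError("net-return sample must be non-empty")
    net = values - cost_per_cow_per_year
    p10, median, p90 = np.percentile(net, [10.0, 50.0, 90.0])
    return NetReturnSummary(
        cost_per_cow_per_year=float(cost_per_cow_per_year),
        p10=float(p10),
        median=float(median),
        p90=float(p90),
        probability_positive=float(np.mean(net > 0)),
    )


def sensitivity_table(
    samples,
    options=None,
    rates_percent=SENSITIVITY_RATES,
    terms_years=(20,),
    model: str = "equal_principal",
) -> pd.DataFrame:
    """Interest-rate x term sensitivity grid for each build option.

    One row per option x rate x term with the per-cow cost difference
    (total and per year) and the net-return summary against ``samples``
    (financial-return differences, GBP/cow/year).  Values are unrounded;
    use :func:`format_sensitivity_table` for display.
    """
    if options is None:
        options = default_build_options()
    if not rates_percent:
        raise ConfigError("at least one interest rate is required")
    if not terms_years:
        raise ConfigError("at least one loan term is required")
    rows = []
    for option in options:
        for years in terms_years:
            for rate in rates_percent:
                terms = LoanTerms(rate / 100.0, years, model)
                amort = annualized_cost_per_cow(option, terms)
                summary = net_return_summary(samples, amort.per_cow_per_year)
                rows.append(
                    {
                        "option": option.name,
                        "rate_percent": rate,
                        "term_years": years,
                        "total_cost_per_cow": amort.total_per_cow,
                        "cost_per_cow_per_year": amort.per_cow_per_year,
                        "net_p10": summary.p10,
                        "net_median": summary.median,
                        "net_p90": summary.p90,
                        "probability_positive": summary.probability_positive,
                    }
                )
    return pd.DataFrame(rows)


def format_sensitivity_table(table: pd.DataFrame) -> str:
    """Aligned text rendering with penny rounding and percent shares."""
    shown = table.copy()
    for col in ("total_cost_per_cow", "cost_per_cow_per_year", "net_p10", "net_median", "net_p90"):
        shown[col] = shown[col].map(lambda v: f"{round_pennies(v):.2f}")
    shown["probability_positive"] = table["probability_positive"].map(lambda v: f"{100 * v:.2f}%")
    return shown.to_string(index=False)
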