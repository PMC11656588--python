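"""Standardized OLS decomposition of the simulated financial return.

The per-cow-per-year financial-return difference is regressed on the
simulation inputs: exit parity as a dummy-coded categorical with
reference level 3, and the continuous inputs centered and standardized
(z-scored with the sample standard deviation).  The response is z-scored
as well by default, so estimates read as response standard deviations per
one-standard-deviation change in a predictor; the stored scaling
constants allow conversion back to GBP/cow/year.  Lifetime days is
excluded by design (nearly collinear with exit parity).  Estimation is
ordinary least squares with classical standard-theory confidence
intervals and two-sided t-test p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ConfigError

#: Continuous predictors in presentation order.
CONTINUOUS_PREDICTORS = (
    "milk_deviation",
    "margin",
    "cost_primiparous",
    "cost_multiparous",
    "ttc_primiparous_high",
    "ttc_primiparous_control",
    "ttc_multiparous_high",
    "ttc_multiparous_control",
    "dry_period",
    "gestation",
    "exit_dim",
)


@dataclass(frozen=True)
class RegressionSpec:
    response: str = "return_per_year"
    parity: str = "exit_parity"
    reference_parity: int = 3
    continuous: tuple[str, ...] = CONTINUOUS_PREDICTORS
    excluded: tuple[str, ...] = ("span_days",)
    standardize_response: bool = True

    def __post_init__(self) -> None:
        overlap = set(self.continuous) & set(self.excluded)
        if overlap:
            raise ConfigError(f"excluded variables present in the design: {sorted(overlap)}")


@dataclass(frozen=True)
class RegressionResult:
    """Fitted coefficients with intervals, fit statistics, and scalings."""

    terms: tuple[str, ...]
    estimates: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    p_values: pd.Series
    r_squared: float
    n_obs: int
    scaling: dict[str, tuple[float, float]]
    response_scaling: tuple[float, float] | None
    parity_terms: tuple[str, ...]

    def estimate_gbp(self, term: str) -> float:
        """Estimate converted back to GBP/cow/year (per sd of the predictor)."""
        value = float(self.estimates[term])
        if self.response_scaling is not None:
            value *= self.response_scaling[1]
        return value


def standardize(values, name: str | None = None) -> tuple[np.ndarray, float, float]:
    """z-score a vector with the sample (n-1) sd; returns (z, mean, sd)."""
    x = np.asarray(values, dtype=float)
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0 or not np.isfinite(sd):
        raise ConfigError(f"predictor '{name or 'vector'}' is constant; cannot standardize")
    return (x - mean) / sd, mean, sd


def _aliased_terms(design: pd.DataFrame) -> list[str]:
    kept: list[int] = []
    aliased: list[str] = []
    matrix = design.to_numpy()
    for j, name in enumerate(design.columns):
        candidate = matrix[:, kept + [j]]
        if np.linalg.matrix_rank(candidate) > len(kept):
            kept.append(j)
        else:
            aliased.append(name)
    return aliased


def build_design(records: pd.DataFrame, spec: RegressionSpec) -> tuple[pd.DataFrame, dict, tuple[str, ...]]:
    """Dummy-coded parity + standardized continuous design matrix."""
    for name in (spec.parity, *spec.continuous, spec.response):
        if name not in records.columns:
            raise ConfigError(f"records are missing column '{name}'")
    levels = sorted(records[spec.parity].unique())
    if len(levels) < 2:
        raise ConfigError("at least two exit-parity levels are required")
    if spec.reference_parity not in levels:
        raise ConfigError(f"reference parity {spec.reference_parity} absent from the records")
    design = pd.DataFrame(index=records.index)
    design["intercept"] = 1.0
    parity_terms = []
    for level in levels:
        if level == spec.reference_parity:
            continue
        term = f"parity_{level}"
        design[term] = (records[spec.parity] == level).astype(float)
        parity_terms.append(term)
    scaling = {}
    for name in spec.continuous:
        z, mean, sd = standardize(records[name], name)
        design[name] = z
        scaling[name] = (mean, sd)
    return design, scaling, tuple(parity_terms)


def fit_return_model(records: pd.DataFrame, spec: RegressionSpec | None = None) -> RegressionResult:
    """Fit the standardized OLS model to simulation records."""
    spec = spec or RegressionSpec()
    design, scaling, parity_terms = build_design(records, spec)
    if len(records) <= design.shape[1]:
        raise ConfigError("more model terms than observations")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        raise ConfigError(f"rank-deficient design; aliased terms: {_aliased_terms(design)}")
    y = records[spec.response].to_numpy(dtype=float)
    response_scaling = None
    if spec.standardize_response:
        y, mean, sd = standardize(y, spec.response)
        response_scaling = (mean, sd)
    fit = sm.OLS(y, design).fit()
    ci = fit.conf_int(alpha=0.05)
    return RegressionResult(
        terms=tuple(design.columns),
        estimates=fit.params,
        ci_low=ci[0],
        ci_high=ci[1],
        p_values=fit.pvalues,
        r_squared=float(fit.rsquared),
        n_obs=int(fit.nobs),
        scaling=scaling,
        response_scaling=response_scaling,
        parity_terms=parity_terms,
    )


def forest_data(result: RegressionResult, spec: RegressionSpec | None = None) -> pd.DataFrame:
    """Plot-ready term list (parity contrasts first, then continuous terms).

    The reference line for a forest plot is 0; the intercept is omitted.
    """
    spec = spec or RegressionSpec()
    order = list(result.parity_terms) + [t for t in spec.continuous if t in result.terms]
    rows = [
        {
            "term": term,
            "estimate": float(result.estimates[term]),
            "ci_low": float(result.ci_low[term]),
            "ci_high": float(result.ci_high[term]),
            "p_value": float(result.p_values[term]),
        }
        for term in order
    ]
    return pd.DataFrame(rows)


def coefficient_table(result: RegressionResult) -> pd.DataFrame:
    """Full coefficient table (intercept included) for CSV export."""
    rows = [
        {
            "term": term,
            "estimate": float(result.estimates[term]),
            "ci_low": float(result.ci_low[term]),
            "ci_high": float(result.ci_high[term]),
            "p_value": float(result.p_values[term]),
        }
        for term in result.terms
    ]
    table = pd.DataFrame(rows)
    table.attrs["n_obs"] = result.n_obs
    table.attrs["r_squared"] = result.r_squared
    return table
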