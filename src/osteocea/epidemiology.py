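"""Baseline epidemiology: age interpolation, risk adjustment to the
very-high-risk cohort, and rate/probability conversions on the half-year cycle.

Conventions: fracture incidence tables hold annual event rates per person;
mortality tables hold annual death probabilities.  All per-cycle probabilities
come from the rate scale (p = 1 - exp(-rate * 0.5)), which keeps competing
risks well behaved and makes the rate -> probability -> rate round trip exact.
"""

from __future__ import annotations

import numpy as np

from .config import AgeTable, MortalityModifier, RiskAdjustment

CYCLE_YEARS = 0.5


def interpolate_age_rate(table: AgeTable, age) -> np.ndarray | float:
    """Linear interpolation between knots, linear extrapolation beyond,
    floored at 0."""
    ages, values = table.as_arrays()
    age_arr = np.atleast_1d(np.asarray(age, dtype=float))
    out = np.interp(age_arr, ages, values)
    below = age_arr < ages[0]
    above = age_arr > ages[-1]
    if below.any():
        slope = (values[1] - values[0]) / (ages[1] - ages[0])
        out[below] = values[0] + slope * (age_arr[below] - ages[0])
    if above.any():
        slope = (values[-1] - values[-2]) / (ages[-1] - ages[-2])
        out[above] = values[-1] + slope * (age_arr[above] - ages[-1])
    out = np.maximum(out, 0.0)
    return out if np.ndim(age) else float(out[0])


def adjust_baseline_risk(
    gen_rate, adj: RiskAdjustment, fracture_type: str
) -> np.ndarray | float:
    """Scale a general-population fracture rate to the modelled cohort.

    Applies the prior-fracture RR and the per-SD BMD RR raised to the T-score
    gap between the cohort and the age-matched general population.
    """
    factor = adj.rr_prior_fracture * adj.rr_per_sd_bmd[fracture_type] ** adj.t_score_gap
    return gen_rate * factor


def rate_to_cycle_prob(annual_rate) -> np.ndarray | float:
    """Annual rate -> per-cycle (6-month) probability."""
    r = np.asarray(annual_rate, dtype=float)
    if np.any(r < 0):
        raise ValueError("annual rate must be >= 0")
    out = -np.expm1(-r * CYCLE_YEARS)
    return out if np.ndim(annual_rate) else float(out)


def cycle_prob_to_rate(prob) -> np.ndarray | float:
    """Inverse of :func:`rate_to_cycle_prob`."""
    p = np.asarray(prob, dtype=float)
    if np.any((p < 0) | (p >= 1)):
        raise ValueError("per-cycle probability must lie in [0, 1)")
    out = -np.log1p(-p) / CYCLE_YEARS
    return out if np.ndim(prob) else float(out)


def annual_prob_to_rate(prob) -> np.ndarray | float:
    """Annual probability -> annual hazard rate (capped just below 1)."""
    p = np.clip(np.asarray(prob, dtype=float), 0.0, 1.0 - 1e-12)
    out = -np.log1p(-p)
    return out if np.ndim(prob) else float(out)


def attributable_rr(rr_state: float | np.ndarray, attributable_fraction: float):
    """Effective mortality RR when only a fraction of the observed excess is
    causally attributed to the fracture: 1 + f * (RR - 1)."""
    return 1.0 + attributable_fraction * (np.asarray(rr_state, float) - 1.0)


def mortality_prob(
    age: float,
    years_since_fracture: float | None,
    fracture_type: str | None,
    base_table: AgeTable,
    rr_tables,
    modifier: MortalityModifier,
) -> float:
    """Per-cycle death probability for a given health state.

    The base annual probability is converted to the rate scale, multiplied by
    the attributable excess-mortality RR while the state lies within the
    excess window of its fracture type, and converted back to a 6-month
    probability.  ``years_since_fracture`` counts from the event (0 at the
    event); the first-year RR band covers [0, 1), the subsequent-years band
    [1, excess_duration).
    """
    base_annual = float(np.clip(interpolate_age_rate(base_table, age), 0.0, 1.0))
    rate = annual_prob_to_rate(base_annual)
    if fracture_type is not None and years_since_fracture is not None:
        duration = modifier.excess_duration_years[fracture_type]
        if years_since_fracture < duration:
            tbl = rr_tables[fracture_type]
            if years_since_fracture < 1.0 or tbl.subsequent_years is None:
                rr = interpolate_age_rate(tbl.first_year, age)
            else:
                rr = interpolate_age_rate(tbl.subsequent_years, age)
            rate = rate * attributable_rr(rr, modifier.attributable_fraction)
    return float(min(rate_to_cycle_prob(rate), 1.0))
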