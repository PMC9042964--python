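"""Valuation of a cohort trace: life-years, QALYs and disaggregated costs per
regimen, discounted and undiscounted, and fully incremental cost-utility
comparison across regimens.

Accruals use start-of-cycle occupancy (no half-cycle correction in the
reference case; a config switch enables the midpoint variant).  Event-attached
quantities (first-year fracture costs, productivity losses, disutilities of
corrected lower-hierarchy events) attach at the event cycle; first-year costs
and corrected-event disutilities are spread over the two cycles of the first
post-fracture year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import FRACTURE_TYPES, CostTables, ModelConfig, RegimenSpec
from .engine import (
    ALIVE,
    HIP_ACUTE,
    HIP_POST,
    HIP_STATES,
    OTHER_STATES,
    VERT_ACUTE,
    VERT_POST,
    CohortTrace,
    FractureLedger,
)

CYCLE_YEARS = 0.5
DAYS_PER_CYCLE = 365.25 / 2.0

COST_COMPONENTS = (
    "drug",
    "monitoring",
    "fracture_first_year_hip",
    "fracture_first_year_vertebral",
    "fracture_first_year_other",
    "fracture_subsequent_hip",
    "fracture_subsequent_vertebral",
    "ltc",
    "societal",
)


def discount_factor(rate: float, t) -> np.ndarray | float:
    """Present-value factor (1 + rate)^(-t) for time t in years."""
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    t_arr = np.asarray(t, float)
    if np.any(t_arr < 0):
        raise ValueError("time must be >= 0")
    out = (1.0 + rate) ** (-t_arr)
    return out if np.ndim(t) else float(out)


@dataclass
class AccrualResult:
    """Per-cycle streams (per 1000) and per-person totals for one regimen."""

    regimen: str
    streams: dict[str, np.ndarray]  # undiscounted, per 1000 per cycle
    totals: dict[str, float]  # per person, undiscounted
    totals_discounted: dict[str, float]  # per person, discounted
    fracture_totals: dict[str, float]  # events per 1000 over lifetime

    def total(self, name: str, discounted: bool = True) -> float:
        return (self.totals_discounted if discounted else self.totals)[name]

    @property
    def cost(self) -> float:
        return self.totals_discounted["total_cost"]

    @property
    def qalys(self) -> float:
        return self.totals_discounted["qalys"]


def _occupancy_for_accrual(trace: CohortTrace, half_cycle: bool) -> np.ndarray:
    occ = trace.occupancy
    if half_cycle:
        return 0.5 * (occ[:-1] + occ[1:])
    return occ[:-1]


def accrue_qalys(
    trace: CohortTrace,
    ledger: FractureLedger,
    config: ModelConfig,
) -> dict[str, np.ndarray]:
    """Per-cycle life-year and QALY streams (per 1000).

    QALYs are occupancy x age-band utility x state multiplier x 0.5 per
    cycle; first-year multipliers in acute states, subsequent-year
    multipliers in post states, the other-fracture multiplier during its
    1-year state.  Corrected lower-hierarchy events subtract a pro-rata
    one-year disutility stream without touching occupancy.
    """
    occ = _occupancy_for_accrual(trace, config.econ.half_cycle_correction)
    n = trace.n_cycles
    u_age = config.epi.utilities.lookup_many(trace.ages)
    m = config.utility_multipliers
    weights = np.ones(len(ALIVE) + 1)
    weights[HIP_ACUTE] = m.first_year["hip"]
    weights[HIP_POST] = m.subsequent_years["hip"]
    weights[VERT_ACUTE] = m.first_year["vertebral"]
    weights[VERT_POST] = m.subsequent_years["vertebral"]
    weights[OTHER_STATES] = m.first_year["other"]
    weights = weights[: occ.shape[1]]
    weights[-1] = 0.0  # dead

    life_years = occ[:, ALIVE].sum(axis=1) * CYCLE_YEARS
    qalys = (occ * weights[None, :]).sum(axis=1) * u_age * CYCLE_YEARS

    # corrected events: one-year disutility, half-year per cycle, pro-rata
    for i, ft in enumerate(FRACTURE_TYPES):
        loss = 1.0 - m.first_year[ft]
        dec = ledger.corrected[:, i] * u_age * loss * CYCLE_YEARS
        qalys -= dec
        qalys[1:] -= dec[:-1]  # second half of the first post-event year

    return {"life_years": life_years, "qalys": qalys}


def accrue_costs(
    trace: CohortTrace,
    ledger: FractureLedger,
    config: ModelConfig,
    regimen: RegimenSpec,
) -> dict[str, np.ndarray]:
    """Per-cycle cost streams (per 1000, undiscounted CAD)."""
    costs: CostTables = config.costs
    occ = _occupancy_for_accrual(trace, config.econ.half_cycle_correction)
    n = trace.n_cycles
    alive = occ[:, ALIVE].sum(axis=1)
    streams = {k: np.zeros(n) for k in COST_COMPONENTS}

    societal = config.econ.perspective == "societal"
    for j in range(min(regimen.treatment_duration_cycles, n)):
        comp = regimen.component_at_cycle(j + 1)
        if comp is None:
            continue
        streams["drug"][j] = alive[j] * comp.annual_drug_cost * CYCLE_YEARS
        streams["monitoring"][j] = alive[j] * comp.annual_monitoring_cost * CYCLE_YEARS
        if societal:
            streams["societal"][j] += (
                alive[j]
                * comp.visits_per_year
                * CYCLE_YEARS
                * costs.societal.visit_out_of_pocket
            )

    events = ledger.per_cycle  # direct + corrected, per 1000
    for i, ft in enumerate(FRACTURE_TYPES):
        unit = costs.first_year_fracture_cost[ft].lookup_many(trace.ages)
        spend = events[:, i] * unit
        half = 0.5 * spend
        streams[f"fracture_first_year_{ft}"] += half
        streams[f"fracture_first_year_{ft}"][1:] += half[:-1]
        if societal:
            prod = (
                events[:, i]
                * costs.societal.hourly_wage
                * costs.societal.time_off_hours[ft]
            )
            streams["societal"] += prod

    streams["fracture_subsequent_hip"] = (
        occ[:, HIP_POST].sum(axis=1) * costs.subsequent_year_cost["hip"] * CYCLE_YEARS
    )
    streams["fracture_subsequent_vertebral"] = (
        occ[:, VERT_POST].sum(axis=1)
        * costs.subsequent_year_cost["vertebral"]
        * CYCLE_YEARS
    )
    if not config.ltc_additive:
        # LTC replaces the post-hip medical cost for the LTC fraction
        streams["fracture_subsequent_hip"] *= 1.0 - costs.ltc_entry_prob_after_hip

    # LTC: a fixed fraction of hip-fracture survivors, for remaining lifetime.
    # Every hip-family occupant has had >= 1 hip fracture and shares the same
    # mortality, so LTC occupancy = entry fraction x hip-family occupancy.
    streams["ltc"] = (
        occ[:, HIP_STATES].sum(axis=1)
        * costs.ltc_entry_prob_after_hip
        * costs.ltc_daily_cost
        * DAYS_PER_CYCLE
    )
    return streams


def valuate(
    trace: CohortTrace,
    ledger: FractureLedger,
    config: ModelConfig,
    regimen: RegimenSpec,
    cohort_size: float = 1000.0,
) -> AccrualResult:
    """Combine QALY and cost streams into per-person totals."""
    streams = accrue_qalys(trace, ledger, config)
    streams.update(accrue_costs(trace, ledger, config, regimen))
    t = CYCLE_YEARS * np.arange(trace.n_cycles)
    df_c = discount_factor(config.econ.discount_rate_costs, t)
    df_q = discount_factor(config.econ.discount_rate_qalys, t)

    totals: dict[str, float] = {}
    totals_d: dict[str, float] = {}
    for name, s in streams.items():
        df = df_q if name in ("life_years", "qalys") else df_c
        totals[name] = float(s.sum() / cohort_size)
        totals_d[name] = float((s * df).sum() / cohort_size)
    for tot in (totals, totals_d):
        tot["fracture_cost"] = sum(
            tot[k] for k in tot if k.startswith("fracture_")
        )
        tot["total_cost"] = (
            tot["drug"] + tot["monitoring"] + tot["fracture_cost"] + tot["ltc"]
            + tot["societal"]
        )
    return AccrualResult(
        regimen=regimen.name,
        streams=streams,
        totals=totals,
        totals_discounted=totals_d,
        fracture_totals=ledger.totals(),
    )


def nmb(delta_qalys: float, delta_cost: float, wtp: float) -> float:
    """Incremental net monetary benefit at willingness-to-pay ``wtp``."""
    return wtp * delta_qalys - delta_cost


def pairwise(
    intervention: AccrualResult, comparator: AccrualResult, wtp: float = 50_000.0
) -> dict:
    """Incremental comparison of one regimen against one comparator."""
    dc = intervention.cost - comparator.cost
    dq = intervention.qalys - comparator.qalys
    if dc < 0 and dq > 0:
        label, icur = "dominant", None
    elif dc > 0 and dq < 0:
        label, icur = "dominated", None
    elif dq == 0:
        label, icur = "equal QALYs", None
    else:
        icur = dc / dq
        label = f"{icur:,.0f}"
    return {
        "intervention": intervention.regimen,
        "comparator": comparator.regimen,
        "delta_cost": dc,
        "delta_qalys": dq,
        "icur": icur,
        "label": label,
        "inmb": nmb(dq, dc, wtp),
    }


def compare(results: list[AccrualResult], wtp: float = 50_000.0) -> pd.DataFrame:
    """Fully incremental analysis: order by QALYs, drop strictly and
    extendedly dominated regimens, report ICURs versus the next non-dominated
    alternative.  Invariant to input order."""
    if len(results) < 2:
        raise ValueError("need at least 2 regimens to compare")
    ordered = sorted(results, key=lambda r: (r.qalys, -r.cost, r.regimen))
    rows = []
    for r in ordered:
        rows.append(
            {"regimen": r.regimen, "cost": r.cost, "qalys": r.qalys, "status": ""}
        )
    df = pd.DataFrame(rows)
    # strict dominance
    for i in range(len(df)):
        for k in range(len(df)):
            if (
                df.loc[k, "cost"] <= df.loc[i, "cost"]
                and df.loc[k, "qalys"] >= df.loc[i, "qalys"]
                and (df.loc[k, "cost"] < df.loc[i, "cost"] or df.loc[k, "qalys"] > df.loc[i, "qalys"])
            ):
                df.loc[i, "status"] = "dominated"
    # extended dominance + ICURs on the efficiency frontier
    changed = True
    while changed:
        changed = False
        idx = [i for i in df.index if df.loc[i, "status"] != "dominated"]
        icurs = {}
        prev = None
        for i in idx:
            if prev is None:
                icurs[i] = None
            else:
                dq = df.loc[i, "qalys"] - df.loc[prev, "qalys"]
                dc = df.loc[i, "cost"] - df.loc[prev, "cost"]
                icurs[i] = dc / dq if dq > 0 else np.inf
            prev = i
        keys = [i for i in idx if icurs[i] is not None]
        for a, b in zip(keys, keys[1:]):
            if icurs[b] < icurs[a]:
                df.loc[a, "status"] = "extendedly dominated"
                changed = True
                break
    idx = [i for i in df.index if df.loc[i, "status"] == ""]
    prev = None
    for i in idx:
        if prev is not None:
            dq = df.loc[i, "qalys"] - df.loc[prev, "qalys"]
            dc = df.loc[i, "cost"] - df.loc[prev, "cost"]
            df.loc[i, "icur"] = dc / dq if dc > 0 else np.nan
            if dc <= 0:
                df.loc[i, "status"] = "dominant"
        prev = i
    df["inmb_vs_first"] = wtp * (df["qalys"] - df["qalys"].iloc[0]) - (
        df["cost"] - df["cost"].iloc[0]
    )
    return df.reset_index(drop=True)
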