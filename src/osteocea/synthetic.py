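"""Synthetic stand-ins for inputs that exist only in appendix tables or as
patient-level trial data: smooth age-increasing fracture-incidence and
mortality tables, post-fracture mortality RR tables, and Weibull time-to-event
fracture records with arm-specific hazards.

Everything here is seed-deterministic, and every stand-in is flagged in the
configuration it feeds (``standin_inputs``) so reports watermark results that
depend on it.  Stand-in fracture-rate magnitudes are anchored to the published
national figure of roughly 16 fragility fractures per 1000 persons aged 50+
per year; they are order-of-magnitude realistic, not reproductions of any
source table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .config import (
    AgeBandTable,
    AgeTable,
    CostTables,
    EconSettings,
    EpiTables,
    ModelConfig,
    MortalityModifier,
    MortalityRRTable,
    PopulationSpec,
    RegimenComponent,
    RegimenSpec,
    RiskAdjustment,
    RRWithCI,
    SocietalInputs,
    SyntheticTrialSpec,
    UncertaintySpec,
    UtilityMultipliers,
)


class SyntheticEpiSpec(BaseModel):
    """Generator spec for stand-in general-population epidemiology tables.

    Fracture rates grow exponentially with age (``rate(age) = base *
    2^((age-50)/doubling_time)``); mortality is Gompertz (annual hazard
    ``level * exp(slope * (age - 50))``, reported as annual probability).
    """

    #: annual rate per 1000 persons at age 50, per fracture type
    base_rate_per_1000_at_50: dict[str, float] = Field(
        default_factory=lambda: {"hip": 0.3, "vertebral": 1.5, "other": 5.0}
    )
    age_doubling_time: dict[str, float] = Field(
        default_factory=lambda: {"hip": 6.0, "vertebral": 10.0, "other": 16.0}
    )
    gompertz_level: float = 0.0015
    gompertz_slope: float = 0.100
    age_min: float = 50.0
    age_max: float = 100.0
    knot_step: float = 5.0
    seed: int = 20220426

    @model_validator(mode="after")
    def _check(self) -> "SyntheticEpiSpec":
        for ft, r in self.base_rate_per_1000_at_50.items():
            if r <= 0:
                raise ValueError(f"base rate for {ft!r} must be > 0")
        for ft, d in self.age_doubling_time.items():
            if d <= 0:
                raise ValueError(f"doubling time for {ft!r} must be > 0")
        if self.gompertz_level <= 0 or self.gompertz_slope <= 0:
            raise ValueError("Gompertz parameters must be > 0")
        return self


# Post-fracture all-cause mortality RRs (age-declining), stand-ins in the
# shape of published Canadian estimates: (RR at 50, RR at 100).
_MORT_RR_RANGES = {
    "hip": {"first_year": (6.0, 2.0), "subsequent_years": (2.2, 1.4)},
    "vertebral": {"first_year": (4.0, 1.6), "subsequent_years": (1.8, 1.2)},
    "other": {"first_year": (1.8, 1.1), "subsequent_years": None},
}


def gompertz_annual_prob(age, level: float, slope: float) -> np.ndarray:
    """Annual death probability from a Gompertz hazard anchored at age 50."""
    age = np.asarray(age, float)
    haz = level * np.exp(slope * (age - 50.0))
    return -np.expm1(-haz)


def make_epi_tables(spec: SyntheticEpiSpec) -> EpiTables:
    """Build stand-in general-population tables at 5-year knots, ages 50-100."""
    knots = np.arange(spec.age_min, spec.age_max + 1e-9, spec.knot_step)
    incidence = {}
    for ft, base in spec.base_rate_per_1000_at_50.items():
        doubling = spec.age_doubling_time[ft]
        per_1000 = base * 2.0 ** ((knots - 50.0) / doubling)
        incidence[ft] = AgeTable(ages=knots.tolist(), values=(per_1000 / 1000.0).tolist())
    mortality = AgeTable(
        ages=knots.tolist(),
        values=np.clip(
            gompertz_annual_prob(knots, spec.gompertz_level, spec.gompertz_slope), 0, 1
        ).tolist(),
    )
    rr_tables = {}
    for ft, bands in _MORT_RR_RANGES.items():
        tbls = {}
        for band, rng_ in bands.items():
            if rng_ is None:
                tbls[band] = None
                continue
            hi, lo = rng_
            vals = hi + (lo - hi) * (knots - 50.0) / (spec.age_max - spec.age_min)
            tbls[band] = AgeTable(ages=knots.tolist(), values=vals.tolist())
        rr_tables[ft] = MortalityRRTable(
            first_year=tbls["first_year"], subsequent_years=tbls["subsequent_years"]
        )
    utilities = AgeBandTable(
        band_lower_edges=[50, 55, 60, 65, 70, 75, 80, 85],
        values=[0.842, 0.830, 0.841, 0.837, 0.831, 0.778, 0.736, 0.616],
    )
    return EpiTables(
        fracture_incidence=incidence,
        mortality=mortality,
        mortality_rr_post_fracture=rr_tables,
        utilities=utilities,
    )


def simulate_trial(spec: SyntheticTrialSpec) -> pd.DataFrame:
    """Simulate two-arm time-to-first-event fracture records.

    Event times are Weibull per arm and endpoint; censoring is the minimum of
    an independent exponential and administrative censoring at end of
    follow-up.  The generating parameters travel in ``df.attrs`` so recovery
    tests can compare against the truth.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    sid = 0
    for arm, endpoints in spec.hazard_model.items():
        for ep, (shape, scale) in endpoints.items():
            n = spec.n_per_arm
            t_event = scale * rng.weibull(shape, size=n)
            if spec.censoring_rate > 0:
                t_cens = rng.exponential(1.0 / spec.censoring_rate, size=n)
            else:
                t_cens = np.full(n, np.inf)
            t_cens = np.minimum(t_cens, spec.follow_up_years)
            time = np.minimum(t_event, t_cens)
            event = t_event <= t_cens
            for i in range(n):
                rows.append((sid + i, arm, ep, float(time[i]), bool(event[i])))
            sid += n
    df = pd.DataFrame(
        rows, columns=["subject_id", "arm", "endpoint", "time_years", "event"]
    )
    df.attrs["generating_params"] = {
        arm: dict(eps) for arm, eps in spec.hazard_model.items()
    }
    df.attrs["spec"] = spec.model_dump()
    return df


# ---------------------------------------------------------------------------
# Reference fixture: every published point value, plus flagged stand-ins.
# ---------------------------------------------------------------------------

#: Per-cycle RR of the bone-forming sequence versus alendronate alone
#: (cycles 1-10; hip and non-vertebral derived from per-arm survival fits in
#: the source analysis, vertebral a step schedule from trial windows).
SEQUENCE_RR_VS_ALENDRONATE = {
    "hip": [0.89, 0.60, 0.56, 0.56, 0.57, 0.58, 0.59, 0.60, 0.62, 0.63],
    "vertebral": [0.64, 0.64, 0.38, 0.38, 0.38, 0.38, 0.38, 0.38, 0.38, 0.38],
    "other": [0.70, 0.75, 0.79, 0.85, 0.90, 0.96, 1.02, 1.08, 1.15, 1.23],
}

#: Placebo-anchored RRs with 95% CIs from the network meta-analysis.
ANCHORS = {
    "alendronate_vs_placebo": {
        "hip": RRWithCI(point=0.61, lower=0.42, upper=0.90),
        "vertebral": RRWithCI(point=0.57, lower=0.45, upper=0.71),
        "other": RRWithCI(point=0.84, lower=0.74, upper=0.94),
    },
    "risedronate_vs_placebo": {
        "hip": RRWithCI(point=0.73, lower=0.58, upper=0.92),
        "vertebral": RRWithCI(point=0.61, lower=0.48, upper=0.78),
        "other": RRWithCI(point=0.78, lower=0.68, upper=0.89),
    },
}

#: Published drug unit costs (2020 CAD) and the printed annual sums.
DRUG_UNIT_COSTS = {
    "romosozumab": {"unit_cost": 328.39, "doses_per_year": 12, "units_per_dose": 2},
    "alendronate": {"unit_cost": 2.10, "doses_per_year": 52, "units_per_dose": 1},
    "risedronate": {"unit_cost": 1.98, "doses_per_year": 52, "units_per_dose": 1},
}
ANNUAL_DRUG_COSTS = {"romosozumab": 7881.0, "alendronate": 109.0, "risedronate": 103.0}
#: Printed annual monitoring/administration sums (BMD $42 + physician $77
#: [+ nurse $191 for the injectable]); the printed sums are authoritative.
MONITORING_COMPONENTS = {"bmd": 42.0, "physician": 77.0, "nurse_romosozumab": 191.0}
ANNUAL_MONITORING_COSTS = {"romosozumab": 310.0, "oral_bisphosphonate": 119.0}

FIRST_YEAR_FRACTURE_COSTS = {
    "hip": [21898.0, 20875.0, 27512.0, 29782.0, 27398.0],
    "vertebral": [11427.0, 15342.0, 18600.0, 23683.0, 28341.0],
    "other": [2025.0, 2709.0, 7268.0, 15175.0, 20203.0],
}
COST_AGE_BANDS = [50.0, 60.0, 70.0, 80.0, 90.0]
SUBSEQUENT_YEAR_COSTS = {"hip": 5171.0, "vertebral": 235.0, "other": 0.0}

UTILITY_MULTIPLIERS = UtilityMultipliers(
    first_year={"hip": 0.55, "vertebral": 0.68, "other": 0.83},
    subsequent_years={"hip": 0.86, "vertebral": 0.85},
)


def annual_drug_cost_from_units(drug: str) -> float:
    """Annual acquisition cost recomputed from unit price and dosing."""
    u = DRUG_UNIT_COSTS[drug]
    return u["unit_cost"] * u["units_per_dose"] * u["doses_per_year"]


def annual_monitoring_cost_from_components(regimen: str) -> float:
    """Annual monitoring/administration cost as the sum of its fee items."""
    c = MONITORING_COMPONENTS
    total = c["bmd"] + c["physician"]
    if regimen == "romosozumab":
        total += c["nurse_romosozumab"]
    return total


def _regimens() -> list[RegimenSpec]:
    ones = {ft: [1.0] * 10 for ft in ("hip", "vertebral", "other")}
    romo = RegimenComponent(
        drug="romosozumab",
        duration_cycles=2,
        annual_drug_cost=ANNUAL_DRUG_COSTS["romosozumab"],
        annual_monitoring_cost=ANNUAL_MONITORING_COSTS["romosozumab"],
        visits_per_year=11.7,  # 0.85*12 nurse visits + physician 1 + BMD 0.5
    )
    aln_4y = RegimenComponent(
        drug="alendronate",
        duration_cycles=8,
        annual_drug_cost=ANNUAL_DRUG_COSTS["alendronate"],
        annual_monitoring_cost=ANNUAL_MONITORING_COSTS["oral_bisphosphonate"],
        visits_per_year=1.5,
    )
    aln_5y = aln_4y.model_copy(update={"duration_cycles": 10})
    ris_5y = RegimenComponent(
        drug="risedronate",
        duration_cycles=10,
        annual_drug_cost=ANNUAL_DRUG_COSTS["risedronate"],
        annual_monitoring_cost=ANNUAL_MONITORING_COSTS["oral_bisphosphonate"],
        visits_per_year=1.5,
    )
    return [
        RegimenSpec(
            name="romosozumab/alendronate",
            components=[romo, aln_4y],
            rr_vs_active=SEQUENCE_RR_VS_ALENDRONATE,
            anchor="alendronate_vs_placebo",
            provenance="direct-table",
        ),
        RegimenSpec(
            name="alendronate",
            components=[aln_5y],
            rr_vs_active=ones,
            anchor="alendronate_vs_placebo",
        ),
        RegimenSpec(
            name="risedronate",
            components=[ris_5y],
            rr_vs_active=ones,
            anchor="risedronate_vs_placebo",
        ),
    ]


def make_reference_fixture(epi_spec: SyntheticEpiSpec | None = None) -> ModelConfig:
    """The reference-case configuration: every published point value from the
    main-text tables, with flagged synthetic stand-ins for appendix-only
    inputs (general-population epidemiology, risk-adjustment RRs,
    post-fracture mortality RRs, societal wage/time-off)."""
    epi_spec = epi_spec or SyntheticEpiSpec()
    epi = make_epi_tables(epi_spec)
    costs = CostTables(
        first_year_fracture_cost={
            ft: AgeBandTable(band_lower_edges=COST_AGE_BANDS, values=vals)
            for ft, vals in FIRST_YEAR_FRACTURE_COSTS.items()
        },
        subsequent_year_cost=dict(SUBSEQUENT_YEAR_COSTS),
        ltc_entry_prob_after_hip=0.37,
        ltc_daily_cost=184.96,
        societal=SocietalInputs(
            hourly_wage=27.0,  # stand-in: mean hourly wage, women 55+
            time_off_hours={"hip": 240.0, "vertebral": 120.0, "other": 60.0},
            visit_out_of_pocket=20.0,
        ),
    )
    risk = RiskAdjustment(
        rr_prior_fracture=2.0,  # stand-in: 50/50 single/multiple prior fracture mix
        rr_per_sd_bmd={"hip": 2.6, "vertebral": 1.8, "other": 1.4},
        t_score_gap=1.0,
    )
    return ModelConfig(
        population=PopulationSpec(),
        regimens=_regimens(),
        efficacy_anchors=ANCHORS,
        epi=epi,
        risk_adjustment=risk,
        costs=costs,
        utility_multipliers=UTILITY_MULTIPLIERS,
        mortality_modifier=MortalityModifier(),
        econ=EconSettings(),
        uncertainty=UncertaintySpec(),
        trial=SyntheticTrialSpec(),
        standin_inputs=[
            "epi.fracture_incidence",
            "epi.mortality",
            "epi.mortality_rr_post_fracture",
            "risk_adjustment",
            "costs.societal.hourly_wage",
            "costs.societal.time_off_hours",
            "trial",
        ],
    )


def write_trial_records(df: pd.DataFrame, path) -> None:
    """Write trial records in the delimited-text dialect."""
    df.to_csv(path, index=False)


def write_age_table(table: AgeTable, path) -> None:
    ages, values = table.as_arrays()
    pd.DataFrame({"age": ages, "value": values}).to_csv(path, index=False)
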