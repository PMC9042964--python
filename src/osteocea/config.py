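"""Model configuration: every input of the cost-utility model as a validated,
serialisable object.

The run configuration is a single YAML document (age-indexed tables may be
externalised to delimited-text files with an ``age``/``value`` header and are
inlined on load).  All monetary fields are 2020 CAD; all rates are annual; the
model cycle is six months.
"""

from __future__ import annotations

import hashlib
import warnings
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

FRACTURE_TYPES = ("hip", "vertebral", "other")
N_TREATMENT_CYCLES = 10
CYCLE_LENGTH_YEARS = 0.5


class ConfigError(ValueError):
    """Raised when a run configuration violates a model invariant."""


class AgeTable(BaseModel):
    """Age-indexed table of non-negative values with strictly increasing ages."""

    ages: list[float]
    values: list[float]

    @model_validator(mode="after")
    def _check(self) -> "AgeTable":
        a = np.asarray(self.ages, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if a.size < 2:
            raise ValueError("age table needs at least 2 knots")
        if a.size != v.size:
            raise ValueError("ages and values differ in length")
        if np.any(np.diff(a) <= 0):
            raise ValueError("ages must be strictly increasing")
        if np.any(v < 0):
            raise ValueError("table values must be >= 0")
        return self

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.ages, float), np.asarray(self.values, float)


class AgeBandTable(BaseModel):
    """Step function over age bands: value of the last band edge <= age."""

    band_lower_edges: list[float]
    values: list[float]

    @model_validator(mode="after")
    def _check(self) -> "AgeBandTable":
        e = np.asarray(self.band_lower_edges, float)
        if e.size != len(self.values) or e.size == 0:
            raise ValueError("band edges and values differ in length")
        if np.any(np.diff(e) <= 0):
            raise ValueError("band edges must be strictly increasing")
        return self

    def lookup(self, age: float) -> float:
        e = np.asarray(self.band_lower_edges, float)
        i = int(np.searchsorted(e, age, side="right")) - 1
        i = max(i, 0)
        return float(self.values[i])

    def lookup_many(self, ages: np.ndarray) -> np.ndarray:
        e = np.asarray(self.band_lower_edges, float)
        idx = np.clip(np.searchsorted(e, ages, side="right") - 1, 0, e.size - 1)
        return np.asarray(self.values, float)[idx]


class PopulationSpec(BaseModel):
    mean_age: float = 74.0
    sex: Literal["female"] = "female"
    t_score: float = -2.5
    prior_fracture_single: float = 0.5
    prior_fracture_multiple: float = 0.5

    @model_validator(mode="after")
    def _check(self) -> "PopulationSpec":
        if not (50.0 <= self.mean_age <= 100.0):
            raise ValueError("mean_age must lie in [50, 100]")
        if self.t_score > -2.5:
            raise ValueError("t_score must be <= -2.5 (very high risk population)")
        for name in ("prior_fracture_single", "prior_fracture_multiple"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if abs(self.prior_fracture_single + self.prior_fracture_multiple - 1.0) > 1e-9:
            raise ValueError("prior fracture proportions must sum to 1")
        return self


class RRWithCI(BaseModel):
    """A relative risk with an optional 95% confidence interval."""

    point: float
    lower: Optional[float] = None
    upper: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "RRWithCI":
        if self.point <= 0:
            raise ValueError("RR point estimate must be > 0")
        if (self.lower is None) != (self.upper is None):
            raise ValueError("CI must give both bounds or neither")
        if self.lower is not None:
            if not (0 < self.lower <= self.point <= self.upper):
                raise ValueError("CI must satisfy 0 < lower <= point <= upper")
        return self


class RegimenComponent(BaseModel):
    drug: str
    duration_cycles: int = Field(gt=0)
    annual_drug_cost: float = Field(ge=0.0)
    annual_monitoring_cost: float = Field(ge=0.0)
    #: scheduled monitoring/administration visits per treated year (societal
    #: out-of-pocket costs attach to these)
    visits_per_year: float = Field(default=0.0, ge=0.0)


class RegimenSpec(BaseModel):
    """A named treatment sequence with its efficacy schedule and cost schedule.

    ``rr_vs_active`` holds the per-cycle RR of the regimen against its anchor
    comparator (identity for the comparators themselves); ``anchor`` names the
    placebo-anchored RR set (with CIs) the schedule is multiplied into, so the
    effective per-cycle RR versus placebo is ``rr_vs_active[c] * anchor_rr``.
    """

    name: str
    components: list[RegimenComponent]
    treatment_duration_cycles: int = N_TREATMENT_CYCLES
    offset_duration_years: float = 5.0
    rr_vs_active: dict[str, list[float]]
    anchor: str
    provenance: Literal["direct-table", "derived-from-fits"] = "direct-table"

    @model_validator(mode="after")
    def _check(self) -> "RegimenSpec":
        if self.treatment_duration_cycles <= 0:
            raise ValueError("treatment_duration_cycles must be > 0")
        if self.offset_duration_years <= 0:
            raise ValueError("offset_duration_years must be > 0")
        total = sum(c.duration_cycles for c in self.components)
        if total != self.treatment_duration_cycles:
            raise ValueError(
                f"component durations sum to {total} cycles, expected "
                f"{self.treatment_duration_cycles}"
            )
        for ft in FRACTURE_TYPES:
            if ft not in self.rr_vs_active:
                raise ValueError(f"rr_vs_active missing fracture type {ft!r}")
            sched = self.rr_vs_active[ft]
            if len(sched) < self.treatment_duration_cycles:
                raise ValueError(
                    f"rr_vs_active[{ft!r}] has {len(sched)} cycles, needs >= "
                    f"{self.treatment_duration_cycles}"
                )
            if any(r <= 0 for r in sched):
                raise ValueError(f"rr_vs_active[{ft!r}] must be > 0 everywhere")
        return self

    def component_at_cycle(self, cycle: int) -> Optional[RegimenComponent]:
        """Active component at 1-based treatment cycle, None after treatment."""
        c = 0
        for comp in self.components:
            c += comp.duration_cycles
            if cycle <= c:
                return comp
        return None


class MortalityRRTable(BaseModel):
    """Post-fracture all-cause mortality RR by years-since-fracture band."""

    first_year: AgeTable
    subsequent_years: Optional[AgeTable] = None


class EpiTables(BaseModel):
    """General-population epidemiology: fracture incidence, mortality, utility."""

    fracture_incidence: dict[str, AgeTable]  # annual rate per person
    mortality: AgeTable  # annual probability of death
    mortality_rr_post_fracture: dict[str, MortalityRRTable]
    utilities: AgeBandTable

    @model_validator(mode="after")
    def _check(self) -> "EpiTables":
        for ft in FRACTURE_TYPES:
            if ft not in self.fracture_incidence:
                raise ValueError(f"fracture_incidence missing table for {ft!r}")
            if ft not in self.mortality_rr_post_fracture:
                raise ValueError(f"mortality_rr_post_fracture missing table for {ft!r}")
        if any(not (0.0 <= u <= 1.0) for u in self.utilities.values):
            raise ValueError("utilities must lie in [0, 1]")
        if any(not (0.0 <= q <= 1.0) for q in self.mortality.values):
            raise ValueError("mortality probabilities must lie in [0, 1]")
        return self


class RiskAdjustment(BaseModel):
    """RRs translating general-population rates to the very-high-risk cohort."""

    rr_prior_fracture: float = Field(gt=0.0)
    rr_per_sd_bmd: dict[str, float]
    t_score_gap: float = Field(ge=0.0)

    @model_validator(mode="after")
    def _check(self) -> "RiskAdjustment":
        for ft in FRACTURE_TYPES:
            if ft not in self.rr_per_sd_bmd:
                raise ValueError(f"rr_per_sd_bmd missing fracture type {ft!r}")
            if self.rr_per_sd_bmd[ft] <= 0:
                raise ValueError("rr_per_sd_bmd entries must be > 0")
        return self


class SocietalInputs(BaseModel):
    hourly_wage: float = Field(ge=0.0)
    time_off_hours: dict[str, float]
    visit_out_of_pocket: float = Field(ge=0.0)

    @model_validator(mode="after")
    def _check(self) -> "SocietalInputs":
        for ft in FRACTURE_TYPES:
            if ft not in self.time_off_hours:
                raise ValueError(f"time_off_hours missing fracture type {ft!r}")
            if self.time_off_hours[ft] < 0:
                raise ValueError("time_off_hours must be >= 0")
        return self


class CostTables(BaseModel):
    first_year_fracture_cost: dict[str, AgeBandTable]  # CAD per event
    subsequent_year_cost: dict[str, float]  # CAD per person-year
    ltc_entry_prob_after_hip: float
    ltc_daily_cost: float = Field(ge=0.0)
    societal: SocietalInputs

    @model_validator(mode="after")
    def _check(self) -> "CostTables":
        for ft in FRACTURE_TYPES:
            if ft not in self.first_year_fracture_cost:
                raise ValueError(f"first_year_fracture_cost missing table for {ft!r}")
        for ft, c in self.subsequent_year_cost.items():
            if c < 0:
                raise ValueError(f"subsequent_year_cost[{ft!r}] must be >= 0")
        if not (0.0 <= self.ltc_entry_prob_after_hip <= 1.0):
            raise ValueError("ltc_entry_prob_after_hip must lie in [0, 1]")
        for tbl in self.first_year_fracture_cost.values():
            if any(v < 0 for v in tbl.values):
                raise ValueError("fracture costs must be >= 0")
        return self


class UtilityMultipliers(BaseModel):
    first_year: dict[str, float]
    subsequent_years: dict[str, float]

    @model_validator(mode="after")
    def _check(self) -> "UtilityMultipliers":
        for ft in FRACTURE_TYPES:
            if ft not in self.first_year:
                raise ValueError(f"first_year multiplier missing for {ft!r}")
        for ft in ("hip", "vertebral"):
            if ft not in self.subsequent_years:
                raise ValueError(f"subsequent_years multiplier missing for {ft!r}")
        for m in list(self.first_year.values()) + list(self.subsequent_years.values()):
            if not (0.0 < m <= 1.0):
                raise ValueError("utility multipliers must lie in (0, 1]")
        return self


class MortalityModifier(BaseModel):
    """Attributable excess mortality after fracture."""

    attributable_fraction: float = 0.30
    excess_duration_years: dict[str, float] = Field(
        default_factory=lambda: {"hip": 8.0, "vertebral": 8.0, "other": 1.0}
    )

    @model_validator(mode="after")
    def _check(self) -> "MortalityModifier":
        if not (0.0 <= self.attributable_fraction <= 1.0):
            raise ValueError("attributable_fraction must lie in [0, 1]")
        for ft in FRACTURE_TYPES:
            if ft not in self.excess_duration_years:
                raise ValueError(f"excess_duration_years missing for {ft!r}")
            if self.excess_duration_years[ft] < 0:
                raise ValueError("excess durations must be >= 0")
        return self


def default_wtp_grid() -> list[float]:
    return [float(x) for x in range(0, 200_001, 1000)]


class EconSettings(BaseModel):
    discount_rate_costs: float = 0.015
    discount_rate_qalys: float = 0.015
    cycle_length_years: float = CYCLE_LENGTH_YEARS
    max_age: float = 100.0
    closeout_max_age: float = 110.0
    wtp_grid: list[float] = Field(default_factory=default_wtp_grid)
    wtp_reference: float = 50_000.0
    perspective: Literal["payer", "societal"] = "payer"
    half_cycle_correction: bool = False

    @model_validator(mode="after")
    def _check(self) -> "EconSettings":
        if self.discount_rate_costs < 0 or self.discount_rate_qalys < 0:
            raise ValueError("discount rates must be >= 0")
        if self.cycle_length_years != CYCLE_LENGTH_YEARS:
            raise ValueError("cycle_length_years must be 0.5 in the reference case")
        if not self.wtp_grid:
            raise ValueError("wtp_grid must be non-empty")
        return self


class UncertaintySpec(BaseModel):
    """How PSA/DSA distributions are built when no CI is published.

    RRs with a CI are lognormal with the point estimate as the median and
    log-sd = (ln upper - ln lower)/3.92.  Where no CI is available the spread
    is a symmetric +/-`default_spread` interpreted as a 95% interval: beta for
    utilities/proportions, gamma for costs, lognormal for RRs, normal for
    survival-model parameters.
    """

    default_spread: float = 0.25
    sample_costs: bool = True
    sample_drug_costs: bool = False

    @model_validator(mode="after")
    def _check(self) -> "UncertaintySpec":
        if not (0.0 < self.default_spread < 1.0):
            raise ValueError("default_spread must lie in (0, 1)")
        return self


class SyntheticTrialSpec(BaseModel):
    """Generator spec for stand-in two-arm time-to-event fracture data."""

    n_per_arm: int = Field(default=2046, gt=0)
    follow_up_years: float = Field(default=3.0, gt=0)
    #: per arm, per endpoint Weibull (shape, scale in years)
    hazard_model: dict[str, dict[str, tuple[float, float]]] = Field(
        default_factory=lambda: {
            "active": {"hip": (1.35, 95.0), "other": (1.25, 22.0)},
            "comparator": {"hip": (1.05, 110.0), "other": (1.02, 24.0)},
        }
    )
    censoring_rate: float = Field(default=0.05, ge=0.0)
    seed: int = 20220426

    @model_validator(mode="after")
    def _check(self) -> "SyntheticTrialSpec":
        for arm, eps in self.hazard_model.items():
            for ep, (shape, scale) in eps.items():
                if shape <= 0 or scale <= 0:
                    raise ValueError(f"Weibull shape/scale for {arm}/{ep} must be > 0")
        return self


class ModelConfig(BaseModel):
    population: PopulationSpec = Field(default_factory=PopulationSpec)
    regimens: list[RegimenSpec]
    #: placebo-anchored RRs (with CIs) the regimen schedules multiply into
    efficacy_anchors: dict[str, dict[str, RRWithCI]]
    epi: EpiTables
    risk_adjustment: RiskAdjustment
    costs: CostTables
    utility_multipliers: UtilityMultipliers
    mortality_modifier: MortalityModifier = Field(default_factory=MortalityModifier)
    econ: EconSettings = Field(default_factory=EconSettings)
    uncertainty: UncertaintySpec = Field(default_factory=UncertaintySpec)
    #: optional generator spec used when efficacy schedules are re-derived from
    #: survival fits (BIC / second-AIC scenarios)
    trial: Optional[SyntheticTrialSpec] = None
    #: whether corrected lower-hierarchy fracture events also contribute excess
    #: mortality (reference: costs and disutilities only)
    corrected_events_affect_mortality: bool = False
    #: whether LTC cost adds to (True) or replaces post-hip medical cost
    ltc_additive: bool = True
    #: names of inputs that are synthetic stand-ins, propagated to reports
    standin_inputs: list[str] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check(self) -> "ModelConfig":
        if len(self.regimens) < 1:
            raise ValueError("at least one regimen required")
        names = [r.name for r in self.regimens]
        if len(set(names)) != len(names):
            raise ValueError("regimen names must be unique")
        for r in self.regimens:
            if r.anchor not in self.efficacy_anchors:
                raise ValueError(
                    f"regimen {r.name!r} references unknown anchor {r.anchor!r}"
                )
            for ft in FRACTURE_TYPES:
                if ft not in self.efficacy_anchors[r.anchor]:
                    raise ValueError(f"anchor {r.anchor!r} missing RR for {ft!r}")
        return self

    def regimen(self, name: str) -> RegimenSpec:
        for r in self.regimens:
            if r.name == name:
                return r
        raise KeyError(name)

    def rr_schedule_vs_placebo(self, regimen: RegimenSpec) -> dict[str, np.ndarray]:
        """Effective per-cycle RR versus placebo over the treatment period."""
        anchors = self.efficacy_anchors[regimen.anchor]
        out = {}
        for ft in FRACTURE_TYPES:
            sched = np.asarray(
                regimen.rr_vs_active[ft][: regimen.treatment_duration_cycles], float
            )
            out[ft] = sched * anchors[ft].point
        return out

    def digest(self) -> str:
        """Stable content hash of the configuration."""
        payload = yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


def validate_rr_schedule(schedule: dict[str, list[float]]) -> dict[str, list[float]]:
    """Check a 10-cycle x 3-type RR schedule.

    RRs above 1 are legal (late-cycle non-vertebral RRs exceed 1) but warned
    about; non-positive RRs are an error.
    """
    for ft in FRACTURE_TYPES:
        if ft not in schedule:
            raise ConfigError(f"RR schedule missing fracture type {ft!r}")
        vals = schedule[ft]
        if len(vals) != N_TREATMENT_CYCLES:
            raise ConfigError(
                f"RR schedule for {ft!r} has {len(vals)} cycles, expected "
                f"{N_TREATMENT_CYCLES}"
            )
        for i, r in enumerate(vals, start=1):
            if r <= 0:
                raise ConfigError(f"RR schedule {ft!r} cycle {i}: RR must be > 0")
            if r > 1:
                warnings.warn(
                    f"RR schedule {ft!r} cycle {i} exceeds 1 ({r}); treatment "
                    "increases this fracture risk in that cycle",
                    UserWarning,
                    stacklevel=2,
                )
    return schedule


def _inline_tables(node, base_dir: Path):
    """Replace {'csv': path} leaves by inline age tables read from disk."""
    if isinstance(node, dict):
        if set(node) == {"csv"}:
            df = pd.read_csv(base_dir / node["csv"])
            cols = [c.lower() for c in df.columns]
            df.columns = cols
            if "age" not in cols or "value" not in cols:
                raise ConfigError(
                    f"external table {node['csv']} must have 'age' and 'value' columns"
                )
            return {"ages": df["age"].tolist(), "values": df["value"].tolist()}
        return {k: _inline_tables(v, base_dir) for k, v in node.items()}
    if isinstance(node, list):
        return [_inline_tables(v, base_dir) for v in node]
    return node


def load_config(path: str | Path) -> ModelConfig:
    """Read and fully validate a YAML run configuration."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path} does not contain a configuration mapping")
    raw = _inline_tables(raw, path.parent)
    try:
        return ModelConfig.model_validate(raw)
    except Exception as exc:  # pydantic ValidationError carries field paths
        raise ConfigError(f"invalid configuration {path}: {exc}") from exc


def write_config(config: ModelConfig, path: str | Path) -> None:
    """Write a configuration to YAML (tables inlined) so it round-trips."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=False)
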