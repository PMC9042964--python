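"""Parameter uncertainty: probabilistic sensitivity analysis with CEACs,
one-way deterministic sensitivity with an INMB tornado, and the scenario
runner.

Distribution conventions: RRs are lognormal with the point estimate as median
(log-sd from the 95% CI where published, otherwise from a +/-25% default
interval); utilities and proportions are beta, costs gamma, both matched to
the point estimate as mean with sd = spread*mean/1.96; survival-model
parameters are resampled from the asymptotic normal of their fit when the
efficacy schedule is derived from fits.  Parameters are sampled
independently.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .config import FRACTURE_TYPES, ModelConfig, RRWithCI
from .efficacy import cycle_rr, schedule_from_trial
from .synthetic import simulate_trial

# --------------------------------------------------------------------------
# distribution builders
# --------------------------------------------------------------------------


def lognormal_sigma_from_ci(lower: float, upper: float) -> float:
    """Log-sd of a lognormal whose 95% CI is (lower, upper)."""
    if not (0 < lower <= upper):
        raise ValueError("need 0 < lower <= upper")
    return (np.log(upper) - np.log(lower)) / (2.0 * 1.959963984540054)


def draw_lognormal_rr(rr: RRWithCI, rng, default_spread: float) -> float:
    """Lognormal draw with the point estimate as the median."""
    if rr.lower is not None:
        sigma = lognormal_sigma_from_ci(rr.lower, rr.upper)
    else:
        sigma = lognormal_sigma_from_ci(
            rr.point * (1 - default_spread), rr.point * (1 + default_spread)
        )
    return float(np.exp(rng.normal(np.log(rr.point), sigma)))


def draw_beta(mean: float, spread: float, rng) -> float:
    """Beta draw matched to mean and sd = spread*mean/1.96, clipped to (0,1)."""
    if mean <= 0.0:
        return mean
    if mean >= 1.0:
        mean = 1.0 - 1e-9
    sd = min(spread * mean / 1.96, 0.99 * np.sqrt(mean * (1 - mean)))
    if sd <= 0:
        return mean
    nu = mean * (1 - mean) / sd**2 - 1.0
    a, b = mean * nu, (1 - mean) * nu
    return float(rng.beta(a, b))


def draw_gamma(mean: float, spread: float, rng) -> float:
    """Gamma draw matched to mean and sd = spread*mean/1.96."""
    if mean <= 0.0:
        return mean
    sd = spread * mean / 1.96
    shape = (mean / sd) ** 2
    return float(rng.gamma(shape, mean / shape))


# --------------------------------------------------------------------------
# parameter paths (shared by DSA and scenario overrides)
# --------------------------------------------------------------------------


def _walk(obj, parts):
    for p in parts:
        if isinstance(obj, dict):
            obj = obj[p]
        elif isinstance(obj, (list, tuple)):
            obj = obj[int(p)]
        else:
            obj = getattr(obj, p)
    return obj


def get_param(config: ModelConfig, path: str):
    return _walk(config, path.split("."))


def set_param(config: ModelConfig, path: str, value) -> None:
    parts = path.split(".")
    parent = _walk(config, parts[:-1])
    last = parts[-1]
    if isinstance(parent, dict):
        parent[last] = value
    elif isinstance(parent, list):
        parent[int(last)] = value
    else:
        setattr(parent, last, value)


# --------------------------------------------------------------------------
# PSA
# --------------------------------------------------------------------------


def sample_params(config: ModelConfig, rng: np.random.Generator) -> ModelConfig:
    """One joint parameter draw; deterministic given the generator state."""
    cfg = config.model_copy(deep=True)
    spread = cfg.uncertainty.default_spread

    for anchor in sorted(cfg.efficacy_anchors):
        for ft in FRACTURE_TYPES:
            rr = config.efficacy_anchors[anchor][ft]
            cfg.efficacy_anchors[anchor][ft] = RRWithCI(
                point=draw_lognormal_rr(rr, rng, spread), lower=None, upper=None
            )

    for reg_old, reg_new in zip(config.regimens, cfg.regimens):
        for ft in FRACTURE_TYPES:
            sched = reg_old.rr_vs_active[ft]
            if all(abs(r - 1.0) < 1e-12 for r in sched):
                continue  # comparator: uncertainty enters through the anchor
            mult = draw_lognormal_rr(
                RRWithCI(point=1.0), rng, spread
            )
            reg_new.rr_vs_active[ft] = [r * mult for r in sched]

    adj_old, adj = config.risk_adjustment, cfg.risk_adjustment
    adj.rr_prior_fracture = draw_lognormal_rr(
        RRWithCI(point=adj_old.rr_prior_fracture), rng, spread
    )
    for ft in FRACTURE_TYPES:
        adj.rr_per_sd_bmd[ft] = draw_lognormal_rr(
            RRWithCI(point=adj_old.rr_per_sd_bmd[ft]), rng, spread
        )

    for ft in FRACTURE_TYPES:
        old_t = config.epi.mortality_rr_post_fracture[ft]
        new_t = cfg.epi.mortality_rr_post_fracture[ft]
        for band in ("first_year", "subsequent_years"):
            tbl_old, tbl_new = getattr(old_t, band), getattr(new_t, band)
            if tbl_old is None:
                continue
            mult = draw_lognormal_rr(RRWithCI(point=1.0), rng, spread)
            tbl_new.values = [v * mult for v in tbl_old.values]

    mod = cfg.mortality_modifier
    mod.attributable_fraction = draw_beta(
        config.mortality_modifier.attributable_fraction, spread, rng
    )

    cfg.epi.utilities.values = [
        draw_beta(u, spread, rng) for u in config.epi.utilities.values
    ]
    um_old, um = config.utility_multipliers, cfg.utility_multipliers
    um.first_year = {
        ft: draw_beta(v, spread, rng) for ft, v in um_old.first_year.items()
    }
    um.subsequent_years = {
        ft: draw_beta(v, spread, rng) for ft, v in um_old.subsequent_years.items()
    }

    if cfg.uncertainty.sample_costs:
        for ft in FRACTURE_TYPES:
            old_tbl = config.costs.first_year_fracture_cost[ft]
            new_tbl = cfg.costs.first_year_fracture_cost[ft]
            new_tbl.values = [draw_gamma(v, spread, rng) for v in old_tbl.values]
        cfg.costs.subsequent_year_cost = {
            ft: draw_gamma(v, spread, rng)
            for ft, v in config.costs.subsequent_year_cost.items()
        }
        cfg.costs.ltc_daily_cost = draw_gamma(config.costs.ltc_daily_cost, spread, rng)
        cfg.costs.ltc_entry_prob_after_hip = draw_beta(
            config.costs.ltc_entry_prob_after_hip, spread, rng
        )
        cfg.costs.societal.hourly_wage = draw_gamma(
            config.costs.societal.hourly_wage, spread, rng
        )
    if cfg.uncertainty.sample_drug_costs:
        for reg_old, reg_new in zip(config.regimens, cfg.regimens):
            for c_old, c_new in zip(reg_old.components, reg_new.components):
                c_new.annual_drug_cost = draw_gamma(c_old.annual_drug_cost, spread, rng)
                c_new.annual_monitoring_cost = draw_gamma(
                    c_old.annual_monitoring_cost, spread, rng
                )
    return cfg


@dataclass
class PSAResult:
    """Per-iteration cost/QALY pairs per regimen, CEACs, probabilistic means."""

    regimens: list[str]
    costs: np.ndarray  # (n_iterations, n_regimens), discounted per person
    qalys: np.ndarray
    fracture_totals: np.ndarray  # (n_iterations, n_regimens), per 1000
    wtp_grid: np.ndarray
    seed: Optional[int]

    @property
    def n_iterations(self) -> int:
        return self.costs.shape[0]

    def means(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "regimen": self.regimens,
                "cost": self.costs.mean(axis=0),
                "qalys": self.qalys.mean(axis=0),
                "fractures_per_1000": self.fracture_totals.mean(axis=0),
            }
        )

    def ceac(self) -> pd.DataFrame:
        """Probability each regimen maximises NMB, per willingness-to-pay.

        Ties go to the cheaper regimen, then to the first listed.
        """
        n, k = self.costs.shape
        out = np.zeros((len(self.wtp_grid), k))
        for gi, lam in enumerate(self.wtp_grid):
            nmb = lam * self.qalys - self.costs
            best = nmb.max(axis=1, keepdims=True)
            is_best = nmb >= best - 1e-9
            masked_cost = np.where(is_best, self.costs, np.inf)
            winner = np.argmin(masked_cost, axis=1)
            out[gi] = np.bincount(winner, minlength=k) / n
        df = pd.DataFrame(out, columns=self.regimens)
        df.insert(0, "wtp", self.wtp_grid)
        return df

    def ceac_at(self, wtp: float, regimen: str) -> float:
        nmb = wtp * self.qalys - self.costs
        best = nmb.max(axis=1, keepdims=True)
        is_best = nmb >= best - 1e-9
        masked_cost = np.where(is_best, self.costs, np.inf)
        winner = np.argmin(masked_cost, axis=1)
        j = self.regimens.index(regimen)
        return float(np.mean(winner == j))

    def scatter(self, intervention: str, comparator: str) -> pd.DataFrame:
        i = self.regimens.index(intervention)
        c = self.regimens.index(comparator)
        return pd.DataFrame(
            {
                "delta_cost": self.costs[:, i] - self.costs[:, c],
                "delta_qalys": self.qalys[:, i] - self.qalys[:, c],
            }
        )

    def plot_ceac(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.ceac()
        for name in self.regimens:
            ax.plot(df["wtp"], df[name], label=name)
        ax.set_xlabel("Willingness to pay (CAD per QALY)")
        ax.set_ylabel("Probability cost-effective")
        ax.set_ylim(0, 1)
        ax.legend()
        return ax


def run_psa(
    run_one: Callable[[ModelConfig], tuple[np.ndarray, np.ndarray, np.ndarray]],
    config: ModelConfig,
    regimens: list[str],
    n_iterations: int = 5000,
    seed: Optional[int] = None,
) -> PSAResult:
    """Sample-run-record loop.  ``run_one(config_draw)`` returns per-regimen
    (costs, qalys, fracture totals) for one parameter draw."""
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    rng = np.random.default_rng(seed)
    k = len(regimens)
    costs = np.zeros((n_iterations, k))
    qalys = np.zeros((n_iterations, k))
    fracs = np.zeros((n_iterations, k))
    for it in range(n_iterations):
        draw = sample_params(config, rng)
        costs[it], qalys[it], fracs[it] = run_one(draw)
    return PSAResult(
        regimens=list(regimens),
        costs=costs,
        qalys=qalys,
        fracture_totals=fracs,
        wtp_grid=np.asarray(config.econ.wtp_grid, float),
        seed=seed,
    )


# --------------------------------------------------------------------------
# DSA
# --------------------------------------------------------------------------


@dataclass
class DSAParameter:
    name: str
    path: str
    low: float
    high: float


def default_dsa_parameters(config: ModelConfig) -> list[DSAParameter]:
    """One-way parameters: published CI bounds where available, +/-25%
    otherwise."""
    s = config.uncertainty.default_spread
    params: list[DSAParameter] = []
    for anchor in sorted(config.efficacy_anchors):
        for ft in FRACTURE_TYPES:
            rr = config.efficacy_anchors[anchor][ft]
            lo = rr.lower if rr.lower is not None else rr.point * (1 - s)
            hi = rr.upper if rr.upper is not None else rr.point * (1 + s)
            params.append(
                DSAParameter(
                    f"RR {ft}, {anchor}",
                    f"efficacy_anchors.{anchor}.{ft}.point",
                    lo,
                    hi,
                )
            )
    def pm(name, path):
        v = get_param(config, path)
        params.append(DSAParameter(name, path, v * (1 - s), v * (1 + s)))

    pm("RR prior fracture", "risk_adjustment.rr_prior_fracture")
    for ft in FRACTURE_TYPES:
        pm(f"RR per SD BMD, {ft}", f"risk_adjustment.rr_per_sd_bmd.{ft}")
    pm("Attributable mortality fraction", "mortality_modifier.attributable_fraction")
    pm("LTC entry probability", "costs.ltc_entry_prob_after_hip")
    pm("LTC daily cost", "costs.ltc_daily_cost")
    pm("Post-hip annual cost", "costs.subsequent_year_cost.hip")
    pm("Utility multiplier, hip year 1", "utility_multipliers.first_year.hip")
    pm("Utility multiplier, hip later years", "utility_multipliers.subsequent_years.hip")
    return params


def run_dsa(
    run_pair: Callable[[ModelConfig], tuple[float, float]],
    config: ModelConfig,
    parameters: Optional[Sequence[DSAParameter]] = None,
    wtp: float = 50_000.0,
) -> pd.DataFrame:
    """One-way sensitivity: ``run_pair(config)`` returns (delta_cost,
    delta_qalys) of the intervention versus its comparator; the tornado ranks
    parameters by INMB bar width at the given willingness-to-pay."""
    parameters = list(parameters or default_dsa_parameters(config))
    dc0, dq0 = run_pair(config)
    base_inmb = wtp * dq0 - dc0
    rows = []
    for p in parameters:
        inmbs = []
        for v in (p.low, p.high):
            cfg = config.model_copy(deep=True)
            set_param(cfg, p.path, v)
            dc, dq = run_pair(cfg)
            inmbs.append(wtp * dq - dc)
        rows.append(
            {
                "parameter": p.name,
                "path": p.path,
                "low": p.low,
                "high": p.high,
                "inmb_low": inmbs[0],
                "inmb_high": inmbs[1],
                "base_inmb": base_inmb,
                "extent": abs(inmbs[1] - inmbs[0]),
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["extent", "parameter"], ascending=[False, True]
    )
    return df.reset_index(drop=True)


# --------------------------------------------------------------------------
# scenarios
# --------------------------------------------------------------------------


@dataclass
class ScenarioSpec:
    name: str
    overrides: list[tuple[str, object]] = field(default_factory=list)
    transform: Optional[Callable[[ModelConfig], ModelConfig]] = None

    def apply(self, config: ModelConfig) -> ModelConfig:
        cfg = config.model_copy(deep=True)
        for path, value in self.overrides:
            set_param(cfg, path, copy.deepcopy(value))
        if self.transform is not None:
            cfg = self.transform(cfg)
        return cfg


def _sequence_regimen(config: ModelConfig):
    for r in config.regimens:
        if any(
            any(abs(x - 1.0) > 1e-12 for x in r.rr_vs_active[ft])
            for ft in FRACTURE_TYPES
        ):
            return r
    return config.regimens[0]


def _romo_risedronate_transform(cfg: ModelConfig) -> ModelConfig:
    """Sequence the bone-forming agent to risedronate: efficacy equal to the
    alendronate sequence while the bone-forming agent is on board (cycles
    1-2), then the sequence-vs-active schedule applied to the risedronate
    placebo anchor."""
    seq = _sequence_regimen(cfg)
    aln = cfg.efficacy_anchors["alendronate_vs_placebo"]
    ris = cfg.efficacy_anchors["risedronate_vs_placebo"]
    ris_reg = next(r for r in cfg.regimens if r.anchor == "risedronate_vs_placebo")
    new_sched = {}
    for ft in FRACTURE_TYPES:
        sched = list(seq.rr_vs_active[ft])
        for c in range(2):  # vs-placebo equality with the alendronate sequence
            sched[c] = sched[c] * aln[ft].point / ris[ft].point
        new_sched[ft] = sched
    seq.name = "romosozumab/risedronate"
    seq.anchor = "risedronate_vs_placebo"
    seq.rr_vs_active = new_sched
    # oral component switches to risedronate pricing
    oral = ris_reg.components[0]
    seq.components = [
        seq.components[0],
        oral.model_copy(update={"duration_cycles": seq.components[1].duration_cycles}),
    ]
    return cfg


def _refit_transform(criterion: str):
    def transform(cfg: ModelConfig) -> ModelConfig:
        if cfg.trial is None:
            raise ValueError(
                "survival-refit scenarios need a trial spec in the configuration"
            )
        records = simulate_trial(cfg.trial)
        sched, _ = schedule_from_trial(records, criterion=criterion)
        seq = _sequence_regimen(cfg)
        seq.rr_vs_active = {
            "hip": sched["hip"],
            "vertebral": list(seq.rr_vs_active["vertebral"]),
            "other": sched["other"],
        }
        seq.provenance = "derived-from-fits"
        return cfg

    return transform


def _offset_transform(years: float):
    def transform(cfg: ModelConfig) -> ModelConfig:
        for r in cfg.regimens:
            r.offset_duration_years = years
        return cfg

    return transform


def _risedronate_price_transform(cfg: ModelConfig) -> ModelConfig:
    for r in cfg.regimens:
        for comp in r.components:
            if comp.drug == "risedronate":
                comp.annual_drug_cost = 617.0
    return cfg


#: alternative fracture disutility multipliers (synthetic stand-in for a
#: Canadian long-term-care HRQoL source; flagged, not published values)
TARRIDE_STANDIN_MULTIPLIERS = {
    "first_year": {"hip": 0.62, "vertebral": 0.72, "other": 0.88},
    "subsequent_years": {"hip": 0.82, "vertebral": 0.87},
}


def reference_scenarios() -> list[ScenarioSpec]:
    """The scenario battery: alternative sequence, perspective, discounting,
    survival-model selection, offset time, excess-mortality assumptions,
    disutility source, and risedronate pricing."""
    return [
        ScenarioSpec("reference case"),
        ScenarioSpec("romosozumab/risedronate sequence", transform=_romo_risedronate_transform),
        ScenarioSpec("societal perspective", overrides=[("econ.perspective", "societal")]),
        ScenarioSpec(
            "discount 0%",
            overrides=[("econ.discount_rate_costs", 0.0), ("econ.discount_rate_qalys", 0.0)],
        ),
        ScenarioSpec(
            "discount 3%",
            overrides=[("econ.discount_rate_costs", 0.03), ("econ.discount_rate_qalys", 0.03)],
        ),
        ScenarioSpec("BIC survival selection", transform=_refit_transform("BIC")),
        ScenarioSpec("second-AIC survival selection", transform=_refit_transform("second-AIC")),
        ScenarioSpec("offset 1 year", transform=_offset_transform(1.0)),
        ScenarioSpec(
            "excess mortality 5 years",
            overrides=[
                ("mortality_modifier.excess_duration_years.hip", 5.0),
                ("mortality_modifier.excess_duration_years.vertebral", 5.0),
            ],
        ),
        ScenarioSpec(
            "excess mortality 10 years",
            overrides=[
                ("mortality_modifier.excess_duration_years.hip", 10.0),
                ("mortality_modifier.excess_duration_years.vertebral", 10.0),
            ],
        ),
        ScenarioSpec(
            "attributable fraction 10%",
            overrides=[("mortality_modifier.attributable_fraction", 0.10)],
        ),
        ScenarioSpec(
            "attributable fraction 50%",
            overrides=[("mortality_modifier.attributable_fraction", 0.50)],
        ),
        ScenarioSpec(
            "hip-only first-year excess mortality",
            overrides=[
                ("mortality_modifier.excess_duration_years.hip", 1.0),
                ("mortality_modifier.excess_duration_years.vertebral", 0.0),
                ("mortality_modifier.excess_duration_years.other", 0.0),
            ],
        ),
        ScenarioSpec(
            "alternative disutilities (stand-in)",
            overrides=[
                ("utility_multipliers.first_year", dict(TARRIDE_STANDIN_MULTIPLIERS["first_year"])),
                (
                    "utility_multipliers.subsequent_years",
                    dict(TARRIDE_STANDIN_MULTIPLIERS["subsequent_years"]),
                ),
            ],
        ),
        ScenarioSpec(
            "risedronate at Actonel DR price", transform=_risedronate_price_transform
        ),
    ]
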