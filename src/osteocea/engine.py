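"""Markov cohort engine: seven health states with year-since-event tunnels,
a severity hierarchy (hip > vertebral > other), corrected counting of
lower-hierarchy fractures, and a microsimulation oracle.

Expanded state space (38 states).  Acute fracture states last 1 year
(2 cycles); hip and vertebral carry an 8-year tunnel (16 cycles) so mortality
can depend on years since the event, followed by a "late" post state with no
excess mortality; "other" lasts 1 year and returns to at-risk.  Occupancy can
only move toward equal-or-higher severity: hip-family states admit hip
re-fracture only, vertebral-family states admit hip or vertebral, the
at-risk and other states admit all three.  Fractures of lower severity that
the hierarchy cannot represent as occupancy are counted separately by
multiplying higher-state occupancy with the lower type's incidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import FRACTURE_TYPES, ModelConfig, RegimenSpec
from .efficacy import offset_rr
from .epidemiology import (
    adjust_baseline_risk,
    annual_prob_to_rate,
    attributable_rr,
    interpolate_age_rate,
)

CYCLE_YEARS = 0.5
N_TUNNEL = 16  # 8 years of half-year layers in hip/vertebral states

AT_RISK = 0
HIP_FIRST = 1
HIP_LATE = HIP_FIRST + N_TUNNEL  # 17
VERT_FIRST = HIP_LATE + 1  # 18
VERT_LATE = VERT_FIRST + N_TUNNEL  # 34
OTHER_1 = VERT_LATE + 1  # 35
OTHER_2 = OTHER_1 + 1  # 36
DEAD = OTHER_2 + 1  # 37
N_STATES = DEAD + 1

HIP_STATES = np.arange(HIP_FIRST, HIP_LATE + 1)
VERT_STATES = np.arange(VERT_FIRST, VERT_LATE + 1)
OTHER_STATES = np.array([OTHER_1, OTHER_2])
ALIVE = np.arange(N_STATES - 1)

HIP_ACUTE = np.array([HIP_FIRST, HIP_FIRST + 1])  # first year after hip fracture
HIP_POST = np.arange(HIP_FIRST + 2, HIP_LATE + 1)  # second and later years
VERT_ACUTE = np.array([VERT_FIRST, VERT_FIRST + 1])
VERT_POST = np.arange(VERT_FIRST + 2, VERT_LATE + 1)

#: the seven reporting states, as aggregations of the expanded space
SEVEN_STATES = {
    "at_risk": np.array([AT_RISK]),
    "hip": HIP_ACUTE,
    "post_hip": HIP_POST,
    "vertebral": VERT_ACUTE,
    "post_vertebral": VERT_POST,
    "other": OTHER_STATES,
    "dead": np.array([DEAD]),
}

# which fracture exits each state admits (severity hierarchy)
ALLOWED_HIP = np.zeros(N_STATES)
ALLOWED_HIP[ALIVE] = 1.0
ALLOWED_VERT = np.zeros(N_STATES)
ALLOWED_VERT[[AT_RISK, OTHER_1, OTHER_2]] = 1.0
ALLOWED_VERT[VERT_STATES] = 1.0
ALLOWED_OTHER = np.zeros(N_STATES)
ALLOWED_OTHER[[AT_RISK, OTHER_1, OTHER_2]] = 1.0

# residual (no event, no death) destination: tunnel aging
ADVANCE = np.arange(N_STATES)
ADVANCE[HIP_FIRST : HIP_LATE + 1] = np.arange(HIP_FIRST + 1, HIP_LATE + 2).clip(
    max=HIP_LATE
)
ADVANCE[VERT_FIRST : VERT_LATE + 1] = np.arange(VERT_FIRST + 1, VERT_LATE + 2).clip(
    max=VERT_LATE
)
ADVANCE[OTHER_1] = OTHER_2
ADVANCE[OTHER_2] = AT_RISK
ADVANCE[DEAD] = DEAD


def treatment_rr(
    config: ModelConfig, regimen: RegimenSpec, cycle: int
) -> dict[str, float]:
    """Effective RR versus placebo at 1-based cycle, including linear waning
    of the risk reduction after the treatment period."""
    sched = config.rr_schedule_vs_placebo(regimen)
    d = regimen.treatment_duration_cycles
    out = {}
    for ft in FRACTURE_TYPES:
        if cycle <= d:
            out[ft] = float(sched[ft][cycle - 1])
        else:
            t_since_stop = (cycle - d - 1) * CYCLE_YEARS
            out[ft] = offset_rr(
                float(sched[ft][d - 1]), t_since_stop, regimen.offset_duration_years
            )
    return out


def cycle_exit_probs(
    fracture_rates: dict[str, float], death_rates: np.ndarray
) -> dict[str, np.ndarray]:
    """Per-state per-cycle exit probabilities from annual rates.

    Competing risks are resolved on the rate scale: the total exit
    probability is 1 - exp(-0.5 * total rate), apportioned proportionally to
    each cause's rate.
    """
    r_hip = fracture_rates["hip"] * ALLOWED_HIP
    r_vert = fracture_rates["vertebral"] * ALLOWED_VERT
    r_oth = fracture_rates["other"] * ALLOWED_OTHER
    m = np.asarray(death_rates, float)
    total = r_hip + r_vert + r_oth + m
    with np.errstate(divide="ignore", invalid="ignore"):
        p_total = -np.expm1(-total * CYCLE_YEARS)
        frac = np.where(total > 0, p_total / np.where(total > 0, total, 1.0), 0.0)
    return {
        "hip": r_hip * frac,
        "vertebral": r_vert * frac,
        "other": r_oth * frac,
        "death": m * frac,
    }


def build_matrix(exit_probs: dict[str, np.ndarray]) -> np.ndarray:
    """Assemble the expanded-state transition matrix from per-state exit
    probabilities; the residual follows the tunnel-aging map."""
    p_hip = np.asarray(exit_probs["hip"], float)
    p_vert = np.asarray(exit_probs["vertebral"], float)
    p_oth = np.asarray(exit_probs["other"], float)
    p_death = np.asarray(exit_probs["death"], float)
    exits = p_hip + p_vert + p_oth + p_death
    if np.any(exits > 1.0 + 1e-12):
        raise ValueError(
            "competing exit probabilities exceed 1 in at least one state "
            "(mis-scaled rates?)"
        )
    M = np.zeros((N_STATES, N_STATES))
    idx = np.arange(N_STATES)
    np.add.at(M, (idx, np.full(N_STATES, HIP_FIRST)), p_hip)
    np.add.at(M, (idx, np.full(N_STATES, VERT_FIRST)), p_vert)
    np.add.at(M, (idx, np.full(N_STATES, OTHER_1)), p_oth)
    np.add.at(M, (idx, np.full(N_STATES, DEAD)), p_death)
    np.add.at(M, (idx, ADVANCE), 1.0 - exits)
    M[DEAD, :] = 0.0
    M[DEAD, DEAD] = 1.0
    return M


@dataclass
class CohortTrace:
    """Per-cycle occupancy (per 1000) of the expanded state space."""

    ages: np.ndarray  # start-of-cycle age, length n_cycles
    occupancy: np.ndarray  # (n_cycles + 1, N_STATES); row 0 = baseline
    #: standalone per-cycle fracture probabilities of the treated cohort
    #: (used for the hierarchy correction), shape (n_cycles, 3)
    fracture_probs: np.ndarray
    regimen: str = ""

    @property
    def n_cycles(self) -> int:
        return len(self.ages)

    @property
    def alive(self) -> np.ndarray:
        return self.occupancy[:, ALIVE].sum(axis=1)

    def seven_state_occupancy(self) -> pd.DataFrame:
        data = {
            name: self.occupancy[:, cols].sum(axis=1)
            for name, cols in SEVEN_STATES.items()
        }
        return pd.DataFrame(data)

    def to_frame(self) -> pd.DataFrame:
        df = self.seven_state_occupancy().iloc[1:].reset_index(drop=True)
        df.insert(0, "age", self.ages)
        df.insert(0, "cycle", np.arange(1, self.n_cycles + 1))
        return df


@dataclass
class FractureLedger:
    """Per-cycle fracture events per 1000, by type: direct transitions plus
    corrected lower-hierarchy additions."""

    direct: np.ndarray  # (n_cycles, 3) ordered as FRACTURE_TYPES
    corrected: np.ndarray  # (n_cycles, 3)

    @property
    def per_cycle(self) -> np.ndarray:
        return self.direct + self.corrected

    def totals(self) -> dict[str, float]:
        tot = self.per_cycle.sum(axis=0)
        out = {ft: float(tot[i]) for i, ft in enumerate(FRACTURE_TYPES)}
        out["total"] = float(tot.sum())
        return out

    def to_frame(self) -> pd.DataFrame:
        cols = {}
        for i, ft in enumerate(FRACTURE_TYPES):
            cols[f"{ft}_direct"] = self.direct[:, i]
            cols[f"{ft}_corrected"] = self.corrected[:, i]
        df = pd.DataFrame(cols)
        df.insert(0, "cycle", np.arange(1, len(df) + 1))
        return df


def correct_hierarchy(trace: CohortTrace) -> np.ndarray:
    """Lower-hierarchy fracture additions per cycle.

    Hip-family occupants contribute vertebral and other events, vertebral-
    family occupants contribute other events, at the treated cohort's
    standalone per-cycle incidence; additions never alter occupancy.
    """
    occ = trace.occupancy[:-1]  # start-of-cycle occupancy per cycle
    hip_occ = occ[:, HIP_STATES].sum(axis=1)
    vert_occ = occ[:, VERT_STATES].sum(axis=1)
    q = trace.fracture_probs  # columns: hip, vertebral, other
    additions = np.zeros((trace.n_cycles, 3))
    additions[:, 1] = hip_occ * q[:, 1]
    additions[:, 2] = hip_occ * q[:, 2] + vert_occ * q[:, 2]
    return additions


class _CyclePlan:
    """Precomputed per-cycle rates for one (config, regimen) pair."""

    def __init__(self, config: ModelConfig, regimen: RegimenSpec):
        self.config = config
        self.regimen = regimen
        econ = config.econ
        age0 = config.population.mean_age
        n_main = max(int(np.ceil((econ.max_age - age0) / CYCLE_YEARS)), 1)
        n_max = max(int(np.ceil((econ.closeout_max_age - age0) / CYCLE_YEARS)), n_main)
        self.n_main = n_main
        self.n_max = n_max
        ages = age0 + CYCLE_YEARS * np.arange(n_max)
        self.ages = ages

        adj = config.risk_adjustment
        self.frac_rates = np.zeros((n_max, 3))
        for i, ft in enumerate(FRACTURE_TYPES):
            gen = interpolate_age_rate(config.epi.fracture_incidence[ft], ages)
            base = adjust_baseline_risk(gen, adj, ft)
            rr = np.array(
                [treatment_rr(config, regimen, j)[ft] for j in range(1, n_max + 1)]
            )
            rate = base * rr
            rate[n_main:] = 0.0  # close-out past max_age: mortality only
            self.frac_rates[:, i] = rate

        base_q = np.clip(interpolate_age_rate(config.epi.mortality, ages), 0.0, 1.0)
        m_base = annual_prob_to_rate(base_q)
        mod = config.mortality_modifier
        f = mod.attributable_fraction
        rr_t = config.epi.mortality_rr_post_fracture

        def band_rate(ft: str, band: str) -> np.ndarray:
            tbl = rr_t[ft]
            at = tbl.first_year if band == "first" else tbl.subsequent_years
            if at is None:
                return m_base.copy()
            rr = interpolate_age_rate(at, ages)
            return m_base * attributable_rr(rr, f)

        # per-cycle death rates for the 38 states
        self.death_rates = np.zeros((n_max, N_STATES))
        self.death_rates[:, AT_RISK] = m_base
        dur_hip = int(round(mod.excess_duration_years["hip"] / CYCLE_YEARS))
        dur_vert = int(round(mod.excess_duration_years["vertebral"] / CYCLE_YEARS))
        hip1, hip2 = band_rate("hip", "first"), band_rate("hip", "subsequent")
        vert1, vert2 = band_rate("vertebral", "first"), band_rate("vertebral", "subsequent")
        oth1 = band_rate("other", "first")
        for c in range(1, N_TUNNEL + 1):  # tunnel layer c = cycles since event
            year = (c + 1) // 2  # 1 for layers 1-2, 2 for 3-4, ...
            s_hip = HIP_FIRST + c - 1
            s_vert = VERT_FIRST + c - 1
            if c <= dur_hip:
                self.death_rates[:, s_hip] = hip1 if year == 1 else hip2
            else:
                self.death_rates[:, s_hip] = m_base
            if c <= dur_vert:
                self.death_rates[:, s_vert] = vert1 if year == 1 else vert2
            else:
                self.death_rates[:, s_vert] = m_base
        self.death_rates[:, HIP_LATE] = m_base
        self.death_rates[:, VERT_LATE] = m_base
        dur_oth = int(round(mod.excess_duration_years["other"] / CYCLE_YEARS))
        self.death_rates[:, OTHER_1] = oth1 if dur_oth >= 1 else m_base
        self.death_rates[:, OTHER_2] = oth1 if dur_oth >= 2 else m_base
        self.death_rates[:, DEAD] = 0.0
        self.m_base = m_base

    def exit_probs(self, j: int) -> dict[str, np.ndarray]:
        """Exit probabilities for 0-based cycle index j."""
        rates = {ft: self.frac_rates[j, i] for i, ft in enumerate(FRACTURE_TYPES)}
        death = self.death_rates[j].copy()
        if self.config.corrected_events_affect_mortality:
            # expected extra hazard from corrected lower-hierarchy events
            # (documented approximation; off in the reference case)
            f = self.config.mortality_modifier.attributable_fraction
            rr_t = self.config.epi.mortality_rr_post_fracture
            age = self.ages[j]
            for ft, allowed in (("vertebral", ALLOWED_VERT), ("other", ALLOWED_OTHER)):
                rr1 = interpolate_age_rate(rr_t[ft].first_year, age)
                q = -np.expm1(-rates[ft] * CYCLE_YEARS)
                extra = q * self.m_base[j] * (attributable_rr(rr1, f) - 1.0)
                death[ALIVE] += extra * (1.0 - allowed[ALIVE])
        return cycle_exit_probs(rates, death)


def run_trace(
    config: ModelConfig, regimen: RegimenSpec, cohort_size: float = 1000.0
) -> tuple[CohortTrace, FractureLedger]:
    """Run the cohort from baseline age to the lifetime horizon.

    The cohort starts at-risk; after ``econ.max_age`` the run closes out under
    mortality alone until living occupancy falls below 1e-6 per 1000 or the
    close-out age cap is reached.
    """
    plan = _CyclePlan(config, regimen)
    occ = np.zeros(N_STATES)
    occ[AT_RISK] = cohort_size
    occ_hist = [occ.copy()]
    direct = []
    probs = []
    n_run = 0
    for j in range(plan.n_max):
        if j >= plan.n_main and occ[ALIVE].sum() < 1e-6:
            break
        ep = plan.exit_probs(j)
        M = build_matrix(ep)
        direct.append(
            [
                float(occ @ ep["hip"]),
                float(occ @ ep["vertebral"]),
                float(occ @ ep["other"]),
            ]
        )
        probs.append(-np.expm1(-plan.frac_rates[j] * CYCLE_YEARS))
        occ = occ @ M
        occ_hist.append(occ.copy())
        n_run += 1
    trace = CohortTrace(
        ages=plan.ages[:n_run],
        occupancy=np.asarray(occ_hist),
        fracture_probs=np.asarray(probs),
        regimen=regimen.name,
    )
    corrected = correct_hierarchy(trace)
    ledger = FractureLedger(direct=np.asarray(direct), corrected=corrected)
    return trace, ledger


def microsim_oracle(
    config: ModelConfig,
    regimen: RegimenSpec,
    n_individuals: int,
    seed: int,
    cohort_size: float = 1000.0,
) -> tuple[CohortTrace, FractureLedger]:
    """Individual-level simulation with the same per-cycle transition
    probabilities as the cohort trace; a Monte-Carlo validation oracle."""
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    rng = np.random.default_rng(seed)
    plan = _CyclePlan(config, regimen)
    states = np.zeros(n_individuals, dtype=np.int64)
    scale = cohort_size / n_individuals
    occ_hist = [np.bincount(states, minlength=N_STATES) * scale]
    direct = []
    corrected = []
    probs = []
    n_run = 0
    for j in range(plan.n_max):
        alive_mask = states != DEAD
        if j >= plan.n_main and not alive_mask.any():
            break
        ep = plan.exit_probs(j)
        M = build_matrix(ep)
        cum = np.cumsum(M, axis=1)
        new_states = states.copy()
        for s in np.unique(states):
            if s == DEAD:
                continue
            mask = states == s
            u = rng.random(mask.sum())
            new_states[mask] = np.searchsorted(cum[s], u, side="right")
        ev = [
            float(np.sum((new_states == HIP_FIRST) & (states != DEAD)) * scale),
            float(np.sum((new_states == VERT_FIRST) & (states != DEAD)) * scale),
            float(np.sum((new_states == OTHER_1) & (states != DEAD)) * scale),
        ]
        q = -np.expm1(-plan.frac_rates[j] * CYCLE_YEARS)
        in_hip = np.isin(states, HIP_STATES)
        in_vert = np.isin(states, VERT_STATES)
        corr_vert = float(np.sum(rng.random(in_hip.sum()) < q[1]) * scale)
        corr_oth = float(
            np.sum(rng.random(in_hip.sum() + in_vert.sum()) < q[2]) * scale
        )
        direct.append(ev)
        corrected.append([0.0, corr_vert, corr_oth])
        probs.append(q)
        states = new_states
        occ_hist.append(np.bincount(states, minlength=N_STATES) * scale)
        n_run += 1
    trace = CohortTrace(
        ages=plan.ages[:n_run],
        occupancy=np.asarray(occ_hist, dtype=float),
        fracture_probs=np.asarray(probs),
        regimen=regimen.name,
    )
    ledger = FractureLedger(direct=np.asarray(direct), corrected=np.asarray(corrected))
    return trace, ledger
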