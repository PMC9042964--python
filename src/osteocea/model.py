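"""Model/Results interface over the cohort engine.

``MarkovCohortModel`` is built from a validated :class:`ModelConfig`;
``fit()`` runs the deterministic model (or the probabilistic model with
``method="psa"``) and returns a results object carrying per-regimen costs,
QALYs and fracture counts, incremental comparisons, and a ``summary()``
table shaped like a standard cost-utility results table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import FRACTURE_TYPES, ModelConfig, RegimenSpec, load_config
from .engine import CohortTrace, FractureLedger, run_trace
from .outcomes import AccrualResult, compare, pairwise, valuate
from .uncertainty import (
    DSAParameter,
    PSAResult,
    ScenarioSpec,
    reference_scenarios,
    run_dsa,
    run_psa,
)


class MarkovCohortModel:
    """Lifetime Markov cohort cost-utility model for osteoporosis treatment
    sequences in postmenopausal women at very high fracture risk.

    Parameters
    ----------
    config
        Fully validated model configuration (population, regimens, efficacy
        anchors, epidemiology tables, costs, utilities, economic settings).

    Examples
    --------
    >>> from osteocea import MarkovCohortModel
    >>> model = MarkovCohortModel.reference_case()
    >>> res = model.fit()
    >>> print(res.summary())  # doctest: +SKIP
    """

    def __init__(self, config: ModelConfig):
        self.config = config

    @classmethod
    def from_config(cls, path) -> "MarkovCohortModel":
        return cls(load_config(path))

    @classmethod
    def reference_case(cls, **kwargs) -> "MarkovCohortModel":
        from .synthetic import make_reference_fixture

        return cls(make_reference_fixture(**kwargs))

    @property
    def regimen_names(self) -> list[str]:
        return [r.name for r in self.config.regimens]

    # -- single runs -------------------------------------------------------

    def run_regimen(
        self, regimen: str | RegimenSpec, config: Optional[ModelConfig] = None
    ) -> tuple[CohortTrace, FractureLedger, AccrualResult]:
        cfg = config or self.config
        spec = cfg.regimen(regimen) if isinstance(regimen, str) else regimen
        trace, ledger = run_trace(cfg, spec)
        return trace, ledger, valuate(trace, ledger, cfg, spec)

    def _run_all(self, config: Optional[ModelConfig] = None) -> dict[str, AccrualResult]:
        cfg = config or self.config
        return {r.name: self.run_regimen(r, cfg)[2] for r in cfg.regimens}

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        method: str = "deterministic",
        n_iterations: int = 5000,
        seed: Optional[int] = None,
    ) -> "CEAResults":
        """Run the model.

        ``method="deterministic"`` evaluates every regimen at the point
        estimates; ``method="psa"`` additionally runs the probabilistic
        model (``n_iterations`` joint parameter draws) and reports
        probabilistic means as the headline estimates.
        """
        accruals = self._run_all()
        if method == "deterministic":
            return CEAResults(model=self, accruals=accruals)
        if method == "psa":
            def run_one(cfg: ModelConfig):
                res = self._run_all(cfg)
                names = [r.name for r in cfg.regimens]
                return (
                    np.array([res[n].cost for n in names]),
                    np.array([res[n].qalys for n in names]),
                    np.array([res[n].fracture_totals["total"] for n in names]),
                )

            psa = run_psa(
                run_one,
                self.config,
                self.regimen_names,
                n_iterations=n_iterations,
                seed=seed,
            )
            return PSAResults(model=self, accruals=accruals, psa=psa)
        raise ValueError(f"unknown method {method!r}")

    # -- sensitivity and scenarios ----------------------------------------

    def run_dsa(
        self,
        parameters: Optional[Sequence[DSAParameter]] = None,
        intervention: Optional[str] = None,
        comparator: Optional[str] = None,
        wtp: Optional[float] = None,
    ) -> pd.DataFrame:
        """One-way deterministic sensitivity (INMB tornado)."""
        names = self.regimen_names
        intervention = intervention or names[0]
        comparator = comparator or names[1]
        wtp = wtp if wtp is not None else self.config.econ.wtp_reference

        def run_pair(cfg: ModelConfig) -> tuple[float, float]:
            res = self._run_all(cfg)
            return (
                res[intervention].cost - res[comparator].cost,
                res[intervention].qalys - res[comparator].qalys,
            )

        return run_dsa(run_pair, self.config, parameters, wtp=wtp)

    def run_scenarios(
        self,
        scenarios: Optional[Sequence[ScenarioSpec]] = None,
        probabilistic: bool = False,
        n_iterations: int = 5000,
        seed: Optional[int] = None,
    ) -> pd.DataFrame:
        """Run named scenarios; report incremental results of the first-listed
        regimen against every comparator."""
        scenarios = list(scenarios or reference_scenarios())
        if len({s.name for s in scenarios}) != len(scenarios):
            raise ValueError("scenario names must be unique")
        rows = []
        for sc in scenarios:
            cfg = sc.apply(self.config)
            sub = MarkovCohortModel(cfg)
            res = sub.fit(
                method="psa" if probabilistic else "deterministic",
                n_iterations=n_iterations,
                seed=seed,
            )
            names = sub.regimen_names
            for comp in names[1:]:
                pw = res.pairwise(names[0], comp)
                rows.append(
                    {
                        "scenario": sc.name,
                        "intervention": names[0],
                        "comparator": comp,
                        "delta_cost": pw["delta_cost"],
                        "delta_qalys": pw["delta_qalys"],
                        "icur": pw["icur"],
                        "label": pw["label"],
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class CEAResults:
    """Deterministic cost-utility results for every regimen."""

    model: MarkovCohortModel
    accruals: dict[str, AccrualResult]

    @property
    def config(self) -> ModelConfig:
        return self.model.config

    def _point(self, name: str) -> tuple[float, float]:
        a = self.accruals[name]
        return a.cost, a.qalys

    def pairwise(self, intervention: str, comparator: str, wtp: Optional[float] = None):
        wtp = wtp if wtp is not None else self.config.econ.wtp_reference
        return pairwise(self.accruals[intervention], self.accruals[comparator], wtp)

    def incremental(self, wtp: Optional[float] = None) -> pd.DataFrame:
        wtp = wtp if wtp is not None else self.config.econ.wtp_reference
        return compare(list(self.accruals.values()), wtp=wtp)

    def table(self) -> pd.DataFrame:
        """Disaggregated per-regimen results (per person unless noted)."""
        rows = {}
        names = list(self.accruals)
        for name in names:
            a = self.accruals[name]
            td, tu = a.totals_discounted, a.totals
            ft = a.fracture_totals
            rows[name] = {
                "hip fractures per 1000": ft["hip"],
                "vertebral fractures per 1000": ft["vertebral"],
                "other fractures per 1000": ft["other"],
                "total fractures per 1000": ft["total"],
                "hip fracture cost": td["fracture_first_year_hip"]
                + td["fracture_subsequent_hip"]
                + td["ltc"],
                "vertebral fracture cost": td["fracture_first_year_vertebral"]
                + td["fracture_subsequent_vertebral"],
                "other fracture cost": td["fracture_first_year_other"],
                "total fracture cost": td["fracture_cost"] + td["ltc"],
                "drug cost": td["drug"],
                "monitoring cost": td["monitoring"],
                "societal cost": td["societal"],
                "total cost (undiscounted)": tu["total_cost"],
                "total cost (discounted)": td["total_cost"],
                "life years (undiscounted)": tu["life_years"],
                "life years (discounted)": td["life_years"],
                "QALYs (undiscounted)": tu["qalys"],
                "QALYs (discounted)": td["qalys"],
            }
        df = pd.DataFrame(rows)
        base = names[0]
        for comp in names[1:]:
            df[f"incr. vs {comp}"] = df[base] - df[comp]
        return df

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Markov cohort cost-utility model - deterministic results",
            f"population: women, mean age {cfg.population.mean_age:.0f}, "
            f"T-score <= {cfg.population.t_score}, prior fragility fracture",
            f"perspective: {cfg.econ.perspective}; discount "
            f"{cfg.econ.discount_rate_costs:.1%} (costs) / "
            f"{cfg.econ.discount_rate_qalys:.1%} (QALYs)",
            "",
            self.table().round(3).to_string(),
            "",
            "Fully incremental comparison (discounted):",
            self.incremental().round(4).to_string(index=False),
        ]
        if cfg.standin_inputs:
            lines += [
                "",
                "NOTE: computed with synthetic stand-in inputs for: "
                + ", ".join(cfg.standin_inputs)
                + ". Absolute results are not reproductions of any published table.",
            ]
        return "\n".join(lines)


@dataclass
class PSAResults(CEAResults):
    """Probabilistic results: headline values are probabilistic means."""

    psa: PSAResult = None

    def _mean(self, name: str) -> tuple[float, float]:
        j = self.psa.regimens.index(name)
        return float(self.psa.costs[:, j].mean()), float(self.psa.qalys[:, j].mean())

    def pairwise(self, intervention: str, comparator: str, wtp: Optional[float] = None):
        wtp = wtp if wtp is not None else self.config.econ.wtp_reference
        ci, qi = self._mean(intervention)
        cc, qc = self._mean(comparator)
        dc, dq = ci - cc, qi - qc
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
            "intervention": intervention,
            "comparator": comparator,
            "delta_cost": dc,
            "delta_qalys": dq,
            "icur": icur,
            "label": label,
            "inmb": wtp * dq - dc,
        }

    def ceac(self) -> pd.DataFrame:
        return self.psa.ceac()

    def summary(self) -> str:
        base = super().summary().replace(
            "deterministic results",
            f"probabilistic results ({self.psa.n_iterations} iterations, "
            f"seed {self.psa.seed})",
        )
        lam = self.config.econ.wtp_reference
        names = self.psa.regimens
        probs = ", ".join(
            f"{n}: {self.psa.ceac_at(lam, n):.1%}" for n in names
        )
        extra = [
            "",
            "Probabilistic means:",
            self.psa.means().round(4).to_string(index=False),
            "",
            f"Probability cost-effective at ${lam:,.0f}/QALY: {probs}",
        ]
        return base + "\n" + "\n".join(extra)
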