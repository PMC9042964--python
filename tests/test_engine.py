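"""Cohort engine: transition-matrix structure, mass conservation, the
fracture hierarchy and its correction, degenerate limits, and determinism."""

import numpy as np
import pytest

from osteocea.engine import (
    ALIVE,
    AT_RISK,
    DEAD,
    HIP_FIRST,
    HIP_STATES,
    N_STATES,
    OTHER_1,
    VERT_FIRST,
    VERT_STATES,
    CohortTrace,
    FractureLedger,
    build_matrix,
    correct_hierarchy,
    cycle_exit_probs,
    microsim_oracle,
    run_trace,
    treatment_rr,
)
from osteocea.epidemiology import annual_prob_to_rate, interpolate_age_rate, rate_to_cycle_prob


def _probs(p_hip=0.0, p_vert=0.0, p_oth=0.0, p_death=0.0):
    z = np.zeros(N_STATES)
    out = {"hip": z.copy(), "vertebral": z.copy(), "other": z.copy(), "death": z.copy()}
    out["hip"][AT_RISK] = p_hip
    out["vertebral"][AT_RISK] = p_vert
    out["other"][AT_RISK] = p_oth
    out["death"][ALIVE] = p_death
    return out


class TestBuildMatrix:
    def test_at_risk_row_construction(self):
        M = build_matrix(_probs(p_hip=0.02, p_death=0.01))
        assert M[AT_RISK, HIP_FIRST] == pytest.approx(0.02)
        assert M[AT_RISK, DEAD] == pytest.approx(0.01)
        assert M[AT_RISK, AT_RISK] == pytest.approx(0.97)

    def test_rows_sum_to_one(self):
        M = build_matrix(_probs(p_hip=0.02, p_vert=0.01, p_oth=0.05, p_death=0.03))
        assert np.allclose(M.sum(axis=1), 1.0, atol=1e-12)

    def test_death_absorbs_whole_cohort(self):
        M = build_matrix(_probs(p_death=1.0))
        occ = np.zeros(N_STATES)
        occ[AT_RISK] = 600
        occ[HIP_FIRST] = 400
        new = occ @ M
        assert new[DEAD] == pytest.approx(1000.0)
        assert new[ALIVE].sum() == pytest.approx(0.0)

    def test_zero_rates_only_tunnel_aging(self):
        M = build_matrix(_probs())
        # at-risk and dead are fixed points; tunnel layers advance
        assert M[AT_RISK, AT_RISK] == 1.0
        assert M[DEAD, DEAD] == 1.0
        assert M[HIP_FIRST, HIP_FIRST + 1] == 1.0

    def test_exit_probabilities_above_one_rejected(self):
        bad = _probs(p_hip=0.7, p_death=0.6)
        with pytest.raises(ValueError, match="exceed 1"):
            build_matrix(bad)

    def test_hierarchy_structural_zeros(self, reference_model):
        from osteocea.engine import _CyclePlan

        cfg = reference_model.config
        plan = _CyclePlan(cfg, cfg.regimens[0])
        for j in (0, 5, 30):
            M = build_matrix(plan.exit_probs(j))
            # hip-family occupancy never flows to vertebral or other states
            assert np.all(M[np.ix_(HIP_STATES, VERT_STATES)] == 0.0)
            assert np.all(M[HIP_STATES, OTHER_1] == 0.0)
            # vertebral-family occupancy never flows to the other state
            assert np.all(M[VERT_STATES, OTHER_1] == 0.0)


class TestCompetingRisks:
    def test_total_exit_from_summed_rates(self):
        rates = {"hip": 0.1, "vertebral": 0.2, "other": 0.3}
        death = np.zeros(N_STATES)
        death[ALIVE] = annual_prob_to_rate(0.05)
        ep = cycle_exit_probs(rates, death)
        total_rate = 0.6 + annual_prob_to_rate(0.05)
        p_total = -np.expm1(-total_rate * 0.5)
        got = sum(ep[k][AT_RISK] for k in ep)
        assert got == pytest.approx(p_total, rel=1e-12)
        # proportional apportionment
        assert ep["hip"][AT_RISK] / got == pytest.approx(0.1 / total_rate, rel=1e-12)


class TestRunTrace:
    def test_mass_conservation_every_cycle(self, reference_run):
        for name, (trace, ledger, _) in reference_run.items():
            total = trace.occupancy.sum(axis=1)
            assert np.allclose(total, 1000.0, atol=1e-9), name
            assert np.all(trace.occupancy >= -1e-12), name

    def test_cumulative_dead_monotone(self, reference_run):
        for name, (trace, _, _) in reference_run.items():
            dead = trace.occupancy[:, DEAD]
            assert np.all(np.diff(dead) >= -1e-12), name

    def test_zero_fracture_rates_reduce_to_life_table(self, reference_config):
        cfg = reference_config.model_copy(deep=True)
        for tbl in cfg.epi.fracture_incidence.values():
            tbl.values = [0.0] * len(tbl.values)
        trace, ledger = run_trace(cfg, cfg.regimens[0])
        assert ledger.totals()["total"] == 0.0
        # independent life-table survival product at the same ages
        expected = [1000.0]
        for age in trace.ages:
            q = np.clip(interpolate_age_rate(cfg.epi.mortality, age), 0, 1)
            p = rate_to_cycle_prob(annual_prob_to_rate(q))
            expected.append(expected[-1] * (1 - p))
        assert np.allclose(trace.alive, expected, atol=1e-9)

    def test_small_rate_linearisation(self, reference_config):
        cfg1 = reference_config.model_copy(deep=True)
        cfg2 = reference_config.model_copy(deep=True)
        for cfg, f in ((cfg1, 1e-3), (cfg2, 2e-3)):
            for tbl in cfg.epi.fracture_incidence.values():
                tbl.values = [v * f for v in tbl.values]
        t1 = run_trace(cfg1, cfg1.regimens[0])[1].totals()["total"]
        t2 = run_trace(cfg2, cfg2.regimens[0])[1].totals()["total"]
        assert t2 / t1 == pytest.approx(2.0, rel=0.01)

    def test_offset_rrs_applied_after_treatment(self, reference_config):
        cfg = reference_config
        seq = cfg.regimen("romosozumab/alendronate")
        sched = cfg.rr_schedule_vs_placebo(seq)
        rr_end = sched["hip"][-1]
        assert treatment_rr(cfg, seq, 10)["hip"] == pytest.approx(rr_end)
        assert treatment_rr(cfg, seq, 11)["hip"] == pytest.approx(rr_end)  # t=0
        # fully waned once a full offset period has elapsed
        assert treatment_rr(cfg, seq, 21)["hip"] == pytest.approx(1.0)
        mid = treatment_rr(cfg, seq, 16)["hip"]
        assert rr_end < mid < 1.0


class TestHierarchyCorrection:
    def test_worked_example(self):
        # 100 persons in a post-hip layer, vertebral cycle prob 0.02
        occ = np.zeros((2, N_STATES))
        occ[0, HIP_FIRST + 4] = 100.0
        trace = CohortTrace(
            ages=np.array([80.0]),
            occupancy=occ,
            fracture_probs=np.array([[0.05, 0.02, 0.01]]),
        )
        add = correct_hierarchy(trace)
        assert add[0, 1] == pytest.approx(2.0)  # vertebral additions
        assert add[0, 2] == pytest.approx(1.0)  # other additions
        assert add[0, 0] == 0.0  # hip is never undercounted

    def test_zero_higher_occupancy_zero_additions(self):
        occ = np.zeros((2, N_STATES))
        occ[0, AT_RISK] = 1000.0
        trace = CohortTrace(
            ages=np.array([80.0]),
            occupancy=occ,
            fracture_probs=np.array([[0.05, 0.02, 0.01]]),
        )
        assert np.all(correct_hierarchy(trace) == 0.0)

    def test_additions_do_not_alter_occupancy(self, reference_run):
        trace, ledger, _ = reference_run["alendronate"]
        # occupancy totals already conserved; corrected events are extra
        assert np.all(ledger.corrected >= 0)
        assert np.allclose(trace.occupancy.sum(axis=1), 1000.0, atol=1e-9)
        assert ledger.totals()["total"] == pytest.approx(
            ledger.per_cycle.sum(), rel=1e-12
        )


class TestMicrosim:
    def test_same_seed_identical(self, reference_model):
        cfg = reference_model.config
        a = microsim_oracle(cfg, cfg.regimens[0], 500, seed=3)
        b = microsim_oracle(cfg, cfg.regimens[0], 500, seed=3)
        assert np.array_equal(a[0].occupancy, b[0].occupancy)
        assert np.array_equal(a[1].direct, b[1].direct)

    def test_single_individual_walks_a_legal_path(self, reference_model):
        cfg = reference_model.config
        trace, _ = microsim_oracle(cfg, cfg.regimens[0], 1, seed=1)
        occ = trace.occupancy
        # one-hot occupancy every cycle
        assert np.allclose(occ.sum(axis=1), 1000.0)
        assert np.all((occ == 0) | (occ == 1000.0))
        # once dead, stays dead
        dead = occ[:, DEAD] > 0
        assert np.all(dead[np.argmax(dead):]) or not dead.any()

    def test_invalid_n(self, reference_model):
        cfg = reference_model.config
        with pytest.raises(ValueError):
            microsim_oracle(cfg, cfg.regimens[0], 0, seed=1)


def test_trace_and_ledger_exports(reference_run):
    trace, ledger, _ = reference_run["risedronate"]
    df = trace.to_frame()
    assert list(df.columns[:2]) == ["cycle", "age"]
    assert {"at_risk", "dead"} <= set(df.columns)
    lf = ledger.to_frame()
    assert "hip_direct" in lf.columns and "other_corrected" in lf.columns
    assert len(df) == len(lf) == trace.n_cycles
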