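"""PSA sampling distributions, CEAC construction, DSA tornado, and the
scenario runner."""

import numpy as np
import pytest

from osteocea import MarkovCohortModel, reference_scenarios
from osteocea.config import RRWithCI
from osteocea.uncertainty import (
    DSAParameter,
    ScenarioSpec,
    draw_beta,
    draw_gamma,
    get_param,
    lognormal_sigma_from_ci,
    sample_params,
    set_param,
)


class TestDistributions:
    def test_lognormal_sigma_from_published_ci(self):
        # RR 0.61 (0.42-0.90): log-sd = (ln 0.90 - ln 0.42)/3.92
        assert lognormal_sigma_from_ci(0.42, 0.90) == pytest.approx(0.1944, abs=2e-4)

    def test_lognormal_median_is_point_estimate(self):
        rng = np.random.default_rng(0)
        from osteocea.uncertainty import draw_lognormal_rr

        draws = [
            draw_lognormal_rr(RRWithCI(point=0.61, lower=0.42, upper=0.90), rng, 0.25)
            for _ in range(4000)
        ]
        assert np.median(draws) == pytest.approx(0.61, rel=0.03)

    def test_beta_gamma_match_moments(self):
        rng = np.random.default_rng(1)
        b = [draw_beta(0.37, 0.25, rng) for _ in range(4000)]
        g = [draw_gamma(5171.0, 0.25, rng) for _ in range(4000)]
        assert np.mean(b) == pytest.approx(0.37, rel=0.02)
        assert np.mean(g) == pytest.approx(5171.0, rel=0.02)
        assert np.std(g) == pytest.approx(0.25 * 5171 / 1.96, rel=0.1)
        assert all(0 < x < 1 for x in b)

    def test_zero_spread_degenerates_to_point(self):
        rng = np.random.default_rng(2)
        assert draw_beta(0.0, 0.25, rng) == 0.0
        assert draw_gamma(0.0, 0.25, rng) == 0.0


class TestParameterPaths:
    def test_get_set_roundtrip(self, reference_config):
        cfg = reference_config.model_copy(deep=True)
        assert get_param(cfg, "costs.ltc_daily_cost") == 184.96
        set_param(cfg, "costs.ltc_daily_cost", 200.0)
        assert cfg.costs.ltc_daily_cost == 200.0
        set_param(cfg, "efficacy_anchors.alendronate_vs_placebo.hip.point", 0.5)
        assert cfg.efficacy_anchors["alendronate_vs_placebo"]["hip"].point == 0.5


class TestSampling:
    def test_same_seed_identical_draw(self, reference_config):
        a = sample_params(reference_config, np.random.default_rng(7))
        b = sample_params(reference_config, np.random.default_rng(7))
        assert a.model_dump(mode="json") == b.model_dump(mode="json")

    def test_draws_differ_and_leave_base_untouched(self, reference_config):
        digest = reference_config.digest()
        rng = np.random.default_rng(8)
        a, b = sample_params(reference_config, rng), sample_params(reference_config, rng)
        assert a.model_dump(mode="json") != b.model_dump(mode="json")
        assert reference_config.digest() == digest

    def test_comparator_schedule_stays_unit(self, reference_config):
        draw = sample_params(reference_config, np.random.default_rng(9))
        aln = draw.regimen("alendronate")
        for ft, sched in aln.rr_vs_active.items():
            assert np.allclose(sched, 1.0)


@pytest.fixture(scope="module")
def psa_results(reference_model):
    return reference_model.fit(method="psa", n_iterations=40, seed=123)


@pytest.fixture(scope="module")
def tornado(reference_model):
    params = [
        DSAParameter("LTC daily cost", "costs.ltc_daily_cost", 138.72, 231.20),
        DSAParameter(
            "RR hip, alendronate",
            "efficacy_anchors.alendronate_vs_placebo.hip.point",
            0.42,
            0.90,
        ),
        DSAParameter(
            "societal wage (inactive under payer perspective)",
            "costs.societal.hourly_wage",
            20.0,
            34.0,
        ),
    ]
    return reference_model.run_dsa(parameters=params)


class TestPSA:
    def test_bit_identical_reproducibility(self, reference_model, psa_results):
        again = reference_model.fit(method="psa", n_iterations=40, seed=123)
        assert np.array_equal(psa_results.psa.costs, again.psa.costs)
        assert np.array_equal(psa_results.psa.qalys, again.psa.qalys)

    def test_ceac_partition_of_unity(self, psa_results):
        ceac = psa_results.ceac()
        probs = ceac.drop(columns="wtp").to_numpy()
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-12)
        assert np.all((probs >= 0) & (probs <= 1))
        assert len(ceac) == 201

    def test_ceac_bounded_below_by_simple_dominance_at_zero_wtp(self, psa_results):
        psa = psa_results.psa
        j = psa.regimens.index("romosozumab/alendronate")
        cheapest = np.argmin(psa.costs, axis=1) == j
        assert psa.ceac_at(0.0, "romosozumab/alendronate") >= cheapest.mean() - 1e-12

    def test_small_and_large_psa_agree_within_mc_error(self, reference_model, psa_results):
        big = reference_model.fit(method="psa", n_iterations=160, seed=99)
        m_small = psa_results.psa.qalys.mean(axis=0)
        m_big = big.psa.qalys.mean(axis=0)
        se = psa_results.psa.qalys.std(axis=0) / np.sqrt(psa_results.psa.n_iterations)
        assert np.all(np.abs(m_small - m_big) <= 4 * se + 1e-9)

    def test_degenerate_distributions_give_certain_winner(self, reference_config):
        cfg = reference_config.model_copy(deep=True)
        cfg.uncertainty.default_spread = 1e-9
        for anchor in cfg.efficacy_anchors.values():
            for ft in anchor:
                anchor[ft] = RRWithCI(point=anchor[ft].point)
        model = MarkovCohortModel(cfg)
        res = model.fit(method="psa", n_iterations=10, seed=1)
        # every iteration near-identical: the winner takes CEAC ~ 1 everywhere
        ceac = res.ceac().drop(columns="wtp").to_numpy()
        assert np.allclose(ceac.max(axis=1), 1.0)


class TestDSA:
    def test_base_inmb_matches_deterministic_reference(self, reference_model, tornado):
        det = reference_model.fit()
        pw = det.pairwise("romosozumab/alendronate", "alendronate")
        assert np.allclose(tornado["base_inmb"], pw["inmb"])

    def test_inactive_parameter_has_zero_extent(self, tornado):
        row = tornado.set_index("path").loc["costs.societal.hourly_wage"]
        assert row["extent"] == pytest.approx(0.0, abs=1e-9)

    def test_sorted_by_extent_and_order_invariant(self, reference_model, tornado):
        assert np.all(np.diff(tornado["extent"]) <= 1e-12)
        params = [
            DSAParameter("LTC daily cost", "costs.ltc_daily_cost", 138.72, 231.20),
            DSAParameter(
                "RR hip, alendronate",
                "efficacy_anchors.alendronate_vs_placebo.hip.point",
                0.42,
                0.90,
            ),
        ]
        t1 = reference_model.run_dsa(parameters=params)
        t2 = reference_model.run_dsa(parameters=params[::-1])
        assert t1["parameter"].tolist() == t2["parameter"].tolist()


class TestScenarios:
    def test_empty_scenario_equals_reference(self, reference_model):
        out = reference_model.run_scenarios([ScenarioSpec("reference case")])
        det = reference_model.fit()
        pw = det.pairwise("romosozumab/alendronate", "alendronate")
        row = out[out.comparator == "alendronate"].iloc[0]
        assert row.delta_cost == pytest.approx(pw["delta_cost"])
        assert row.delta_qalys == pytest.approx(pw["delta_qalys"])

    def test_zero_discount_scenario_equalises_discounted_totals(self, reference_model):
        sc = ScenarioSpec(
            "discount 0%",
            overrides=[
                ("econ.discount_rate_costs", 0.0),
                ("econ.discount_rate_qalys", 0.0),
            ],
        )
        cfg = sc.apply(reference_model.config)
        sub = MarkovCohortModel(cfg)
        for name in sub.regimen_names:
            _, _, res = sub.run_regimen(name)
            assert res.totals_discounted["total_cost"] == res.totals["total_cost"]
            assert res.totals_discounted["qalys"] == res.totals["qalys"]

    def test_one_year_offset_strictly_reduces_incremental_qalys(self, reference_model):
        scenarios = [s for s in reference_scenarios() if s.name in ("reference case", "offset 1 year")]
        out = reference_model.run_scenarios(scenarios)
        sub = out[out.comparator == "alendronate"].set_index("scenario")
        assert (
            sub.loc["offset 1 year", "delta_qalys"]
            < sub.loc["reference case", "delta_qalys"]
        )

    def test_duplicate_names_rejected(self, reference_model):
        with pytest.raises(ValueError, match="unique"):
            reference_model.run_scenarios([ScenarioSpec("x"), ScenarioSpec("x")])

    def test_full_battery_runs_deterministically(self, reference_model):
        out = reference_model.run_scenarios()
        assert set(out.scenario) == {s.name for s in reference_scenarios()}
        # the sequence regimen stays dominant or cost-effective in every row
        assert np.all(out.delta_qalys > 0)

    def test_risedronate_price_scenario_raises_risedronate_cost(self, reference_model):
        out = reference_model.run_scenarios(
            [s for s in reference_scenarios() if "Actonel" in s.name or s.name == "reference case"]
        )
        ris = out[out.comparator == "risedronate"].set_index("scenario")
        assert (
            ris.loc["risedronate at Actonel DR price", "delta_cost"]
            < ris.loc["reference case", "delta_cost"]
        )
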