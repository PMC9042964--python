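"""Survival fitting, model selection, per-cycle incidence/RR derivation, and
the treatment-offset decay."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from osteocea.config import SyntheticTrialSpec
from osteocea.efficacy import (
    DEFAULT_FAMILIES,
    FitError,
    SurvivalFit,
    compose_vs_placebo,
    cycle_incidence,
    cycle_rr,
    fit_survival,
    offset_rr,
    schedule_from_trial,
    select_family,
)
from osteocea.synthetic import simulate_trial


def _records(shape, scale, n=20_000, follow_up=5.0, censoring=0.0, seed=5):
    spec = SyntheticTrialSpec(
        n_per_arm=n,
        follow_up_years=follow_up,
        hazard_model={"active": {"hip": (shape, scale)}},
        censoring_rate=censoring,
        seed=seed,
    )
    return simulate_trial(spec)


def _fit(family, **kw):
    return fit_survival(_records(**kw), "hip", "active", family)


class TestFitting:
    def test_exponential_mle_equals_events_over_exposure(self):
        rec = _records(shape=1.0, scale=10.0)
        fit = fit_survival(rec, "hip", "active", "exponential")
        rate_closed_form = rec.event.sum() / rec.time_years.sum()
        assert fit.params["rate"] == pytest.approx(rate_closed_form, rel=1e-5)
        se = rate_closed_form / np.sqrt(rec.event.sum())
        assert abs(fit.params["rate"] - 0.1) <= 3 * se

    def test_weibull_on_shape_one_data_recovers_unit_shape(self):
        fit = _fit("weibull", shape=1.0, scale=10.0)
        assert fit.params["shape"] == pytest.approx(1.0, abs=0.03)

    def test_weibull_matches_lifelines_oracle(self):
        from lifelines import WeibullFitter

        rec = _records(shape=1.4, scale=8.0, n=5000, censoring=0.05)
        fit = fit_survival(rec, "hip", "active", "weibull")
        wf = WeibullFitter().fit(rec.time_years.clip(lower=1e-9), rec.event)
        assert fit.params["scale"] == pytest.approx(wf.lambda_, rel=1e-4)
        assert fit.params["shape"] == pytest.approx(wf.rho_, rel=1e-4)
        assert fit.log_likelihood == pytest.approx(wf.log_likelihood_, rel=1e-8)

    def test_aic_bic_arithmetic(self):
        fit = SurvivalFit(
            family="weibull",
            theta=np.zeros(2),
            params={},
            intercept=0.0,
            scale=1.0,
            log_likelihood=-100.0,
            n_params=2,
            n=50,
            n_events=40,
        )
        assert fit.aic == 204.0  # 2*2 - 2*(-100)
        assert fit.bic == pytest.approx(2 * np.log(50) + 200.0)

    def test_no_events_is_an_error(self):
        rec = _records(shape=1.0, scale=10.0, n=100)
        rec["event"] = False
        with pytest.raises(FitError, match="no events"):
            fit_survival(rec, "hip", "active", "weibull")

    def test_survival_function_starts_at_one_and_decreases(self):
        for family in DEFAULT_FAMILIES:
            fit = _fit(family, shape=1.2, scale=6.0, n=4000, censoring=0.05)
            t = np.linspace(0, 10, 50)
            s = fit.survival(t)
            assert s[0] == pytest.approx(1.0, abs=1e-9), family
            assert np.all(np.diff(s) <= 1e-12), family


class TestSelection:
    def _mk(self, family, lnl, k):
        return SurvivalFit(
            family=family,
            theta=np.zeros(k),
            params={},
            intercept=0.0,
            scale=1.0,
            log_likelihood=lnl,
            n_params=k,
            n=100,
            n_events=80,
        )

    def test_argmin_aic(self):
        f1, f2 = self._mk("weibull", -100, 2), self._mk("log-normal", -103, 2)
        assert select_family([f2, f1], "AIC") is f1

    def test_tie_prefers_fewer_parameters(self):
        f1 = self._mk("exponential", -101, 1)  # AIC 204
        f2 = self._mk("weibull", -100, 2)  # AIC 204
        assert select_family([f2, f1], "AIC") is f1

    def test_tie_then_lexicographic_name(self):
        f1 = self._mk("weibull", -100, 2)
        f2 = self._mk("log-normal", -100, 2)
        assert select_family([f1, f2], "AIC").family == "log-normal"

    def test_second_aic_definition(self):
        fits = [self._mk("a", -100, 2), self._mk("b", -103, 2), self._mk("c", -113, 2)]
        assert select_family(fits, "second-AIC").aic == 210.0

    def test_bic_can_differ_from_aic(self):
        f1 = self._mk("exponential", -102, 1)  # AIC 206, BIC 208.6
        f2 = self._mk("weibull", -100, 2)  # AIC 204, BIC 209.2
        assert select_family([f1, f2], "AIC") is f2
        assert select_family([f1, f2], "BIC") is f1


class TestCycleIncidence:
    def test_exponential_closed_form(self):
        fit = _fit("exponential", shape=1.0, scale=10.0)
        rate = fit.params["rate"]
        expected = -np.expm1(-rate * 0.5)
        assert cycle_incidence(fit, 1) == pytest.approx(expected, rel=1e-9)
        # memorylessness: identical across cycles
        for j in range(2, 11):
            assert cycle_incidence(fit, j) == pytest.approx(expected, rel=1e-9)

    def test_increasing_hazard_gives_increasing_incidence(self):
        fit = _fit("weibull", shape=1.6, scale=8.0)
        inc = [cycle_incidence(fit, j) for j in range(1, 11)]
        assert np.all(np.diff(inc) > 0)

    def test_identical_fits_give_unit_rr_each_cycle(self):
        fit = _fit("weibull", shape=1.3, scale=9.0)
        for j in (1, 4, 10):
            assert cycle_rr(fit, fit, j) == 1.0

    def test_monotone_vs_constant_hazard_rr_is_monotone(self):
        rising = _fit("weibull", shape=1.6, scale=8.0)
        flat = _fit("exponential", shape=1.0, scale=8.0, seed=6)
        rrs = [cycle_rr(rising, flat, j) for j in range(1, 11)]
        assert np.all(np.diff(rrs) > 0)


class TestComposition:
    def test_published_products(self):
        # hip cycle 1 and vertebral cycle 3 against the alendronate anchor
        assert compose_vs_placebo([0.89], 0.61)[0] == pytest.approx(0.5429)
        assert compose_vs_placebo([0.38], 0.57)[0] == pytest.approx(0.2166)

    def test_identity_schedule_returns_anchor(self):
        out = compose_vs_placebo([1.0] * 10, 0.61)
        assert np.allclose(out, 0.61)

    @given(
        a=st.floats(0.1, 2.0),
        b=st.floats(0.1, 2.0),
        c=st.floats(0.1, 2.0),
    )
    @settings(derandomize=True, max_examples=50)
    def test_scalar_composition_is_associative(self, a, b, c):
        left = compose_vs_placebo(compose_vs_placebo([a], b), c)[0]
        right = compose_vs_placebo([a], b * c)[0]
        assert left == pytest.approx(right, rel=1e-12)


class TestOffset:
    def test_boundary_identities(self):
        assert offset_rr(0.6, 0.0, 5.0) == pytest.approx(0.6)
        assert offset_rr(0.6, 5.0, 5.0) == pytest.approx(1.0)
        assert offset_rr(0.6, 7.5, 5.0) == pytest.approx(1.0)

    def test_linear_midpoint(self):
        assert offset_rr(0.6, 2.5, 5.0) == pytest.approx(0.8)

    def test_invalid_offset_duration(self):
        with pytest.raises(ValueError):
            offset_rr(0.6, 1.0, 0.0)

    @given(
        base=st.floats(0.05, 0.999),
        offset=st.floats(0.5, 10.0),
        t1=st.floats(0.0, 12.0),
        dt=st.floats(0.0, 3.0),
    )
    @settings(derandomize=True, max_examples=100)
    def test_monotone_nondecreasing_and_bounded(self, base, offset, t1, dt):
        r1 = offset_rr(base, t1, offset)
        r2 = offset_rr(base, t1 + dt, offset)
        assert r2 >= r1 - 1e-12
        assert base - 1e-12 <= r1 <= 1.0 + 1e-12

    def test_continuity_at_offset_end(self):
        eps = 1e-9
        assert offset_rr(0.6, 5.0 - eps, 5.0) == pytest.approx(1.0, abs=1e-6)


def test_schedule_from_trial_identical_arms_near_unity():
    spec = SyntheticTrialSpec(
        n_per_arm=40_000,
        follow_up_years=5.0,
        hazard_model={
            "active": {"hip": (1.0, 15.0), "other": (1.0, 8.0)},
            "comparator": {"hip": (1.0, 15.0), "other": (1.0, 8.0)},
        },
        censoring_rate=0.05,
        seed=13,
    )
    rec = simulate_trial(spec)
    sched, selected = schedule_from_trial(rec, families=("exponential", "weibull"))
    for ep in ("hip", "other"):
        assert np.allclose(sched[ep], 1.0, atol=0.06)
        assert set(selected[ep]) == {"active", "comparator"}
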