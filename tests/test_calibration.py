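"""Calibration summaries, objective, search, rate ratios and TOST."""

import math

import numpy as np
import pytest
from scipy import stats

from crcsim.calibration import (
    CalibrationTarget,
    apply_free_parameters,
    calibrate,
    calibration_objective,
    ci_coverage_count,
    model_summaries,
    rate_ratio_ci,
    tost_equivalence,
)
from crcsim.fixtures import synth_calibration_targets

from _markov import run as markov_run
from conftest import make_uniform_bundle


def _target(quantity="prevalence_aa", sex="male", lo=40, hi=50, value=0.02, half=0.005):
    return CalibrationTarget(
        quantity=quantity, sex=sex, age_lo=lo, age_hi=hi,
        value=value, ci_low=value - half, ci_high=value + half,
    )


class TestModelSummaries:
    def test_zero_world_gives_zero_prevalence(self):
        b = make_uniform_bundle(p_trans=(0, 0, 0, 0), initial=(1, 0, 0, 0))
        s = model_summaries(b, n=2000, seed=1)
        for (q, *_), v in s.items():
            if q.startswith("prevalence"):
                assert v == 0.0

    def test_static_aa_prevalence_preserved(self):
        """5% advanced adenomas, no transitions, no death: the prevalence
        stays 5% in every band."""
        b = make_uniform_bundle(p_trans=(0, 0, 0, 0), p_other=0.0, initial=(0.95, 0.0, 0.05, 0.0))
        s = model_summaries(b, n=50_000, seed=2)
        for (q, sex, lo, hi), v in s.items():
            if q == "prevalence_aa":
                assert v == pytest.approx(0.05, abs=3 * math.sqrt(0.05 * 0.95 / 25_000))

    def test_matches_markov_oracle_rates(self):
        """Band incidence rates from the simulation agree with the exact
        chain's flow/exposure ratio within Monte-Carlo error."""
        p_trans = (0.02, 0.05, 0.10, 0.30)
        p_other = 0.01
        q = (0.2, 0.15, 0.1, 0.08, 0.05)
        initial = (0.9, 0.07, 0.025, 0.005)
        b = make_uniform_bundle(p_trans=p_trans, p_other=p_other, q=q, initial=initial)
        n = 200_000
        s = model_summaries(b, n=n, seed=3, bands=[(40, 60), (60, 80)])
        occ, inc_flow, _ = markov_run(initial, [p_trans] * 40, q, [p_other] * 40, 40)
        for lo, hi in [(40, 60), (60, 80)]:
            sl = slice(lo - 40, hi - 40)
            # exact exposure among the undiagnosed (half-credit on exit)
            undiag = occ[:, :4].sum(axis=1)
            exits = undiag[:-1] - undiag[1:]
            py = undiag[1:][sl].sum() + 0.5 * exits[sl].sum()
            exact_rate = 1e5 * inc_flow[sl].sum() / py
            sim_rate = s[("incidence", "male", lo, hi)] * 0.5 + s[
                ("incidence", "female", lo, hi)
            ] * 0.5
            se = exact_rate / math.sqrt(max(inc_flow[sl].sum() * n, 1))
            assert sim_rate == pytest.approx(exact_rate, abs=3 * se + 0.05 * exact_rate)


class TestObjective:
    def test_zero_iff_exact(self):
        t = [_target(value=0.02), _target(quantity="incidence", value=30, half=5)]
        pred = {x.key(): x.value for x in t}
        assert calibration_objective(pred, t) == 0.0

    def test_ci_bound_contributes_unit(self):
        t = [_target(value=0.02, half=0.005)]
        pred = {t[0].key(): 0.025}  # exactly at ci_high
        assert calibration_objective(pred, t) == pytest.approx(1.0)

    def test_matches_hand_sum_and_order_invariance(self):
        rng = np.random.default_rng(5)
        targets, pred, expected = [], {}, 0.0
        for i in range(10):
            v = rng.uniform(10, 50)
            half = rng.uniform(1, 5)
            t = _target(quantity="incidence", lo=40 + i, hi=41 + i, value=v, half=half)
            p = v + rng.normal(0, 2)
            targets.append(t)
            pred[t.key()] = p
            expected += ((p - v) / half) ** 2
        assert calibration_objective(pred, targets) == pytest.approx(expected)
        assert calibration_objective(pred, targets[::-1]) == pytest.approx(expected)

    def test_zero_half_width_rejected(self):
        t = CalibrationTarget("incidence", "male", 40, 50, 10.0, 10.0, 10.0)
        with pytest.raises(ValueError, match="half-width"):
            calibration_objective({t.key(): 10.0}, [t])


class TestCoverage:
    def test_exact_predictions_fully_covered(self):
        t = [_target(value=0.02), _target(quantity="incidence", value=30, half=3)]
        pred = {x.key(): x.value for x in t}
        assert ci_coverage_count(pred, t) == (2, 2)

    def test_all_misses(self):
        t = [_target(value=0.02, half=0.001) for _ in range(1)]
        assert ci_coverage_count({t[0].key(): 1.0}, t) == (0, 1)

    def test_mixed_hand_count(self):
        targets = [
            _target(lo=40 + i, hi=41 + i, value=0.02, half=0.005) for i in range(5)
        ]
        preds = [0.02, 0.0251, 0.0249, 0.01, 0.022]
        pred = {t.key(): p for t, p in zip(targets, preds)}
        assert ci_coverage_count(pred, targets) == (3, 5)


class TestCalibrate:
    def test_budget_one_returns_single_candidate(self, default_bundle):
        targets = synth_calibration_targets(default_bundle, n=2000, noise=0.2, seed=4)
        _, diag = calibrate(
            targets, {"mult:p_naa_to_aa": (0.8, 1.2)}, budget=1, seed=4,
            base_bundle=default_bundle, n_sim=2000, refine_sweeps=0,
        )
        assert diag.evaluations >= 1
        assert 0.8 <= diag.best_parameters["mult:p_naa_to_aa"] <= 1.2

    def test_collapsed_bounds_return_the_point(self, default_bundle):
        targets = synth_calibration_targets(default_bundle, n=2000, noise=0.2, seed=4)
        fitted, diag = calibrate(
            targets, {"mult:p_naa_to_aa": (1.3, 1.3)}, budget=5, seed=4,
            base_bundle=default_bundle, n_sim=2000,
        )
        assert diag.best_parameters["mult:p_naa_to_aa"] == pytest.approx(1.3)
        np.testing.assert_allclose(
            fitted.transitions.probs["male"][:, 1],
            default_bundle.transitions.probs["male"][:, 1] * 1.3,
        )

    def test_recovers_known_multipliers(self, default_bundle):
        """Round trip: noise-free targets from a perturbed bundle are
        refit from the base bundle; every free transition probability is
        recovered within 10% relative error."""
        truth = {
            "mult:p_norm_to_naa": 1.25,
            "mult:p_naa_to_aa": 0.80,
            "mult:p_aa_to_preclin": 1.20,
        }
        true_bundle = apply_free_parameters(default_bundle, truth)
        targets = synth_calibration_targets(true_bundle, n=20_000, noise=0.0, seed=11)
        fitted, diag = calibrate(
            targets, {k: (0.5, 2.0) for k in truth}, budget=30, seed=11,
            base_bundle=default_bundle, n_sim=20_000, refine_sweeps=3,
        )
        for k, v_true in truth.items():
            rel = abs(diag.best_parameters[k] - v_true) / v_true
            assert rel < 0.10, (k, diag.best_parameters[k], v_true)


class TestRateRatio:
    def test_equal_rates_give_unity(self):
        rr, lo, hi = rate_ratio_ci(100.0, 100.0, 500, 500)
        assert rr == 1.0 and lo < 1.0 < hi

    def test_closed_form(self):
        rr, lo, hi = rate_ratio_ci(110.0, 100.0, 1000, 1000)
        assert rr == pytest.approx(1.10)
        se = math.sqrt(1 / 1000 + 1 / 1000)
        z = stats.norm.ppf(0.975)
        assert lo == pytest.approx(1.10 * math.exp(-z * se))
        assert hi == pytest.approx(1.10 * math.exp(z * se))

    def test_interval_contains_point(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            m, o = rng.uniform(10, 200, 2)
            me, oe = rng.integers(5, 5000, 2)
            rr, lo, hi = rate_ratio_ci(m, o, int(me), int(oe))
            assert lo <= rr <= hi

    def test_zero_events_flagged(self):
        with pytest.raises(ValueError, match="event counts"):
            rate_ratio_ci(10.0, 10.0, 0, 100)


class TestTOST:
    def test_tiny_se_near_unity_is_equivalent(self):
        res = tost_equivalence([(0.0, 1e-4), (0.0, 1e-4)], margin=0.2)
        assert res.equivalent
        assert res.p_lower < 1e-10 and res.p_upper < 1e-10
        assert res.rate_ratio == pytest.approx(1.0)

    def test_point_on_upper_bound_gives_half(self):
        log_rr = math.log(1.2)
        res = tost_equivalence([(log_rr, 0.05), (log_rr, 0.05)], margin=0.2)
        assert res.p_upper == pytest.approx(0.5, abs=1e-9)
        assert not res.equivalent

    def test_homogeneous_inputs_reduce_to_inverse_variance_mean(self):
        """With no between-band heterogeneity the random-effects pooled
        estimate equals the fixed-effect inverse-variance mean."""
        xs = [0.05, 0.05, 0.05]
        ses = [0.1, 0.2, 0.05]
        res = tost_equivalence(list(zip(xs, ses)), margin=0.2)
        w = np.array([1 / s**2 for s in ses])
        assert math.log(res.rate_ratio) == pytest.approx(np.sum(w * xs) / w.sum())
        assert res.tau2 == 0.0

    def test_symmetric_bounds_swap_p_values(self):
        """Negating every log rate ratio swaps the two one-sided p-values
        exactly when the bounds are symmetric on the log scale."""
        data = [(0.08, 0.06), (0.03, 0.09), (0.12, 0.05)]
        bounds = (-math.log(1.2), math.log(1.2))
        res = tost_equivalence(data, bounds=bounds)
        neg = tost_equivalence([(-x, s) for x, s in data], bounds=bounds)
        assert res.p_lower == pytest.approx(neg.p_upper, abs=1e-12)
        assert res.p_upper == pytest.approx(neg.p_lower, abs=1e-12)

    def test_single_band_warns_and_falls_back(self):
        res = tost_equivalence([(0.0, 0.01)], margin=0.2)
        assert res.warning is not None
        assert res.equivalent
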