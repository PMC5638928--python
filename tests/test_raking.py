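import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from trajweight.margins import MarginSpec
from trajweight.raking import (
    CalibrationConfig,
    InfeasibleMarginsError,
    RakingWeighter,
    WeightSet,
    adjustment_factor,
    calibrate_logit,
    ipf_rake,
    margin_report,
    trim_and_rerake,
)

from conftest import make_cohort


def random_instance(rng: np.random.Generator):
    """Small random cohort + feasible margins over 2-3 categorical variables."""
    n_vars = rng.integers(2, 4)
    n = int(rng.integers(20, 51))
    variables = {}
    columns = {}
    for v in range(n_vars):
        k = int(rng.integers(2, 4))
        cats = [f"c{v}{j}" for j in range(k)]
        labels = cats + list(rng.choice(cats, size=n - k))
        rng.shuffle(labels)
        columns[f"v{v}"] = labels
        props = rng.dirichlet(np.ones(k)) * 0.7 + 0.3 / k  # keep away from 0
        props /= props.sum()
        variables[f"v{v}"] = dict(zip(cats, props.tolist()))
    margins = MarginSpec(variables)
    cohort = make_cohort(columns, ages=rng.uniform(3, 18, n), n=n)
    return cohort, margins


class TestAdjustmentFactor:
    def test_zero_eta_returns_center(self):
        cfg = CalibrationConfig(lower_bound=0, upper_bound=10, center=1)
        assert adjustment_factor(0.0, cfg) == pytest.approx(1.0)

    def test_limits_approach_bounds(self):
        cfg = CalibrationConfig(lower_bound=0, upper_bound=10, center=1)
        assert adjustment_factor(50.0, cfg) == pytest.approx(10.0, abs=1e-6)
        assert adjustment_factor(-50.0, cfg) == pytest.approx(0.0, abs=1e-6)

    def test_known_value_at_eta_one(self):
        cfg = CalibrationConfig(lower_bound=0, upper_bound=2, center=1)
        expected = 2 * math.e / (1 + math.e)  # direct evaluation of the link
        assert adjustment_factor(1.0, cfg) == pytest.approx(expected, abs=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(
        eta=st.floats(-700, 700),
        delta=st.floats(1e-6, 10.0),
    )
    def test_bounded_and_strictly_increasing(self, eta, delta):
        cfg = CalibrationConfig(lower_bound=0.2, upper_bound=7.0, center=1.0)
        a, b = adjustment_factor(eta, cfg), adjustment_factor(eta + delta, cfg)
        assert 0.2 <= a <= 7.0
        assert b >= a

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError, match="l < c < u"):
            CalibrationConfig(lower_bound=2.0, upper_bound=1.0)


class TestIpfRake:
    def test_identity_when_margins_already_match(self, exact_margin_cohort, sample_margins):
        ws = ipf_rake(exact_margin_cohort, sample_margins)
        np.testing.assert_allclose(ws.final, 1.0, atol=1e-12)
        assert ws.converged and ws.iterations == 1

    def test_two_by_two_matches_brute_force_ipf(self):
        # cells (a1,b1)=10 (a1,b2)=30 (a2,b1)=30 (a2,b2)=30; targets 0.5 each
        counts = np.array([[10.0, 30.0], [30.0, 30.0]])
        cells = [(i, j) for i in range(2) for j in range(2)]
        labels_a, labels_b = [], []
        for (i, j) in cells:
            labels_a += [f"a{i}"] * int(counts[i, j])
            labels_b += [f"b{j}"] * int(counts[i, j])
        cohort = make_cohort({"va": labels_a, "vb": labels_b}, n=100)
        margins = MarginSpec(
            {"va": {"a0": 0.5, "a1": 0.5}, "vb": {"b0": 0.5, "b1": 0.5}}
        )
        ws = ipf_rake(cohort, margins)
        # independent brute-force IPF on the 2x2 contingency table
        M = counts.copy()
        for _ in range(200):
            M *= (0.5 * M.sum() / M.sum(axis=1))[:, None]
            M *= (0.5 * M.sum() / M.sum(axis=0))[None, :]
        expected = np.concatenate(
            [np.full(int(counts[i, j]), M[i, j] / counts[i, j]) for (i, j) in cells]
        )
        np.testing.assert_allclose(ws.final, expected, rtol=1e-6)

    def test_empty_support_category_raises_naming_it(self):
        cohort = make_cohort({"va": ["x"] * 10})
        margins = MarginSpec({"va": {"x": 0.8, "missing": 0.2}})
        with pytest.raises(InfeasibleMarginsError, match="missing"):
            ipf_rake(cohort, margins)

    def test_variable_cycle_order_invariant_at_convergence(self):
        rng = np.random.default_rng(42)
        cohort, margins = random_instance(rng)
        reversed_margins = MarginSpec(
            {v: margins.variables[v] for v in reversed(margins.variable_names)}
        )
        w1 = ipf_rake(cohort, margins)
        w2 = ipf_rake(cohort, reversed_margins)
        assert w1.converged and w2.converged
        np.testing.assert_allclose(w1.final, w2.final, rtol=1e-6)


class TestCalibrateLogit:
    def test_identity_beta_zero_when_margins_match(
        self, exact_margin_cohort, sample_margins
    ):
        ws = calibrate_logit(exact_margin_cohort, sample_margins)
        assert ws.converged
        np.testing.assert_allclose(ws.beta, 0.0, atol=1e-6)
        np.testing.assert_allclose(ws.final, 1.0, atol=1e-6)

    @pytest.mark.parametrize("seed", range(8))
    def test_equivalent_to_ipf_with_wide_bounds(self, seed):
        # with u large the bounded-logit link reduces to the exponential
        # (raking) link, so both algorithms solve the same calibration problem
        rng = np.random.default_rng(seed)
        cohort, margins = random_instance(rng)
        ipf = ipf_rake(cohort, margins)
        logit = calibrate_logit(
            cohort, margins, CalibrationConfig(upper_bound=1e6)
        )
        assert ipf.converged and logit.converged
        np.testing.assert_allclose(logit.final, ipf.final, rtol=1e-4)

    def test_weights_respect_logit_bounds(self):
        rng = np.random.default_rng(5)
        cohort, margins = random_instance(rng)
        cfg = CalibrationConfig(lower_bound=0.0, upper_bound=100.0)
        ws = calibrate_logit(cohort, margins, cfg)
        ratio = ws.final / ws.initial
        assert np.all(ratio > 0.0) and np.all(ratio < 100.0)
        assert np.all(ws.final > 0)

    def test_binding_upper_bound_reports_nonconvergence(self):
        # one rare category needing a 3x up-weight, but alpha capped at 1.5
        cohort = make_cohort(
            {"g": ["A"] * 9 + ["B"], "s": ["x", "y"] * 5}
        )
        margins = MarginSpec(
            {"g": {"A": 0.7, "B": 0.3}, "s": {"x": 0.5, "y": 0.5}}
        )
        cfg = CalibrationConfig(upper_bound=1.5, max_iterations=50)
        ws = calibrate_logit(cohort, margins, cfg)
        assert not ws.converged
        assert np.all(ws.final / ws.initial <= 1.5 + 1e-9)
        # the shortfall concentrates on the infeasible up-weighted category
        worst = max(ws.residuals, key=lambda k: abs(ws.residuals[k]))
        assert worst in ("g/B", "g/A")
        assert ws.residuals["g/B"] < -0.05

    def test_weighted_margins_hit_targets(self, target_margins):
        from trajweight.synthetic import generate_demographics
        from trajweight.margins import child_cohort_margins

        cohort = generate_demographics(child_cohort_margins(), n=1162, seed=0)
        ws = calibrate_logit(cohort, target_margins)
        assert ws.converged
        assert max(abs(v) for v in ws.residuals.values()) < 1e-8
        assert ws.final.sum() == pytest.approx(1162, rel=1e-8)

    def test_monotone_response_to_target_increase(self):
        rng = np.random.default_rng(17)
        cohort, margins = random_instance(rng)
        var = margins.variable_names[0]
        cats = margins.categories(var)
        before = calibrate_logit(cohort, margins)
        bumped = dict(margins.variables)
        p = dict(bumped[var])
        boost = min(0.15, 1 - p[cats[0]])
        p[cats[0]] += boost
        scale = (1 - p[cats[0]]) / sum(p[c] for c in cats[1:])
        for c in cats[1:]:
            p[c] *= scale
        bumped[var] = p
        after = calibrate_logit(cohort, MarginSpec(bumped))
        mask = (cohort[var] == cats[0]).to_numpy()
        assert after.final[mask].mean() >= before.final[mask].mean() - 1e-9


class TestTrimming:
    def _weight_set(self, finals: np.ndarray) -> WeightSet:
        n = len(finals)
        return WeightSet(
            participant_ids=np.array([f"S{i}" for i in range(n)]),
            initial=np.ones(n),
            final=finals.astype(float),
            method="logit",
            converged=True,
            iterations=1,
            max_residual=0.0,
        )

    def test_outlier_clipped_to_fence_then_recalibrated(self):
        finals = np.concatenate([np.full(580, 0.8), np.full(580, 1.2), [100.0]])
        n = len(finals)
        cohort = make_cohort({"g": ["x"] * n}, n=n)
        margins = MarginSpec({"g": {"x": 1.0}})
        ws = trim_and_rerake(self._weight_set(finals), cohort, margins)
        assert ws.trimming_applied
        # Q1=0.8, Q3=1.2 -> upper fence 1.2 + 3*0.4 = 2.4
        assert ws.fences[1] == pytest.approx(2.4)
        assert ws.gamma.max() == pytest.approx(2.4 / 1.0)
        assert ws.final.max() <= 2.4 * (1 + 1e-6)
        assert ws.final.sum() == pytest.approx(n, rel=1e-6)

    def test_all_inside_fence_is_identity(self):
        finals = np.linspace(0.9, 1.1, 50)
        ws = self._weight_set(finals)
        out = trim_and_rerake(ws, make_cohort({"g": ["x"] * 50}, n=50),
                              MarginSpec({"g": {"x": 1.0}}))
        assert out is ws

    def test_constant_weights_unchanged(self):
        ws = self._weight_set(np.full(30, 1.0))
        out = trim_and_rerake(ws, make_cohort({"g": ["x"] * 30}, n=30),
                              MarginSpec({"g": {"x": 1.0}}))
        assert out is ws

    def test_idempotent_with_stored_fences(self):
        finals = np.concatenate([np.full(580, 0.8), np.full(580, 1.2), [100.0]])
        n = len(finals)
        cohort = make_cohort({"g": ["x"] * n}, n=n)
        margins = MarginSpec({"g": {"x": 1.0}})
        once = trim_and_rerake(self._weight_set(finals), cohort, margins)
        twice = trim_and_rerake(once, cohort, margins)
        assert twice is once


class TestMarginReport:
    def test_unweighted_differences_match_rounded_arithmetic(
        self, exact_margin_cohort, target_margins
    ):
        rep = margin_report(
            exact_margin_cohort, np.ones(len(exact_margin_cohort)), target_margins
        )
        white = rep.set_index(["variable", "category"]).loc[("race", "White")]
        assert white["unweighted_minus_target"] == pytest.approx(-27.6)
        educ = rep.set_index(["variable", "category"]).loc[
            ("parental_education", "More than college")
        ]
        assert educ["unweighted_minus_target"] == pytest.approx(23.4)

    def test_weighted_differences_zero_after_raking(
        self, exact_margin_cohort, target_margins
    ):
        ws = calibrate_logit(exact_margin_cohort, target_margins)
        rep = margin_report(exact_margin_cohort, ws, target_margins)
        assert (rep["weighted_minus_target"] == 0.0).all()

    def test_single_category_variable_reports_100_percent(self):
        cohort = make_cohort({"g": ["only"] * 10})
        margins = MarginSpec({"g": {"only": 1.0}})
        rep = margin_report(cohort, np.ones(10), margins)
        assert rep.loc[0, "weighted_pct"] == 100.0
        assert rep.loc[0, "weighted_minus_target"] == 0.0

    def test_length_mismatch_rejected(self):
        cohort = make_cohort({"g": ["x"] * 5})
        with pytest.raises(ValueError, match="length"):
            margin_report(cohort, np.ones(4), MarginSpec({"g": {"x": 1.0}}))


class TestRakingWeighter:
    def test_sklearn_interface_roundtrip(self, target_margins):
        from trajweight.synthetic import generate_demographics
        from trajweight.margins import child_cohort_margins

        cohort = generate_demographics(child_cohort_margins(), n=400, seed=1)
        est = RakingWeighter(margins=target_margins, method="logit", trim=True)
        assert est.get_params()["method"] == "logit"
        est.set_params(tolerance=1e-10)
        est.fit(cohort)
        assert est.converged_
        assert len(est.weights_) == 400
        assert (est.margin_report(cohort)["weighted_minus_target"] == 0.0).all()

    def test_unknown_method_rejected(self, target_margins):
        with pytest.raises(ValueError, match="method"):
            RakingWeighter(margins=target_margins, method="bogus").fit(
                make_cohort({"g": ["x"] * 3})
            )
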