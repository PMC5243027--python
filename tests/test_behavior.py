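"""Behavioral analysis pipeline: decisions, fits, and nonparametric tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from attractorchoice.behavior import (
    HysteresisLogit,
    PsychometricLogit,
    WeibullPsychometric,
    anova_oneway,
    detect_decision,
    dt_difference_regression,
    filter_trials,
    hysteresis_logistic,
    indecision_points,
    mann_whitney_u,
    weibull_accuracy_threshold,
    wilcoxon_signed_rank,
)
from attractorchoice.neural import RateTrace
from attractorchoice.synthetic import SyntheticSpec, generate_session


def _trace(times, rates):
    return RateTrace(np.asarray(times, float), np.asarray(rates, float))


def _records(choices, coherences, prev=None, dts=None, subject=0):
    n = len(choices)
    prev = prev if prev is not None else ["none"] + list(choices[:-1])
    return pd.DataFrame(
        {
            "subject_id": subject,
            "condition": "none",
            "trial_index": np.arange(n),
            "coherence_signed": coherences,
            "choice": choices,
            "previous_choice": prev,
            "decision_time": dts if dts is not None else np.full(n, 0.3),
            "valid": [c in ("left", "right") for c in choices],
        }
    )


class TestDetectDecision:
    def setup_method(self):
        self.t = np.arange(0.0, 3000.0, 0.5)

    def test_single_crossing(self):
        right = np.where(self.t >= 1350.0, 25.0, 5.0)
        left = np.full_like(self.t, 5.0)
        choice, dt = detect_decision(
            _trace(self.t, left), _trace(self.t, right), 20.0, (1000.0, 3000.0)
        )
        assert choice == "right"
        assert dt == pytest.approx(350.0, abs=1.0)

    def test_no_crossing(self):
        flat = np.full_like(self.t, 5.0)
        choice, dt = detect_decision(
            _trace(self.t, flat), _trace(self.t, flat), 20.0, (1000.0, 3000.0)
        )
        assert (choice, dt) == ("none", None)

    def test_first_crossing_wins(self):
        left = np.where(self.t >= 1200.0, 25.0, 5.0)
        right = np.where(self.t >= 1400.0, 30.0, 5.0)
        choice, dt = detect_decision(
            _trace(self.t, left), _trace(self.t, right), 20.0, (1000.0, 3000.0)
        )
        assert choice == "left"
        assert dt == pytest.approx(200.0, abs=1.0)

    def test_simultaneous_crossing_broken_by_height(self):
        left = np.where(self.t >= 1200.0, 21.0, 5.0)
        right = np.where(self.t >= 1200.0, 30.0, 5.0)
        choice, _ = detect_decision(
            _trace(self.t, left), _trace(self.t, right), 20.0, (1000.0, 3000.0)
        )
        assert choice == "right"

    def test_bad_threshold_rejected(self):
        flat = np.full_like(self.t, 5.0)
        with pytest.raises(ValueError):
            detect_decision(
                _trace(self.t, flat), _trace(self.t, flat), 0.0, (1000.0, 3000.0)
            )


class TestFilterTrials:
    def test_identical_times_remove_nothing(self):
        r = _records(["left"] * 6, [0.1] * 6, dts=[0.3] * 6)
        out = filter_trials(r)
        assert out["valid"].all()

    def test_single_gross_outlier_removed(self):
        dts = [0.30, 0.31, 0.32, 0.29, 3.0]
        # hand check: median 0.31, MAD = median(|d - 0.31|) = 0.01,
        # 3 * 1.4826 * 0.01 = 0.0445 -> only the 3.0 s trial exceeds it
        r = _records(["left"] * 5, [0.1] * 5, dts=dts)
        out = filter_trials(r)
        assert out["valid"].tolist() == [True, True, True, True, False]

    def test_non_response_always_invalid(self):
        r = _records(["left", "none", "right"], [0.1] * 3, dts=[0.3, np.nan, 0.3])
        out = filter_trials(r)
        assert out["valid"].tolist() == [True, False, True]

    def test_never_removes_more_than_half_a_group(self, rng):
        dts = np.concatenate([np.full(4, 0.3), rng.uniform(5, 50, 8)])
        r = _records(["left"] * 12, [0.1] * 12, dts=dts)
        out = filter_trials(r)
        assert (~out["valid"]).sum() <= 6


class TestWeibull:
    def test_recovers_known_threshold_from_noiseless_data(self):
        alpha, beta = 0.1, 2.0
        c = np.array([0.02, 0.05, 0.08, 0.12, 0.2, 0.4])
        acc = 1 - 0.5 * np.exp(-((c / alpha) ** beta))
        fit = weibull_accuracy_threshold(np.column_stack([c, acc, np.full(6, 50)]), 0.8)
        # closed-form inverse oracle
        expected = alpha * (-np.log(2 * (1 - 0.8))) ** (1 / beta)
        assert expected == pytest.approx(0.0957, abs=2e-4)
        assert fit.accuracy_threshold == pytest.approx(expected, rel=0.01)
        assert fit.alpha == pytest.approx(alpha, rel=0.05)
        assert fit.beta == pytest.approx(beta, rel=0.05)

    def test_threshold_approaches_zero_at_chance_target(self):
        alpha, beta = 0.1, 2.0
        c = np.array([0.02, 0.05, 0.08, 0.12, 0.2, 0.4])
        acc = 1 - 0.5 * np.exp(-((c / alpha) ** beta))
        data = np.column_stack([c, acc, np.full(6, 50)])
        thr = [
            weibull_accuracy_threshold(data, tgt).accuracy_threshold
            for tgt in (0.7, 0.6, 0.55, 0.51)
        ]
        assert all(np.diff(thr) < 0)
        assert thr[-1] < 0.02

    def test_ceiling_accuracy_flags_non_converged(self):
        data = np.column_stack([[0.05, 0.1, 0.2], [1.0, 1.0, 1.0], [50, 50, 50]])
        fit = weibull_accuracy_threshold(data, 0.8)
        assert not fit.converged

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            WeibullPsychometric([0.1, 0.2], [0.6, 0.9])


class TestDtDifferenceRegression:
    def test_identical_conditions_give_zero(self):
        m = np.array([[0.5, 0.4, 0.3]])
        fit = dt_difference_regression(m, m, coherences=[0.1, 0.2, 0.4])
        assert fit.beta0 == pytest.approx(0.0, abs=1e-12)
        assert fit.beta1 == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_line_recovered_exactly(self):
        c = np.array([0.032, 0.064, 0.128, 0.256, 0.512])
        diff = 0.05 - 0.1 * c
        fit = dt_difference_regression(diff[None, :], np.zeros((1, 5)), coherences=c)
        assert fit.beta0 == pytest.approx(0.05, abs=1e-10)
        assert fit.beta1 == pytest.approx(-0.1, abs=1e-10)

    def test_constant_offset_has_zero_slope(self):
        c = np.array([0.1, 0.2, 0.4])
        fit = dt_difference_regression(
            np.full((3, 3), 0.51), np.full((3, 3), 0.5), coherences=c
        )
        assert fit.beta0 == pytest.approx(0.01, abs=1e-10)
        assert fit.beta1 == pytest.approx(0.0, abs=1e-10)

    def test_single_coherence_rejected(self):
        with pytest.raises(ValueError):
            dt_difference_regression([[0.5]], [[0.4]], coherences=[0.1])


class TestIndecisionPoints:
    def test_history_free_choices_give_near_zero_shift(self):
        spec = SyntheticSpec(a0=0.0, a1=10.0, a2=0.0, reps=400, seed=3)
        r = generate_session(spec).rename(columns={"decision_time_s": "decision_time"})
        ip_l, ip_r, shift = indecision_points(r)
        assert abs(shift) < 0.02

    def test_hysteresis_produces_positive_shift(self):
        spec = SyntheticSpec(a0=0.0, a1=10.0, a2=0.8, reps=400, seed=4)
        r = generate_session(spec).rename(columns={"decision_time_s": "decision_time"})
        _, _, shift = indecision_points(r)
        assert shift > 0.02

    def test_known_midpoint_recovered(self):
        rng = np.random.default_rng(8)
        c0, k = 0.05, 15.0
        c = rng.uniform(-0.5, 0.5, 4000)
        p = 1 / (1 + np.exp(-k * (c - c0)))
        y = rng.random(4000) < p
        fit = PsychometricLogit(y, c).fit()
        assert fit.converged
        assert fit.indecision_point == pytest.approx(c0, abs=0.02)
        assert fit.slope == pytest.approx(k, rel=0.15)


class TestHysteresisLogit:
    def test_null_previous_choice_effect_recovered(self):
        spec = SyntheticSpec(a0=0.0, a1=10.0, a2=0.0, reps=500, seed=5)
        r = generate_session(spec).rename(columns={"decision_time_s": "decision_time"})
        fit = hysteresis_logistic(r)
        assert fit.bse is None or abs(fit.a2) < 2.5 * fit.bse[2]

    def test_coefficients_recovered_within_ten_percent(self):
        spec = SyntheticSpec(a0=0.0, a1=10.0, a2=0.5, reps=1000, seed=6)
        r = generate_session(spec).rename(columns={"decision_time_s": "decision_time"})
        fit = hysteresis_logistic(r)
        assert fit.a1 == pytest.approx(10.0, rel=0.10)
        assert fit.a2 == pytest.approx(0.5, rel=0.10)
        assert fit.ratio == pytest.approx(0.05, rel=0.2)

    def test_all_identical_choices_raise(self):
        r = _records(["right"] * 30, [0.1] * 30)
        with pytest.raises(ValueError):
            hysteresis_logistic(r)

    def test_grid_search_oracle_agrees(self):
        """MLE fit matches an independent coarse likelihood grid search."""
        spec = SyntheticSpec(a0=0.2, a1=8.0, a2=0.6, reps=25, seed=7)  # 250 trials
        r = generate_session(spec).rename(columns={"decision_time_s": "decision_time"})
        model = HysteresisLogit.from_trials(r)
        fit = model.fit()

        y, X = model.endog, model.exog
        grid_a0 = np.linspace(-1.5, 1.5, 31)
        grid_a1 = np.linspace(2.0, 16.0, 29)
        grid_a2 = np.linspace(-1.0, 2.0, 31)
        best, best_ll = None, -np.inf
        for a0 in grid_a0:
            for a1 in grid_a1:
                for a2 in grid_a2:
                    z = a0 * X[:, 0] + a1 * X[:, 1] + a2 * X[:, 2]
                    ll = np.sum(y * z - np.logaddexp(0.0, z))
                    if ll > best_ll:
                        best_ll, best = ll, (a0, a1, a2)
        assert fit.a0 == pytest.approx(best[0], abs=0.11)
        assert fit.a1 == pytest.approx(best[1], abs=0.51)
        assert fit.a2 == pytest.approx(best[2], abs=0.11)

    def test_sign_consistency_with_indecision_shift(self):
        """sign(shift) matches sign(a2) on strong-hysteresis synthetic data."""
        agree = 0
        for rep in range(20):
            spec = SyntheticSpec(a0=0.0, a1=10.0, a2=0.5, reps=200, seed=100 + rep)
            r = generate_session(spec).rename(
                columns={"decision_time_s": "decision_time"}
            )
            fit = hysteresis_logistic(r)
            _, _, shift = indecision_points(r)
            if np.sign(shift) == np.sign(fit.a2):
                agree += 1
        assert agree >= 19


class TestWilcoxon:
    def test_hand_ranked_example(self):
        # |d| = {1, 2, 3} -> ranks {1, 2, 3}; W+ = 1 + 3 = 4, W- = 2
        res = wilcoxon_signed_rank([1.0, -2.0, 3.0])
        assert res.statistic == 2.0

    def test_identical_samples_degenerate(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_exact_p_for_uniform_signs(self):
        # all five differences positive: P(W- = 0) under H0 is 2/2^5
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0, 5.0])
        assert res.p_value == pytest.approx(2 / 32)

    @given(
        st.lists(
            st.integers(min_value=-9, max_value=9).filter(lambda v: v != 0),
            min_size=5,
            max_size=10,
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_exact_p_matches_brute_force_enumeration(self, diffs):
        d = np.array(diffs, dtype=float)
        res = wilcoxon_signed_rank(d)
        # oracle: independent enumeration over all sign assignments
        ranks = scipy.stats.rankdata(np.abs(d))
        total = ranks.sum()
        count = 0
        n_pat = 0
        for signs in itertools.product([0, 1], repeat=len(d)):
            wp = sum(r for r, s in zip(ranks, signs) if s)
            w = min(wp, total - wp)
            n_pat += 1
            if w <= res.statistic + 1e-12:
                count += 1
        assert res.p_value == pytest.approx(count / n_pat)

    def test_matches_scipy_exact_when_tie_free(self, rng):
        for _ in range(10):
            d = rng.normal(size=9)
            ours = wilcoxon_signed_rank(d)
            ref = scipy.stats.wilcoxon(d, method="exact")
            assert ours.p_value == pytest.approx(ref.pvalue)


class TestMannWhitney:
    def test_complete_separation_gives_zero_u(self):
        assert mann_whitney_u([1.0, 2.0], [3.0, 4.0]).statistic == 0.0
        assert mann_whitney_u([1.0], [2.0]).statistic == 0.0

    def test_identical_samples_give_half_the_pairs(self):
        a = [1.0, 2.0, 3.0, 4.0]
        res = mann_whitney_u(a, list(a))
        assert res.statistic == len(a) ** 2 / 2

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestAnova:
    def test_two_groups_equal_squared_t(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 15)
        f = anova_oneway([a, b])
        t = scipy.stats.ttest_ind(a, b)
        assert f.statistic == pytest.approx(t.statistic**2, rel=1e-10)
        assert f.p_value == pytest.approx(t.pvalue, rel=1e-10)

    def test_hand_computed_example(self):
        res = anova_oneway([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        assert res.statistic == pytest.approx(13.5)
        assert res.n == (1, 4)

    def test_equal_means_give_small_f(self, rng):
        groups = [rng.normal(0, 1, 400) for _ in range(3)]
        res = anova_oneway(groups)
        assert res.p_value > 0.01 or res.statistic < 6

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(ValueError):
            anova_oneway([[1.0, 2.0]])
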