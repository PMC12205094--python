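import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from coldtrial.design import (
    InterimDecision,
    TrialDesign,
    TrialState,
    ValidationError,
    decision_table,
    interim_decision,
    interim_schedule,
    operating_characteristics,
    posterior_tail_prob,
    predictive_prob_success,
    simulate_trial,
    update_posterior,
)

DEFAULT = TrialDesign()


# ---------------------------------------------------------------- oracles


def trapezoid_quantiles(a, b, probs, n_grid=400_001):
    """Credible-interval oracle: trapezoid integration of the Beta(a, b)
    density on a fine grid, inverted by interpolation."""
    x = np.linspace(0.0, 1.0, n_grid)
    pdf = stats.beta.pdf(x, a, b)
    pdf = np.nan_to_num(pdf, posinf=0.0)  # endpoint singularities
    cdf = integrate.cumulative_trapezoid(pdf, x, initial=0.0)
    cdf /= cdf[-1]
    return np.interp(probs, cdf, x)


def enumerate_predictive_success(design, state):
    """Exhaustive-sequence oracle: sum predictive probabilities over all
    2^m future response sequences (Polya-urn sequential weights)."""
    m = design.n_max - state.n_evaluable
    total = 0.0
    for seq in itertools.product((0, 1), repeat=m):
        a = design.prior_alpha + state.n_responders
        b = design.prior_beta + state.n_evaluable - state.n_responders
        prob = 1.0
        for x in seq:
            p1 = a / (a + b)
            prob *= p1 if x else 1.0 - p1
            a += x
            b += 1 - x
        r_final = state.n_responders + sum(seq)
        a_f = design.prior_alpha + r_final
        b_f = design.prior_beta + design.n_max - r_final
        if stats.beta.sf(design.p_efficacy, a_f, b_f) >= design.threshold_efficacy:
            total += prob
    return total


# ------------------------------------------------------- update_posterior


class TestUpdatePosterior:
    def test_uniform_prior_no_data(self):
        post = update_posterior(DEFAULT, TrialState(0, 0))
        assert post.mean == 0.5
        assert post.ci_low == pytest.approx(0.025, abs=1e-12)
        assert post.ci_high == pytest.approx(0.975, abs=1e-12)

    def test_reported_outcome(self):
        # 4 responders of 43 evaluable under the uniform prior
        post = update_posterior(DEFAULT, TrialState(43, 4))
        assert post.mean == pytest.approx(5 / 45)
        assert abs(100 * post.mean - 11.0) < 0.5
        assert abs(100 * post.ci_low - 4.0) < 1.0
        assert abs(100 * post.ci_high - 22.0) < 1.0

    def test_informative_prior_vs_trapezoid_oracle(self):
        design = TrialDesign(prior_alpha=2, prior_beta=3)
        post = update_posterior(design, TrialState(10, 3))
        assert post.alpha_post == 5 and post.beta_post == 10
        assert post.mean == pytest.approx(1 / 3)
        lo, hi = trapezoid_quantiles(5, 10, [0.025, 0.975])
        assert post.ci_low == pytest.approx(lo, abs=1e-5)
        assert post.ci_high == pytest.approx(hi, abs=1e-5)

    @pytest.mark.parametrize("a,b", [(1, 1), (5, 40), (2.5, 7.5), (100, 100), (80, 3)])
    def test_quantiles_match_oracle_across_shapes(self, a, b):
        design = TrialDesign(prior_alpha=a, prior_beta=b)
        post = update_posterior(design, TrialState(0, 0))
        lo, hi = trapezoid_quantiles(a, b, [0.025, 0.975])
        assert post.ci_low == pytest.approx(lo, abs=1e-5)
        assert post.ci_high == pytest.approx(hi, abs=1e-5)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValidationError):
            TrialState(10, 11)
        with pytest.raises(ValidationError):
            TrialState(-1, 0)
        with pytest.raises(ValidationError):
            TrialState(5, -2)

    @given(
        n1=st.integers(0, 30),
        n2=st.integers(0, 30),
        data=st.data(),
    )
    @settings(max_examples=50, deadline=None)
    def test_conjugacy_pooled_equals_sequential(self, n1, n2, data):
        r1 = data.draw(st.integers(0, n1))
        r2 = data.draw(st.integers(0, n2))
        pooled = update_posterior(DEFAULT, TrialState(n1 + n2, r1 + r2))
        step1 = update_posterior(DEFAULT, TrialState(n1, r1))
        design2 = TrialDesign(prior_alpha=step1.alpha_post, prior_beta=step1.beta_post)
        step2 = update_posterior(design2, TrialState(n2, r2))
        assert pooled.alpha_post == step2.alpha_post
        assert pooled.beta_post == step2.beta_post

    def test_hpd_interval_is_narrower_than_equal_tailed(self):
        eq = update_posterior(DEFAULT, TrialState(43, 4))
        hp = update_posterior(DEFAULT, TrialState(43, 4), hpd=True)
        assert hp.ci_high - hp.ci_low <= eq.ci_high - eq.ci_low + 1e-9
        mass = stats.beta.cdf(hp.ci_high, 5, 40) - stats.beta.cdf(hp.ci_low, 5, 40)
        assert mass == pytest.approx(0.95, abs=1e-6)


# ----------------------------------------------------- posterior_tail_prob


class TestTailProb:
    def test_full_support(self):
        post = update_posterior(DEFAULT, TrialState(7, 2))
        assert posterior_tail_prob(post, 1.0, "at_most") == 1.0

    def test_uniform_cdf(self):
        post = update_posterior(DEFAULT, TrialState(0, 0))
        assert posterior_tail_prob(post, 0.25, "at_least") == pytest.approx(0.75)

    def test_quadrature_oracle(self):
        design = TrialDesign(prior_alpha=5, prior_beta=40)
        post = update_posterior(design, TrialState(0, 0))
        val, _ = integrate.quad(lambda x: stats.beta.pdf(x, 5, 40), 0, 0.10)
        assert posterior_tail_prob(post, 0.10, "at_most") == pytest.approx(val, abs=1e-6)

    @pytest.mark.parametrize("n,r,t", [(0, 0, 0.3), (10, 2, 0.1), (43, 4, 0.25)])
    def test_directions_sum_to_one(self, n, r, t):
        post = update_posterior(DEFAULT, TrialState(n, r))
        s = posterior_tail_prob(post, t, "at_most") + posterior_tail_prob(
            post, t, "at_least"
        )
        assert abs(s - 1.0) <= 1e-9

    def test_bad_direction(self):
        post = update_posterior(DEFAULT, TrialState(0, 0))
        with pytest.raises(ValidationError):
            posterior_tail_prob(post, 0.5, "above")


# ------------------------------------------------- predictive_prob_success


class TestPredictiveProb:
    def test_terminal_states(self):
        # enough responders at n_max for the final criterion
        r_yes = next(
            r
            for r in range(DEFAULT.n_max + 1)
            if stats.beta.sf(0.25, 1 + r, 1 + DEFAULT.n_max - r) >= 0.80
        )
        assert predictive_prob_success(DEFAULT, TrialState(50, r_yes)) == 1.0
        assert predictive_prob_success(DEFAULT, TrialState(50, 0)) == 0.0

    def test_matches_exhaustive_enumeration_small(self):
        design = TrialDesign(n_first_interim=10, n_max=15)
        state = TrialState(10, 2)
        got = predictive_prob_success(design, state)
        want = enumerate_predictive_success(design, state)
        assert got == pytest.approx(want, abs=1e-9)

    @pytest.mark.parametrize("n,r", [(40, 0), (40, 8), (45, 5), (42, 10), (50, 13)])
    def test_matches_enumeration_default_design(self, n, r):
        state = TrialState(n, r)
        got = predictive_prob_success(DEFAULT, state)
        want = enumerate_predictive_success(DEFAULT, state)
        assert got == pytest.approx(want, abs=1e-9)

    def test_beyond_n_max_rejected(self):
        with pytest.raises(ValidationError):
            predictive_prob_success(DEFAULT, TrialState(51, 5))


# --------------------------------------------------------- interim_decision


class TestInterimDecision:
    def test_futility_continue_at_first_look(self):
        d = interim_decision(DEFAULT, TrialState(10, 0))
        # closed form: P(p <= 0.1 | Beta(1, 11)) = 1 - 0.9^11
        assert d.prob_futility_event == pytest.approx(1 - 0.9**11, abs=1e-9)
        assert d.action == "continue"

    def test_futility_stop_at_second_look(self):
        d = interim_decision(DEFAULT, TrialState(15, 0))
        assert d.prob_futility_event == pytest.approx(1 - 0.9**16, abs=1e-9)
        assert d.action == "stop_futility"

    def test_efficacy_stop_all_responders(self):
        d = interim_decision(DEFAULT, TrialState(10, 10))
        # Beta(11, 1): P(p >= 0.25) = 1 - 0.25^11
        assert d.prob_efficacy_event == pytest.approx(1 - 0.25**11, abs=1e-9)
        assert d.action == "stop_efficacy"

    @pytest.mark.parametrize("rule", ["posterior", "predictive"])
    def test_action_monotone_in_responders(self, rule):
        design = TrialDesign(rule_interpretation=rule)
        for n in interim_schedule(design):
            actions = [
                interim_decision(design, TrialState(n, r)).action
                for r in range(n + 1)
            ]
            order = {"stop_futility": 0, "continue": 1, "stop_efficacy": 2}
            ranks = [order[a] for a in actions]
            assert ranks == sorted(ranks), f"non-monotone actions at n={n}: {actions}"

    def test_rules_never_both_fire(self):
        # with default thresholds the two stopping events are mutually
        # exclusive at every scheduled look
        for n in interim_schedule(DEFAULT):
            for r in range(n + 1):
                d = interim_decision(DEFAULT, TrialState(n, r))
                fires = (d.prob_futility_event >= 0.80) + (
                    d.prob_efficacy_event >= 0.80
                )
                assert fires <= 1

    def test_predictive_rule_terminal_look_matches_posterior_criterion(self):
        design = TrialDesign(rule_interpretation="predictive")
        for r in (0, 4, 10, 20):
            d = interim_decision(design, TrialState(50, r))
            assert d.prob_efficacy_event in (0.0, 1.0)
            assert d.prob_futility_event in (0.0, 1.0)


# --------------------------------------------------------- interim_schedule


class TestSchedule:
    def test_default(self):
        assert interim_schedule(DEFAULT) == [10, 15, 20, 25, 30, 35, 40, 45, 50]

    def test_single_look(self):
        d = TrialDesign(n_first_interim=10, n_max=10, cohort_step=5)
        assert interim_schedule(d) == [10]

    def test_capped_sequence(self):
        d = TrialDesign(n_first_interim=4, cohort_step=3, n_max=10)
        assert interim_schedule(d) == [4, 7, 10]

    def test_always_ends_at_n_max(self):
        d = TrialDesign(n_first_interim=10, cohort_step=7, n_max=50)
        sched = interim_schedule(d)
        assert sched[-1] == 50
        assert sched == sorted(set(sched))


# ----------------------------------------------------------- simulate_trial


class TestSimulateTrial:
    def test_zero_orr_stops_at_15_futility(self):
        # under the default posterior rule 0 responders first trigger
        # futility at n = 15 (1 - 0.9^16 >= 0.80)
        for seed in range(5):
            traj = simulate_trial(DEFAULT, 0.0, seed)
            assert traj.final_action == "stop_futility"
            assert traj.final_n == 15
            assert sum(traj.responses) == 0

    def test_certain_response_stops_at_first_look(self):
        traj = simulate_trial(DEFAULT, 1.0, seed=3)
        assert traj.final_action == "stop_efficacy"
        assert traj.final_n == 10

    def test_seed_determinism(self):
        t1 = simulate_trial(DEFAULT, 0.2, seed=42)
        t2 = simulate_trial(DEFAULT, 0.2, seed=42)
        assert t1 == t2

    def test_final_n_on_schedule(self):
        sched = set(interim_schedule(DEFAULT))
        for seed in range(10):
            assert simulate_trial(DEFAULT, 0.15, seed).final_n in sched


# ------------------------------------------------ operating_characteristics


class TestOperatingCharacteristics:
    def test_certain_response(self):
        (oc,) = operating_characteristics(DEFAULT, [1.0], n_sims=50, seed=0)
        assert oc.prob_stop_efficacy == 1.0
        assert oc.expected_n == DEFAULT.n_first_interim

    def test_degenerate_single_look_design(self):
        d = TrialDesign(n_first_interim=10, n_max=10)
        (oc,) = operating_characteristics(d, [0.2], n_sims=200, seed=1)
        assert oc.expected_n == 10

    def test_probabilities_sum_to_one(self):
        results = operating_characteristics(DEFAULT, [0.05, 0.15, 0.3], 400, seed=2)
        for oc in results:
            total = oc.prob_stop_futility + oc.prob_stop_efficacy + oc.prob_run_to_n_max
            assert total == pytest.approx(1.0, abs=1e-12)
            assert sum(oc.stop_stage_distribution.values()) == pytest.approx(1.0)
            assert DEFAULT.n_first_interim <= oc.expected_n <= DEFAULT.n_max

    def test_monotone_in_true_orr(self):
        n_sims = 4000
        low, high = operating_characteristics(DEFAULT, [0.10, 0.25], n_sims, seed=7)
        se = 3 * math.sqrt(0.25 / n_sims)
        assert low.prob_stop_futility >= high.prob_stop_futility - se
        assert low.prob_stop_efficacy <= high.prob_stop_efficacy + se

    def test_extremes_converge(self):
        (fut,) = operating_characteristics(DEFAULT, [0.0], 500, seed=11)
        (eff,) = operating_characteristics(DEFAULT, [1.0], 500, seed=12)
        assert fut.prob_stop_futility == 1.0
        assert eff.prob_stop_efficacy == 1.0

    def test_reproducible(self):
        a = operating_characteristics(DEFAULT, [0.15], 300, seed=9)
        b = operating_characteristics(DEFAULT, [0.15], 300, seed=9)
        assert a == b


# ----------------------------------------------------------- design checks


class TestDesignValidation:
    def test_defaults_valid(self):
        d = TrialDesign()
        assert d.p_futility == 0.10 and d.p_efficacy == 0.25
        assert d.threshold_futility == d.threshold_efficacy == 0.80
        assert d.n_max == 50 and d.evaluation_window_weeks == 16.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"prior_alpha": 0},
            {"p_futility": 0.3, "p_efficacy": 0.2},
            {"threshold_futility": 0.4},
            {"threshold_efficacy": 1.0},
            {"n_first_interim": 0},
            {"n_first_interim": 60},
            {"cohort_step": 0},
            {"rule_interpretation": "magic"},
        ],
    )
    def test_invalid_designs_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            TrialDesign(**kwargs)

    def test_decision_table_covers_schedule(self):
        table = decision_table(DEFAULT)
        assert set(table) == set(interim_schedule(DEFAULT))
        for n, actions in table.items():
            assert len(actions) == n + 1
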