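import math

import numpy as np
import pytest

import noisymh as nm
from noisymh.exact import kernel_tail_rule
from noisymh.kernels import ChainState, make_streams


def brute_force_alpha_n1(ratio, b, eps):
    """Four-outcome hand enumeration of the noisy acceptance at N = 1."""
    s = (1 - eps) / (b - eps)
    total = 0.0
    for u, pu in ((eps, 1 - s), (b, s)):
        for w, pw in ((eps, 1 - s), (b, s)):
            total += pu * pw * min(1.0, ratio * u / w)
    return total


class TestExactNoisyAlpha:
    def test_unit_weights_reduce_to_marginal(self):
        w = nm.unit_weights()
        for ratio in (0.0, 0.3, 1.0, 2.5):
            assert abs(nm.exact_noisy_alpha(1, 2, ratio, w, 1)
                       - min(1.0, ratio)) < 1e-15

    @pytest.mark.parametrize("ratio", [0.05, 0.4, 1.0, 3.0])
    def test_matches_four_term_enumeration(self, ratio):
        b, eps = 3.0, 0.25
        w = nm.two_point_homogeneous(b, eps)
        assert nm.exact_noisy_alpha(1, 2, ratio, w, 1) == pytest.approx(
            brute_force_alpha_n1(ratio, b, eps), abs=1e-14)

    def test_saturates_at_one_for_large_ratio(self):
        b, eps = 3.0, 0.25
        w = nm.two_point_homogeneous(b, eps)
        assert nm.exact_noisy_alpha(1, 2, b / eps, w, 2) == pytest.approx(1.0, abs=1e-14)

    def test_requires_enumerable_weights(self):
        with pytest.raises(ValueError):
            nm.exact_noisy_alpha(1, 2, 0.5, nm.lognormal_base(5.0), 1)

    def test_matches_monte_carlo_step_frequency(self, geometric, symmetric_walk):
        """Empirical acceptance of repeated noisy steps matches the exact sum."""
        w = nm.two_point_homogeneous(3.0, 0.25)
        m = 5
        ratio = geometric.exact_pmf(m + 1) / geometric.exact_pmf(m)
        alpha = nm.exact_noisy_alpha(m, m + 1, ratio, w, 2)
        streams = make_streams(13)
        seen = acc = 0
        for _ in range(40_000):
            _, proposed, accepted = nm.noisy_step(ChainState(m), geometric,
                                                  symmetric_walk, w, 2, streams)
            if proposed == m + 1:
                seen += 1
                acc += accepted
        se = math.sqrt(alpha * (1 - alpha) / seen)
        assert abs(acc / seen - alpha) < 3 * se

    def test_symmetric_ratio_one_accepts_at_least_half(self):
        """For homogeneous weights the ratio W'/W is symmetric about 1."""
        for w in (nm.two_point_homogeneous(3.0, 0.25),
                  nm.two_point_homogeneous(5.0, 0.1)):
            for N in (1, 3):
                assert nm.exact_noisy_alpha(1, 2, 1.0, w, N) >= 0.5 - 1e-12


class TestTransitionTables:
    def test_unit_weights_reproduce_marginal_table(self, geometric, symmetric_walk):
        noisy = nm.noisy_transition_table(geometric, symmetric_walk,
                                          nm.unit_weights(), 1, 50)
        marg = nm.marginal_transition_table(geometric, symmetric_walk, 50)
        assert np.allclose(noisy.p_up, marg.p_up, atol=1e-15)
        assert np.allclose(noisy.p_down, marg.p_down, atol=1e-15)

    def test_rows_sum_to_one(self, transient_homog):
        t, p, w = transient_homog
        table = nm.noisy_transition_table(t, p, w, 3, 80)
        assert np.allclose(table.p_up + table.p_down + table.p_hold, 1.0, atol=1e-12)

    def test_marginal_detailed_balance(self, geometric, symmetric_walk):
        """pi(m) P(m, m+1) = pi(m+1) P(m+1, m) exactly on the window."""
        table = nm.marginal_transition_table(geometric, symmetric_walk, 60)
        for m in range(1, 59):
            lhs = geometric.exact_pmf(m) * table.p_up[m - 1]
            rhs = geometric.exact_pmf(m + 1) * table.p_down[m]
            assert abs(lhs - rhs) < 1e-12

    def test_homogeneous_setting_down_dominates_up(self, geometric, symmetric_walk):
        """Log-concavity plus ratio symmetry: moves towards the mode win."""
        w = nm.two_point_homogeneous(3.0, 0.25)
        table = nm.noisy_transition_table(geometric, symmetric_walk, w, 1, 60)
        assert np.all(table.p_down[1:] >= table.p_up[1:] - 1e-12)

    def test_transient_construction_up_dominates_down(self, transient_homog):
        t, p, w = transient_homog
        table = nm.noisy_transition_table(t, p, w, 1, 60)
        assert np.all(table.p_up[1:] > table.p_down[1:])

    def test_small_window_raises(self, geometric, symmetric_walk):
        with pytest.raises(ValueError):
            nm.noisy_transition_table(geometric, symmetric_walk, nm.unit_weights(), 1, 1)


class TestRecurrenceVerdict:
    def test_marginal_chain_recurrent(self, geometric, symmetric_walk):
        table = nm.marginal_transition_table(geometric, symmetric_walk, 100)
        assert nm.recurrence_verdict(table) == "recurrent"

    def test_transient_constructions(self, transient_homog):
        t, p, w = transient_homog
        table = nm.noisy_transition_table(t, p, w, 1, 100)
        rule = kernel_tail_rule(t, p, w, 1)
        assert nm.recurrence_verdict(table, rule) == "transient"

    def test_state_dependent_transient_needs_tail_rule(self):
        """The theta=0.25 construction is transient only asymptotically."""
        t, p, w = nm.transient_state_dependent_config(0.25)
        table = nm.noisy_transition_table(t, p, w, 1, 100)
        rule = kernel_tail_rule(t, p, w, 1)
        assert nm.recurrence_verdict(table, rule) == "transient"

    def test_explicit_tail_limit_overrides(self, geometric, symmetric_walk):
        table = nm.marginal_transition_table(geometric, symmetric_walk, 50)
        assert nm.recurrence_verdict(table, tail_ratio_limit=0.5) == "transient"
        assert nm.recurrence_verdict(table, tail_ratio_limit=1.0) == "inconclusive"


class TestDriftCheck:
    def test_marginal_drift_holds(self, geometric, symmetric_walk):
        table = nm.marginal_transition_table(geometric, symmetric_walk, 200)
        V = nm.pmf_power_drift_function(geometric, 0.5)
        rep = nm.drift_check(table, V)
        assert rep.verdict and rep.lambda_hat < 1.0

    def test_ergodic_homogeneous_construction(self):
        t, p, w = nm.homogeneous_geometric_config()
        table = nm.noisy_transition_table(t, p, w, 1, 200)
        rep = nm.drift_check(table, nm.pmf_power_drift_function(t, 0.5))
        assert rep.verdict

    def test_transient_table_fails_drift(self, transient_homog):
        t, p, w = transient_homog
        table = nm.noisy_transition_table(t, p, w, 1, 200)
        rep = nm.drift_check(table, nm.pmf_power_drift_function(t, 0.5))
        assert not rep.verdict and rep.lambda_hat > 1.0

    def test_v_below_one_raises(self, geometric, symmetric_walk):
        table = nm.marginal_transition_table(geometric, symmetric_walk, 50)
        with pytest.raises(ValueError):
            nm.drift_check(table, lambda m: 0.5)


class TestErgodicityVsN:
    def test_averaging_recovers_ergodicity(self, transient_homog):
        """The transient construction becomes geometrically ergodic at finite N*."""
        t, p, w = transient_homog
        out = nm.ergodicity_vs_N(t, p, w, [1, 2, 5, 10], 200)
        assert out.loc[out["N"] == 1, "recurrence"].iloc[0] == "transient"
        assert not out.loc[out["N"] == 1, "drift_verdict"].iloc[0]
        n_star = out.attrs["N_star"]
        assert n_star is not None
        assert (out.loc[out["N"] >= n_star, "lambda_hat"] < 1.0).all()

    def test_growing_b_transient_for_all_N(self):
        t, p, w = nm.persistent_transient_config()
        out = nm.ergodicity_vs_N(t, p, w, [1, 2, 5, 10], 200)
        assert (out["recurrence"] == "transient").all()

    def test_converging_eps_ratio_ergodic_at_n1(self, geometric, symmetric_walk):
        """b_m -> inf, eps_m -> 0 with converging eps-ratio: ergodic at every N.

        One concrete member of the family: b_m = 1 + log(1 + m), eps_m = 1/m.
        """
        w = nm.two_point_state_dependent(lambda m: 1.0 + math.log(1.0 + m),
                                         lambda m: 1.0 / m)
        out = nm.ergodicity_vs_N(geometric, symmetric_walk, w, [1, 2], 200)
        assert out["drift_verdict"].all()


class TestBoundInequalities:
    def test_noisy_alpha_bounded_by_neg_moment(self, enumerable_weight_models):
        """alpha~_N(x,y) <= alpha(x,y) E[W_{x,N}^{-1}] on every enumerated model."""
        for w in enumerable_weight_models.values():
            for ratio in (0.2, 0.8, 1.5):
                for N in (1, 3):
                    x, y = 5, 6
                    lhs = nm.exact_noisy_alpha(x, y, ratio, w, N)
                    rhs = min(1.0, ratio) * w.neg_moment(x, N)
                    assert lhs <= rhs + 1e-12

    @pytest.mark.parametrize("eta", [0.1, 0.5])
    def test_additive_alpha_difference_bound(self, enumerable_weight_models, eta):
        """alpha~ - alpha <= eta + 2 sup_x P[|W - 1| >= eta/(2(1+eta))]."""
        states = [2, 3, 5, 8, 13, 50]
        delta = eta / (2 * (1 + eta))
        for w in enumerable_weight_models.values():
            for N in (1, 2):
                tail = nm.check_W1(w, states, [N], delta)["sup_prob"].iloc[0]
                for ratio in (0.3, 1.0, 2.0):
                    for x in (2, 5):
                        diff = (nm.exact_noisy_alpha(x, x + 1, ratio, w, N)
                                - min(1.0, ratio))
                        assert diff <= eta + 2 * tail + 1e-12
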