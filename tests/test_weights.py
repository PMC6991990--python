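import math

import numpy as np
import pytest
from scipy import stats

import noisymh as nm


def enumerated_mean(atoms):
    return sum(v * p for v, p in atoms)


class TestUnitWeights:
    def test_degenerate(self):
        w = nm.unit_weights()
        rng = np.random.default_rng(0)
        assert w.sample(3, 10, rng) == 1.0
        assert w.enumerate(3, 7) == [(1.0, 1.0)]
        assert w.neg_moment(3, 7) == 1.0


class TestLogNormal:
    def test_unit_mean_monte_carlo(self):
        w = nm.lognormal_base(5.0)
        rng = np.random.default_rng(3)
        draws = w.sample_many(0.0, 1, 100_000, rng)
        se = draws.std(ddof=1) / math.sqrt(draws.size)
        assert abs(draws.mean() - 1.0) < 4 * se

    def test_neg_moment_closed_form(self):
        # E[W^{-1}] = exp(-mu + s2/2) = exp(s2) with mu = -s2/2
        assert nm.lognormal_base(5.0).neg_moment(0.0, 1) == pytest.approx(math.exp(5.0))

    def test_invalid_sigma2(self):
        with pytest.raises(ValueError):
            nm.lognormal_base(0.0)


class TestTwoPointHomogeneous:
    def test_transient_construction_parameters(self):
        # eps = 2 - sqrt(3), b = 2 eps theta/(1-theta) at theta = 0.75
        eps = 2.0 - math.sqrt(3.0)
        b = 2.0 * eps * 3.0
        w = nm.two_point_homogeneous(b, eps)
        atoms = w.enumerate(1, 1)
        assert enumerated_mean(atoms) == pytest.approx(1.0, abs=1e-12)
        assert b / eps == pytest.approx(6.0)

    def test_neg_moment_two_atom_formula(self):
        b, eps = 3.0, 0.25
        w = nm.two_point_homogeneous(b, eps)
        s = (1 - eps) / (b - eps)
        assert w.neg_moment(0, 1) == pytest.approx((1 - s) / eps + s / b)

    @pytest.mark.parametrize("b,eps", [(1.0, 0.5), (0.9, 0.5), (2.0, 0.0), (2.0, 1.0)])
    def test_invalid_parameters(self, b, eps):
        with pytest.raises(ValueError):
            nm.two_point_homogeneous(b, eps)

    @pytest.mark.parametrize("N", [1, 2, 5])
    def test_unit_mean_preserved_under_averaging(self, N):
        w = nm.two_point_homogeneous(3.0, 0.25)
        assert enumerated_mean(w.enumerate(0, N)) == pytest.approx(1.0, abs=1e-12)

    def test_average_n2_binomial_atoms(self):
        b, eps = 3.0, 0.25
        w = nm.two_point_homogeneous(b, eps)
        s = (1 - eps) / (b - eps)
        atoms = sorted(w.enumerate(0, 2))
        assert len(atoms) == 3
        vals = [a[0] for a in atoms]
        probs = [a[1] for a in atoms]
        assert vals == pytest.approx([eps, (eps + b) / 2, b])
        assert probs == pytest.approx([(1 - s) ** 2, 2 * s * (1 - s), s ** 2])

    def test_sampling_frequencies_match_enumeration(self):
        """Chi-square goodness of fit of N-average draws against the binomial atoms."""
        w = nm.two_point_homogeneous(3.0, 0.25)
        N, n = 4, 50_000
        atoms = w.enumerate(0, N)
        rng = np.random.default_rng(7)
        draws = w.sample_many(0, N, n, rng)
        vals = np.array([a[0] for a in atoms])
        expected = np.array([a[1] for a in atoms]) * n
        counts = np.array([(np.abs(draws - v) < 1e-9).sum() for v in vals])
        chi2 = ((counts - expected) ** 2 / expected).sum()
        assert stats.chi2.sf(chi2, df=len(vals) - 1) > 0.001


class TestTwoPointStateDependent:
    def test_mod3_sequence_value(self):
        # eps_3 = 3^{-3} = 1/27 on the m mod 3 = 0 branch
        assert nm.eps_mod3(3) == pytest.approx(1.0 / 27.0)
        assert nm.eps_mod3(2) == pytest.approx(0.5)

    def test_fig_configuration_atoms(self):
        _, _, w = nm.transient_state_dependent_config(0.5)
        b = 3.0 + 1.0  # 3 + ((1-theta)/theta)^3 at theta = 0.5
        atoms = dict(w.enumerate(3, 1))
        assert any(abs(v - 1.0 / 27.0) < 1e-12 for v in atoms)
        assert any(abs(v - b) < 1e-12 for v in atoms)
        assert enumerated_mean(list(atoms.items())) == pytest.approx(1.0, abs=1e-12)

    def test_growing_b_sequence(self):
        _, _, w = nm.persistent_transient_config()
        atoms = sorted(w.enumerate(5, 1))
        assert atoms[-1][0] == 5.0  # b_m = m

    def test_degenerate_eps_one(self):
        # eps_1 = 1 forces W = 1 regardless of b
        _, _, w = nm.persistent_transient_config()
        assert w.enumerate(1, 1) == [(1.0, 1.0)]

    def test_invalid_sequences_raise(self):
        w = nm.two_point_state_dependent(lambda m: 0.5, nm.eps_mod3)
        with pytest.raises(ValueError):
            w.enumerate(2, 1)  # b_m = 0.5 <= 1
        w2 = nm.two_point_state_dependent(3.0, lambda m: 1.5)
        with pytest.raises(ValueError):
            w2.enumerate(2, 1)


class TestArithmeticAverage:
    def test_n1_identical_law(self):
        base = nm.two_point_homogeneous(3.0, 0.25)
        avg = nm.arithmetic_average(base, 1)
        assert avg.enumerate(0, 1) == base.enumerate(0, 1)

    def test_frozen_n_enumeration(self):
        base = nm.two_point_homogeneous(3.0, 0.25)
        avg = nm.arithmetic_average(base, 3)
        assert avg.enumerate(0, 1) == base.enumerate(0, 3)

    @pytest.mark.parametrize("model_key", ["two_point_generic", "state_dep_mod3"])
    def test_neg_moment_monotone_in_N(self, enumerable_weight_models, model_key):
        """Averaging never increases the first negative moment."""
        w = enumerable_weight_models[model_key]
        vals = [w.neg_moment(5, N) for N in range(1, 12)]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))


class TestConditionChecks:
    def test_w1_unit_weights_zero(self):
        out = nm.check_W1(nm.unit_weights(), [1, 5], [1, 10], delta=0.1)
        assert (out["sup_prob"] == 0.0).all()

    def test_w1_two_point_exact_value(self):
        b, eps = 3.0, 0.25
        w = nm.two_point_homogeneous(b, eps)
        s = (1 - eps) / (b - eps)
        out = nm.check_W1(w, [1], [1], delta=0.5)
        # both atoms are further than 0.5 from 1, so the probability is 1
        assert out["sup_prob"].iloc[0] == pytest.approx(1.0)
        out2 = nm.check_W1(w, [1], [1], delta=1.99)
        assert out2["sup_prob"].iloc[0] == pytest.approx(s)  # only b = 3 is that far

    def test_w1_decreasing_for_averages(self):
        w = nm.two_point_homogeneous(3.0, 0.25)
        out = nm.check_W1(w, [1, 100], [1, 4, 16, 64], delta=0.5)
        assert out.attrs["decreasing"]

    def test_w1_lognormal_monte_carlo_decreasing(self):
        w = nm.lognormal_base(5.0)
        out = nm.check_W1(w, [0.0], [10, 1000], delta=0.5, n_mc=20_000, seed=5)
        assert out["sup_prob"].iloc[1] < out["sup_prob"].iloc[0]
        assert (out["method"] == "monte_carlo").all()

    def test_w1_empty_states_raises(self):
        with pytest.raises(ValueError):
            nm.check_W1(nm.unit_weights(), [], [1], delta=0.1)

    def test_negative_moment_exact_and_sup(self):
        w = nm.two_point_homogeneous(3.0, 0.25)
        out = nm.check_negative_moment(w, [1, 7], [1, 4, 16])
        assert (out["method"] == "exact").all()
        sups = out.attrs["sup_by_N"]
        assert sups[16] <= sups[4] <= sups[1]
        assert out.attrs["approaches_one"]
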