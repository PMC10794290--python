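"""Log-space likelihood machinery against exact linear-domain oracles."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import _oracles as oracle
from lfdr_snv.counts_io import SiteCounts
from lfdr_snv.likelihood import (
    LossSpec,
    ModelParams,
    category_probs,
    decide,
    lfdr,
    lfdr_arrays,
    lfdr_from_bayes_factor,
    log_alt_likelihood_at_theta,
    log_alt_likelihood_empirical,
    log_alt_likelihood_empirical_arrays,
    log_multinomial_coef,
    log_null_likelihood,
    log_null_likelihood_arrays,
)


def site(r, m, x1=0, x2=0):
    """Bare count tuple for likelihood evaluation; unlike SiteCounts it does
    not require the dominant-allele ordering, so arbitrary compositions can
    be enumerated."""
    from types import SimpleNamespace

    return SimpleNamespace(K=r + m + x1 + x2, R=r, M=m, X1=x1, X2=x2)


class TestLogMultinomialCoef:
    @pytest.mark.parametrize("counts,expected", [
        ((2, 1, 1, 0, 0), math.log(2)),   # two orderings
        ((7, 7, 0, 0, 0), 0.0),           # single arrangement
        ((3, 1, 1, 1, 0), math.log(6)),   # 3! arrangements
    ])
    def test_small_enumerations(self, counts, expected):
        assert log_multinomial_coef(*counts) == pytest.approx(expected, abs=1e-12)

    def test_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            log_multinomial_coef(5, 1, 1, 1, 1)


class TestNullLikelihood:
    def test_all_reference(self):
        assert log_null_likelihood(site(10, 0), 0.01) == pytest.approx(10 * math.log(0.99))

    def test_error_free_all_reference_is_certain(self):
        assert log_null_likelihood(site(10, 0), 0.0) == 0.0

    def test_alternative_reads_impossible_without_error(self):
        assert log_null_likelihood(site(9, 1), 0.0) == -math.inf

    def test_total_probability_over_compositions(self):
        # summing the null pmf over every (R, M, X1, X2) composition must give 1
        for k in (1, 5, 12):
            total = sum(
                math.exp(log_null_likelihood(site(*c), 0.05))
                for c in oracle.all_compositions(k)
            )
            assert total == pytest.approx(1.0, abs=1e-10)


class TestAltLikelihood:
    def test_exact_binomial_arithmetic(self):
        # theta=0.5, e=0: heterozygous site with one ref and one alt read
        assert log_alt_likelihood_at_theta(site(1, 1), 0.0, 0.5) == pytest.approx(math.log(0.5))

    def test_theta_zero_equals_null(self):
        s = site(8, 2, 1, 0)
        assert log_alt_likelihood_at_theta(s, 0.01, 0.0) == pytest.approx(
            log_null_likelihood(s, 0.01), rel=1e-12)

    def test_pure_alternative_certainty(self):
        assert log_alt_likelihood_at_theta(site(0, 7), 0.0, 1.0) == 0.0

    def test_single_atom_reduction(self):
        s = site(5, 5)
        assert log_alt_likelihood_empirical(s, 0.01, [0.5]) == pytest.approx(
            log_alt_likelihood_at_theta(s, 0.01, 0.5))

    def test_two_atoms_average_in_linear_domain(self):
        s = site(3, 2)
        lin = np.mean([math.exp(log_alt_likelihood_at_theta(s, 0.05, t)) for t in (0.3, 0.7)])
        assert log_alt_likelihood_empirical(s, 0.05, [0.3, 0.7]) == pytest.approx(math.log(lin))

    def test_duplicate_atom_invariance(self):
        s = site(4, 6)
        one = log_alt_likelihood_empirical(s, 0.01, [0.4])
        many = log_alt_likelihood_empirical(s, 0.01, [0.4] * 7)
        assert many == pytest.approx(one, rel=1e-12)

    def test_empty_atoms_rejected(self):
        with pytest.raises(ValueError):
            log_alt_likelihood_empirical(site(1, 1), 0.01, [])

    @given(st.floats(0, 1), st.floats(0.001, 0.999))
    def test_category_probs_normalize(self, theta, e):
        assert sum(category_probs(theta, e)) == pytest.approx(1.0, abs=1e-12)


class TestOracleEquivalence:
    """Log-space values match exact rational linear-domain arithmetic."""

    @pytest.mark.parametrize("e", [Fraction(1, 100), Fraction(1, 10)])
    def test_null_and_alt_match_rational_oracle(self, e):
        atoms = [Fraction(i, 10) for i in range(1, 10)]
        ef = float(e)
        for k in (0, 1, 4, 9):
            for c in oracle.all_compositions(k):
                s = site(*c)
                got0 = log_null_likelihood(s, ef)
                exp0 = oracle.log_of_fraction(oracle.rational_null_likelihood(*c, e))
                assert got0 == pytest.approx(exp0, rel=1e-10, abs=1e-10)
                got1 = log_alt_likelihood_empirical(s, ef, [float(t) for t in atoms])
                exp1 = oracle.log_of_fraction(
                    oracle.rational_alt_likelihood_mixture(*c, e, atoms))
                assert got1 == pytest.approx(exp1, rel=1e-10, abs=1e-10)

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(5)
        n = 60
        m = rng.integers(0, 30, n)
        r = rng.integers(0, 30, n)
        x1 = rng.integers(0, 3, n)
        x2 = np.minimum(x1, rng.integers(0, 3, n))
        mm = np.maximum(m, x1)
        k = r + mm + x1 + x2
        e = rng.uniform(0.001, 0.2, n)
        atoms = rng.uniform(0.05, 1.0, 13)
        sites = [site(int(a), int(b), int(c), int(d)) for a, b, c, d in zip(r, mm, x1, x2)]
        vec0 = log_null_likelihood_arrays(k, r, mm, x1, x2, e)
        vec1 = log_alt_likelihood_empirical_arrays(k, r, mm, x1, x2, e, atoms, block_size=7)
        for i, s in enumerate(sites):
            assert vec0[i] == pytest.approx(log_null_likelihood(s, e[i]), rel=1e-12)
            assert vec1[i] == pytest.approx(
                log_alt_likelihood_empirical(s, e[i], atoms), rel=1e-12)


class TestLfdr:
    def test_pi0_boundaries_exact(self):
        assert lfdr(-5.0, -1.0, 1.0).psi == 1.0
        assert lfdr(-5.0, -1.0, 0.0).psi == 0.0

    def test_equal_evidence_returns_pi0(self):
        res = lfdr(-3.7, -3.7, 0.3)
        assert res.psi == pytest.approx(0.3, rel=1e-12)

    def test_both_zero_likelihood_flagged(self):
        res = lfdr(-math.inf, -math.inf, 0.5)
        assert res.flagged and math.isnan(res.psi)

    def test_extreme_ratio_no_underflow(self):
        res = lfdr(-1000 * math.log(10), 0.0, 0.5)
        import mpmath
        mpmath.mp.dps = 60
        expected = mpmath.log(1 / (1 + mpmath.mpf(10) ** 1000), 10)
        assert res.log10_psi == pytest.approx(float(expected), abs=1e-6)
        assert res.psi == 0.0  # below linear range, by design

    def test_monotone_evidence_in_m(self):
        # more alternative reads can only decrease the posterior null probability
        params = ModelParams(pi0=0.95, theta_atoms=np.array([0.5]))
        vals = []
        for m in range(31):
            s = site(30 - m, m)
            l0 = log_null_likelihood(s, 0.01)
            l1 = log_alt_likelihood_empirical(s, 0.01, params.theta_atoms)
            vals.append(lfdr(l0, l1, params.pi0).log10_psi)
        assert all(b <= a + 1e-12 for a, b in zip(vals, vals[1:]))

    @given(st.floats(-50, 50), st.floats(0.001, 0.999))
    def test_bayes_factor_identity(self, log_bf, pi0):
        direct = lfdr_from_bayes_factor(log_bf, pi0)
        via_likelihoods = lfdr(log_bf - 3.0, -3.0, pi0)
        assert direct.log10_psi == pytest.approx(via_likelihoods.log10_psi, rel=1e-9, abs=1e-12)

    def test_bayes_factor_boundaries(self):
        assert lfdr_from_bayes_factor(0.0, 0.5).psi == pytest.approx(0.5)
        assert lfdr_from_bayes_factor(12.0, 0.0).psi == 0.0

    def test_array_form_matches_scalar(self):
        lp0 = np.array([-3.0, -700.0, -1.0])
        lp1 = np.array([-5.0, -1.0, -2500.0])
        got = lfdr_arrays(lp0, lp1, 0.9)
        for i in range(3):
            assert got[i] == pytest.approx(lfdr(lp0[i], lp1[i], 0.9).log10_psi, rel=1e-12)


class TestDecide:
    def test_boundary_inclusive(self):
        res = lfdr(-1.0, -1.0, 0.5)  # psi = 0.5
        assert decide(res, LossSpec(l_I=1, l_II=1)) == 1

    def test_above_threshold_not_called(self):
        res = lfdr(math.log(0.6) , math.log(0.4), 0.5)  # psi = 0.6
        assert decide(res, LossSpec(l_I=1, l_II=1)) == 0

    def test_loss_ratio_threshold(self):
        # a missed variant nine times as costly as a false call raises the
        # call threshold to 9/(1+9) = 0.9
        res = lfdr(math.log(0.85), math.log(0.15), 0.5)  # psi = 0.85
        assert LossSpec(l_I=1, l_II=9).threshold == pytest.approx(0.9)
        assert decide(res, LossSpec(l_I=1, l_II=9)) == 1
        assert decide(res, LossSpec(l_I=9, l_II=1)) == 0

    def test_explicit_tau_wins(self):
        assert LossSpec(l_I=9, l_II=1, tau=0.25).threshold == 0.25

    def test_rule_minimizes_posterior_loss_small(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            p = int(rng.integers(1, 9))
            psi = rng.random(p)
            l_i, l_ii = rng.uniform(0.1, 5, 2)
            tau = LossSpec(l_I=l_i, l_II=l_ii).threshold
            delta = [1 if x <= tau else 0 for x in psi]
            achieved = oracle.posterior_expected_loss(delta, psi, l_i, l_ii)
            best = oracle.best_decision_by_enumeration(psi, l_i, l_ii)
            assert achieved == pytest.approx(best, abs=1e-12)
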