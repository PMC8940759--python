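"""Incomplete beta (negative parameter), confluent hypergeometric, Q."""

import mpmath as mp
import pytest
from hypothesis import given, settings, strategies as st

import gpcpk as g
from gpcpk.policy import matching_digits

POL = g.PrecisionPolicy(target_digits=65)


def mp_betainc(z, A, B, dps=90):
    """Independent oracle: mpmath's hypergeometric-based incomplete beta."""
    with mp.workdps(dps):
        return mp.betainc(mp.mpf(A), mp.mpf(B), 0, mp.mpf(z))


class TestBetaInc:
    def test_endpoints(self):
        assert g.beta_inc(0, 2.5, -0.7, POL) == 0
        # B_1(A,B) is the complete beta when finite
        v = g.beta_inc(1, 2.0, 3.0, POL)
        with mp.workdps(80):
            assert matching_digits(v, mp.beta(2, 3)) >= 60

    def test_uniform_cdf(self):
        for z in (0.1, 0.5, 0.9):
            assert matching_digits(g.beta_inc(z, 1, 1, POL), mp.mpf(z)) >= 60

    @pytest.mark.parametrize(
        "z,A,B",
        [
            (0.3, 2.5, -0.7),       # negative second parameter
            (0.9, 1.35, -0.2644),   # reflection route, GPC-like values
            (0.2, 0.35, -0.26),
            (0.7, 4.2, 1.3),        # positive-parameter sanity
        ],
    )
    def test_against_mpmath_oracle(self, z, A, B):
        v = g.beta_inc(z, A, B, POL)
        assert matching_digits(v, mp_betainc(z, A, B)) >= 60

    def test_negative_parameter_vs_quadrature(self):
        # directly integrate u^(A-1) (1-u)^(B-1) on (0, 0.3)
        with mp.workdps(80):
            A, B, z = mp.mpf(2.5), mp.mpf(-0.7), mp.mpf(0.3)
            q = mp.quad(lambda u: u ** (A - 1) * (1 - u) ** (B - 1), [0, z])
        assert matching_digits(g.beta_inc(0.3, 2.5, -0.7, POL), q) >= 30

    def test_domain_and_pole_errors(self):
        with pytest.raises(g.DomainError):
            g.beta_inc(1.2, 1.0, 1.0, POL)
        with pytest.raises(g.PoleError):
            g.beta_inc(1.0, 1.5, -2.0, POL)  # complete beta at pole
        with pytest.raises(g.PoleError):
            g.beta_inc(0.4, -3.0, 0.5, POL)  # nonpositive-integer A

    def test_monotone_in_z_for_positive_B(self):
        vals = [g.beta_inc(z, 1.7, 0.4, POL) for z in (0.1, 0.3, 0.6, 0.95)]
        assert all(v2 > v1 for v1, v2 in zip(vals, vals[1:]))


class TestReflectAndIbp:
    def test_reflection_z1_is_zero(self):
        assert g.beta_inc_reflect(1, 1.3, 0.7, POL) == 0

    def test_symmetry_point(self):
        direct = g.beta_inc(0.5, 0.5, 0.5, POL)
        refl = g.beta_inc_reflect(0.5, 0.5, 0.5, POL)
        assert matching_digits(direct, refl) >= 60

    def test_cross_route_negative_parameter(self):
        # B_{0.875}(1.35, -0.2644) two ways; dyadic z so 1-z is exact
        refl = g.beta_inc_reflect(0.125, 1.35, -0.2644, POL)
        direct = g.beta_inc(0.875, 1.35, -0.2644, POL)
        assert matching_digits(refl, direct) >= 60

    @pytest.mark.parametrize("z,A,B", [(0.4, 1.0, 1.0), (0.2, 0.35, -0.26),
                                       (0.8, 2.1, 0.9)])
    def test_ibp_identity_routes_agree(self, z, A, B):
        via_identity = g.beta_ibp_reduce(z, A, B, POL)
        with mp.workdps(90):
            direct = g.beta_inc(z, mp.mpf(A) + 1, B, POL)
        assert matching_digits(via_identity, direct) >= 55

    def test_ibp_simple_closed_form(self):
        # A=B=1: B_z(2,1) = z^2/2
        with mp.workdps(90):
            z = mp.mpf(0.37)
            ref = z**2 / 2
        assert matching_digits(g.beta_ibp_reduce(0.37, 1, 1, POL), ref) >= 60

    def test_ibp_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            g.beta_ibp_reduce(0.4, 0.5, -0.5, POL)

    @settings(max_examples=25, deadline=None)
    @given(
        z=st.floats(0.05, 0.95),
        A=st.floats(0.3, 4.0),
        B=st.floats(0.2, 3.0),
    )
    def test_routes_agree_property(self, z, A, B):
        with mp.workdps(90):
            zc = 1 - mp.mpf(z)
            direct = g.beta_inc(zc, A, B, POL)
        refl = g.beta_inc_reflect(z, A, B, POL)
        assert matching_digits(direct, refl) >= 55


class TestHyp1F1:
    def test_at_zero(self):
        assert matching_digits(g.hyp1f1(0.7, 2.3, 0, POL), mp.mpf(1)) >= 60

    def test_equal_params_is_exp(self):
        with mp.workdps(80):
            assert matching_digits(g.hyp1f1(0.31, 0.31, 2.5, POL),
                                   mp.e ** mp.mpf("2.5")) >= 60

    def test_terminating_vs_direct_series_large_negative_x(self):
        # brute-force direct series at heavily elevated precision
        A, k, x = 0.3493, 3, -100.0
        with mp.workdps(220):
            s = mp.mpf(0)
            for n in range(2000):
                s += (mp.rf(mp.mpf(A), n) * mp.mpf(x) ** n
                      / (mp.rf(mp.mpf(A) - k, n) * mp.factorial(n)))
        v = g.hyp1f1(A, A - k, x, POL)
        assert matching_digits(v, s) >= 50

    def test_pole_error(self):
        with pytest.raises(g.PoleError):
            g.hyp1f1(0.5, -2.0, 1.0, POL)


class TestHyp1F1Reg:
    def test_at_zero_is_reciprocal_gamma(self):
        with mp.workdps(80):
            assert matching_digits(g.hyp1f1_reg(0.7, 2.3, 0, POL),
                                   mp.rgamma(mp.mpf(2.3))) >= 55

    def test_matches_unregularised_at_positive_B(self):
        with mp.workdps(80):
            ref = g.hyp1f1(0.4, 2.0, -1.5, POL) / mp.gamma(2)
        assert matching_digits(g.hyp1f1_reg(0.4, 2.0, -1.5, POL), ref) >= 55

    def test_gpc_asymptote_arguments_vs_gamma_regularised_series(self):
        # direct entire series sum_n (A)_n x^n / (Gamma(B+n) n!) as the oracle
        A, B, x = 0.2644 + 0.3493, 0.3493 - 0.2644, -50.0
        with mp.workdps(160):
            s = mp.mpf(0)
            for n in range(1200):
                s += (mp.rf(mp.mpf(A), n) * mp.mpf(x) ** n
                      * mp.rgamma(mp.mpf(B) + n) / mp.factorial(n))
        assert matching_digits(g.hyp1f1_reg(A, B, x, POL), s) >= 45

    def test_continuous_across_nonpositive_integer_B(self):
        eps = 1e-30
        at_pole = g.hyp1f1_reg(0.7, -2.0, 1.3, POL)
        near = g.hyp1f1_reg(0.7, -2.0 + eps, 1.3, POL)
        assert matching_digits(at_pole, near) >= 25


class TestGammaQ:
    def test_at_zero(self):
        assert g.gamma_reg_Q(0.3493, 0, POL) == 1

    def test_exponential_tail(self):
        with mp.workdps(80):
            assert matching_digits(g.gamma_reg_Q(1, 2.5, POL),
                                   mp.e ** mp.mpf("-2.5")) >= 60

    def test_vs_quadrature(self):
        a, x = 0.3493, 2.5
        with mp.workdps(60):
            q = mp.quad(lambda u: u ** (mp.mpf(a) - 1) * mp.e ** (-u),
                        [x, mp.inf]) / mp.gamma(a)
        assert matching_digits(g.gamma_reg_Q(a, x, POL), q) >= 30

    def test_complement_and_monotonicity(self):
        with mp.workdps(80):
            for x in (0.1, 1.0, 7.0):
                P = mp.gammainc(mp.mpf(0.62), 0, x, regularized=True)
                Q = g.gamma_reg_Q(0.62, x, POL)
                assert matching_digits(P + Q, mp.mpf(1)) >= 55
        vals = [g.gamma_reg_Q(0.62, x, POL) for x in (0.1, 1.0, 7.0, 30.0)]
        assert all(v2 < v1 for v1, v2 in zip(vals, vals[1:]))

    def test_domain_error(self):
        with pytest.raises(g.DomainError):
            g.gamma_reg_Q(-1.0, 2.0, POL)


class TestPochhammer:
    def test_definition(self):
        assert g.pochhammer(0.6507, 0) == 1
        with mp.workdps(40):
            assert matching_digits(g.pochhammer(1, 5), mp.factorial(5)) >= 30
            ref = mp.mpf("0.6507") * mp.mpf("1.6507") * mp.mpf("2.6507")
            assert matching_digits(g.pochhammer(0.6507, 3), ref) >= 14
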