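"""Short-t and long-t series engines against independent oracles."""

import math

import mpmath as mp
import pytest

import gpcpk as g
from gpcpk.policy import matching_digits
from conftest import random_params

POL30 = g.PrecisionPolicy(target_digits=30)
POL65 = g.PrecisionPolicy(target_digits=65)


class TestComponentDensities:
    def test_pareto_step(self, dog1):
        assert g.pd_pdf(dog1.beta_h, dog1.alpha, dog1.beta_h) == 0
        assert g.pd_pdf(dog1.beta_h / 2, dog1.alpha, dog1.beta_h) == 0
        assert g.pd_pdf(2 * dog1.beta_h, dog1.alpha, dog1.beta_h) > 0

    def test_pareto_closed_form_alpha1(self):
        # alpha=1 at t=2*beta: (1/t)(beta/t) = beta/(4 beta^2) = 1/(4 beta)
        beta = 0.25
        v = g.pd_pdf(2 * beta, 1.0, beta)
        assert matching_digits(v, mp.mpf(1) / (4 * beta)) >= 25

    def test_gamma_normalisation(self):
        with mp.workdps(40):
            q = mp.quad(lambda t: g.gd_pdf(t, 0.7, 2.0), [0, 5, mp.inf])
        assert matching_digits(q, mp.mpf(1)) >= 20


class TestQuadratureOracle:
    def test_zero_below_beta(self, dog1):
        assert g.conv_quadrature_oracle(dog1.beta_h / 2, dog1) == 0

    @pytest.mark.parametrize(
        "params,t",
        [(g.GPCParams(0.5, 1.0, 0.5, 0.1), 0.3), (None, 1.0)],
    )
    def test_density_matches_oracle(self, dog1, params, t):
        p = params or dog1
        oracle = g.conv_quadrature_oracle(t, p, g.PrecisionPolicy(target_digits=40))
        v = g.evaluate_short("pdf", t, p, POL65)
        assert matching_digits(v.value, oracle) >= 30

    def test_random_sweep(self, rng):
        for p in random_params(rng, 4):
            t = float(rng.uniform(2 * p.beta_h, 20.0 / p.b))
            oracle = g.conv_quadrature_oracle(t, p, g.PrecisionPolicy(target_digits=35))
            v = g.evaluate_short("pdf", t, p, POL65)
            assert matching_digits(v.value, oracle) >= 25


class TestScan:
    def test_monotone_terms_near_beta(self, dog1):
        # just above beta the magnitude sequence starts at its maximum
        t = dog1.beta_h * 1.01
        n, mx = g.scan_short_terms("pdf", t, dog1, POL65)
        from gpcpk.engines import _short_term_log10
        z = 1.0 - dog1.beta_h / t
        assert mx == round(_short_term_log10("pdf", 0, t, dog1, z))

    def test_counts_grow_with_t(self, dog1):
        n1, m1 = g.scan_short_terms("pdf", 1.0, dog1, POL65)
        n2, m2 = g.scan_short_terms("pdf", 72.0, dog1, POL65)
        n3, m3 = g.scan_short_terms("pdf", 1000.0, dog1, POL65)
        assert n1 < n2 < n3 and m1 < m2 < m3

    def test_domain_error(self, dog1):
        with pytest.raises(g.DomainError):
            g.scan_short_terms("pdf", dog1.beta_h / 2, dog1, POL65)


class TestShortEngine:
    def test_zero_at_and_below_beta(self, dog1):
        for kind in g.FUNCTION_KINDS:
            r = g.evaluate_short(kind, dog1.beta_h, dog1, POL65)
            assert r.value == 0 and r.n_terms == 0

    def test_terms_alternate_and_decrease_below_4beta(self, dog1):
        # Summand sign alternation and monotone decay in the short regime
        from gpcpk.engines import _short_summand_mp
        with mp.workdps(60):
            t = mp.mpf(3.5) * dog1.beta_h
            terms = [_short_summand_mp("pdf", n, t, dog1, POL30) for n in range(8)]
        signs = [mp.sign(x) for x in terms]
        assert all(s1 == -s2 for s1, s2 in zip(signs, signs[1:]))
        mags = [abs(x) for x in terms]
        assert all(m2 < m1 for m1, m2 in zip(mags, mags[1:]))

    def test_cdf_matches_quadrature_of_density(self):
        p = g.GPCParams(0.5, 1.0, 0.5, 0.01)
        pol = g.PrecisionPolicy(target_digits=40)
        with mp.workdps(60):
            q = mp.quad(lambda u: g.evaluate_short("pdf", u, p, pol).value,
                        [p.beta_h, 0.1, 0.5])
        v = g.evaluate_short("cdf", 0.5, p, POL65)
        assert matching_digits(v.value, q) >= 25


class TestLongEngine:
    @pytest.mark.parametrize("kind", g.FUNCTION_KINDS)
    @pytest.mark.parametrize("t", [0.05, 1.0, 12.0])
    def test_branch_agreement_all_kinds(self, dog1, kind, t):
        s = g.evaluate_short(kind, t, dog1, POL30)
        l = g.evaluate_long(kind, t, dog1, POL30)
        # the absolute 10^-30 stopping rule leaves slightly fewer relative
        # digits for kinds whose values are far below 1 (e.g. deriv ~ 1e-4)
        assert matching_digits(s.value, l.value) >= 26

    def test_single_term_at_half_year(self, dog1):
        r = g.evaluate_long("pdf", 4396.0, dog1, POL65)
        assert r.n_terms == 1
        # that only term is vanishingly small (order 10^-1400)
        assert r.max_term_log10 < -1000

    def test_cdf_approaches_one_from_below(self, dog1):
        vals = [float(g.evaluate_long("cdf", t, dog1, POL30).value)
                for t in (1e2, 1e4, 1e6, 1e8)]
        assert all(v2 > v1 for v1, v2 in zip(vals, vals[1:]))
        assert all(0 < v < 1 for v in vals)
        # power-tail survival: 1-F scales as t^-alpha, so log-survival is
        # linear in log t with slope -alpha
        slope = (math.log10(1 - vals[2]) - math.log10(1 - vals[1])) / 2
        assert abs(-slope - dog1.alpha) < 0.01

    def test_deriv_matches_finite_difference(self, dog1):
        pol = g.PrecisionPolicy(target_digits=40)
        with mp.workdps(60):
            h = mp.mpf(10) ** -12
            t0 = mp.mpf(100)
            fd = (g.evaluate_long("pdf", t0 + h, dog1, pol).value
                  - g.evaluate_long("pdf", t0 - h, dog1, pol).value) / (2 * h)
        d = g.evaluate_long("deriv", 100.0, dog1, pol)
        assert matching_digits(fd, d.value) >= 20


class TestCalculusChain:
    """d/dt supercdf = cdf, d/dt cdf = pdf, d/dt pdf = deriv."""

    @pytest.mark.parametrize("upper,lower", [("supercdf", "cdf"),
                                             ("cdf", "pdf"),
                                             ("pdf", "deriv")])
    def test_numerical_derivative(self, dog1, upper, lower):
        pol = g.PrecisionPolicy(target_digits=45)
        with mp.workdps(70):
            t0 = mp.mpf(12)
            h = mp.mpf(10) ** -14
            fd = (g.evaluate_long(upper, t0 + h, dog1, pol).value
                  - g.evaluate_long(upper, t0 - h, dog1, pol).value) / (2 * h)
        ref = g.evaluate_long(lower, 12.0, dog1, pol)
        assert matching_digits(fd, ref.value) >= 20


class TestAsymptote:
    def test_relative_error_shrinks(self, dog1):
        errs = []
        for t in (1e2, 1e3, 1e4):
            full = g.evaluate_long("pdf", t, dog1, POL30).value
            with mp.workdps(40):
                gam = g.gd_pdf(t, dog1.a, dog1.b, POL30)
                err = abs(full - gam - g.asymptote_pdf(t, dog1, POL30)) / abs(full)
            errs.append(err)
        assert errs[0] > errs[1] > errs[2]

    def test_domain_error(self, dog1):
        with pytest.raises(g.DomainError):
            g.asymptote_pdf(dog1.beta_h / 2, dog1, POL30)

    def test_integer_alpha_rejected_at_construction(self):
        with pytest.raises(g.PoleError):
            g.GPCParams(0.5, 1.0, 1.0, 0.01)


class TestLongTermRatio:
    def test_terms_collapse_far_from_beta(self, dog1):
        # each successive simplified term is ~3 decades smaller at t=12 h
        for k in range(1, 6):
            r = float(g.long_term_ratio(k, 12.0, dog1, POL30))
            assert 0 < r < 0.01

    def test_beta_over_kt_scale_in_small_bt_regime(self, dog1):
        # the beta/(k t) approximation is a small-(b t) statement; near the
        # 4*beta dispatch floor it holds to within a small factor
        t = 4 * dog1.beta_h
        for k in range(1, 5):
            r = float(g.long_term_ratio(k, t, dog1, POL30))
            assert r <= 3 * dog1.beta_h / (k * t)

    def test_quarter_bound_at_4beta(self, dog1):
        # at the dispatch floor the next term is at worst ~1/4 the current
        t = 4 * dog1.beta_h
        assert float(g.long_term_ratio(1, t, dog1, POL30)) <= 0.30

    def test_term_magnitudes_strictly_decreasing(self, dog1):
        from gpcpk.engines import _long_term
        with mp.workdps(45):
            t = mp.mpf(5.0)
            mags = [abs(_long_term("pdf", k, t, dog1, mp.rf(1 - mp.mpf(dog1.a), k)))
                    for k in range(1, 8)]
        assert all(m2 < m1 for m1, m2 in zip(mags, mags[1:]))
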