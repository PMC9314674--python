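"""Implied covariance algebra, derived quantities, pattern probabilities
and the raw-data ML fit."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import twinace as ta
from twinace.cholesky import loglik
from conftest import expected_count_records


class TestImpliedCovariance:
    def test_pure_nonshared_environment_gives_identity(self):
        p = ta.CholeskyParams(e11=1.0, e22=1.0, tau3=1.0, tau7=1.0)
        for group in (ta.MZ, ta.DZ):
            m = ta.implied_covariance(p, group).matrix
            assert np.allclose(m, np.eye(4))

    def test_reference_component_reconstruction(self, generating_params):
        """Paths rebuilt from the reference standardized components imply the
        reference MZ/DZ cross-twin correlations."""
        mz = ta.implied_covariance(generating_params, ta.MZ).matrix
        dz = ta.implied_covariance(generating_params, ta.DZ).matrix
        assert mz[0, 2] == pytest.approx(0.954, abs=0.005)  # a11^2 + c11^2
        assert dz[0, 2] == pytest.approx(0.555, abs=0.005)  # a11^2/2 + c11^2
        assert mz[1, 3] == pytest.approx(0.904, abs=0.005)
        assert dz[1, 3] == pytest.approx(0.452, abs=0.005)

    def test_structure_invariants(self, generating_params):
        for group in (ta.MZ, ta.DZ):
            m = ta.implied_covariance(generating_params, group).matrix
            assert np.allclose(m, m.T)
            assert np.allclose(np.diag(m), 1.0, atol=1e-10)
            assert np.allclose(m[:2, :2], m[2:, 2:])  # twin exchangeability
            assert np.allclose(m[:2, 2:], m[:2, 2:].T)

    def test_mz_exceeds_dz_with_positive_a_paths(self, generating_params):
        mz = ta.implied_covariance(generating_params, ta.MZ).matrix
        dz = ta.implied_covariance(generating_params, ta.DZ).matrix
        cross = np.s_[:2, 2:]
        assert np.all(mz[cross] > dz[cross])


class TestDerivedQuantities:
    def test_zero_cross_path_zeroes_genetic_stability(self):
        p = ta.params_from_components(0.6, 0.2, 0.2, 0.5, 0.2, 0.3,
                                      r_a=0.0, r_e=0.3, tau3=1.0, tau7=1.0)
        _, stab = ta.derived_quantities(p)
        assert stab.r_a == pytest.approx(0.0, abs=1e-12)
        assert stab.contribution_a == pytest.approx(0.0, abs=1e-12)

    def test_reference_stability_decomposition(self, generating_params):
        """Reference components + rA/rE reproduce the reference contributions,
        proportions and total liability correlation."""
        _, stab = ta.derived_quantities(generating_params)
        assert stab.contribution_a == pytest.approx(0.685, abs=0.002)
        assert stab.contribution_e == pytest.approx(0.062, abs=0.002)
        assert round(stab.proportion_a, 3) == 0.917
        assert round(stab.proportion_e, 3) == 0.083
        assert stab.r_liability == pytest.approx(0.746, abs=0.005)

    def test_contributions_sum_to_implied_covariance_entry(self, generating_params):
        _, stab = ta.derived_quantities(generating_params)
        implied = ta.implied_covariance(generating_params, ta.MZ).matrix[0, 1]
        total = (stab.contribution_a + stab.contribution_c
                 + stab.contribution_e + stab.contribution_prs)
        assert total == pytest.approx(stab.r_liability, abs=1e-10)
        assert total == pytest.approx(implied, abs=1e-10)

    def test_undefined_correlations_flagged_not_nan(self):
        p = ta.CholeskyParams(e11=1.0, e21=0.3,
                              e22=float(np.sqrt(1 - 0.09)), tau3=1.0, tau7=1.0)
        vc, stab = ta.derived_quantities(p)
        assert stab.r_a is None
        assert stab.r_e is not None
        assert vc.age3.total == pytest.approx(1.0, abs=1e-6)


class TestPatternProbability:
    def test_all_missing_is_one(self, generating_params):
        assert ta.pair_pattern_probability(
            generating_params, ta.MZ, (None, None, None, None), ("M", "M")) == 1.0

    def test_independence_factorizes(self):
        p = ta.CholeskyParams(e11=1.0, e22=1.0, tau3=1.2, tau7=1.4)
        prob = ta.pair_pattern_probability(p, ta.MZ, (1, 0, 1, 0), ("F", "F"))
        q3 = ta.prevalence_from_threshold(1.2)
        q7 = 1.0 - ta.prevalence_from_threshold(1.4)
        assert prob == pytest.approx((q3 * q7) ** 2, abs=1e-9)

    def test_patterns_sum_to_one(self, generating_params):
        for group, sexes in ((ta.MZ, ("M", "M")), (ta.DZ, ("M", "F"))):
            total = sum(
                ta.pair_pattern_probability(generating_params, group, pat, sexes)
                for pat in itertools.product([0, 1], repeat=4))
            assert total == pytest.approx(1.0, abs=1e-6)

    def test_concordant_pattern_matches_monte_carlo(self, generating_params):
        """4-D affected-affected-affected-affected probability vs a plain
        Monte-Carlo oracle simulated from the path model."""
        p = generating_params
        prob = ta.pair_pattern_probability(p, ta.MZ, (1, 1, 1, 1), ("M", "M"))
        rng = np.random.default_rng(123)
        n = 2 * 10 ** 6
        cov = ta.implied_covariance(p, ta.MZ).matrix
        z = rng.standard_normal((n, 4)) @ np.linalg.cholesky(cov).T
        thr = np.array([p.tau3 - p.beta_sex3, p.tau7 - p.beta_sex7] * 2)
        mc = np.mean(np.all(z > thr, axis=1))
        se = np.sqrt(mc * (1 - mc) / n)
        assert abs(prob - mc) < 3 * se

    def test_observed_prs_shifts_risk(self, generating_params):
        b = 0.2
        p = ta.params_from_components(0.796, 0.157, 0.046, 0.904, 0.0, 0.096,
                                      0.807, 0.934, tau3=1.3, tau7=1.4,
                                      b3=b, b7=b)
        hi = ta.pair_pattern_probability(p, ta.MZ, (1, None, None, None),
                                         ("F", "F"), prs=(2.0, 2.0))
        lo = ta.pair_pattern_probability(p, ta.MZ, (1, None, None, None),
                                         ("F", "F"), prs=(-2.0, -2.0))
        marginal = ta.pair_pattern_probability(p, ta.MZ, (1, None, None, None),
                                               ("F", "F"))
        assert hi > marginal > lo


class TestLikelihood:
    def test_collapsed_equals_naive(self, tiny_cohort, generating_params):
        ll_c = loglik(tiny_cohort, generating_params, points=512, collapse=True)
        ll_n = loglik(tiny_cohort, generating_params, points=512, collapse=False)
        assert ll_c == pytest.approx(ll_n, abs=1e-9)

    def test_twin_order_exchangeable(self, tiny_cohort, generating_params):
        swapped = [ta.TwinPairRecord(r.pair_id, r.zygosity, r.sex2, r.sex1,
                                     r.phen3_2, r.phen7_2, r.phen3_1, r.phen7_1,
                                     r.prs2, r.prs1)
                   for r in tiny_cohort]
        ll = loglik(tiny_cohort, generating_params, points=512)
        ll_swapped = loglik(swapped, generating_params, points=512)
        assert ll == pytest.approx(ll_swapped, abs=1e-8)


class TestFitMl:
    def test_single_age_fit_reproduces_falconer(self):
        """ML on data whose MZ/DZ tetrachorics are exactly (0.954, 0.555)
        returns the closed-form Falconer solution."""
        records = expected_count_records(0.954, 0.555, 0.1039, 50_000)
        fit = ta.fit_ml(records, ta.ModelSpec(ages=(3,), sex_effect=False),
                        seed=0, points=512)
        falconer = ta.fit_to_correlations(0.954, 0.555)
        vc = fit.variance_components.age3
        assert vc.a == pytest.approx(falconer.a, abs=1e-3)
        assert vc.c == pytest.approx(falconer.c, abs=1e-3)
        assert vc.e == pytest.approx(falconer.e, abs=1e-3)

    def test_standardization_and_reported_loglik(self, small_cohort):
        fit = ta.fit_ml(small_cohort, seed=1, points=256)
        vc = fit.variance_components
        assert vc.age3.total == pytest.approx(1.0, abs=1e-6)
        assert vc.age7.total == pytest.approx(1.0, abs=1e-6)
        recomputed = loglik(small_cohort, fit.params, fit.model, points=256)
        assert fit.loglik == pytest.approx(recomputed, abs=1e-6)
        stab = fit.stability
        total = (stab.contribution_a + stab.contribution_c
                 + stab.contribution_e + stab.contribution_prs)
        assert total == pytest.approx(stab.r_liability, abs=1e-10)

    def test_degenerate_group_raises_named_error(self):
        records = [
            ta.TwinPairRecord("a", "MZ", "F", "F", 1, 0, 1, 0),
            ta.TwinPairRecord("b", "MZ", "F", "F", 0, 1, 0, 0),
            ta.TwinPairRecord("c", "DZSS", "F", "F", 1, 1, 1, 1),  # all affected
        ]
        with pytest.raises(ValueError, match="DZ"):
            ta.fit_ml(records, seed=0, points=64)

    def test_missing_zygosity_group_raises(self):
        records = [ta.TwinPairRecord(f"m{i}", "MZ", "F", "F", i % 2, 0, i % 2, 1)
                   for i in range(10)]
        with pytest.raises(ValueError, match="MZ and .* DZ"):
            ta.fit_ml(records, seed=0, points=64)


class TestFalconer:
    @pytest.mark.parametrize("rmz,rdz,expected", [
        (0.904, 0.452, (0.904, 0.0, 0.096)),
        (0.0, 0.0, (0.0, 0.0, 1.0)),
        (0.954, 0.555, (0.798, 0.156, 0.046)),
    ])
    def test_known_solutions(self, rmz, rdz, expected):
        f = ta.fit_to_correlations(rmz, rdz)
        assert (f.a, f.c, f.e) == pytest.approx(expected, abs=1e-9)

    def test_truncation_flagged_when_rmz_below_rdz(self):
        f = ta.fit_to_correlations(0.3, 0.4)
        assert f.truncated_a and f.a == 0.0

    @given(st.floats(-0.95, 0.95), st.floats(-0.95, 0.95))
    def test_components_are_proportions(self, rmz, rdz):
        f = ta.fit_to_correlations(rmz, rdz)
        assert f.a >= 0 and f.c >= 0 and f.e >= 0
        assert f.a + f.c + f.e == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("bad", [1.0, -1.0, 1.5])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            ta.fit_to_correlations(bad, 0.2)
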