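"""Thresholds, MVN rectangle probabilities and tetrachoric ML."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import dblquad
from scipy.optimize import brentq
from scipy.special import erfc, ndtr
from scipy.stats import multivariate_normal

import twinace as ta
from twinace.liability import genz_rectangles


def quantile_oracle(p: float) -> float:
    """Upper-tail standard-normal quantile by bisection on erfc, independent
    of the inverse-CDF routine used by the implementation."""
    return brentq(lambda x: 0.5 * erfc(x / np.sqrt(2.0)) - p, -10, 10,
                  xtol=1e-13)


class TestThresholds:
    @pytest.mark.parametrize("p,expected,tol", [
        (0.5, 0.0, 1e-12),
        ((734 + 847) / 15213, 1.2595034, 1e-6),   # frozen from quantile oracle
        (0.158655, 1.0, 1e-5),
    ])
    def test_known_quantiles(self, p, expected, tol):
        assert ta.threshold_from_prevalence(p) == pytest.approx(expected, abs=tol)
        assert ta.threshold_from_prevalence(p) == pytest.approx(
            quantile_oracle(p), abs=1e-10)

    def test_inverse_on_grid(self):
        grid = np.linspace(0.001, 0.999, 200)
        for p in grid:
            tau = ta.threshold_from_prevalence(p)
            assert abs(ta.prevalence_from_threshold(tau) - p) < 1e-10

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.7, np.nan])
    def test_domain_errors_name_the_value(self, bad):
        with pytest.raises(ValueError, match="prevalence"):
            ta.threshold_from_prevalence(bad)

    @given(st.floats(min_value=1e-6, max_value=1 - 1e-6))
    def test_round_trip_property(self, p):
        tau = ta.threshold_from_prevalence(p)
        assert ta.prevalence_from_threshold(tau) == pytest.approx(p, abs=1e-12)


def random_correlation(rng: np.random.Generator, d: int) -> np.ndarray:
    a = rng.standard_normal((d, d + 2))
    s = a @ a.T
    sd = np.sqrt(np.diag(s))
    return s / np.outer(sd, sd)


class TestMvnRectangle:
    def test_independent_upper_orthant(self):
        spec = ta.RectangleSpec(np.zeros(2), np.full(2, np.inf), np.eye(2))
        assert ta.mvn_rectangle(spec) == pytest.approx(0.25, abs=1e-12)

    def test_comonotone_degenerate(self):
        h = 0.7
        corr = np.array([[1.0, 1.0], [1.0, 1.0]])
        spec = ta.RectangleSpec(np.full(2, h), np.full(2, np.inf), corr)
        assert ta.mvn_rectangle(spec) == pytest.approx(
            ta.prevalence_from_threshold(h), abs=1e-10)

    def test_orthant_partition_sums_to_one(self):
        rng = np.random.default_rng(5)
        for d in (2, 3, 4):
            corr = random_correlation(rng, d)
            total = 0.0
            for signs in itertools.product([0, 1], repeat=d):
                lo = np.where(signs, 0.0, -np.inf)
                hi = np.where(signs, np.inf, 0.0)
                total += ta.mvn_rectangle(ta.RectangleSpec(lo, hi, corr))
            assert total == pytest.approx(1.0, abs=1e-6)

    def test_unbounded_dimension_marginalizes(self):
        rng = np.random.default_rng(11)
        corr = random_correlation(rng, 4)
        lo = np.array([-0.5, -np.inf, 0.2, -1.0])
        hi = np.array([1.5, np.inf, np.inf, 2.0])
        keep = [0, 2, 3]
        full = ta.mvn_rectangle(ta.RectangleSpec(lo, hi, corr))
        reduced = ta.mvn_rectangle(ta.RectangleSpec(
            lo[keep], hi[keep], corr[np.ix_(keep, keep)]))
        assert full == pytest.approx(reduced, abs=1e-7)

    def test_monotone_in_bounds(self):
        rng = np.random.default_rng(3)
        corr = random_correlation(rng, 4)
        lo = np.array([-1.0, -0.5, -2.0, -1.5])
        hi = np.array([0.5, 1.0, 0.3, 1.2])
        base = ta.mvn_rectangle(ta.RectangleSpec(lo, hi, corr))
        for j in range(4):
            hi2 = hi.copy()
            hi2[j] += 0.4
            assert ta.mvn_rectangle(ta.RectangleSpec(lo, hi2, corr)) >= base - 1e-9
            lo2 = lo.copy()
            lo2[j] += 0.4
            assert ta.mvn_rectangle(ta.RectangleSpec(lo2, hi, corr)) <= base + 1e-9

    def test_deterministic_across_calls(self):
        rng = np.random.default_rng(8)
        corr = random_correlation(rng, 4)
        spec = ta.RectangleSpec(np.full(4, -1.0), np.full(4, 0.8), corr)
        assert ta.mvn_rectangle(spec) == ta.mvn_rectangle(spec)

    def test_agrees_with_scipy_cdf(self):
        """Independent route: scipy's own MVN CDF on one-sided rectangles."""
        rng = np.random.default_rng(21)
        for d in (3, 4):
            for _ in range(3):
                corr = random_correlation(rng, d)
                upper = rng.uniform(-0.5, 1.5, d)
                spec = ta.RectangleSpec(np.full(d, -np.inf), upper, corr)
                ours = ta.mvn_rectangle(spec, points=2 ** 14)
                ref = float(multivariate_normal(mean=np.zeros(d), cov=corr,
                                                seed=1234).cdf(upper))
                assert ours == pytest.approx(ref, abs=5e-5)

    def test_validation_errors(self):
        with pytest.raises(ValueError, match="lower bound"):
            ta.RectangleSpec(np.array([1.0]), np.array([0.0]), np.eye(1))
        bad = np.array([[1.0, 0.9], [0.9, 0.5]])
        with pytest.raises(ValueError, match="diagonal"):
            ta.RectangleSpec(np.zeros(2), np.ones(2), bad)
        nonpsd = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="semidefinite"):
            ta.RectangleSpec(np.zeros(2), np.ones(2), nonpsd)

    def test_batched_rows_match_single_calls(self):
        rng = np.random.default_rng(9)
        corr = random_correlation(rng, 3)
        lower = rng.uniform(-2, 0, (6, 3))
        upper = lower + rng.uniform(0.5, 2.5, (6, 3))
        batch = genz_rectangles(lower, upper, corr, points=2048)
        for i in range(6):
            single = genz_rectangles(lower[i], upper[i], corr, points=2048)
            assert batch[i] == pytest.approx(float(single[0]), abs=1e-12)


def tetrachoric_quadrature_oracle(table: ta.TwoByTwoTable) -> float:
    """Root-find the score equation using 2-D adaptive quadrature for the
    joint cell probability — fully independent of the package's bivariate
    CDF and optimizer."""
    t1 = ta.threshold_from_prevalence(table.prevalence1)
    t2 = ta.threshold_from_prevalence(table.prevalence2)

    def p11(rho):
        s = np.sqrt(1 - rho ** 2)
        val, _ = dblquad(
            lambda y, x: np.exp(-0.5 * (x * x - 2 * rho * x * y + y * y) / (s * s))
            / (2 * np.pi * s),
            t1, 8.5, lambda x: t2, lambda x: 8.5, epsabs=1e-11)
        return val

    def score(rho):
        q1, q2 = ndtr(-t1), ndtr(-t2)
        p = p11(rho)
        cells = np.array([p, q1 - p, q2 - p, 1 - q1 - q2 + p])
        counts = np.array([table.n11, table.n10, table.n01, table.n00])
        h = 1e-5
        p_hi, p_lo = p11(rho + h), p11(rho - h)
        dcells = np.array([p_hi - p_lo, -(p_hi - p_lo), -(p_hi - p_lo),
                           p_hi - p_lo]) / (2 * h)
        return float(np.sum(counts * dcells / cells))

    return brentq(score, 0.01, 0.99, xtol=1e-8)


class TestTetrachoric:
    def test_independence_table(self):
        res = ta.tetrachoric_ml(ta.TwoByTwoTable(25, 25, 25, 25))
        assert abs(res.rho) < 1e-6

    def test_perfect_concordance_boundary(self):
        res = ta.tetrachoric_ml(ta.TwoByTwoTable(30, 0, 0, 30))
        assert res.boundary
        assert res.rho > 0.999

    def test_matches_quadrature_oracle(self):
        table = ta.TwoByTwoTable(734, 847, 573, 13059)
        ours = ta.tetrachoric_ml(table)
        oracle = tetrachoric_quadrature_oracle(table)
        assert ours.rho == pytest.approx(oracle, abs=1e-4)

    def test_score_vanishes_at_optimum(self):
        from twinace.liability import tetrachoric_loglik
        table = ta.TwoByTwoTable(120, 80, 60, 740)
        res = ta.tetrachoric_ml(table)
        h = 1e-5
        grad = (tetrachoric_loglik(table, res.rho + h, res.tau1, res.tau2)
                - tetrachoric_loglik(table, res.rho - h, res.tau1, res.tau2)
                ) / (2 * h)
        assert abs(grad) < 1e-4  # finite-difference resolution of the score

    def test_recovers_generating_rho_from_expected_counts(self):
        """At n = 1e6 with exact expected cell counts the ML estimate is
        within 1e-3 of the generating correlation."""
        rho, tau1, tau2 = 0.65, 1.1, 1.3
        n = 10 ** 6
        q1, q2 = float(ndtr(-tau1)), float(ndtr(-tau2))
        p11 = 1 - ndtr(tau1) - ndtr(tau2) + ta.bvn_cdf(tau1, tau2, rho)
        cells = [p11, q1 - p11, q2 - p11, 1 - q1 - q2 + p11]
        counts = [int(round(c * n)) for c in cells]
        res = ta.tetrachoric_ml(ta.TwoByTwoTable(*counts))
        assert res.rho == pytest.approx(rho, abs=1e-3)

    def test_degenerate_margin_raises(self):
        with pytest.raises(ValueError, match="degenerate margin"):
            ta.tetrachoric_ml(ta.TwoByTwoTable(0, 0, 30, 70))

    def test_zero_cell_continuity_correction(self):
        res = ta.tetrachoric_ml(ta.TwoByTwoTable(40, 0, 25, 500))
        assert res.continuity_corrected
        assert -1 < res.rho < 1
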