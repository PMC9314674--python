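"""Hypothesis tests for the liability twin model.

Three test families:

* likelihood-ratio tests between nested Cholesky model fits, with an
  optional 50:50 chi-bar-square mixture reference when the constrained
  parameter sits on a variance boundary (e.g. a C path fixed to zero);
* sex-limitation tests on group-specific tetrachoric correlations
  (equality of MZ-male vs MZ-female correlations, and of the three DZ
  groups including opposite-sex pairs — the latter is also sensitive to
  qualitative sex differences, i.e. partly different genes in boys and
  girls);
* polygenic-score tests: equal slopes at the two ages (b3 = b7) and a
  zero common slope (b = 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from .cholesky import FitResult, ModelSpec, DEFAULT_MODEL, fit_ml
from .liability import (
    TetrachoricResult,
    TwoByTwoTable,
    tetrachoric_loglik,
    tetrachoric_ml,
    threshold_from_prevalence,
)

logger = logging.getLogger("twinace")

__all__ = [
    "LRTResult",
    "likelihood_ratio_test",
    "GroupCorrelation",
    "SexLimitationReport",
    "sex_limitation_test",
    "PrsTestResult",
    "prs_tests",
]

# Free parameters whose removal pins a variance component to its boundary.
_BOUNDARY_NAMES = {"a11", "a22", "c11", "c22"}


@dataclass(frozen=True)
class LRTResult:
    """Likelihood-ratio test between a full and a nested model."""

    loglik_full: float
    loglik_nested: float
    df: int
    statistic: float
    p_value: float
    boundary_flag: bool = False
    p_value_mixture: float | None = None


def _chi2_sf(stat: float, df: int) -> float:
    if df == 0:
        return 0.0 if stat > 0 else 1.0
    return float(chi2.sf(stat, df))


def _lrt(ll_full: float, ll_nested: float, df: int, boundary: bool) -> LRTResult:
    stat = 2.0 * (ll_full - ll_nested)
    if stat < -1e-6:
        logger.warning("LRT statistic %.3g below 0 beyond tolerance; clamping", stat)
    stat = max(stat, 0.0)
    p = _chi2_sf(stat, df)
    p_mix = None
    if boundary:
        # 50:50 mixture of chi2(df) and chi2(df-1) for one boundary component
        p_mix = 0.5 * (_chi2_sf(stat, df) + _chi2_sf(stat, df - 1))
    return LRTResult(ll_full, ll_nested, df, stat, p, boundary, p_mix)


def likelihood_ratio_test(
    full: FitResult,
    nested: FitResult,
    boundary: bool | None = None,
) -> LRTResult:
    """Chi-square LRT of a nested model against its full model.

    The nested model's free parameters must be a structural subset of the
    full model's.  ``boundary`` defaults to auto-detection: the flag is set
    when the constraint removes a diagonal (variance) path, in which case a
    50:50 chi-bar-square mixture p-value is also reported.
    """
    full_names = set(full.free_names)
    nested_names = set(nested.free_names)
    if not nested_names < full_names:
        raise ValueError(
            "models are not nested: nested free parameters "
            f"{sorted(nested_names)} are not a strict subset of "
            f"{sorted(full_names)}"
        )
    df = full.n_free - nested.n_free
    if boundary is None:
        boundary = bool((full_names - nested_names) & _BOUNDARY_NAMES)
    return _lrt(full.loglik, nested.loglik, df, boundary)


# ---------------------------------------------------------------------------
# sex-limitation tests on tetrachoric correlations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupCorrelation:
    group: str
    age: int
    rho: float
    se: float | None
    n_pairs: int
    boundary: bool = False


@dataclass(frozen=True)
class SexLimitationReport:
    """Group-specific twin correlations per age with equality tests.

    ``mz_tests``/``dz_tests`` map age to an `LRTResult` comparing free
    group-specific correlations against a common correlation (thresholds
    stay group-specific throughout).  The DZ test spans DZ-MM, DZ-FF and
    DZ-OS and therefore also probes qualitative sex differences.
    """

    correlations: tuple[GroupCorrelation, ...]
    mz_tests: dict[int, LRTResult]
    dz_tests: dict[int, LRTResult]
    flags: tuple[str, ...] = ()

    def correlation(self, group: str, age: int) -> GroupCorrelation | None:
        for c in self.correlations:
            if c.group == group and c.age == age:
                return c
        return None


def _group_of(rec) -> str | None:
    z = rec.zygosity.upper()
    if z == "MZ":
        return f"MZ-{rec.sex1}{rec.sex2}"
    if z == "DZSS":
        return f"DZ-{rec.sex1}{rec.sex2}"
    if z == "DZOS":
        return "DZ-OS"
    return None


def _cross_twin_table(records, age: int) -> TwoByTwoTable | None:
    xs, ys = [], []
    for rec in records:
        p1, p2 = ((rec.phen3_1, rec.phen3_2) if age == 3
                  else (rec.phen7_1, rec.phen7_2))
        if p1 is not None and p2 is not None:
            xs.append(p1)
            ys.append(p2)
    if not xs:
        return None
    try:
        return TwoByTwoTable.from_pairs(xs, ys)
    except ValueError:
        return None


def _equality_test(fits: list[tuple[TwoByTwoTable, TetrachoricResult]]) -> LRTResult:
    """Free (group-specific rho) vs constrained (common rho) comparison;
    thresholds remain fixed at each group's margins."""
    work = []
    ll_free = 0.0
    for table, fit in fits:
        t = table
        if fit.continuity_corrected:
            t = TwoByTwoTable(t.n11 + 0.5, t.n10 + 0.5, t.n01 + 0.5, t.n00 + 0.5)
        tau1 = threshold_from_prevalence(t.prevalence1)
        tau2 = threshold_from_prevalence(t.prevalence2)
        work.append((t, tau1, tau2))
        ll_free += tetrachoric_loglik(t, fit.rho, tau1, tau2)

    def neg_common(rho: float) -> float:
        return -sum(tetrachoric_loglik(t, rho, t1, t2) for t, t1, t2 in work)

    res = minimize_scalar(neg_common, bounds=(-1 + 1e-8, 1 - 1e-8),
                          method="bounded", options={"xatol": 1e-10})
    return _lrt(ll_free, -float(res.fun), df=len(fits) - 1, boundary=False)


def sex_limitation_test(records, ages: tuple[int, ...] = (3, 7)) -> SexLimitationReport:
    """Estimate twin correlations per sex-by-zygosity group and test their
    equality within MZ (1 df) and across the three DZ groups (2 df).

    Groups with degenerate or absent data are flagged and skipped; tests
    requiring a missing group are omitted from the report.
    """
    by_group: dict[str, list] = {}
    for rec in records:
        g = _group_of(rec)
        if g is not None:
            by_group.setdefault(g, []).append(rec)

    correlations: list[GroupCorrelation] = []
    fits: dict[tuple[str, int], tuple[TwoByTwoTable, TetrachoricResult]] = {}
    flags: list[str] = []
    for group in ("MZ-MM", "MZ-FF", "DZ-MM", "DZ-FF", "DZ-OS"):
        recs = by_group.get(group, [])
        for age in ages:
            table = _cross_twin_table(recs, age)
            if table is None:
                flags.append(f"{group} age {age}: absent or degenerate")
                continue
            try:
                fit = tetrachoric_ml(table)
            except ValueError as exc:
                flags.append(f"{group} age {age}: {exc}")
                continue
            fits[(group, age)] = (table, fit)
            correlations.append(GroupCorrelation(
                group=group, age=age, rho=fit.rho, se=fit.se,
                n_pairs=int(table.total), boundary=fit.boundary,
            ))

    mz_tests: dict[int, LRTResult] = {}
    dz_tests: dict[int, LRTResult] = {}
    for age in ages:
        mz = [fits[k] for k in ((g, age) for g in ("MZ-MM", "MZ-FF")) if k in fits]
        if len(mz) == 2:
            mz_tests[age] = _equality_test(mz)
        dz = [fits[k] for k in ((g, age) for g in ("DZ-MM", "DZ-FF", "DZ-OS"))
              if k in fits]
        if len(dz) == 3:
            dz_tests[age] = _equality_test(dz)
    return SexLimitationReport(tuple(correlations), mz_tests, dz_tests,
                               tuple(flags))


# ---------------------------------------------------------------------------
# polygenic-score tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrsTestResult:
    """PRS slope estimates and the two slope tests.

    ``equal_slopes`` tests b3 = b7 (free-slope model vs one common slope);
    ``zero_slope`` tests b = 0 in the common-slope model.  ``var3``/``var7``
    are the implied PRS shares of liability variance (b^2) under the
    free-slope model.
    """

    b3: float
    b7: float
    b_common: float
    var3: float
    var7: float
    equal_slopes: LRTResult
    zero_slope: LRTResult
    fits: dict[str, FitResult] = field(repr=False, default_factory=dict)


def prs_tests(
    records,
    model: ModelSpec = DEFAULT_MODEL,
    *,
    seed: int = 0,
    points: int = 1024,
) -> PrsTestResult:
    """Fit the no-PRS, common-slope and free-slope models and report both
    slope tests.  Pairs without genotype data contribute through the
    marginal (PRS-integrated) likelihood."""
    observed = [v for rec in records for v in (rec.prs1, rec.prs2) if v is not None]
    if not observed:
        raise ValueError("no PRS values observed in the dataset")
    if float(np.var(observed)) == 0.0:
        raise ValueError("PRS is constant across genotyped individuals")

    m_none = replace(model, prs="none")
    m_equal = replace(model, prs="equal")
    m_free = replace(model, prs="free")
    fit_none = fit_ml(records, m_none, seed=seed, points=points)
    fit_equal = fit_ml(records, m_equal, seed=seed, points=points, start=fit_none)
    fit_free = fit_ml(records, m_free, seed=seed, points=points, start=fit_equal)

    # guard against a restart landing worse than the nested optimum
    equal = _lrt(fit_free.loglik, fit_equal.loglik, df=1, boundary=False)
    zero = _lrt(fit_equal.loglik, fit_none.loglik, df=1, boundary=False)
    return PrsTestResult(
        b3=fit_free.params.b3, b7=fit_free.params.b7,
        b_common=fit_equal.params.b3,
        var3=fit_free.params.b3 ** 2, var7=fit_free.params.b7 ** 2,
        equal_slopes=equal, zero_slope=zero,
        fits={"none": fit_none, "equal": fit_equal, "free": fit_free},
    )
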