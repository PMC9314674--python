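"""Bivariate Cholesky ACE decomposition of liability at two ages.

The model: each person's liability to the phenotype at ages 3 and 7 is a
linear combination of latent additive-genetic (A), shared-environment (C)
and non-shared-environment (E) factors, loaded through a lower-triangular
(Cholesky) path matrix

    liability(3) = a11*A1 + c11*C1 + e11*E1 (+ b3*PRS + beta3*male)
    liability(7) = a21*A1 + a22*A2 + c21*C1 + c22*C2
                   + e21*E1 + e22*E2 (+ b7*PRS + beta7*male)

A factors correlate 1 across monozygotic (MZ) co-twins and 0.5 across
dizygotic (DZ) co-twins, C factors correlate 1, E factors 0; an optional
observed polygenic score (PRS) enters as a fixed-effect regressor with
age-specific slopes.  The liability is standardized, so squared paths are
proportions of variance: heritability at age 3 is a11^2 and at age 7
a21^2 + a22^2, and the cross-age liability correlation decomposes additively
into a11*a21 (A), c11*c21 (C), e11*e21 (E) and b3*b7 (PRS).

Binary phenotypes are linked to liability by the threshold model of
:mod:`twinace.liability`; fitting maximizes the raw-data (full-information)
multinomial likelihood, with pairs collapsed to distinct
(group, sex, response-pattern) cells so one likelihood evaluation costs a
handful of vectorized rectangle integrations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize

from .liability import (
    DEFAULT_QMC_POINTS,
    genz_rectangles,
    mvn_rectangle,
    RectangleSpec,
    threshold_from_prevalence,
    tetrachoric_ml,
    TwoByTwoTable,
)

logger = logging.getLogger("twinace")

__all__ = [
    "CholeskyParams",
    "ZygosityGroup",
    "MZ",
    "DZ",
    "ModelSpec",
    "ImpliedCovariance",
    "ComponentShares",
    "VarianceComponents",
    "StabilityDecomposition",
    "FalconerComponents",
    "FitResult",
    "implied_covariance",
    "derived_quantities",
    "pair_pattern_probability",
    "loglik",
    "fit_ml",
    "fit_to_correlations",
]

_MIN_E_VAR = 1e-4   # smallest admissible non-shared environment variance
_FLOOR_WIDTH = 1e-5  # smoothing width of the variance floor


def _smooth_floor(gap: float) -> tuple[float, float]:
    """Smooth positive part: returns (floored gap, violation), both C^1 in
    ``gap``.  A hard ``max(gap, 0)`` puts a kink exactly where boundary
    solutions live and stalls quasi-Newton line searches."""
    r = float(np.hypot(gap, _FLOOR_WIDTH))
    return 0.5 * (gap + r), 0.5 * (r - gap)


# ---------------------------------------------------------------------------
# parameters and groups
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CholeskyParams:
    """All path coefficients, PRS slopes, sex effects and thresholds."""

    a11: float = 0.0
    a21: float = 0.0
    a22: float = 0.0
    c11: float = 0.0
    c21: float = 0.0
    c22: float = 0.0
    e11: float = 1.0
    e21: float = 0.0
    e22: float = 1.0
    b3: float = 0.0
    b7: float = 0.0
    beta_sex3: float = 0.0
    beta_sex7: float = 0.0
    tau3: float = 0.0
    tau7: float = 0.0

    @property
    def var_a3(self) -> float:
        return self.a11 ** 2

    @property
    def var_a7(self) -> float:
        return self.a21 ** 2 + self.a22 ** 2

    @property
    def var_c3(self) -> float:
        return self.c11 ** 2

    @property
    def var_c7(self) -> float:
        return self.c21 ** 2 + self.c22 ** 2

    @property
    def var_e3(self) -> float:
        return self.e11 ** 2

    @property
    def var_e7(self) -> float:
        return self.e21 ** 2 + self.e22 ** 2

    @property
    def var3(self) -> float:
        return self.var_a3 + self.var_c3 + self.var_e3 + self.b3 ** 2

    @property
    def var7(self) -> float:
        return self.var_a7 + self.var_c7 + self.var_e7 + self.b7 ** 2

    def check(self, standardized: bool = True, atol: float = 1e-8) -> None:
        if self.e11 <= 0 or self.e22 <= 0:
            raise ValueError("non-shared environment paths e11, e22 must be > 0")
        if self.a11 < 0 or self.a22 < 0 or self.c11 < 0 or self.c22 < 0:
            raise ValueError("diagonal Cholesky paths must be nonnegative")
        if standardized:
            if abs(self.var3 - 1.0) > atol or abs(self.var7 - 1.0) > atol:
                raise ValueError(
                    "standardization violated: per-age liability variances are "
                    f"{self.var3:.10f} and {self.var7:.10f}"
                )


@dataclass(frozen=True)
class ZygosityGroup:
    """Relatedness structure of a twin group.

    ``k`` is the additive-genetic relatedness (1 for MZ, 0.5 for DZ);
    shared environment correlates 1 in both; the PRS, being an additive
    genotype score, is shared exactly by MZ co-twins and correlates ``k``
    in DZ pairs.  ``a_corr`` overrides the cross-twin A correlation for
    sex-limitation variants (e.g. a free opposite-sex genetic correlation).
    """

    label: str
    k: float
    c_corr: float = 1.0
    a_corr: float | None = None
    prs_corr: float | None = None

    def __post_init__(self) -> None:
        if self.k not in (1.0, 0.5):
            raise ValueError(f"genetic relatedness k must be 1 or 0.5; got {self.k}")

    @property
    def ra(self) -> float:
        return self.k if self.a_corr is None else self.a_corr

    @property
    def rp(self) -> float:
        return self.k if self.prs_corr is None else self.prs_corr


MZ = ZygosityGroup("MZ", 1.0)
DZ = ZygosityGroup("DZ", 0.5)


@dataclass(frozen=True)
class ModelSpec:
    """Structural configuration of the fitted model.

    ``prs`` is one of ``"none"`` (PRS ignored), ``"equal"`` (one slope b at
    both ages) or ``"free"`` (separate b3, b7).  ``ages`` is ``(3, 7)`` for
    the longitudinal model or ``(3,)`` for the single-age reduction (which
    then uses only the age-3 parameter slots).  ``free_dzo_ra`` frees the
    opposite-sex DZ genetic correlation for the qualitative sex-limitation
    test.
    """

    a: bool = True
    c3: bool = True
    c7: bool = False
    prs: str = "none"
    sex_effect: bool = True
    ages: tuple[int, ...] = (3, 7)
    free_dzo_ra: bool = False

    def __post_init__(self) -> None:
        if self.prs not in ("none", "equal", "free"):
            raise ValueError(f"prs must be none/equal/free; got {self.prs!r}")
        if tuple(self.ages) not in ((3, 7), (3,)):
            raise ValueError("ages must be (3, 7) or (3,)")

    @property
    def bivariate(self) -> bool:
        return len(self.ages) == 2

    @property
    def label(self) -> str:
        comps = "A" * self.a + ("C3" if self.c3 and not self.c7 else "C" if self.c7 else "") + "E"
        tags = [comps]
        if self.prs != "none":
            tags.append(f"prs-{self.prs}")
        if self.free_dzo_ra:
            tags.append("free-ros")
        if not self.bivariate:
            tags.append("univariate")
        return "+".join(tags)


# Default structural model: A and E at both ages, C at age 3 only, sex covariate.
DEFAULT_MODEL = ModelSpec(a=True, c3=True, c7=False, prs="none", sex_effect=True)


# ---------------------------------------------------------------------------
# implied covariance and derived quantities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImpliedCovariance:
    """Model-implied liability covariance, ordered
    (twin1-age3, twin1-age7, twin2-age3, twin2-age7) in the bivariate case."""

    matrix: np.ndarray
    label: str
    ages: tuple[int, ...] = (3, 7)


def _within_block(p: CholeskyParams, ages: tuple[int, ...]) -> np.ndarray:
    if len(ages) == 1:
        return np.array([[p.var3]])
    cov37 = p.a11 * p.a21 + p.c11 * p.c21 + p.e11 * p.e21 + p.b3 * p.b7
    return np.array([[p.var3, cov37], [cov37, p.var7]])


def _cross_block(p: CholeskyParams, g: ZygosityGroup, ages: tuple[int, ...]) -> np.ndarray:
    x33 = g.ra * p.var_a3 + g.c_corr * p.var_c3 + g.rp * p.b3 ** 2
    if len(ages) == 1:
        return np.array([[x33]])
    x77 = g.ra * p.var_a7 + g.c_corr * p.var_c7 + g.rp * p.b7 ** 2
    x37 = g.ra * p.a11 * p.a21 + g.c_corr * p.c11 * p.c21 + g.rp * p.b3 * p.b7
    return np.array([[x33, x37], [x37, x77]])


def implied_covariance(
    params: CholeskyParams,
    group: ZygosityGroup,
    ages: tuple[int, ...] = (3, 7),
) -> ImpliedCovariance:
    """Assemble the per-pair liability covariance matrix for one group.

    E never contributes across twins; A contributes with weight ``k``
    (1 MZ, 0.5 DZ), C with weight 1, the PRS with its cross-twin
    correlation.
    """
    w = _within_block(params, ages)
    x = _cross_block(params, group, ages)
    return ImpliedCovariance(np.block([[w, x], [x.T, w]]), group.label, tuple(ages))


@dataclass(frozen=True)
class ComponentShares:
    """Proportions of liability variance at one age."""

    a: float
    c: float
    e: float
    prs: float = 0.0

    @property
    def total(self) -> float:
        return self.a + self.c + self.e + self.prs


@dataclass(frozen=True)
class VarianceComponents:
    age3: ComponentShares
    age7: ComponentShares | None = None


@dataclass(frozen=True)
class StabilityDecomposition:
    """Additive decomposition of the cross-age liability covariance.

    Under standardization the within-person cross-age covariance *is* the
    liability correlation, and it splits exactly into A, C, E (and PRS)
    contributions.  ``r_a``/``r_e`` are the factor correlations across ages
    (None when the corresponding variance vanishes at either age).
    Proportions are contributions divided by their sum (None when the total
    covariance is zero).
    """

    contribution_a: float
    contribution_c: float
    contribution_e: float
    contribution_prs: float
    r_liability: float
    r_a: float | None
    r_e: float | None
    proportion_a: float | None
    proportion_c: float | None
    proportion_e: float | None
    proportion_prs: float | None


def derived_quantities(
    params: CholeskyParams,
) -> tuple[VarianceComponents, StabilityDecomposition]:
    """Variance components per age and the stability decomposition."""
    p = params
    v3, v7 = p.var3, p.var7
    vc = VarianceComponents(
        age3=ComponentShares(p.var_a3 / v3, p.var_c3 / v3, p.var_e3 / v3,
                             p.b3 ** 2 / v3),
        age7=ComponentShares(p.var_a7 / v7, p.var_c7 / v7, p.var_e7 / v7,
                             p.b7 ** 2 / v7),
    )
    ca = p.a11 * p.a21
    cc = p.c11 * p.c21
    ce = p.e11 * p.e21
    cp = p.b3 * p.b7
    total = ca + cc + ce + cp

    r_a = None
    if p.var_a3 > 0 and p.var_a7 > 0:
        r_a = ca / np.sqrt(p.var_a3 * p.var_a7)
    r_e = None
    if p.var_e3 > 0 and p.var_e7 > 0:
        r_e = ce / np.sqrt(p.var_e3 * p.var_e7)

    if total != 0.0:
        props = (ca / total, cc / total, ce / total, cp / total)
    else:
        props = (None, None, None, None)
    stab = StabilityDecomposition(
        contribution_a=ca, contribution_c=cc, contribution_e=ce,
        contribution_prs=cp, r_liability=total, r_a=r_a, r_e=r_e,
        proportion_a=props[0], proportion_c=props[1],
        proportion_e=props[2], proportion_prs=props[3],
    )
    return vc, stab


# ---------------------------------------------------------------------------
# pair pattern probabilities
# ---------------------------------------------------------------------------

def _dims(ages: tuple[int, ...]) -> list[tuple[int, int]]:
    """Observation dimensions as (twin index, age) in canonical order."""
    return [(t, a) for t in (0, 1) for a in ages]


def _tau(p: CholeskyParams, age: int) -> float:
    return p.tau3 if age == 3 else p.tau7


def _beta(p: CholeskyParams, age: int) -> float:
    return p.beta_sex3 if age == 3 else p.beta_sex7


def _conditional_on_prs(
    params: CholeskyParams,
    group: ZygosityGroup,
    obs: tuple[bool, bool],
    ages: tuple[int, ...],
) -> tuple[np.ndarray, np.ndarray]:
    """Liability covariance and mean map given the observed PRS values.

    Returns ``(sigma, mean_map)`` where the conditional mean of the
    liability vector is ``mean_map @ prs_obs``.
    """
    d = 2 * len(ages)
    acepart = implied_covariance(replace(params, b3=0.0, b7=0.0), group, ages).matrix
    b_by_age = {3: params.b3, 7: params.b7}
    B = np.zeros((d, 2))
    for i, (twin, age) in enumerate(_dims(ages)):
        B[i, twin] = b_by_age[age]
    rp = group.rp
    sigma_p = np.array([[1.0, rp], [rp, 1.0]])
    idx = [i for i, o in enumerate(obs) if o]
    if not idx:
        return acepart + B @ sigma_p @ B.T, np.zeros((d, 0))
    s_oo = sigma_p[np.ix_(idx, idx)]
    # pinv: MZ co-twins share the PRS exactly, so s_oo can be singular
    K = sigma_p[:, idx] @ np.linalg.pinv(s_oo)  # (2, n_obs)
    V = sigma_p - K @ sigma_p[idx, :]
    sigma = acepart + B @ V @ B.T
    return sigma, B @ K


def pair_pattern_probability(
    params: CholeskyParams,
    group: ZygosityGroup,
    pattern: Sequence[int | None],
    sexes: tuple[str, str],
    prs: tuple[float | None, float | None] = (None, None),
    ages: tuple[int, ...] = (3, 7),
    points: int = DEFAULT_QMC_POINTS,
) -> float:
    """Probability of one pair's observed response pattern.

    ``pattern`` follows the (twin1-age3, twin1-age7, twin2-age3, twin2-age7)
    ordering with entries 1 (affected), 0 (unaffected) or None (missing);
    missing dimensions are marginalized out exactly.  Affected means
    liability above the sex-adjusted threshold.  Observed PRS values shift
    the conditional liability mean; missing PRS is integrated out.
    """
    d = 2 * len(ages)
    if len(pattern) != d:
        raise ValueError(f"pattern must have length {d}")
    males = [s == "M" for s in sexes]
    if any(s not in ("M", "F") for s in sexes):
        raise ValueError(f"sexes must be 'M'/'F'; got {sexes!r}")

    obs = (prs[0] is not None, prs[1] is not None)
    if params.b3 == 0.0 and params.b7 == 0.0:
        obs = (False, False)  # PRS carries no information
    if any(obs):
        sigma, mean_map = _conditional_on_prs(params, group, obs, ages)
        mean = mean_map @ np.array([v for v in prs if v is not None], dtype=float)
    else:
        sigma = implied_covariance(params, group, ages).matrix
        mean = np.zeros(d)

    sd = np.sqrt(np.diag(sigma))
    corr = sigma / np.outer(sd, sd)
    lower = np.full(d, -np.inf)
    upper = np.full(d, np.inf)
    for i, (twin, age) in enumerate(_dims(ages)):
        if pattern[i] is None:
            continue
        thr = (_tau(params, age) - _beta(params, age) * males[twin] - mean[i]) / sd[i]
        if pattern[i]:
            lower[i] = thr
        else:
            upper[i] = thr
    keep = [i for i in range(d) if pattern[i] is not None]
    if not keep:
        return 1.0
    spec = RectangleSpec(lower[keep], upper[keep], corr[np.ix_(keep, keep)])
    return mvn_rectangle(spec, points=points)


# ---------------------------------------------------------------------------
# collapsed raw-data likelihood
# ---------------------------------------------------------------------------

@dataclass
class _PatternBlock:
    zclass: str
    mask: tuple[int, ...]
    affected: np.ndarray  # (m, d) bool
    male: np.ndarray      # (m, d) bool
    counts: np.ndarray    # (m,)


@dataclass
class _PrsBlock:
    zclass: str
    mask: tuple[int, ...]
    obs: tuple[bool, bool]
    affected: np.ndarray
    male: np.ndarray
    prs: np.ndarray       # (m, n_obs)


@dataclass
class _LikelihoodData:
    pattern_blocks: list[_PatternBlock]
    prs_blocks: list[_PrsBlock]
    n_pairs: int
    n_dropped: int
    zclasses: tuple[str, ...]


def _zclass(zygosity: str, model: ModelSpec) -> str:
    z = zygosity.upper()
    if z == "MZ":
        return "MZ"
    if z in ("DZSS", "DZ"):
        return "DZ"
    if z == "DZOS":
        return "DZO" if model.free_dzo_ra else "DZ"
    raise ValueError(f"unknown zygosity label {zygosity!r}")


def _canonical_twins(rec) -> tuple[tuple, tuple]:
    """Deterministic twin ordering so the likelihood is exchangeable."""

    def key(t):
        out = [t[0]]
        for v in t[1:]:
            out.append((v is None, 0.0 if v is None else float(v)))
        return tuple(out)

    t0 = (rec.sex1, rec.phen3_1, rec.phen7_1, rec.prs1)
    t1 = (rec.sex2, rec.phen3_2, rec.phen7_2, rec.prs2)
    return (t1, t0) if key(t1) < key(t0) else (t0, t1)


def _build_likelihood_data(records: Iterable, model: ModelSpec) -> _LikelihoodData:
    dims = _dims(tuple(model.ages))
    d = len(dims)
    pat_acc: dict = {}
    prs_acc: dict = {}
    n_pairs = 0
    n_dropped = 0
    zclasses = set()
    for rec in records:
        t0, t1 = _canonical_twins(rec)
        twins = (t0, t1)
        zc = _zclass(rec.zygosity, model)
        phen = []
        male = []
        for twin, age in dims:
            sex, p3, p7, _prs = twins[twin]
            male.append(sex == "M")
            phen.append(p3 if age == 3 else p7)
        mask = tuple(i for i in range(d) if phen[i] is not None)
        if not mask:
            n_dropped += 1
            continue
        n_pairs += 1
        zclasses.add(zc)
        affected = tuple(bool(phen[i]) for i in mask)
        mal = tuple(male[i] for i in mask)
        prs_pair = (t0[3], t1[3])
        if model.prs != "none" and any(v is not None for v in prs_pair):
            obs = tuple(v is not None for v in prs_pair)
            key = (zc, mask, obs)
            prs_acc.setdefault(key, []).append(
                (affected, mal, tuple(v for v in prs_pair if v is not None))
            )
        else:
            key = (zc, mask)
            cell = (affected, mal)
            pat_acc.setdefault(key, {})
            pat_acc[key][cell] = pat_acc[key].get(cell, 0.0) + 1.0

    pattern_blocks = []
    for (zc, mask), cells in sorted(pat_acc.items()):
        items = sorted(cells.items())
        pattern_blocks.append(_PatternBlock(
            zclass=zc, mask=mask,
            affected=np.array([a for (a, _m), _ in items], dtype=bool),
            male=np.array([m for (_a, m), _ in items], dtype=bool),
            counts=np.array([c for _, c in items], dtype=float),
        ))
    prs_blocks = []
    for (zc, mask, obs), rows in sorted(prs_acc.items()):
        prs_blocks.append(_PrsBlock(
            zclass=zc, mask=mask, obs=obs,
            affected=np.array([r[0] for r in rows], dtype=bool),
            male=np.array([r[1] for r in rows], dtype=bool),
            prs=np.array([r[2] for r in rows], dtype=float),
        ))
    if n_dropped:
        logger.info("dropped %d pairs with no observed phenotype", n_dropped)
    return _LikelihoodData(pattern_blocks, prs_blocks, n_pairs, n_dropped,
                           tuple(sorted(zclasses)))


def _groups_for(model: ModelSpec, r_os: float | None) -> dict[str, ZygosityGroup]:
    groups = {"MZ": MZ, "DZ": DZ}
    if model.free_dzo_ra:
        groups["DZO"] = ZygosityGroup("DZO", 0.5, a_corr=r_os)
    return groups


def _block_loglik(
    params: CholeskyParams,
    model: ModelSpec,
    data: _LikelihoodData,
    r_os: float | None,
    points: int,
) -> float:
    ages = tuple(model.ages)
    dims = _dims(ages)
    groups = _groups_for(model, r_os)
    sigmas = {zc: implied_covariance(params, g, ages).matrix
              for zc, g in groups.items()}
    tau_dim = np.array([_tau(params, age) for _, age in dims])
    beta_dim = np.array([_beta(params, age) for _, age in dims])
    ll = 0.0
    for blk in data.pattern_blocks:
        sigma = sigmas[blk.zclass]
        sub = sigma[np.ix_(blk.mask, blk.mask)]
        sd = np.sqrt(np.diag(sub))
        corr = sub / np.outer(sd, sd)
        idx = list(blk.mask)
        thr = (tau_dim[idx][None, :] - beta_dim[idx][None, :] * blk.male) / sd[None, :]
        lower = np.where(blk.affected, thr, -np.inf)
        upper = np.where(blk.affected, np.inf, thr)
        p = genz_rectangles(lower, upper, corr, points)
        ll += float(blk.counts @ np.log(np.clip(p, 1e-300, None)))
    cond_cache: dict = {}
    for blk in data.prs_blocks:
        zc = blk.zclass
        key = (zc, blk.obs)
        if key not in cond_cache:
            cond_cache[key] = _conditional_on_prs(params, groups[zc], blk.obs, ages)
        sigma, mean_map = cond_cache[key]
        mean = blk.prs @ mean_map.T  # (m, d_full)
        sub = sigma[np.ix_(blk.mask, blk.mask)]
        sd = np.sqrt(np.diag(sub))
        corr = sub / np.outer(sd, sd)
        idx = list(blk.mask)
        thr = (tau_dim[idx][None, :]
               - beta_dim[idx][None, :] * blk.male
               - mean[:, idx]) / sd[None, :]
        lower = np.where(blk.affected, thr, -np.inf)
        upper = np.where(blk.affected, np.inf, thr)
        p = genz_rectangles(lower, upper, corr, points)
        ll += float(np.sum(np.log(np.clip(p, 1e-300, None))))
    return ll


def loglik(
    records: Sequence,
    params: CholeskyParams,
    model: ModelSpec = DEFAULT_MODEL,
    r_os: float | None = None,
    points: int = 1024,
    collapse: bool = True,
) -> float:
    """Raw-data log-likelihood of a set of pair records.

    ``collapse=False`` evaluates pair by pair (same numerics, no pattern
    collapsing); it exists for verification and is much slower.
    """
    if collapse:
        data = _build_likelihood_data(records, model)
        return _block_loglik(params, model, data, r_os, points)
    total = 0.0
    for rec in records:
        data = _build_likelihood_data([rec], model)
        total += _block_loglik(params, model, data, r_os, points)
    return total


# ---------------------------------------------------------------------------
# parameterization for fitting
# ---------------------------------------------------------------------------

_BOUNDS = {
    "tau3": (-4.0, 4.0), "tau7": (-4.0, 4.0),
    "beta_sex3": (-3.0, 3.0), "beta_sex7": (-3.0, 3.0),
    "a11": (0.0, 0.9999), "a21": (-0.9999, 0.9999), "a22": (0.0, 0.9999),
    "c11": (0.0, 0.9999), "c21": (-0.9999, 0.9999), "c22": (0.0, 0.9999),
    "e21": (-0.9999, 0.9999),
    "b": (-0.95, 0.95), "b3": (-0.95, 0.95), "b7": (-0.95, 0.95),
    "r_os": (0.0, 1.0),
}


class _Parameterization:
    """Maps a free-parameter vector to standardized `CholeskyParams`.

    Standardization is enforced structurally: e11 (and e22 in the bivariate
    case) absorb whatever variance the free paths leave, so every interior
    point of the feasible region satisfies unit liability variance exactly.
    """

    def __init__(self, model: ModelSpec):
        self.model = model
        names = ["tau3"]
        if model.bivariate:
            names.append("tau7")
        if model.sex_effect:
            names.append("beta_sex3")
            if model.bivariate:
                names.append("beta_sex7")
        if model.a:
            names.append("a11")
            if model.bivariate:
                names += ["a21", "a22"]
        if model.c3:
            names.append("c11")
        if model.c7 and model.bivariate:
            names += ["c21", "c22"]
        if model.bivariate:
            names.append("e21")
        if model.prs == "equal":
            names.append("b")
        elif model.prs == "free":
            names.append("b3")
            if model.bivariate:
                names.append("b7")
        if model.free_dzo_ra:
            names.append("r_os")
        self.names = names
        self.bounds = [_BOUNDS[n] for n in names]

    @property
    def n_free(self) -> int:
        return len(self.names)

    def unpack(self, theta: np.ndarray) -> tuple[CholeskyParams, float | None, float]:
        """Returns (params, r_os, violation).

        When the free paths leave less than the floor `_MIN_E_VAR` for a
        non-shared-environment variance, that variance is clamped at the
        floor and the excess is reported as ``violation`` so the objective
        can apply a smooth penalty (a hard cliff would break the
        finite-difference line search near the boundary)."""
        v = dict(zip(self.names, theta))
        b3 = v.get("b", v.get("b3", 0.0))
        b7 = v.get("b", v.get("b7", 0.0)) if self.model.bivariate else 0.0
        a11 = v.get("a11", 0.0)
        c11 = v.get("c11", 0.0)
        rem3 = 1.0 - a11 ** 2 - c11 ** 2 - b3 ** 2
        gap3, viol3 = _smooth_floor(rem3 - _MIN_E_VAR)
        rem3 = _MIN_E_VAR + gap3
        violation = viol3
        rem7 = 1.0
        if self.model.bivariate:
            rem7 = (1.0 - v.get("a21", 0.0) ** 2 - v.get("a22", 0.0) ** 2
                    - v.get("c21", 0.0) ** 2 - v.get("c22", 0.0) ** 2
                    - v.get("e21", 0.0) ** 2 - b7 ** 2)
            gap7, viol7 = _smooth_floor(rem7 - _MIN_E_VAR)
            rem7 = _MIN_E_VAR + gap7
            violation += viol7
        params = CholeskyParams(
            a11=a11, a21=v.get("a21", 0.0), a22=v.get("a22", 0.0),
            c11=c11, c21=v.get("c21", 0.0), c22=v.get("c22", 0.0),
            e11=float(np.sqrt(rem3)),
            e21=v.get("e21", 0.0),
            e22=float(np.sqrt(rem7)) if self.model.bivariate else 1.0,
            b3=b3, b7=b7,
            beta_sex3=v.get("beta_sex3", 0.0), beta_sex7=v.get("beta_sex7", 0.0),
            tau3=v["tau3"], tau7=v.get("tau7", 0.0),
        )
        return params, v.get("r_os"), 0.0


# ---------------------------------------------------------------------------
# starting values
# ---------------------------------------------------------------------------

def _empirical_tables(records) -> dict:
    """Pooled 2x2 tables used for starting values."""
    acc = {("MZ", 3): ([], []), ("MZ", 7): ([], []),
           ("DZ", 3): ([], []), ("DZ", 7): ([], []),
           "cross": ([], [])}
    prev = {("M", 3): [0, 0], ("F", 3): [0, 0], ("M", 7): [0, 0], ("F", 7): [0, 0]}
    for rec in records:
        zc = "MZ" if rec.zygosity.upper() == "MZ" else "DZ"
        for age, p1, p2 in ((3, rec.phen3_1, rec.phen3_2), (7, rec.phen7_1, rec.phen7_2)):
            if p1 is not None and p2 is not None:
                acc[(zc, age)][0].append(p1)
                acc[(zc, age)][1].append(p2)
        for sex, p3, p7 in ((rec.sex1, rec.phen3_1, rec.phen7_1),
                            (rec.sex2, rec.phen3_2, rec.phen7_2)):
            if p3 is not None and p7 is not None:
                acc["cross"][0].append(p3)
                acc["cross"][1].append(p7)
            for age, p in ((3, p3), (7, p7)):
                if p is not None:
                    prev[(sex, age)][0] += int(p)
                    prev[(sex, age)][1] += 1
    return {"tables": acc, "prev": prev}


def _safe_tetrachoric(x, y) -> float:
    try:
        table = TwoByTwoTable.from_pairs(x, y)
        return float(np.clip(tetrachoric_ml(table).rho, -0.98, 0.98))
    except ValueError:
        return 0.0


def _starting_theta(records, prm: _Parameterization) -> np.ndarray:
    model = prm.model
    emp = _empirical_tables(records)
    tabs, prev = emp["tables"], emp["prev"]

    def prevalence(sex, age):
        n1, n = prev[(sex, age)]
        return (n1 + 0.5) / (n + 1.0)

    def pooled_prev(age):
        n1 = prev[("M", age)][0] + prev[("F", age)][0]
        n = prev[("M", age)][1] + prev[("F", age)][1]
        return (n1 + 0.5) / (n + 1.0)

    r_mz3 = _safe_tetrachoric(*tabs[("MZ", 3)])
    r_dz3 = _safe_tetrachoric(*tabs[("DZ", 3)])
    falc3 = fit_to_correlations(r_mz3, r_dz3)
    if model.bivariate:
        r_mz7 = _safe_tetrachoric(*tabs[("MZ", 7)])
        r_dz7 = _safe_tetrachoric(*tabs[("DZ", 7)])
        r37 = _safe_tetrachoric(*tabs["cross"])
        falc7 = fit_to_correlations(r_mz7, r_dz7)

    start = {}
    if model.sex_effect:
        start["tau3"] = threshold_from_prevalence(prevalence("F", 3))
        start["beta_sex3"] = start["tau3"] - threshold_from_prevalence(prevalence("M", 3))
        if model.bivariate:
            start["tau7"] = threshold_from_prevalence(prevalence("F", 7))
            start["beta_sex7"] = start["tau7"] - threshold_from_prevalence(prevalence("M", 7))
    else:
        start["tau3"] = threshold_from_prevalence(pooled_prev(3))
        if model.bivariate:
            start["tau7"] = threshold_from_prevalence(pooled_prev(7))

    a3 = falc3.a if model.c3 else min(falc3.a + falc3.c, 0.95)
    start["a11"] = float(np.sqrt(max(a3, 0.01)))
    start["c11"] = float(np.sqrt(max(falc3.c, 0.01)))
    if model.bivariate:
        a7 = falc7.a if model.c7 else min(falc7.a + falc7.c, 0.95)
        a21 = np.clip(r37 / max(start["a11"], 0.3), -0.9, 0.9)
        a21 = float(np.clip(a21, -0.95 * np.sqrt(max(a7, 0.01)),
                            0.95 * np.sqrt(max(a7, 0.01))))
        start["a21"] = a21
        start["a22"] = float(np.sqrt(max(a7 - a21 ** 2, 0.01)))
        start["c21"] = 0.1
        start["c22"] = 0.1
        start["e21"] = float(0.5 * np.sqrt(max(falc7.e, 0.01)))
    start["b"] = 0.0
    start["b3"] = 0.0
    start["b7"] = 0.0
    start["r_os"] = 0.5
    theta = np.array([start[n] for n in prm.names])
    lo = np.array([b[0] for b in prm.bounds])
    hi = np.array([b[1] for b in prm.bounds])
    return np.clip(theta, lo + 1e-6, hi - 1e-6)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Converged ML estimates with all derived quantities."""

    params: CholeskyParams
    model: ModelSpec
    loglik: float
    n_free: int
    converged: bool
    grad_norm: float
    variance_components: VarianceComponents
    stability: StabilityDecomposition
    implied: dict[str, ImpliedCovariance]
    n_pairs: int
    n_dropped: int
    r_os: float | None = None
    message: str = ""
    n_starts_used: int = 1
    theta: np.ndarray | None = None
    free_names: tuple[str, ...] = ()


class FitError(RuntimeError):
    """Optimization failure; carries the best point found."""

    def __init__(self, message: str, best: FitResult | None = None):
        super().__init__(message)
        self.best = best


def _validate_dataset(data: _LikelihoodData, records, model: ModelSpec) -> None:
    if data.n_pairs == 0:
        raise ValueError("dataset contains no pairs with observed phenotypes")
    zygs = {_zclass(r.zygosity, ModelSpec()) for r in records}
    if "MZ" not in zygs or "DZ" not in zygs:
        raise ValueError("dataset must contain at least one MZ and one DZ pair")
    # non-degenerate phenotype margins per zygosity class and age
    seen: dict = {}
    for rec in records:
        zc = "MZ" if rec.zygosity.upper() == "MZ" else "DZ"
        for age in model.ages:
            vals = ((rec.phen3_1, rec.phen3_2) if age == 3
                    else (rec.phen7_1, rec.phen7_2))
            for v in vals:
                if v is not None:
                    seen.setdefault((zc, age), set()).add(int(v))
    for zc in ("MZ", "DZ"):
        for age in model.ages:
            got = seen.get((zc, age), set())
            if got != {0, 1}:
                raise ValueError(
                    f"degenerate phenotype margin in group {zc} at age {age}: "
                    f"observed values {sorted(got)}"
                )


def fit_ml(
    records: Sequence,
    model: ModelSpec = DEFAULT_MODEL,
    *,
    seed: int = 0,
    n_starts: int = 1,
    points: int = 1024,
    maxiter: int = 500,
    start: "FitResult | np.ndarray | None" = None,
    gtol: float = 1e-5,
    ftol: float = 1e-11,
) -> FitResult:
    """Raw-data maximum-likelihood fit of the liability Cholesky model.

    Pairs are collapsed to distinct (group, sex configuration, response
    pattern) cells before evaluation, so each likelihood call costs one
    vectorized rectangle integration per (group, missingness mask) rather
    than one per pair.  Starting values derive from Falconer estimates of
    pooled tetrachoric correlations; additional jittered restarts (seeded)
    are used if the first optimization does not converge, or when
    ``n_starts > 1`` is requested.
    """
    records = list(records)
    data = _build_likelihood_data(records, model)
    _validate_dataset(data, records, model)
    prm = _Parameterization(model)

    def objective(theta: np.ndarray) -> float:
        params, r_os, violation = prm.unpack(theta)
        penalty = 1e4 * violation + 1e6 * violation ** 2
        return penalty - _block_loglik(params, model, data, r_os, points)

    base = _starting_theta(records, prm)
    if start is not None:
        warm = start.theta if isinstance(start, FitResult) else np.asarray(start)
        if isinstance(start, FitResult):
            lookup = dict(zip(start.free_names, warm))
            if "b" in lookup:  # common slope seeds the free slopes
                lookup.setdefault("b3", lookup["b"])
                lookup.setdefault("b7", lookup["b"])
            base = np.array([lookup.get(n, b) for n, b in zip(prm.names, base)])
        else:
            base = np.asarray(warm, dtype=float)

    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in prm.bounds])
    hi = np.array([b[1] for b in prm.bounds])
    best = None
    tried = 0
    max_total = max(n_starts, 5)
    while tried < max_total:
        theta0 = base if tried == 0 else np.clip(
            base + rng.normal(0.0, 0.05, size=base.shape), lo + 1e-6, hi - 1e-6)
        res = minimize(objective, theta0, method="L-BFGS-B", bounds=prm.bounds,
                       options={"maxiter": maxiter, "ftol": ftol, "gtol": 1e-7})
        tried += 1
        if best is None or res.fun < best.fun:
            best = res
        if tried >= n_starts:
            grad = np.linalg.norm(np.asarray(best.jac)) if best.jac is not None else np.inf
            if best.success or grad < gtol * max(1.0, abs(best.fun)):
                break
    if best is None:
        raise FitError("optimization failed to produce any result")

    params, r_os, violation = prm.unpack(best.x)
    if violation > 1e-6:
        logger.warning("fit ended on the E-variance floor (violation %.2e); "
                       "non-shared environment variance clamped at %g",
                       violation, _MIN_E_VAR)
    grad_norm = float(np.linalg.norm(np.asarray(best.jac)))
    converged = bool(best.success or grad_norm < gtol * max(1.0, abs(best.fun)))
    vc, stab = derived_quantities(params)
    groups = _groups_for(model, r_os)
    implied = {zc: implied_covariance(params, g, tuple(model.ages))
               for zc, g in groups.items()}
    result = FitResult(
        params=params, model=model, loglik=float(-best.fun),
        n_free=prm.n_free, converged=converged, grad_norm=grad_norm,
        variance_components=vc, stability=stab, implied=implied,
        n_pairs=data.n_pairs, n_dropped=data.n_dropped, r_os=r_os,
        message=str(best.message), n_starts_used=tried,
        theta=np.asarray(best.x, dtype=float), free_names=tuple(prm.names),
    )
    if not converged:
        raise FitError(f"fit did not converge after {tried} starts "
                       f"(grad norm {grad_norm:.3g}): {best.message}", best=result)
    return result


# ---------------------------------------------------------------------------
# Falconer method-of-moments solution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FalconerComponents:
    """Single-age method-of-moments ACE solution from twin correlations."""

    a: float
    c: float
    e: float
    truncated_a: bool = False
    truncated_c: bool = False


def fit_to_correlations(r_mz: float, r_dz: float) -> FalconerComponents:
    """Falconer estimates A = 2(rMZ - rDZ), C = 2 rDZ - rMZ, E = 1 - rMZ.

    Negative A or C estimates are truncated to zero (flagged) and the
    remainder renormalized to sum to one.
    """
    for name, r in (("r_mz", r_mz), ("r_dz", r_dz)):
        if not -1.0 < r < 1.0:
            raise ValueError(f"{name} must lie strictly in (-1, 1); got {r!r}")
    a = 2.0 * (r_mz - r_dz)
    c = 2.0 * r_dz - r_mz
    e = 1.0 - r_mz
    trunc_a = a < 0.0
    trunc_c = c < 0.0
    if trunc_a:
        logger.warning("rMZ <= rDZ: additive-genetic estimate truncated to 0")
    a, c = max(a, 0.0), max(c, 0.0)
    total = a + c + e
    return FalconerComponents(a / total, c / total, e / total, trunc_a, trunc_c)
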