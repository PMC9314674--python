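"""Numerical foundations of the liability-threshold model.

The liability-threshold model posits a latent standard-normal "liability"
per person; the observed binary phenotype is 1 when liability exceeds a
threshold fixed by the phenotype's prevalence.  Everything downstream
(tetrachoric correlations, the ACE likelihood) reduces to rectangle
probabilities of low-dimensional multivariate normal vectors, so this module
provides:

* prevalence <-> threshold conversion,
* rectangle probabilities ``P(lower < X < upper)`` for zero-mean normal
  vectors of dimension 1-4 (exact special-function formulas in 1-D/2-D,
  separable quasi-Monte-Carlo integration with a *fixed* scrambled Sobol
  point set in 3-D/4-D so that likelihood values are reproducible
  run-to-run),
* maximum-likelihood tetrachoric correlation for a 2x2 table of
  dichotomized pairs (two-step: thresholds from the margins, then a
  bracketed 1-D search over the latent correlation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import ndtr, ndtri
from scipy.stats import qmc

logger = logging.getLogger("twinace")

__all__ = [
    "DEFAULT_QMC_POINTS",
    "ThresholdSet",
    "TwoByTwoTable",
    "RectangleSpec",
    "TetrachoricResult",
    "threshold_from_prevalence",
    "prevalence_from_threshold",
    "bvn_cdf",
    "bvn_rectangle",
    "mvn_rectangle",
    "tetrachoric_ml",
]

#: Default quasi-Monte-Carlo point count for 3-D/4-D rectangle probabilities.
DEFAULT_QMC_POINTS = 8192

# Fixed scrambling seed for the Sobol point set: rectangle probabilities (and
# hence likelihood values) must be identical across calls and across runs.
_QMC_SEED = 186525

_PSD_TOL = 1e-10
_RHO_BOUND = 1.0 - 1e-8
# Integration limit for the 2-D quadrature; |x| > 8.5 carries < 1e-17 mass.
_TAIL = 8.5
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(24)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


# ---------------------------------------------------------------------------
# thresholds
# ---------------------------------------------------------------------------

def threshold_from_prevalence(p: float) -> float:
    """Standard-normal threshold above which a fraction ``p`` of mass lies.

    The estimated threshold equals the standard-normal quantile associated
    with probability ``1 - p``; an individual is affected when liability
    exceeds it.
    """
    p = float(p)
    if not 0.0 < p < 1.0:
        raise ValueError(f"prevalence must lie strictly in (0, 1); got {p!r}")
    return float(-ndtri(p))


def prevalence_from_threshold(tau: float) -> float:
    """Upper-tail mass above ``tau``; inverse of `threshold_from_prevalence`."""
    return float(ndtr(-float(tau)))


@dataclass(frozen=True)
class ThresholdSet:
    """Per-age thresholds with optional male-vs-female liability shifts.

    The sex effect is a liability mean shift for males, which is equivalent
    to a lowered effective threshold: ``tau_age - beta_sex_age`` for boys.
    """

    tau_age3: float
    tau_age7: float
    beta_sex_age3: float = 0.0
    beta_sex_age7: float = 0.0

    def __post_init__(self) -> None:
        for name in ("tau_age3", "tau_age7", "beta_sex_age3", "beta_sex_age7"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def effective(self, age: int, male: bool) -> float:
        """Effective threshold for one person (``age`` is 3 or 7)."""
        if age == 3:
            return self.tau_age3 - (self.beta_sex_age3 if male else 0.0)
        if age == 7:
            return self.tau_age7 - (self.beta_sex_age7 if male else 0.0)
        raise ValueError(f"age must be 3 or 7; got {age!r}")


# ---------------------------------------------------------------------------
# 2x2 tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwoByTwoTable:
    """Joint counts of two dichotomized variables.

    ``n11`` counts pairs affected on both variables, ``n10`` affected on the
    first only, ``n01`` on the second only, ``n00`` on neither.
    """

    n11: float
    n10: float
    n01: float
    n00: float

    def __post_init__(self) -> None:
        cells = (self.n11, self.n10, self.n01, self.n00)
        if any(c < 0 for c in cells):
            raise ValueError(f"cell counts must be nonnegative; got {cells}")
        if self.total <= 0:
            raise ValueError("table must have a positive total count")

    @property
    def total(self) -> float:
        return self.n11 + self.n10 + self.n01 + self.n00

    @property
    def prevalence1(self) -> float:
        """Marginal prevalence of the first (row) variable."""
        return (self.n11 + self.n10) / self.total

    @property
    def prevalence2(self) -> float:
        """Marginal prevalence of the second (column) variable."""
        return (self.n11 + self.n01) / self.total

    @classmethod
    def from_pairs(cls, x, y) -> "TwoByTwoTable":
        """Cross-tabulate two aligned 0/1 vectors (NaN/None entries dropped)."""
        x = np.asarray([np.nan if v is None else v for v in x], dtype=float)
        y = np.asarray([np.nan if v is None else v for v in y], dtype=float)
        keep = ~(np.isnan(x) | np.isnan(y))
        x, y = x[keep].astype(bool), y[keep].astype(bool)
        return cls(
            n11=int(np.sum(x & y)),
            n10=int(np.sum(x & ~y)),
            n01=int(np.sum(~x & y)),
            n00=int(np.sum(~x & ~y)),
        )


# ---------------------------------------------------------------------------
# MVN rectangle probabilities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RectangleSpec:
    """A rectangle ``(lower, upper)`` under a zero-mean normal with unit
    variances and the given correlation matrix (dimension 1-4)."""

    lower: np.ndarray
    upper: np.ndarray
    corr: np.ndarray

    def __post_init__(self) -> None:
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        corr = np.asarray(self.corr, dtype=float)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        object.__setattr__(self, "corr", corr)
        d = lower.shape[0]
        if lower.ndim != 1 or upper.shape != (d,) or not 1 <= d <= 4:
            raise ValueError("bounds must be 1-D arrays of equal length 1-4")
        if corr.shape != (d, d):
            raise ValueError(f"correlation matrix must be {d}x{d}")
        if not np.all(lower < upper):
            raise ValueError("every lower bound must be below its upper bound")
        if not np.allclose(corr, corr.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(corr).min() < -_PSD_TOL:
            raise ValueError("correlation matrix is not positive semidefinite")

    @property
    def dim(self) -> int:
        return self.lower.shape[0]


def bvn_cdf(h: float, k: float, rho: float) -> float:
    """``P(X <= h, Y <= k)`` for a standard bivariate normal.

    Computed by composite Gauss-Legendre quadrature of
    ``int phi(x) Phi((k - rho x)/sqrt(1-rho^2)) dx`` on panels of width
    <= 0.5, which is accurate to near machine precision and fully
    deterministic.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"correlation must lie in [-1, 1]; got {rho!r}")
    if np.isneginf(h) or np.isneginf(k):
        return 0.0
    if np.isposinf(h):
        return float(ndtr(k))
    if np.isposinf(k):
        return float(ndtr(h))
    if rho >= 1.0 - 1e-14:
        return float(ndtr(min(h, k)))
    if rho <= -1.0 + 1e-14:
        return float(max(0.0, ndtr(h) + ndtr(k) - 1.0))
    hi = min(h, _TAIL)
    if hi <= -_TAIL:
        return 0.0
    n_panels = max(4, int(np.ceil((hi + _TAIL) / 0.5)))
    edges = np.linspace(-_TAIL, hi, n_panels + 1)
    mid = 0.5 * (edges[1:] + edges[:-1])
    half = 0.5 * np.diff(edges)
    x = (mid[:, None] + half[:, None] * _GL_NODES[None, :]).ravel()
    w = (half[:, None] * _GL_WEIGHTS[None, :]).ravel()
    s = np.sqrt(1.0 - rho * rho)
    val = np.sum(w * np.exp(-0.5 * x * x) * ndtr((k - rho * x) / s))
    return float(np.clip(val * _INV_SQRT_2PI, 0.0, 1.0))


def _bvn_cdf_inf(x: float, y: float, rho: float) -> float:
    if np.isneginf(x) or np.isneginf(y):
        return 0.0
    return bvn_cdf(x, y, rho)


def bvn_rectangle(a1: float, b1: float, a2: float, b2: float, rho: float) -> float:
    """``P(a1 < X < b1, a2 < Y < b2)`` for a standard bivariate normal."""
    val = (
        _bvn_cdf_inf(b1, b2, rho)
        - _bvn_cdf_inf(a1, b2, rho)
        - _bvn_cdf_inf(b1, a2, rho)
        + _bvn_cdf_inf(a1, a2, rho)
    )
    return float(np.clip(val, 0.0, 1.0))


@lru_cache(maxsize=32)
def _sobol_points(n_coords: int, n_points: int) -> np.ndarray:
    eng = qmc.Sobol(d=n_coords, scramble=True, seed=_QMC_SEED)
    return eng.random_base2(int(np.log2(n_points)))


def _safe_cholesky(corr: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor, tolerating tiny negative eigenvalues."""
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        vals, vecs = np.linalg.eigh(corr)
        vals = np.clip(vals, 1e-12, None)
        fixed = (vecs * vals) @ vecs.T
        d = np.sqrt(np.diag(fixed))
        fixed = fixed / np.outer(d, d)
        return np.linalg.cholesky(fixed + 1e-12 * np.eye(corr.shape[0]))


def genz_rectangles(
    lower: np.ndarray,
    upper: np.ndarray,
    corr: np.ndarray,
    points: int = DEFAULT_QMC_POINTS,
) -> np.ndarray:
    """Vectorized rectangle probabilities for many bound sets sharing one
    correlation matrix.

    Uses the separation-of-variables transform (sequential conditioning on
    the Cholesky factor) with a fixed scrambled Sobol point set, so results
    are deterministic for fixed inputs.  ``lower``/``upper`` have shape
    ``(m, d)``; the return has shape ``(m,)``.
    """
    lower = np.atleast_2d(np.asarray(lower, dtype=float))
    upper = np.atleast_2d(np.asarray(upper, dtype=float))
    m, d = lower.shape
    if d == 1:
        return np.clip(ndtr(upper[:, 0]) - ndtr(lower[:, 0]), 0.0, 1.0)
    n = 1 << max(1, int(np.ceil(np.log2(points))))
    L = _safe_cholesky(np.asarray(corr, dtype=float))
    u = _sobol_points(d - 1, n)  # (n, d-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        d_prev = ndtr(lower[:, 0] / L[0, 0])[:, None]  # (m, 1)
        e_prev = ndtr(upper[:, 0] / L[0, 0])[:, None]
        f = e_prev - d_prev  # broadcasts to (m, n) later
        ys: list[np.ndarray] = []
        for j in range(1, d):
            w = u[:, j - 1][None, :]  # (1, n)
            z = d_prev + w * (e_prev - d_prev)
            z = np.clip(z, 1e-15, 1.0 - 1e-15)
            ys.append(ndtri(z))
            s = sum(L[j, i] * ys[i] for i in range(j))
            lo = (lower[:, j][:, None] - s) / L[j, j]
            up = (upper[:, j][:, None] - s) / L[j, j]
            d_prev = ndtr(lo)
            e_prev = ndtr(up)
            f = f * (e_prev - d_prev)
    return np.clip(f.mean(axis=1), 0.0, 1.0)


def mvn_rectangle(spec: RectangleSpec, points: int = DEFAULT_QMC_POINTS) -> float:
    """``P(lower < X < upper)`` for a zero-mean normal vector.

    Dimensions that are unbounded on both sides are marginalized out
    exactly before integration.  1-D and 2-D cases use exact
    special-function formulas; 3-D/4-D use the deterministic
    quasi-Monte-Carlo scheme of `genz_rectangles`.
    """
    keep = ~(np.isneginf(spec.lower) & np.isposinf(spec.upper))
    lower, upper = spec.lower[keep], spec.upper[keep]
    corr = spec.corr[np.ix_(keep, keep)]
    d = lower.shape[0]
    if d == 0:
        return 1.0
    if d == 1:
        return float(np.clip(ndtr(upper[0]) - ndtr(lower[0]), 0.0, 1.0))
    if d == 2:
        return bvn_rectangle(lower[0], upper[0], lower[1], upper[1], corr[0, 1])
    return float(genz_rectangles(lower[None, :], upper[None, :], corr, points)[0])


# ---------------------------------------------------------------------------
# tetrachoric correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TetrachoricResult:
    """ML tetrachoric correlation with margin-fixed thresholds."""

    rho: float
    tau1: float
    tau2: float
    loglik: float
    se: float | None = None
    boundary: bool = False
    continuity_corrected: bool = False


def _cell_probabilities(tau1: float, tau2: float, rho: float) -> np.ndarray:
    """Predicted (p11, p10, p01, p00) under the bivariate normal model."""
    q1 = float(ndtr(-tau1))
    q2 = float(ndtr(-tau2))
    p11 = 1.0 - ndtr(tau1) - ndtr(tau2) + bvn_cdf(tau1, tau2, rho)
    p11 = float(np.clip(p11, 0.0, min(q1, q2)))
    p10 = max(q1 - p11, 0.0)
    p01 = max(q2 - p11, 0.0)
    p00 = max(1.0 - q1 - q2 + p11, 0.0)
    return np.array([p11, p10, p01, p00])


def tetrachoric_loglik(table: TwoByTwoTable, rho: float,
                       tau1: float | None = None,
                       tau2: float | None = None) -> float:
    """Multinomial log-likelihood of the table at latent correlation ``rho``."""
    if tau1 is None:
        tau1 = threshold_from_prevalence(table.prevalence1)
    if tau2 is None:
        tau2 = threshold_from_prevalence(table.prevalence2)
    probs = _cell_probabilities(tau1, tau2, rho)
    counts = np.array([table.n11, table.n10, table.n01, table.n00])
    return float(np.sum(counts * np.log(np.clip(probs, 1e-300, None))))


def tetrachoric_ml(table: TwoByTwoTable) -> TetrachoricResult:
    """Two-step ML tetrachoric correlation for a 2x2 table.

    Thresholds are fixed at the standard-normal quantiles of the marginal
    prevalences; the correlation maximizes the multinomial likelihood of the
    four cells via a bracketed Brent search on ``[-1 + 1e-8, 1 - 1e-8]``.

    Perfect association (both discordant, or both concordant, cells zero)
    is returned as a boundary estimate at ``+/-(1 - 1e-8)``.  If only some
    cells are zero, 0.5 is added to every cell (flagged) to keep the
    estimate finite.
    """
    margins = (
        table.n11 + table.n10, table.n01 + table.n00,
        table.n11 + table.n01, table.n10 + table.n00,
    )
    if any(mgn <= 0 for mgn in margins):
        raise ValueError(
            "degenerate margin: both outcomes must occur on each variable; "
            f"margins (row1, row0, col1, col0) = {margins}"
        )
    tau1 = threshold_from_prevalence(table.prevalence1)
    tau2 = threshold_from_prevalence(table.prevalence2)

    if table.n10 == 0 and table.n01 == 0:
        rho = _RHO_BOUND
        return TetrachoricResult(rho, tau1, tau2,
                                 tetrachoric_loglik(table, rho, tau1, tau2),
                                 se=None, boundary=True)
    if table.n11 == 0 and table.n00 == 0:
        rho = -_RHO_BOUND
        return TetrachoricResult(rho, tau1, tau2,
                                 tetrachoric_loglik(table, rho, tau1, tau2),
                                 se=None, boundary=True)

    corrected = False
    work = table
    if 0 in (table.n11, table.n10, table.n01, table.n00):
        corrected = True
        work = TwoByTwoTable(table.n11 + 0.5, table.n10 + 0.5,
                             table.n01 + 0.5, table.n00 + 0.5)
        tau1 = threshold_from_prevalence(work.prevalence1)
        tau2 = threshold_from_prevalence(work.prevalence2)

    res = minimize_scalar(
        lambda r: -tetrachoric_loglik(work, r, tau1, tau2),
        bounds=(-_RHO_BOUND, _RHO_BOUND),
        method="bounded",
        options={"xatol": 1e-10},
    )
    rho = float(res.x)
    boundary = abs(rho) > 1.0 - 1e-6
    if boundary:
        rho = float(np.sign(rho)) * _RHO_BOUND
    loglik = tetrachoric_loglik(work, rho, tau1, tau2)

    se = None
    if not boundary:
        h = 1e-5
        d2 = (
            tetrachoric_loglik(work, rho + h, tau1, tau2)
            - 2.0 * loglik
            + tetrachoric_loglik(work, rho - h, tau1, tau2)
        ) / (h * h)
        if d2 < 0:
            se = float(1.0 / np.sqrt(-d2))
    return TetrachoricResult(rho, tau1, tau2, loglik, se=se,
                             boundary=boundary, continuity_corrected=corrected)
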