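"""Synthetic twin-registry cohorts with the structure the analysis assumes.

The generator draws latent A/C/E factor scores per pair exactly as the
Cholesky path model prescribes — A factors correlated ``k`` across co-twins
(1 for MZ, 0.5 for DZ), C shared, E independent, an optional additive
polygenic score shared by MZ co-twins and correlated 0.5 in DZ pairs —
builds liabilities through the paths plus a male mean shift, dichotomizes at
the thresholds, and applies completely-at-random per-observation
missingness.

Defaults emulate a registry cohort of ~7,300 MZ and ~14,200 DZ pairs with
age-3 prevalence near 10%, age-7 prevalence near 9%, a male excess among
cases, and roughly 35% of children observed at both ages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .cholesky import CholeskyParams
from .liability import threshold_from_prevalence

logger = logging.getLogger("twinace")

__all__ = [
    "TwinPairRecord",
    "SimulationConfig",
    "default_generating_params",
    "params_from_components",
    "simulate_pairs",
    "Table1Summary",
    "table1_like_summary",
]


# Sex-specific prevalence targets derived from the four-phenotype-by-sex
# cross-tabulation of a registry cohort of 15,213 children: age 3 affected
# = transient + persistent, age 7 affected = school-age onset + persistent.
PREV3_MALE = 946 / 7538
PREV3_FEMALE = 635 / 7675
PREV7_MALE = 773 / 7538
PREV7_FEMALE = 534 / 7675

#: Generating values for the standardized variance components.
COMPONENTS_AGE3 = {"a": 0.796, "c": 0.157, "e": 0.046}
COMPONENTS_AGE7 = {"a": 0.904, "c": 0.0, "e": 0.096}
GENETIC_CORRELATION = 0.807
ENVIRONMENT_CORRELATION = 0.934


@dataclass(frozen=True)
class TwinPairRecord:
    """One twin pair: zygosity, sexes, binary phenotypes at two ages,
    optional standardized polygenic scores.  ``None`` marks missing."""

    pair_id: str
    zygosity: str  # MZ | DZSS | DZOS
    sex1: str
    sex2: str
    phen3_1: int | None
    phen7_1: int | None
    phen3_2: int | None
    phen7_2: int | None
    prs1: float | None = None
    prs2: float | None = None

    def __post_init__(self) -> None:
        if self.zygosity not in ("MZ", "DZSS", "DZOS"):
            raise ValueError(f"unknown zygosity {self.zygosity!r}")
        for s in (self.sex1, self.sex2):
            if s not in ("M", "F"):
                raise ValueError(f"sex must be 'M' or 'F'; got {s!r}")
        if self.zygosity == "MZ" and self.sex1 != self.sex2:
            raise ValueError("MZ pairs must be same-sex")
        for v in (self.phen3_1, self.phen7_1, self.phen3_2, self.phen7_2):
            if v not in (0, 1, None):
                raise ValueError(f"phenotypes must be 0/1/None; got {v!r}")


def params_from_components(
    a3: float, c3: float, e3: float,
    a7: float, c7: float, e7: float,
    r_a: float, r_e: float,
    tau3: float, tau7: float,
    beta_sex3: float = 0.0, beta_sex7: float = 0.0,
    b3: float = 0.0, b7: float = 0.0,
) -> CholeskyParams:
    """Cholesky paths reproducing given standardized components and factor
    correlations.

    With PRS slopes the A/C/E shares are rescaled so the total per-age
    variance (including b^2) is one.
    """
    scale3 = 1.0 - b3 ** 2
    scale7 = 1.0 - b7 ** 2
    tot3, tot7 = a3 + c3 + e3, a7 + c7 + e7
    for name, tot in (("age 3", tot3), ("age 7", tot7)):
        if abs(tot - 1.0) > 0.005:  # allow shares rounded to 3 decimals
            raise ValueError(f"{name} components must sum to 1; got {tot}")
    a3, c3, e3 = (v * scale3 / tot3 for v in (a3, c3, e3))
    a7, c7, e7 = (v * scale7 / tot7 for v in (a7, c7, e7))
    a11 = np.sqrt(a3)
    c11 = np.sqrt(c3)
    e11 = np.sqrt(e3)
    a21 = r_a * np.sqrt(a7) if a3 > 0 else 0.0
    e21 = r_e * np.sqrt(e7)
    c21 = np.sqrt(c7) if c3 > 0 and c7 > 0 else 0.0  # rC = 1 when both present
    a22 = np.sqrt(max(a7 - a21 ** 2, 0.0))
    c22 = np.sqrt(max(c7 - c21 ** 2, 0.0))
    e22 = np.sqrt(max(e7 - e21 ** 2, 0.0))
    return CholeskyParams(
        a11=a11, a21=a21, a22=a22, c11=c11, c21=c21, c22=c22,
        e11=e11, e21=e21, e22=e22, b3=b3, b7=b7,
        beta_sex3=beta_sex3, beta_sex7=beta_sex7, tau3=tau3, tau7=tau7,
    )


def default_generating_params(b3: float = 0.0, b7: float = 0.0) -> CholeskyParams:
    """Generating values: the default cohort's components and correlations,
    with thresholds and male shifts matching the registry-like
    sex-specific prevalences."""
    tau3 = threshold_from_prevalence(PREV3_FEMALE)
    tau7 = threshold_from_prevalence(PREV7_FEMALE)
    return params_from_components(
        COMPONENTS_AGE3["a"], COMPONENTS_AGE3["c"], COMPONENTS_AGE3["e"],
        COMPONENTS_AGE7["a"], COMPONENTS_AGE7["c"], COMPONENTS_AGE7["e"],
        GENETIC_CORRELATION, ENVIRONMENT_CORRELATION,
        tau3=tau3, tau7=tau7,
        beta_sex3=tau3 - threshold_from_prevalence(PREV3_MALE),
        beta_sex7=tau7 - threshold_from_prevalence(PREV7_MALE),
        b3=b3, b7=b7,
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort composition and generating values.

    Group sizes default to a registry-like cohort: 7,329 MZ pairs (split
    evenly by sex), 7,177 same-sex DZ pairs (split evenly) and 7,035
    opposite-sex DZ pairs.  ``miss3``/``miss7`` are per-observation
    missingness probabilities (completely at random); 0.406 makes ~35% of
    children complete at both ages.
    """

    n_mz_mm: int = 3665
    n_mz_ff: int = 3664
    n_dz_mm: int = 3589
    n_dz_ff: int = 3588
    n_dz_os: int = 7035
    params: CholeskyParams = field(default_factory=default_generating_params)
    include_prs: bool = False
    genotyped_fraction: float = 0.155
    miss3: float = 0.406
    miss7: float = 0.406
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = (self.n_mz_mm, self.n_mz_ff, self.n_dz_mm, self.n_dz_ff, self.n_dz_os)
        if any(n < 0 for n in sizes) or sum(sizes) == 0:
            raise ValueError("group sizes must be nonnegative with positive total")
        for name in ("genotyped_fraction", "miss3", "miss7"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]; got {v}")
        if not self.include_prs and (self.params.b3 != 0.0 or self.params.b7 != 0.0):
            raise ValueError("nonzero PRS slopes require include_prs=True")

    @property
    def total_pairs(self) -> int:
        return self.n_mz_mm + self.n_mz_ff + self.n_dz_mm + self.n_dz_ff + self.n_dz_os

    def scaled(self, factor: float) -> "SimulationConfig":
        """Same conditions at a down-scaled cohort size (desk-scale runs)."""
        return replace(
            self,
            n_mz_mm=int(round(self.n_mz_mm * factor)),
            n_mz_ff=int(round(self.n_mz_ff * factor)),
            n_dz_mm=int(round(self.n_dz_mm * factor)),
            n_dz_ff=int(round(self.n_dz_ff * factor)),
            n_dz_os=int(round(self.n_dz_os * factor)),
        )


def _correlated_pair(rng: np.random.Generator, n: int, rho: float) -> tuple[np.ndarray, np.ndarray]:
    """Two standard-normal vectors with correlation ``rho`` (factor shared
    exactly when rho == 1)."""
    if rho >= 1.0:
        z = rng.standard_normal(n)
        return z, z.copy()
    shared = rng.standard_normal(n)
    u1 = rng.standard_normal(n)
    u2 = rng.standard_normal(n)
    s, u = np.sqrt(rho), np.sqrt(1.0 - rho)
    return s * shared + u * u1, s * shared + u * u2


def simulate_pairs(config: SimulationConfig) -> list[TwinPairRecord]:
    """Draw a full cohort; byte-identical output for a fixed config/seed.

    Pairs with no observed phenotype at all are dropped (with a logged
    count), matching the retention rule of the raw-data likelihood.
    """
    rng = np.random.default_rng(config.seed)
    p = config.params
    groups = [
        ("MZ", "M", "M", config.n_mz_mm, 1.0),
        ("MZ", "F", "F", config.n_mz_ff, 1.0),
        ("DZSS", "M", "M", config.n_dz_mm, 0.5),
        ("DZSS", "F", "F", config.n_dz_ff, 0.5),
        ("DZOS", "M", "F", config.n_dz_os, 0.5),
    ]
    records: list[TwinPairRecord] = []
    n_dropped = 0
    for gi, (zyg, sex1, sex2, n, k) in enumerate(groups):
        if n == 0:
            continue
        a1_1, a1_2 = _correlated_pair(rng, n, k)   # age-3 A factor
        a2_1, a2_2 = _correlated_pair(rng, n, k)   # age-7-specific A factor
        c1 = rng.standard_normal(n)                # C shared exactly
        c2 = rng.standard_normal(n)
        e1_1, e1_2 = rng.standard_normal(n), rng.standard_normal(n)
        e2_1, e2_2 = rng.standard_normal(n), rng.standard_normal(n)
        if config.include_prs:
            prs_1, prs_2 = _correlated_pair(rng, n, 1.0 if k == 1.0 else 0.5)
            genotyped = rng.random(n) < config.genotyped_fraction
        else:
            prs_1 = prs_2 = np.zeros(n)
            genotyped = np.zeros(n, dtype=bool)

        def liability(a1, a2, e1, e2, prs, male: bool):
            liab3 = (p.a11 * a1 + p.c11 * c1 + p.e11 * e1 + p.b3 * prs
                     + (p.beta_sex3 if male else 0.0))
            liab7 = (p.a21 * a1 + p.a22 * a2 + p.c21 * c1 + p.c22 * c2
                     + p.e21 * e1 + p.e22 * e2 + p.b7 * prs
                     + (p.beta_sex7 if male else 0.0))
            return liab3, liab7

        l3_1, l7_1 = liability(a1_1, a2_1, e1_1, e2_1, prs_1, sex1 == "M")
        l3_2, l7_2 = liability(a1_2, a2_2, e1_2, e2_2, prs_2, sex2 == "M")
        y3_1 = (l3_1 > p.tau3).astype(int)
        y7_1 = (l7_1 > p.tau7).astype(int)
        y3_2 = (l3_2 > p.tau3).astype(int)
        y7_2 = (l7_2 > p.tau7).astype(int)
        obs = rng.random((n, 4)) >= np.array([config.miss3, config.miss7,
                                              config.miss3, config.miss7])
        for i in range(n):
            vals = (
                int(y3_1[i]) if obs[i, 0] else None,
                int(y7_1[i]) if obs[i, 1] else None,
                int(y3_2[i]) if obs[i, 2] else None,
                int(y7_2[i]) if obs[i, 3] else None,
            )
            if all(v is None for v in vals):
                n_dropped += 1
                continue
            records.append(TwinPairRecord(
                pair_id=f"{zyg}{gi}-{i:05d}",
                zygosity=zyg, sex1=sex1, sex2=sex2,
                phen3_1=vals[0], phen7_1=vals[1],
                phen3_2=vals[2], phen7_2=vals[3],
                prs1=float(prs_1[i]) if genotyped[i] else None,
                prs2=float(prs_2[i]) if genotyped[i] else None,
            ))
    if n_dropped:
        logger.info("simulate_pairs: dropped %d pairs with no observed phenotype",
                    n_dropped)
    return records


# ---------------------------------------------------------------------------
# four-group phenotype classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Table1Summary:
    """Per-child classification by phenotype course between the two ages."""

    transient: int        # affected at 3, not at 7
    school_age_onset: int  # not at 3, affected at 7
    persistent: int       # affected at both
    never: int            # affected at neither
    incomplete: int       # missing either age

    @property
    def classified(self) -> int:
        return self.transient + self.school_age_onset + self.persistent + self.never

    @property
    def percentages(self) -> dict[str, float]:
        n = self.classified
        return {
            "transient": 100.0 * self.transient / n,
            "school_age_onset": 100.0 * self.school_age_onset / n,
            "persistent": 100.0 * self.persistent / n,
            "never": 100.0 * self.never / n,
        }


def table1_like_summary(records) -> Table1Summary:
    """Classify children with both ages observed as transient (1,0),
    school-age onset (0,1), persistent (1,1) or never (0,0); children
    missing either age are counted separately.  Percentages use the
    classified total as denominator."""
    counts = {"transient": 0, "school_age_onset": 0, "persistent": 0,
              "never": 0, "incomplete": 0}
    for rec in records:
        for p3, p7 in ((rec.phen3_1, rec.phen7_1), (rec.phen3_2, rec.phen7_2)):
            if p3 is None or p7 is None:
                counts["incomplete"] += 1
            elif p3 and p7:
                counts["persistent"] += 1
            elif p3:
                counts["transient"] += 1
            elif p7:
                counts["school_age_onset"] += 1
            else:
                counts["never"] += 1
    return Table1Summary(**counts)
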