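import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import twinace as ta
from twinace.liability import bvn_cdf, threshold_from_prevalence

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def generating_params() -> ta.CholeskyParams:
    return ta.default_generating_params()


@pytest.fixture(scope="session")
def small_cohort() -> list[ta.TwinPairRecord]:
    """~1,000-pair cohort at the default generating conditions."""
    return ta.simulate_pairs(ta.SimulationConfig(seed=42).scaled(0.05))


@pytest.fixture(scope="session")
def tiny_cohort() -> list[ta.TwinPairRecord]:
    """~200-pair fixture for likelihood equivalence checks."""
    return ta.simulate_pairs(ta.SimulationConfig(seed=7).scaled(0.01))


def expected_count_records(
    rho_mz: float,
    rho_dz: float,
    prevalence: float,
    n_per_group: int,
) -> list[ta.TwinPairRecord]:
    """Single-age pair records whose cross-twin 2x2 cells equal the
    *expected* counts under given tetrachoric correlations (no sampling)."""
    tau = threshold_from_prevalence(prevalence)
    from scipy.special import ndtr

    records = []
    for zyg, rho in (("MZ", rho_mz), ("DZSS", rho_dz)):
        q = float(ndtr(-tau))
        p11 = 1.0 - 2.0 * float(ndtr(tau)) + bvn_cdf(tau, tau, rho)
        p10 = q - p11
        p00 = 1.0 - 2.0 * q + p11
        for pat, frac in (((1, 1), p11), ((1, 0), p10), ((0, 1), p10), ((0, 0), p00)):
            for i in range(int(round(frac * n_per_group))):
                records.append(ta.TwinPairRecord(
                    pair_id=f"{zyg}-{pat[0]}{pat[1]}-{i}", zygosity=zyg,
                    sex1="F", sex2="F",
                    phen3_1=pat[0], phen7_1=None, phen3_2=pat[1], phen7_2=None,
                ))
    return records
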