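import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import blockrand as br
from blockrand.model import ExperimentalUnit

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def s1_cohort():
    """The 16-unit, 3-covariate, marked synthetic worked-example cohort."""
    return br.s1_like_cohort(seed=1)


@pytest.fixture(scope="session")
def s1_design():
    return br.BlockDesign(block_sizes=(8, 8), subgroup_sizes=(4, 4))


@pytest.fixture
def tiny_cohort():
    """Four units, one covariate 1..4, no markers."""
    units = tuple(
        ExperimentalUnit(id=lab, covariates=(float(v),))
        for lab, v in zip("abcd", (1, 2, 3, 4))
    )
    return br.CohortTable(covariate_names=("x",), units=units)


@pytest.fixture(scope="session")
def s1_all_scores(s1_cohort):
    """Exhaustive oracle: every unique [8,8] block set of the fixture, scored."""
    from blockrand.simulation import score_full_enumeration

    return score_full_enumeration(s1_cohort, (8, 8))


def pure_python_score(block_set, cohort, weights=None):
    """Independent balance-score oracle using statistics-module arithmetic.

    Deliberately avoids numpy and the package's ranking code paths.
    """
    import statistics

    p = cohort.n_covariates
    weights = weights or [1.0] * p
    index = {u.id: u for u in cohort.units}
    total = 0.0
    for i in range(p):
        means, cvs = [], []
        pooled = []
        for block in block_set.blocks:
            vals = [index[u].covariates[i] for u in block]
            pooled.extend(vals)
            mu = statistics.fmean(vals)
            sd = statistics.stdev(vals) if len(vals) > 1 else 0.0
            means.append(mu)
            cvs.append(sd / mu)
        blockset_sd = statistics.stdev(pooled) if len(pooled) > 1 else 0.0
        mean_term = (
            (max(means) - min(means)) / blockset_sd if blockset_sd > 0 else 0.0
        )
        total += (mean_term + (max(cvs) - min(cvs))) * weights[i]
    return total
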