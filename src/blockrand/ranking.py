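"""Balance score of a block set.

For every covariate i the score accumulates two between-block imbalance
terms: the maximal difference of block means, expressed as a proportion of
the SD of the covariate over all blocked units, and the maximal difference
of block coefficients of variation (CV = SD / mean).  Each covariate's
contribution is multiplied by its user weight and the contributions are
summed:

    score = sum_i (dMeanMax_i / SD_blockset_i + dCVMax_i) * w_i

Lower is better; 0 means every covariate has identical block means and CVs.
Conventions (configurable on :class:`~blockrand.model.BlockDesign`):
sample SD (n-1) everywhere, CV as a proportion, singleton-block CV = 0, and
a constant covariate (zero block-set SD) contributes a zero mean term.  A
block mean of exactly zero makes the CV undefined and is a hard error; the
score therefore presumes positive-valued (or at least sign-stable, nonzero
mean) covariates, as is natural for baseline measurements such as body
weight or plasma lipid levels.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from .model import (
    BlockDesign,
    BlockSet,
    CohortTable,
    CovariateSummary,
    RankedBlockSet,
    RankingError,
    UndefinedCVError,
)

logger = logging.getLogger(__name__)


def _sd(values: np.ndarray, sample: bool) -> float:
    if values.size < 2:
        return 0.0
    return float(np.std(values, ddof=1 if sample else 0))


def summarize_covariate(
    block_set: BlockSet,
    cohort: CohortTable,
    i: int,
    *,
    sample_sd: bool = True,
    cv_percent: bool = False,
) -> CovariateSummary:
    """Per-block means, SDs and CVs of covariate ``i`` plus the max-difference
    terms entering the balance score.

    Raises
    ------
    UndefinedCVError
        If any block mean is exactly zero.
    """
    X = cohort.covariate_matrix()
    index = cohort.index
    means, sds, cvs = [], [], []
    blocked: list[np.ndarray] = []
    for b in block_set.blocks:
        vals = X[[index[u] for u in b], i]
        blocked.append(vals)
        mean = float(np.mean(vals))
        if mean == 0.0:
            raise UndefinedCVError(
                f"covariate {cohort.covariate_names[i]!r}: a block mean is exactly 0, "
                "its coefficient of variation is undefined"
            )
        if mean < 0:
            logger.warning(
                "covariate %r has a negative block mean (%.4g); CVs of "
                "negative-mean covariates are signed",
                cohort.covariate_names[i],
                mean,
            )
        sd = _sd(vals, sample_sd)
        means.append(mean)
        sds.append(sd)
        cvs.append(sd / mean * (100.0 if cv_percent else 1.0))
    pooled = np.concatenate(blocked)
    return CovariateSummary(
        covariate_index=i,
        block_means=tuple(means),
        block_sds=tuple(sds),
        block_cvs=tuple(cvs),
        blockset_sd=_sd(pooled, sample_sd),
        delta_mean_max=float(max(means) - min(means)),
        delta_cv_max=float(max(cvs) - min(cvs)),
    )


def rank_block_set(
    block_set: BlockSet, cohort: CohortTable, design: BlockDesign
) -> RankedBlockSet:
    """Score one block set and attach its per-covariate summaries.

    ``marker_modifications`` is left unset here; the engine fills it in when
    subgroups are defined (it is reported beside the score, never added to
    it).
    """
    weights = design.weights
    if weights is None:
        weights = tuple(1.0 for _ in range(cohort.n_covariates))
    if len(weights) != cohort.n_covariates:
        raise RankingError(
            f"{len(weights)} weights for {cohort.n_covariates} covariates"
        )
    summaries = tuple(
        summarize_covariate(
            block_set,
            cohort,
            i,
            sample_sd=design.sample_sd,
            cv_percent=design.cv_percent,
        )
        for i in range(cohort.n_covariates)
    )
    value = float(
        sum((s.mean_term() + s.delta_cv_max) * w for s, w in zip(summaries, weights))
    )
    return RankedBlockSet(block_set=block_set, ranking_value=value, summaries=summaries)


def batch_ranking_values(
    blocks_flat: np.ndarray,
    block_sizes: Sequence[int],
    X: np.ndarray,
    weights: Sequence[float],
    *,
    sample_sd: bool = True,
    cv_percent: bool = False,
) -> np.ndarray:
    """Vectorized scores for many block sets at once.

    Parameters
    ----------
    blocks_flat:
        (M, sum(block_sizes)) integer array of unit positions; row layout is
        the blocks in ``block_sizes`` order, concatenated.
    X:
        (n_units, n_covariates) covariate matrix in cohort order.

    Returns
    -------
    (M,) array of balance scores, identical (to floating round-off) to
    :func:`rank_block_set` applied row by row.
    """
    blocks_flat = np.asarray(blocks_flat)
    M = blocks_flat.shape[0]
    sizes = [int(b) for b in block_sizes]
    m = sum(sizes)
    if blocks_flat.shape[1] != m:
        raise RankingError(
            f"row length {blocks_flat.shape[1]} does not match block sizes {sizes}"
        )
    weights = np.asarray(list(weights), dtype=float)
    p = X.shape[1]
    if weights.shape[0] != p:
        raise RankingError(f"{weights.shape[0]} weights for {p} covariates")
    ddof = 1 if sample_sd else 0
    cv_scale = 100.0 if cv_percent else 1.0
    scores = np.zeros(M, dtype=float)
    offsets = np.cumsum([0] + sizes)
    for i in range(p):
        v = X[:, i]
        vals = v[blocks_flat]  # (M, m)
        means = np.empty((M, len(sizes)))
        cvs = np.empty((M, len(sizes)))
        for j, b in enumerate(sizes):
            seg = vals[:, offsets[j] : offsets[j + 1]]
            mu = seg.mean(axis=1)
            if np.any(mu == 0.0):
                raise UndefinedCVError(
                    f"covariate {i}: a block mean is exactly 0 in the batch"
                )
            sd = seg.std(axis=1, ddof=ddof) if b > 1 else np.zeros(M)
            means[:, j] = mu
            cvs[:, j] = sd / mu * cv_scale
        blockset_sd = vals.std(axis=1, ddof=ddof if m > 1 else 0)
        dmean = means.max(axis=1) - means.min(axis=1)
        dcv = cvs.max(axis=1) - cvs.min(axis=1)
        mean_term = np.divide(
            dmean, blockset_sd, out=np.zeros(M), where=blockset_sd > 0
        )
        scores += (mean_term + dcv) * weights[i]
    return scores
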