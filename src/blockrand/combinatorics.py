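"""Exact counting of unique block sets and search-coverage probabilities.

The number of distinct divisions of ``n`` units into unlabeled blocks of
given sizes (plus a distinguished leftover pool of the remaining units) is

    n! / (prod_j b_j! * r!) / prod_s m_s!

where ``r = n - sum_j b_j`` and ``m_s`` counts the blocks sharing size ``s``.
Equal-size blocks are interchangeable; the leftover pool is not a block and
is never interchangeable with one.  For 16 units and two blocks of 8 this
gives C(16,8)/2 = 6435.

All arithmetic is exact (arbitrary-precision integers / rationals).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_EVEN
from fractions import Fraction
from typing import Sequence

from .model import DesignError


@dataclass(frozen=True)
class DesignCount:
    """Exact number of unique block sets realizable under a design."""

    total_unique: int

    def scientific(self, sig: int = 2) -> str:
        return to_scientific(self.total_unique, sig)

    def __int__(self) -> int:
        return self.total_unique


def to_scientific(value: int, sig: int = 2) -> str:
    """Round an exact integer to `sig` significant figures (half-even),
    rendered like ``1.8e+36``."""
    if sig < 1:
        raise ValueError("sig must be >= 1")
    d = Decimal(value)
    if d == 0:
        return f"{0:.{sig - 1}e}"
    exponent = d.adjusted()  # floor(log10(|value|))
    q = Decimal(1).scaleb(exponent - sig + 1)
    rounded = d.quantize(q, rounding=ROUND_HALF_EVEN)
    return f"{rounded:.{sig - 1}e}"


def count_unique_block_sets(n_units: int, block_sizes: Sequence[int]) -> DesignCount:
    """Exact count of unlabeled block sets for ``n_units`` and ``block_sizes``.

    Raises
    ------
    DesignError
        If the block sizes oversubscribe the cohort or are non-positive.
    """
    sizes = [int(b) for b in block_sizes]
    if not sizes or any(b <= 0 for b in sizes):
        raise DesignError(f"block sizes must be positive, got {block_sizes}")
    if n_units < 1:
        raise DesignError("n_units must be positive")
    assigned = sum(sizes)
    if assigned > n_units:
        raise DesignError(
            f"block sizes sum to {assigned} > cohort size {n_units}"
        )
    r = n_units - assigned
    count = math.factorial(n_units)
    for b in sizes:
        count //= math.factorial(b)
    count //= math.factorial(r)
    for multiplicity in Counter(sizes).values():
        count //= math.factorial(multiplicity)
    return DesignCount(total_unique=count)


def top_k_miss_probability(total: int, sampled: int, k: int) -> float:
    """Probability that a uniform without-replacement sample of ``sampled``
    distinct block sets contains none of a designated best ``k``.

    Hypergeometric: C(total-k, sampled) / C(total, sampled), evaluated as an
    exact rational and returned as a float.
    """
    if total < 0 or not (0 <= sampled <= total) or not (0 <= k <= total):
        raise ValueError(
            f"need 0 <= sampled <= total and 0 <= k <= total, "
            f"got total={total}, sampled={sampled}, k={k}"
        )
    if sampled > total - k:
        return 0.0
    p = Fraction(math.comb(total - k, sampled), math.comb(total, sampled))
    return float(p)
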