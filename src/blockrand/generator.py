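"""Random generation of unique block sets and the ranked-search engine.

Sampling draws one uniform permutation of all unit ids (Fisher-Yates, via
numpy) and slices it into the designed blocks, the remainder becoming the
leftover pool.  This is uniform over labeled partitions, and since every
unlabeled partition corresponds to the same number of labeled ones
(prod_s m_s! permutations of equal-size blocks), it is uniform over the
unlabeled block sets counted by
:func:`blockrand.combinatorics.count_unique_block_sets`.

Each drawn set is reduced to a canonical form (ids sorted within blocks,
blocks sorted by size then by smallest member, leftover as a distinguished
terminal segment); a registry of canonical keys rejects duplicates so every
unique set is scored exactly once.  Accepted sets are scored with the
balance metric and fed into a bounded leaderboard that remembers only the
best-balanced sets (100 by default).
"""

from __future__ import annotations

import bisect
import logging
import math
from dataclasses import dataclass
from typing import Iterator, Optional, Union

import numpy as np

from . import markers as markers_mod
from . import ranking
from .combinatorics import count_unique_block_sets
from .model import (
    BlockDesign,
    BlockSet,
    CohortTable,
    DesignError,
    RankedBlockSet,
    validate_design,
)

logger = logging.getLogger(__name__)

_BLOCK_SEP = "\x1e"
_UNIT_SEP = "\x1f"
_LEFTOVER_SEP = "\x1d"

RngLike = Union[int, np.random.Generator, None]


def _as_rng(rng: RngLike) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def canonical_key(block_set: BlockSet) -> str:
    """Deterministic serialization invariant to within-block order and to
    permutation of equal-size blocks.

    Two block sets have equal keys iff they are the same unlabeled partition
    (with identical leftover pools).
    """
    blocks = [sorted(b, key=str) for b in block_set.blocks]
    blocks.sort(key=lambda ids: (len(ids), [str(u) for u in ids]))
    body = _BLOCK_SEP.join(_UNIT_SEP.join(str(u) for u in ids) for ids in blocks)
    tail = _UNIT_SEP.join(sorted((str(u) for u in block_set.leftover)))
    return body + _LEFTOVER_SEP + tail


def sample_block_set(
    cohort: CohortTable, design: BlockDesign, rng: RngLike = None
) -> BlockSet:
    """Draw one uniformly distributed block set."""
    design = validate_design(cohort, design)
    gen = _as_rng(rng)
    perm = gen.permutation(cohort.n_units)
    ids = cohort.ids
    blocks = []
    pos = 0
    for b in design.block_sizes:
        blocks.append(frozenset(ids[perm[j]] for j in range(pos, pos + b)))
        pos += b
    leftover = frozenset(ids[perm[j]] for j in range(pos, cohort.n_units))
    return BlockSet(blocks=tuple(blocks), leftover=leftover)


@dataclass(frozen=True)
class StopCriteria:
    """When to stop creating block sets.

    At least one of ``target_unique`` / ``target_fraction`` must be set; the
    effective target is the minimum of the specified targets and the total
    number of unique sets.  ``max_attempts`` is a safety cap against the
    coupon-collector slowdown near exhaustion (default 50x the target).
    """

    target_unique: Optional[int] = None
    target_fraction: Optional[float] = None
    max_attempts: Optional[int] = None

    def __post_init__(self) -> None:
        if self.target_unique is None and self.target_fraction is None:
            raise DesignError("set target_unique and/or target_fraction")
        if self.target_unique is not None and self.target_unique < 1:
            raise DesignError("target_unique must be positive")
        if self.target_fraction is not None and not (0 < self.target_fraction <= 1):
            raise DesignError("target_fraction must be in (0, 1]")

    def effective_target(self, total_unique: int) -> int:
        target = total_unique
        if self.target_unique is not None:
            target = min(target, self.target_unique)
        if self.target_fraction is not None:
            target = min(target, math.ceil(self.target_fraction * total_unique))
        return max(target, 1)

    def effective_max_attempts(self, target: int) -> int:
        if self.max_attempts is not None:
            return self.max_attempts
        return 50 * target


@dataclass
class EngineStats:
    """Bookkeeping of one engine run: attempts = unique + rejected duplicates."""

    attempts: int = 0
    unique_created: int = 0
    duplicates_rejected: int = 0
    target: int = 0
    total_unique: int = 0
    capped: bool = False  # max_attempts reached before the target


class Leaderboard:
    """Bounded store of the best (lowest-score) entries.

    Entries are kept sorted ascending by ``(score, discovery sequence)``:
    among equal scores the earlier-discovered entry ranks first, and the
    worst entry is evicted when capacity is exceeded.
    """

    def __init__(self, capacity: int = 100):
        if capacity < 1:
            raise DesignError("leaderboard capacity must be positive")
        self.capacity = capacity
        self._keys: list[tuple[float, int]] = []
        self._payloads: list = []

    def __len__(self) -> int:
        return len(self._payloads)

    def __iter__(self):
        return iter(self._payloads)

    @property
    def entries(self) -> list:
        return list(self._payloads)

    @property
    def scores(self) -> list[float]:
        return [k[0] for k in self._keys]

    @property
    def best(self):
        return self._payloads[0]

    @property
    def best_score(self) -> float:
        return self._keys[0][0]

    def would_accept(self, score: float) -> bool:
        return len(self._payloads) < self.capacity or (score, -1) < self._keys[-1]

    def add(self, score: float, seq: int, payload) -> bool:
        """Insert; returns True if the entry was retained."""
        key = (score, seq)
        if len(self._payloads) >= self.capacity and key >= self._keys[-1]:
            return False
        pos = bisect.bisect_left(self._keys, key)
        self._keys.insert(pos, key)
        self._payloads.insert(pos, payload)
        if len(self._payloads) > self.capacity:
            self._keys.pop()
            self._payloads.pop()
        return True


class UniqueSampler:
    """Batched uniform sampler of unique block sets at the index level.

    Yields, per internal batch, the canonical rows (blocks sorted by size
    then smallest member, ids ascending within blocks) and the raw as-drawn
    rows of the newly discovered sets.  Attempt accounting is exact: the run
    stops on the precise draw that reaches the target.
    """

    def __init__(
        self,
        n_units: int,
        block_sizes: tuple[int, ...],
        rng: RngLike = None,
        batch_size: int = 4096,
    ):
        self.n = int(n_units)
        self.sizes = tuple(int(b) for b in block_sizes)
        if sum(self.sizes) > self.n:
            raise DesignError("block sizes oversubscribe the cohort")
        self.rng = _as_rng(rng)
        self.batch_size = int(batch_size)
        self.seen: set[bytes] = set()
        self.attempts = 0
        self.unique = 0
        self.duplicates = 0
        self._m = sum(self.sizes)
        # canonical block order: ascending size, stable
        self._canon_order = sorted(range(len(self.sizes)), key=lambda j: self.sizes[j])
        self._offsets = np.cumsum([0] + list(self.sizes))
        if self.n <= 0xFF:
            self._key_dtype = np.uint8
        elif self.n <= 0xFFFF:
            self._key_dtype = np.uint16
        else:
            self._key_dtype = np.uint32

    def _canonicalize(self, raw: np.ndarray) -> np.ndarray:
        """Raw (B, m) rows -> canonical (B, m) rows."""
        B = raw.shape[0]
        blocks = [
            np.sort(raw[:, self._offsets[j] : self._offsets[j + 1]], axis=1)
            for j in range(len(self.sizes))
        ]
        out_cols: list[np.ndarray] = []
        i = 0
        order = self._canon_order
        while i < len(order):
            size = self.sizes[order[i]]
            j = i
            while j < len(order) and self.sizes[order[j]] == size:
                j += 1
            group = [blocks[order[t]] for t in range(i, j)]
            if len(group) == 1:
                out_cols.append(group[0])
            else:
                stacked = np.stack(group, axis=1)  # (B, m_s, size)
                # disjoint blocks: lex order of sorted tuples == order of minima
                perm = np.argsort(stacked[:, :, 0], axis=1)
                reordered = np.take_along_axis(stacked, perm[:, :, None], axis=1)
                out_cols.append(reordered.reshape(B, -1))
            i = j
        return np.concatenate(out_cols, axis=1)

    def _keys(self, canon: np.ndarray) -> list[bytes]:
        arr = np.ascontiguousarray(canon.astype(self._key_dtype))
        row = arr.shape[1] * arr.itemsize
        buf = arr.tobytes()
        return [buf[i * row : (i + 1) * row] for i in range(arr.shape[0])]

    def take(
        self, target: int, max_attempts: int
    ) -> Iterator[tuple[np.ndarray, np.ndarray]]:
        """Yield (canonical_new, raw_new) batches until ``target`` new unique
        sets have been produced (cumulative over the sampler's lifetime) or
        ``max_attempts`` total draws are spent."""
        base = np.arange(self.n)
        while self.unique < target and self.attempts < max_attempts:
            B = min(self.batch_size, max_attempts - self.attempts)
            perms = self.rng.permuted(np.broadcast_to(base, (B, self.n)), axis=1)
            raw = perms[:, : self._m]
            canon = self._canonicalize(raw)
            keys = self._keys(canon)
            new_rows: list[int] = []
            for r, key in enumerate(keys):
                self.attempts += 1
                if key in self.seen:
                    self.duplicates += 1
                    continue
                self.seen.add(key)
                self.unique += 1
                new_rows.append(r)
                if self.unique >= target:
                    break
            if new_rows:
                idx = np.array(new_rows)
                yield canon[idx], raw[idx]


def run_engine(
    cohort: CohortTable,
    design: BlockDesign,
    stop: StopCriteria,
    rng: RngLike = None,
    *,
    batch_size: int = 4096,
    log_every: int = 0,
) -> tuple[Leaderboard, EngineStats]:
    """Create unique block sets at random, score them, and keep the best.

    Repeatedly samples block sets, rejects duplicates via the canonical-key
    registry, scores accepted sets with the balance metric, and inserts them
    into a bounded leaderboard.  Stops when the effective target of unique
    sets is reached (possibly the full enumeration) or at the attempt cap.
    Deterministic given the seed (at fixed ``batch_size``).

    Returns
    -------
    (Leaderboard of RankedBlockSet, EngineStats)
    """
    design = validate_design(cohort, design)
    total = count_unique_block_sets(cohort.n_units, design.block_sizes).total_unique
    target = stop.effective_target(total)
    max_attempts = stop.effective_max_attempts(target)

    sampler = UniqueSampler(
        cohort.n_units, design.block_sizes, rng=rng, batch_size=batch_size
    )
    X = cohort.covariate_matrix()
    weights = design.weights or tuple(1.0 for _ in range(cohort.n_covariates))
    canon_sizes = tuple(sorted(design.block_sizes))

    board: Leaderboard = Leaderboard(design.leaderboard_capacity)
    seq = 0
    batches_done = 0
    for canon_new, _raw in sampler.take(target, max_attempts):
        if cohort.n_covariates:
            scores = ranking.batch_ranking_values(
                canon_new,
                canon_sizes,
                X,
                weights,
                sample_sd=design.sample_sd,
                cv_percent=design.cv_percent,
            )
        else:
            scores = np.zeros(canon_new.shape[0])
        for r in range(canon_new.shape[0]):
            s = float(scores[r])
            if board.would_accept(s):
                board.add(s, seq, canon_new[r].copy())
            seq += 1
        batches_done += 1
        if log_every and batches_done % log_every == 0:
            logger.info(
                "engine: %d/%d unique sets (%d attempts, best %.6g)",
                sampler.unique,
                target,
                sampler.attempts,
                board.best_score if len(board) else float("nan"),
            )

    stats = EngineStats(
        attempts=sampler.attempts,
        unique_created=sampler.unique,
        duplicates_rejected=sampler.duplicates,
        target=target,
        total_unique=total,
        capped=sampler.unique < target,
    )
    if stats.capped:
        logger.warning(
            "attempt cap reached: %d attempts produced %d/%d unique sets",
            stats.attempts,
            stats.unique_created,
            target,
        )

    final = Leaderboard(design.leaderboard_capacity)
    ids = cohort.ids
    subgroup_spec = design.subgroup_spec()
    for (score, disc_seq), row in zip(board._keys, board._payloads):
        blocks = []
        pos = 0
        for b in canon_sizes:
            blocks.append(frozenset(ids[j] for j in row[pos : pos + b]))
            pos += b
        blocked = set(row.tolist())
        leftover = frozenset(
            ids[j] for j in range(cohort.n_units) if j not in blocked
        )
        bset = BlockSet(blocks=tuple(blocks), leftover=leftover)
        ranked = ranking.rank_block_set(bset, cohort, design)
        mods = None
        if subgroup_spec is not None and cohort.has_markers:
            mods = markers_mod.total_modifications(bset, cohort, design)
        ranked = RankedBlockSet(
            block_set=bset,
            ranking_value=ranked.ranking_value,
            summaries=ranked.summaries,
            marker_modifications=mods,
        )
        final.add(score, disc_seq, ranked)
    return final, stats
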