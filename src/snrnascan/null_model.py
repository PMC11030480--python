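"""Random intergenic null regions and the Fisher-Pitman permutation test.

To ask whether a gene's standing-variation level is unusual, its
sliding-window summary is compared against the same summary computed over
random intergenic regions of identical length: the complement of all
annotated transcripts (padded by a safety buffer) on one chromosome is the
sampling pool, fixed-length non-overlapping regions are drawn from it, and
a one-way Fisher-Pitman permutation test (Monte-Carlo or exhaustive)
compares the two groups of summaries.
"""

from __future__ import annotations

import logging
import math
import warnings
from bisect import bisect_left, insort
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import _intervals
from .constraint import PopulationVariantTable, WindowProfile, sliding_window_profile
from .gene_model import GeneLocus

logger = logging.getLogger(__name__)


@dataclass
class IntergenicPool:
    """Disjoint intergenic intervals available for null-region sampling."""

    chromosome: str
    intervals: list[tuple[int, int]]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = _intervals.merge(self.intervals, join_adjacent=False)
        if merged != sorted(self.intervals):
            raise ValueError("pool intervals must be disjoint and sorted")
        self.intervals = merged

    def total_length(self) -> int:
        return _intervals.total_length(self.intervals)

    def capacity(self, length: int) -> int:
        """Maximum number of non-overlapping length-bp placements."""
        return sum((e - s + 1) // length for s, e in self.intervals)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for s, e in self.intervals:
                fh.write(f"{self.chromosome}\t{s - 1}\t{e}\tintergenic\n")


@dataclass
class RandomRegionSet:
    """Non-overlapping fixed-length regions sampled from a pool."""

    chromosome: str
    regions: list[tuple[int, int]]
    length: int
    seed: int | None

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, (s, e) in enumerate(self.regions):
                fh.write(f"{self.chromosome}\t{s - 1}\t{e}\tnull_{i}\n")


@dataclass
class PermutationTestResult:
    statistic_observed: float
    p_value: float
    n_permutations: int
    mode: str  # "monte_carlo" | "exhaustive"
    alternative: str
    statistic: str
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "statistic_observed": self.statistic_observed,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "mode": self.mode,
            "alternative": self.alternative,
            "statistic": self.statistic,
            "seed": self.seed,
        }


def build_intergenic_pool(
    transcripts: list[tuple[int, int]],
    chromosome: str,
    chromosome_length: int,
    buffer_bp: int = 10_000,
    min_len: int = 141,
    exclusions: list[tuple[int, int]] | None = None,
) -> IntergenicPool:
    """Intergenic intervals: the chromosome minus transcripts +/- buffer.

    ``transcripts`` and ``exclusions`` (e.g. the centromere) are 1-based
    inclusive intervals; the result keeps only intervals at least
    ``min_len`` bp long.
    """
    blocked = _intervals.pad(transcripts, buffer_bp)
    blocked = [(max(1, s), min(chromosome_length, e)) for s, e in blocked if e >= 1 and s <= chromosome_length]
    if exclusions:
        blocked += [tuple(x) for x in exclusions]
    remaining = _intervals.subtract([(1, chromosome_length)], blocked)
    remaining = [(s, e) for s, e in remaining if e - s + 1 >= min_len]
    return IntergenicPool(
        chromosome,
        remaining,
        provenance={
            "chromosome_length": chromosome_length,
            "n_transcripts": len(transcripts),
            "buffer_bp": buffer_bp,
            "min_len": min_len,
            "n_exclusions": len(exclusions or []),
        },
    )


def sample_regions(
    pool: IntergenicPool,
    n: int = 1000,
    length: int = 141,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> RandomRegionSet:
    """Draw n non-overlapping length-bp regions uniformly from the pool.

    Sequential rejection sampling: starts are drawn uniformly over all valid
    placements and redrawn on overlap with an already-placed region.
    Deterministic for a fixed seed. Raises if the pool cannot hold n
    non-overlapping regions, naming the achievable maximum.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    capacity = pool.capacity(length)
    if n > capacity:
        raise ValueError(
            f"cannot place {n} non-overlapping {length} bp regions; pool capacity is {capacity}"
        )
    # valid start positions per pool interval, addressed through a cumulative index
    spans = [(s, e - length + 1) for s, e in pool.intervals if e - s + 1 >= length]
    n_starts = np.array([hi - lo + 1 for lo, hi in spans])
    cum = np.concatenate([[0], np.cumsum(n_starts)])
    total = int(cum[-1])

    placed_starts: list[int] = []  # sorted genomic starts of placed regions

    def overlaps(start: int) -> bool:
        i = bisect_left(placed_starts, start)
        if i < len(placed_starts) and placed_starts[i] < start + length:
            return True
        if i > 0 and placed_starts[i - 1] > start - length:
            return True
        return False

    max_attempts = max(10_000, 1000 * n)
    attempts = 0
    while len(placed_starts) < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"rejection sampling stalled after {max_attempts} attempts; "
                f"placed {len(placed_starts)} of {n} (pool too fragmented/dense)"
            )
        u = int(rng.integers(0, total))
        k = int(np.searchsorted(cum, u, side="right")) - 1
        start = spans[k][0] + (u - int(cum[k]))
        if not overlaps(start):
            insort(placed_starts, start)
    regions = [(s, s + length - 1) for s in placed_starts]
    return RandomRegionSet(pool.chromosome, regions, length, seed)


def region_summary(
    region_or_gene,
    pop: PopulationVariantTable,
    window_size: int = 18,
    chromosome: str | None = None,
) -> float:
    """Median sliding-window observed/possible SNV proportion of a region.

    Accepts a :class:`GeneLocus` (reference-checked possible SNVs) or a
    plain ``(start, end)`` genomic interval with ``chromosome`` given, in
    which case every distinct alternate allele recorded at a position counts
    (capped at 3 per position).
    """
    if isinstance(region_or_gene, GeneLocus):
        profile = sliding_window_profile(region_or_gene, pop, window_size=window_size)
        return float(profile.windows["proportion"].median())
    g_start, g_end = region_or_gene
    if chromosome is None:
        raise ValueError("chromosome required for a plain interval")
    length = g_end - g_start + 1
    if length < window_size:
        raise ValueError(f"region ({length} bp) shorter than window ({window_size} bp)")
    sub = pop.snvs_in(chromosome, g_start, g_end)
    counts = np.zeros(length, dtype=np.int64)
    per_pos = sub.groupby("position")["alt"].nunique()
    for position, k in per_pos.items():
        counts[position - g_start] = min(int(k), 3)
    csum = np.concatenate([[0], np.cumsum(counts)])
    window_counts = csum[window_size:] - csum[:-window_size]
    return float(np.median(window_counts / (3.0 * window_size)))


def fisher_pitman_mc(
    group_a,
    group_b,
    n_permutations: int = 1000,
    alternative: str = "greater",
    statistic: str = "mean",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    exhaustive_cap: int = 100_000,
) -> PermutationTestResult:
    """Two-sample Fisher-Pitman permutation test.

    The test statistic is the difference of group summaries (``mean`` for
    the classical Fisher-Pitman test; ``median`` available), and the null is
    generated by reallocating the pooled values to groups of the original
    sizes. When the number of distinct allocations is at most
    ``exhaustive_cap`` the exact tail fraction is returned; otherwise
    ``n_permutations`` Monte-Carlo reallocations are drawn and the add-one
    corrected p-value ``(1 + #{permuted >= observed}) / (1 + n)`` is
    returned.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    stat_fn = {"mean": np.mean, "median": np.median}.get(statistic)
    if stat_fn is None:
        raise ValueError(f"unknown statistic {statistic!r}")

    pooled = np.concatenate([a, b])
    na, n = a.size, pooled.size
    observed = float(stat_fn(a) - stat_fn(b))

    if np.ptp(pooled) == 0:
        warnings.warn("all pooled values identical; permutation test degenerate, p = 1")
        return PermutationTestResult(observed, 1.0, 0, "degenerate", alternative, statistic, seed)

    tol = 1e-12 * max(1.0, abs(observed))

    def tail_count(stats: np.ndarray) -> int:
        if alternative == "greater":
            return int(np.sum(stats >= observed - tol))
        if alternative == "less":
            return int(np.sum(stats <= observed + tol))
        return int(np.sum(np.abs(stats) >= abs(observed) - tol))

    n_total = math.comb(n, na)
    if n_total <= exhaustive_cap:
        stats = np.empty(n_total)
        idx = np.arange(n)
        for i, chosen in enumerate(combinations(range(n), na)):
            mask = np.zeros(n, dtype=bool)
            mask[list(chosen)] = True
            stats[i] = stat_fn(pooled[mask]) - stat_fn(pooled[~mask])
        p = tail_count(stats) / n_total
        return PermutationTestResult(observed, p, n_total, "exhaustive", alternative, statistic, seed)

    if rng is None:
        rng = np.random.default_rng(seed)
    mat = rng.permuted(np.broadcast_to(pooled, (n_permutations, n)).copy(), axis=1)
    if statistic == "mean":
        stats = mat[:, :na].mean(axis=1) - mat[:, na:].mean(axis=1)
    else:
        stats = np.median(mat[:, :na], axis=1) - np.median(mat[:, na:], axis=1)
    p = (1 + tail_count(stats)) / (1 + n_permutations)
    return PermutationTestResult(observed, p, n_permutations, "monte_carlo", alternative, statistic, seed)
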