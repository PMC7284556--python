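"""Read quality trimming and kmer-coverage normalization.

Normalization downsamples redundant high-coverage reads to a target median
kmer coverage, and can additionally eliminate reads whose kmer coverage
profile is *aberrant*: a read mixing very-high- and very-low-coverage kmers
(typically a sequencing error inside an abundant transcript) has a large
percent standard deviation of kmer coverage.  The ``max_pct_stdev``
threshold controls this filter — a permissive value (10,000) retains such
reads, a strict value (100) eliminates them, enriching the kept set for
error-free reads.

Percent standard deviation here is 100 * sample stdev / mean of the read's
canonical-kmer coverages (lower median convention for even counts, stdev 0
for a single kmer).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np

from .seqio import ReadRecord

__all__ = [
    "TrimConfig",
    "NormConfig",
    "KmerStats",
    "quality_trim",
    "count_kmers",
    "read_kmer_stats",
    "normalize_reads",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

ReadOrPair = Union[ReadRecord, tuple[ReadRecord, ReadRecord]]


@dataclass(frozen=True)
class TrimConfig:
    """Quality-trimming parameters (leading/trailing strip + sliding window)."""

    phred_threshold: int = 35
    window: int = 4
    min_len: int = 36

    def __post_init__(self) -> None:
        if not 0 <= self.phred_threshold <= 93:
            raise ValueError("phred_threshold must be in [0, 93]")
        if self.window < 1 or self.min_len < 1:
            raise ValueError("window and min_len must be >= 1")


@dataclass(frozen=True)
class NormConfig:
    """Kmer-coverage normalization parameters."""

    k: int = 25
    target_cov: int = 50
    max_pct_stdev: float = 10_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1 or self.target_cov < 1:
            raise ValueError("k and target_cov must be >= 1")
        if self.max_pct_stdev <= 0:
            raise ValueError("max_pct_stdev must be > 0")


@dataclass(frozen=True)
class KmerStats:
    """Coverage profile of one read's kmers."""

    coverages: tuple[int, ...]
    median: float
    mean: float
    stdev: float
    pct_stdev: float


def quality_trim(read: ReadRecord, cfg: TrimConfig | None = None) -> ReadRecord | None:
    """Trim low-quality bases; return the trimmed read or None if dropped.

    Steps, in order: (i) strip leading then trailing bases with phred below
    the threshold; (ii) scan a sliding window from the 5' end and cut at the
    first window whose mean phred falls below the threshold; (iii) drop the
    read if the final length is below ``min_len``.
    """
    cfg = cfg or TrimConfig()
    thr = cfg.phred_threshold
    quals = read.quals
    lo, hi = 0, len(quals)
    while lo < hi and quals[lo] < thr:
        lo += 1
    while hi > lo and quals[hi - 1] < thr:
        hi -= 1
    q = quals[lo:hi]
    for i in range(len(q) - cfg.window + 1):
        if sum(q[i : i + cfg.window]) / cfg.window < thr:
            hi = lo + i
            break
    if hi - lo < cfg.min_len:
        return None
    if lo == 0 and hi == len(quals):
        return read
    return ReadRecord(
        id=read.id,
        bases=read.bases[lo:hi],
        quals=quals[lo:hi],
        mate=read.mate,
    )


def canonical_kmer(kmer: str) -> str:
    """Lexicographic minimum of a kmer and its reverse complement."""
    rc = kmer.translate(_COMPLEMENT)[::-1]
    return kmer if kmer <= rc else rc


def _iter_reads(reads: Iterable[ReadOrPair]):
    for item in reads:
        if isinstance(item, tuple):
            yield from item
        else:
            yield item


def count_kmers(reads: Iterable[ReadOrPair], k: int) -> dict[str, int]:
    """Count canonical kmers over all reads; kmers containing non-ACGT skipped."""
    if k < 1:
        raise ValueError("k must be >= 1")
    table: dict[str, int] = {}
    for read in _iter_reads(reads):
        seq = read.bases
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if any(c not in "ACGT" for c in kmer):
                continue
            can = canonical_kmer(kmer)
            table[can] = table.get(can, 0) + 1
    return table


def read_kmer_stats(read: ReadRecord, table: dict[str, int], k: int) -> KmerStats:
    """Coverage statistics of one read's kmers against a count table.

    Median is the lower of the two middle values for even counts; stdev is
    the sample standard deviation (0 for a single kmer); pct_stdev is
    100*stdev/mean (0 when the mean is 0).  A read shorter than k has empty
    coverages and all statistics 0.
    """
    seq = read.bases
    cov = []
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if any(c not in "ACGT" for c in kmer):
            continue
        cov.append(table.get(canonical_kmer(kmer), 0))
    if not cov:
        return KmerStats(coverages=(), median=0.0, mean=0.0, stdev=0.0, pct_stdev=0.0)
    ordered = sorted(cov)
    median = float(ordered[(len(ordered) - 1) // 2])
    mean = sum(cov) / len(cov)
    if len(cov) > 1:
        var = sum((c - mean) ** 2 for c in cov) / (len(cov) - 1)
        stdev = math.sqrt(var)
    else:
        stdev = 0.0
    pct = 100.0 * stdev / mean if mean > 0 else 0.0
    return KmerStats(
        coverages=tuple(cov), median=median, mean=mean, stdev=stdev, pct_stdev=pct
    )


def normalize_reads(
    reads: Sequence[ReadOrPair],
    cfg: NormConfig | None = None,
    table: dict[str, int] | None = None,
) -> list[ReadOrPair]:
    """Downsample to target kmer coverage, eliminating aberrant-profile reads.

    For each read (or pair): if the percent standard deviation of its kmer
    coverage exceeds ``max_pct_stdev`` the read is eliminated; otherwise it
    is kept with probability ``min(1, target_cov / median)`` using a seeded
    pseudo-random stream in input order (median at or below the target means
    certain retention).  Pairs are decided jointly, using the mean of the two
    reads' medians and the max of their pct_stdevs.

    One random draw is consumed per input item regardless of the elimination
    decision, so runs differing only in ``max_pct_stdev`` keep nested subsets.
    """
    cfg = cfg or NormConfig()
    if table is None:
        table = count_kmers(reads, cfg.k)
    rng = np.random.default_rng(cfg.seed)
    kept: list[ReadOrPair] = []
    for item in reads:
        u = rng.random()
        if isinstance(item, tuple):
            stats = [read_kmer_stats(r, table, cfg.k) for r in item]
            median = sum(s.median for s in stats) / len(stats)
            pct = max(s.pct_stdev for s in stats)
        else:
            s = read_kmer_stats(item, table, cfg.k)
            median, pct = s.median, s.pct_stdev
        if pct > cfg.max_pct_stdev:
            continue
        if median <= cfg.target_cov or u < cfg.target_cov / median:
            kept.append(item)
    return kept
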