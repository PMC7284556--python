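"""Shared fixtures and independent oracles used across the test suite."""

from __future__ import annotations

import random
import re

import pytest

from proxydb.seqio import SequenceRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def rng():
    return random.Random(20201)


def random_nt(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


def random_protein(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(AA20) for _ in range(length))


def brute_force_six_frame(nt: str, min_len: int) -> set[tuple[int, str]]:
    """Per-offset/per-strand translation split on stops: the 6FT oracle.

    Translates every (strand, offset) combination with Biopython on
    codon-trimmed substrings and splits the result at '*', independent of
    the package's frame/segment machinery.  Returns {(frame, aa_seq)} as a
    multiset encoded with occurrence indices.
    """
    from Bio.Seq import Seq

    out: list[tuple[int, str]] = []
    rc = str(Seq(nt).reverse_complement())
    for sign, strand in ((1, nt), (-1, rc)):
        for offset in range(3):
            frame = sign * (offset + 1)
            sub = strand[offset:]
            sub = sub[: len(sub) - len(sub) % 3]
            aa = str(Seq(sub).translate()) if sub else ""
            for segment in re.split(r"\*", aa):
                if len(segment) >= min_len:
                    out.append((frame, segment))
    counted: dict[tuple[int, str], int] = {}
    result = set()
    for key in out:
        counted[key] = counted.get(key, 0) + 1
        result.add((*key, counted[key]))
    return result


def segments_as_multiset(segments) -> set[tuple[int, str, int]]:
    counted: dict[tuple[int, str], int] = {}
    result = set()
    for seg in segments:
        key = (seg.frame, seg.aa_seq)
        counted[key] = counted.get(key, 0) + 1
        result.add((*key, counted[key]))
    return result


def brute_force_n50(lengths) -> int:
    """Definitional N50: the largest length L with sum(x >= L) >= total/2."""
    total = sum(lengths)
    candidates = [
        L for L in sorted(set(lengths), reverse=True)
        if sum(x for x in lengths if x >= L) >= total / 2
    ]
    return max(candidates)


def lcs_dp(a: str, b: str) -> int:
    """Quadratic longest-common-substring DP oracle."""
    best = 0
    prev = [0] * (len(b) + 1)
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        for j in range(1, len(b) + 1):
            if a[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                best = max(best, cur[j])
        prev = cur
    return best


def nt_record(rng: random.Random, length: int, rec_id: str = "s") -> SequenceRecord:
    return SequenceRecord(id=rec_id, residues=random_nt(rng, length))
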