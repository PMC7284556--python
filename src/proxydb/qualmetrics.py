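"""Assembly and database quality metrics: N50, totals, contiguity coverage.

Contiguity follows the reference-based convention for de-novo transcriptome
assessment: a reference protein counts as *covered* when a single transcript
matches it exactly (100% identity) along at least 90% of its length.  The
match is evaluated at the amino-acid level as the longest exact common
substring between the protein and any six-frame translation of a transcript.
"""

from __future__ import annotations

from dataclasses import dataclass
from difflib import SequenceMatcher
from typing import Sequence

from .dbbuild import ProteinDatabase
from .seqio import SequenceRecord
from .translate import FRAMES, translate_frame

__all__ = ["AssemblyMetrics", "n50", "assembly_metrics", "contiguity_coverage"]


@dataclass(frozen=True)
class AssemblyMetrics:
    n_transcripts: int
    total_bases: int
    n50: int
    contiguity_covered: int | None = None
    contiguity_total: int | None = None


def n50(lengths: Sequence[int]) -> int:
    """The length at which the descending cumulative sum first reaches half
    the total: the classic contig/transcript N50."""
    if not lengths:
        raise ValueError("n50 of an empty length list is undefined")
    if any(l <= 0 for l in lengths):
        raise ValueError("lengths must be positive")
    half = sum(lengths) / 2
    acc = 0
    for length in sorted(lengths, reverse=True):
        acc += length
        if acc >= half:
            return length
    raise AssertionError("unreachable")


def assembly_metrics(transcripts: Sequence[SequenceRecord]) -> AssemblyMetrics:
    """Transcript count, total assembled bases, and N50."""
    lengths = [len(t) for t in transcripts]
    return AssemblyMetrics(
        n_transcripts=len(lengths),
        total_bases=sum(lengths),
        n50=n50(lengths) if lengths else 0,
    )


def _longest_common_substring(a: str, b: str) -> int:
    if not a or not b:
        return 0
    match = SequenceMatcher(None, a, b, autojunk=False).find_longest_match(
        0, len(a), 0, len(b)
    )
    return match.size


def contiguity_coverage(
    reference: ProteinDatabase,
    transcripts: Sequence[SequenceRecord],
    min_fraction: float = 0.9,
    min_identity: float = 1.0,
) -> tuple[AssemblyMetrics, dict[str, float]]:
    """Count reference proteins covered >= ``min_fraction`` by one transcript.

    For each reference protein, the best single-transcript coverage is the
    longest exact common substring between the protein and any six-frame
    translation of any transcript, divided by the protein length.  Only
    exact identity is supported (``min_identity`` must be 1.0).  Returns the
    combined metrics and a per-protein best-coverage table.
    """
    if min_identity != 1.0:
        raise ValueError("only exact identity (min_identity=1.0) is supported")
    if not 0 < min_fraction <= 1.0:
        raise ValueError("min_fraction must be in (0, 1]")
    if reference.n_sequences == 0:
        raise ValueError("reference database must be non-empty")
    translations = [
        translate_frame(t.residues, frame)
        for t in transcripts
        for frame in FRAMES
    ]
    best: dict[str, float] = {}
    for rec in reference:
        longest = 0
        for aa in translations:
            if len(aa) <= longest:
                continue
            # a full-length containment check is much cheaper than LCS
            if rec.residues in aa:
                longest = len(rec.residues)
                break
            longest = max(longest, _longest_common_substring(rec.residues, aa))
        best[rec.id] = longest / len(rec.residues)
    covered = sum(1 for frac in best.values() if frac >= min_fraction)
    base = assembly_metrics(transcripts)
    metrics = AssemblyMetrics(
        n_transcripts=base.n_transcripts,
        total_bases=base.total_bases,
        n50=base.n50,
        contiguity_covered=covered,
        contiguity_total=reference.n_sequences,
    )
    return metrics, best
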