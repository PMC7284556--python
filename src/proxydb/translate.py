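"""Six-frame translation, genome chunking, and ORF extraction.

A "proxy" protein search database for an unsequenced organism is built by
translating nucleotide sequence in all six reading frames (three forward,
three on the reverse complement) and keeping the stop-free stretches, or by
extracting open reading frames from assembled transcripts.  Both routes are
implemented here on top of a shared frame/segment machinery.

Frames are labelled +1, +2, +3, -1, -2, -3: +k reads the forward strand
starting at 0-based offset k-1; -k reads the reverse complement starting at
offset k-1 of the reverse-complemented sequence.  Codons containing any
non-ACGT character (ambiguity codes, N) translate to 'X'; translations are
split into segments only at stop codons ('*'), never at 'X'.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterator, Sequence

from Bio.Data import CodonTable
from Bio.Seq import reverse_complement as _bio_reverse_complement

from .seqio import SequenceRecord

__all__ = [
    "FRAMES",
    "OrfSegment",
    "reverse_complement",
    "translate_frame",
    "six_frame_translate",
    "split_genome_chunks",
    "extract_orfs",
]

FRAMES = (1, 2, 3, -1, -2, -3)

DEFAULT_MIN_SEGMENT_AA = 7  # shortest tryptic peptide worth indexing
DEFAULT_MIN_ORF_AA = 100  # common ORF-finder default for transcripts
DEFAULT_CHUNK_SIZE = 100_000
DEFAULT_CHUNK_OVERLAP = 120  # 40 aa * 3 nt: no realistic peptide lost at borders


@lru_cache(maxsize=None)
def _codon_map(table_id: int) -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    return mapping


@dataclass(frozen=True)
class OrfSegment:
    """A stop-free translated segment or ORF with forward-strand coordinates.

    ``nt_start``/``nt_end`` are 0-based half-open on the forward strand of the
    source sequence and include the terminating stop codon when
    ``has_stop_codon`` is set.
    """

    source_id: str
    frame: int
    aa_seq: str
    nt_start: int
    nt_end: int
    has_start_codon: bool = False
    has_stop_codon: bool = False

    @property
    def accession(self) -> str:
        return f"{self.source_id}|{self.frame:+d}|{self.nt_start}"

    def to_record(self) -> SequenceRecord:
        desc = f"frame={self.frame:+d} loc={self.nt_start}:{self.nt_end}"
        return SequenceRecord(id=self.accession, description=desc, residues=self.aa_seq)


def reverse_complement(nt: str) -> str:
    """Reverse complement, with IUPAC ambiguity codes mapped to their complements."""
    if not nt:
        return ""
    return str(_bio_reverse_complement(nt.upper()))


def translate_frame(nt: str, frame: int, table: int = 1) -> str:
    """Translate one reading frame into a protein string.

    Successive complete codons are translated (trailing 1-2 nt dropped);
    stop codons emit '*'; any codon containing a non-ACGT character emits 'X'.
    """
    if frame not in FRAMES:
        raise ValueError(f"frame must be one of {FRAMES}, got {frame}")
    seq = nt.upper() if frame > 0 else reverse_complement(nt)
    offset = abs(frame) - 1
    mapping = _codon_map(table)
    out = []
    for i in range(offset, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        out.append(mapping.get(codon, "X"))
    return "".join(out)


def _segment_bounds(aa: str) -> Iterator[tuple[int, int, bool]]:
    """Yield (start, end, followed_by_stop) for maximal stop-free runs of aa."""
    start = 0
    n = len(aa)
    for i in range(n + 1):
        if i == n or aa[i] == "*":
            if i > start:
                yield start, i, i < n
            start = i + 1


def _frame_coords(
    frame: int, aa_start: int, aa_end: int, has_stop: bool, source_len: int
) -> tuple[int, int]:
    """Forward-strand nt coordinates of an aa range in the given frame."""
    offset = abs(frame) - 1
    local_start = offset + 3 * aa_start
    local_end = offset + 3 * aa_end + (3 if has_stop else 0)
    if frame > 0:
        return local_start, local_end
    return source_len - local_end, source_len - local_start


def six_frame_translate(
    record: SequenceRecord,
    min_len: int = DEFAULT_MIN_SEGMENT_AA,
    table: int = 1,
) -> list[OrfSegment]:
    """All maximal stop-free translated segments of length >= ``min_len``.

    The translation of each of the six frames is split at '*' only (an 'X'
    from an ambiguous codon blocks peptide matches locally without discarding
    flanking sequence).  Output is ordered by frame then position.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    nt = record.residues.upper()
    rc = reverse_complement(nt)
    segments = []
    for frame in FRAMES:
        aa = translate_frame(nt, frame, table=table)
        strand_seq = nt if frame > 0 else rc
        offset = abs(frame) - 1
        for aa_start, aa_end, has_stop in _segment_bounds(aa):
            if aa_end - aa_start < min_len:
                continue
            nt_start, nt_end = _frame_coords(frame, aa_start, aa_end, has_stop, len(nt))
            first_codon = strand_seq[offset + 3 * aa_start : offset + 3 * aa_start + 3]
            segments.append(
                OrfSegment(
                    source_id=record.id,
                    frame=frame,
                    aa_seq=aa[aa_start:aa_end],
                    nt_start=nt_start,
                    nt_end=nt_end,
                    has_start_codon=first_codon == "ATG",
                    has_stop_codon=has_stop,
                )
            )
    return segments


def split_genome_chunks(
    record: SequenceRecord,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
    overlap: int = DEFAULT_CHUNK_OVERLAP,
) -> list[SequenceRecord]:
    """Split a long sequence into overlapping chunks for batched translation.

    Chunks of ``chunk_size`` step by ``chunk_size - overlap``; the last chunk
    may be shorter.  Chunk ids are ``<source_id>|<start>`` with the 0-based
    start offset.  Every window of length <= overlap+1 lies wholly inside at
    least one chunk, so peptides of up to floor((overlap+1)/3) residues are
    never lost at chunk borders.
    """
    if overlap < 0:
        raise ValueError("overlap must be >= 0")
    if chunk_size <= overlap:
        raise ValueError(f"chunk_size ({chunk_size}) must exceed overlap ({overlap})")
    nt = record.residues
    step = chunk_size - overlap
    chunks = []
    start = 0
    while True:
        end = min(start + chunk_size, len(nt))
        chunks.append(
            SequenceRecord(
                id=f"{record.id}|{start}",
                description=record.description,
                residues=nt[start:end],
            )
        )
        if end >= len(nt):
            break
        start += step
    return chunks


def extract_orfs(
    transcript: SequenceRecord,
    min_aa: int = DEFAULT_MIN_ORF_AA,
    require_start: bool = True,
    table: int = 1,
) -> list[OrfSegment]:
    """Maximal ORFs from all six frames of a transcript.

    With ``require_start``, each ORF runs from the first ATG after the
    previous stop to the next stop; otherwise from the segment start (open
    5' ends allowed, modelling truncated transcripts).  ORFs shorter than
    ``min_aa`` are discarded; per stop-free segment only the longest
    candidate (the earliest start) is kept.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    nt = transcript.residues.upper()
    rc = reverse_complement(nt)
    orfs = []
    for frame in FRAMES:
        aa = translate_frame(nt, frame, table=table)
        strand_seq = nt if frame > 0 else rc
        offset = abs(frame) - 1
        for seg_start, seg_end, has_stop in _segment_bounds(aa):
            orf_start = seg_start
            if require_start:
                orf_start = None
                for j in range(seg_start, seg_end):
                    if (
                        aa[j] == "M"
                        and strand_seq[offset + 3 * j : offset + 3 * j + 3] == "ATG"
                    ):
                        orf_start = j
                        break
                if orf_start is None:
                    continue
            if seg_end - orf_start < min_aa:
                continue
            nt_start, nt_end = _frame_coords(frame, orf_start, seg_end, has_stop, len(nt))
            first_codon = strand_seq[offset + 3 * orf_start : offset + 3 * orf_start + 3]
            orfs.append(
                OrfSegment(
                    source_id=transcript.id,
                    frame=frame,
                    aa_seq=aa[orf_start:seg_end],
                    nt_start=nt_start,
                    nt_end=nt_end,
                    has_start_codon=first_codon == "ATG",
                    has_stop_codon=has_stop,
                )
            )
    return orfs


def orf_records(segments: Sequence[OrfSegment]) -> list[SequenceRecord]:
    """Convert segments to protein records suitable for database assembly."""
    return [seg.to_record() for seg in segments]
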