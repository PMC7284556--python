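"""Reading and writing FASTA/FASTQ with strict, validated record semantics.

Every other module consumes the two record types defined here.  Parsing is
deliberately strict: records are validated against a declared alphabet at
parse time, framing violations raise errors that name the offending line or
record, and write→read round trips preserve records exactly.
"""

from __future__ import annotations

import gzip
import io
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Sequence, Union

__all__ = [
    "SequenceRecord",
    "ReadRecord",
    "FastaParseError",
    "FastqParseError",
    "AlphabetError",
    "parse_fasta",
    "parse_fastq",
    "write_records",
    "read_fasta",
    "read_fastq",
    "write_fasta",
    "write_fastq",
]

# Nucleotide: ACGTUN plus IUPAC ambiguity codes; stored uppercase with U→T.
NUCLEOTIDE_ALPHABET = frozenset("ACGTUNRYSWKMBDHV")
# Protein: the 20 standard residues, X (unknown) and * (stop).
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")

_ALPHABETS = {
    "nt": NUCLEOTIDE_ALPHABET,
    "nucleotide": NUCLEOTIDE_ALPHABET,
    "aa": PROTEIN_ALPHABET,
    "protein": PROTEIN_ALPHABET,
}

MAX_PHRED = 93
PHRED_OFFSET = 33


class FastaParseError(ValueError):
    """Malformed FASTA input."""


class FastqParseError(ValueError):
    """Malformed FASTQ input."""


class AlphabetError(ValueError):
    """A residue outside the declared alphabet."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide or amino-acid sequence.

    ``id`` is the first whitespace-delimited token of the header;
    ``description`` is the remainder (possibly empty).  ``residues`` is
    stored uppercase with no whitespace.
    """

    id: str
    description: str = ""
    residues: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid record id: {self.id!r}")
        if any(c.isspace() for c in self.residues):
            raise ValueError(f"record {self.id!r}: residues contain whitespace")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def header(self) -> str:
        return f"{self.id} {self.description}".rstrip()


@dataclass(frozen=True)
class ReadRecord:
    """A sequencing read with per-base phred quality scores."""

    id: str
    bases: str
    quals: tuple[int, ...]
    mate: int | None = None

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid read id: {self.id!r}")
        object.__setattr__(self, "quals", tuple(self.quals))
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.id!r}: quality length mismatch "
                f"({len(self.bases)} bases, {len(self.quals)} scores)"
            )
        for q in self.quals:
            if not 0 <= q <= MAX_PHRED:
                raise ValueError(f"read {self.id!r}: phred score {q} out of range")
        if self.mate not in (None, 1, 2):
            raise ValueError(f"read {self.id!r}: mate must be 1, 2 or None")

    def __len__(self) -> int:
        return len(self.bases)


def _alphabet_set(alphabet: str | frozenset) -> frozenset:
    if isinstance(alphabet, (set, frozenset)):
        return frozenset(alphabet)
    try:
        return _ALPHABETS[alphabet]
    except KeyError:
        raise ValueError(f"unknown alphabet {alphabet!r}; use 'nt' or 'aa'") from None


def _validate_residues(residues: str, allowed: frozenset, record_id: str) -> None:
    for c in residues:
        if c not in allowed:
            raise AlphabetError(
                f"record {record_id!r}: illegal character {c!r} for alphabet"
            )


def _as_lines(stream: Union[str, IO, Iterable[str]]) -> Iterable[str]:
    if isinstance(stream, str):
        return io.StringIO(stream)
    return stream


def parse_fasta(
    stream: Union[str, IO, Iterable[str]], alphabet: str = "nt"
) -> Iterator[SequenceRecord]:
    """Yield :class:`SequenceRecord` objects from FASTA text in file order.

    Multi-line sequences are concatenated and uppercased; for the nucleotide
    alphabet, U is normalized to T.  A record with an empty sequence is
    permitted but triggers a :class:`UserWarning`.

    Raises
    ------
    FastaParseError
        If the first non-blank character is not ``>`` (names the line).
    AlphabetError
        If a residue falls outside the declared alphabet (names the record).
    """
    allowed = _alphabet_set(alphabet)
    is_nt = allowed is NUCLEOTIDE_ALPHABET
    header: str | None = None
    parts: list[str] = []

    def _emit() -> SequenceRecord:
        assert header is not None
        fields = header.split(None, 1)
        rec_id = fields[0]
        desc = fields[1] if len(fields) > 1 else ""
        residues = "".join(parts).upper()
        _validate_residues(residues, allowed, rec_id)
        if is_nt:
            residues = residues.replace("U", "T")
        if not residues:
            warnings.warn(f"record {rec_id!r} has an empty sequence", stacklevel=3)
        return SequenceRecord(id=rec_id, description=desc, residues=residues)

    for lineno, raw in enumerate(_as_lines(stream), start=1):
        line = raw.rstrip("\r\n")
        if not line.strip():
            continue
        if line.startswith(">"):
            if header is not None:
                yield _emit()
            stripped = line[1:].strip()
            if not stripped:
                raise FastaParseError(f"line {lineno}: empty FASTA header")
            header = stripped
            parts = []
        else:
            if header is None:
                raise FastaParseError(
                    f"line {lineno}: expected '>' at start of FASTA input"
                )
            parts.append(line.strip())
    if header is not None:
        yield _emit()


def _infer_mate(read_id: str) -> int | None:
    if read_id.endswith("/1"):
        return 1
    if read_id.endswith("/2"):
        return 2
    return None


def parse_fastq(stream: Union[str, IO, Iterable[str]]) -> Iterator[ReadRecord]:
    """Yield :class:`ReadRecord` objects from 4-line phred+33 FASTQ text.

    Raises :class:`FastqParseError` on truncated records, framing violations
    (missing ``@``/``+``), quality-length mismatches (names the read id), and
    quality characters outside the printable phred+33 range.
    """
    it = iter(_as_lines(stream))
    lineno = 0
    while True:
        try:
            head = next(it)
        except StopIteration:
            return
        lineno += 1
        head = head.rstrip("\r\n")
        if not head.strip():
            continue
        if not head.startswith("@"):
            raise FastqParseError(f"line {lineno}: expected '@' header, got {head!r}")
        fields = head[1:].split(None, 1)
        if not fields:
            raise FastqParseError(f"line {lineno}: empty FASTQ header")
        read_id = fields[0]
        try:
            bases = next(it).rstrip("\r\n")
            plus = next(it).rstrip("\r\n")
            qual = next(it).rstrip("\r\n")
            lineno += 3
        except StopIteration:
            raise FastqParseError(f"read {read_id!r}: truncated FASTQ record") from None
        if not plus.startswith("+"):
            raise FastqParseError(f"read {read_id!r}: expected '+' separator")
        if len(bases) != len(qual):
            raise FastqParseError(f"read {read_id!r}: quality length mismatch")
        quals = []
        for c in qual:
            q = ord(c) - PHRED_OFFSET
            if not 0 <= q <= MAX_PHRED:
                raise FastqParseError(
                    f"read {read_id!r}: quality character {c!r} out of range"
                )
            quals.append(q)
        yield ReadRecord(
            id=read_id, bases=bases.upper(), quals=tuple(quals), mate=_infer_mate(read_id)
        )


def _format_fasta(record, line_width: int) -> str:
    if isinstance(record, ReadRecord):
        header, seq = record.id, record.bases
    else:
        header, seq = record.header, record.residues
    lines = [f">{header}"]
    if line_width <= 0:
        lines.append(seq)
    else:
        lines.extend(seq[i : i + line_width] for i in range(0, len(seq), line_width))
    if not seq:
        return lines[0] + "\n"
    return "\n".join(lines) + "\n"


def _format_fastq(record) -> str:
    if not isinstance(record, ReadRecord):
        raise ValueError(
            f"record {record.id!r} has no quality scores; cannot write FASTQ"
        )
    qual = "".join(chr(q + PHRED_OFFSET) for q in record.quals)
    return f"@{record.id}\n{record.bases}\n+\n{qual}\n"


def write_records(
    records: Iterable[Union[SequenceRecord, ReadRecord]],
    handle: IO | None = None,
    format: str = "fasta",
    line_width: int = 60,
) -> str | None:
    """Write records as FASTA (wrapped at ``line_width``) or 4-line FASTQ.

    Writes to ``handle`` when given, otherwise returns the formatted text.
    Output is deterministic and round-trips through the matching parser.
    """
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unknown format {format!r}")
    chunks = []
    for rec in records:
        if format == "fasta":
            chunks.append(_format_fasta(rec, line_width))
        else:
            chunks.append(_format_fastq(rec))
    text = "".join(chunks)
    if handle is None:
        return text
    handle.write(text)
    return None


def _open_text(path, mode: str = "rt") -> IO:
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path, alphabet: str = "nt") -> list[SequenceRecord]:
    """Read a (possibly gzipped) FASTA file into a list of records."""
    with _open_text(path) as fh:
        return list(parse_fasta(fh, alphabet))


def read_fastq(path) -> list[ReadRecord]:
    """Read a (possibly gzipped) FASTQ file into a list of reads."""
    with _open_text(path) as fh:
        return list(parse_fastq(fh))


def write_fasta(records: Sequence, path, line_width: int = 60) -> None:
    with _open_text(path, "wt") as fh:
        write_records(records, fh, format="fasta", line_width=line_width)


def write_fastq(records: Sequence[ReadRecord], path) -> None:
    with _open_text(path, "wt") as fh:
        write_records(records, fh, format="fastq")
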