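"""Assembly of final searchable protein databases.

Databases built from different sources (proteome, translated transcriptome,
six-frame genome) differ hugely in size, and probability-based search scoring
is sensitive to search-space size.  To compare databases fairly they are
*sized*: filler (e.g. bacterial) protein sequences are appended until every
database holds exactly the same total residue count.  Records carry a
provenance tag (``subject``, ``contaminant``, ``filler``) in their FASTA
description so that downstream peptide accounting can ignore padding.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import numpy as np

from .seqio import SequenceRecord, read_fasta, write_fasta

__all__ = [
    "ProteinDatabase",
    "DbStats",
    "dedup_exact",
    "concat_databases",
    "pad_to_target",
    "db_stats",
]

PROVENANCE_TAGS = ("subject", "contaminant", "filler")
_SRC_RE = re.compile(r"\bsrc=(\w+)\b")


def _tag_description(description: str, source: str) -> str:
    if _SRC_RE.search(description):
        return _SRC_RE.sub(f"src={source}", description)
    return f"{description} src={source}".strip()


def record_provenance(record: SequenceRecord) -> str:
    """Provenance tag parsed from the description; ``subject`` by default."""
    m = _SRC_RE.search(record.description)
    return m.group(1) if m else "subject"


class ProteinDatabase:
    """An ordered collection of protein records with unique accessions.

    On ingest, ``*`` characters are stripped with a warning (annotation
    pipelines sometimes emit trailing stops) and zero-length records are
    rejected; duplicate ids are rejected because parsimony bookkeeping needs
    unique accessions.
    """

    def __init__(self, records: Iterable[SequenceRecord], source: str | None = None):
        cleaned: list[SequenceRecord] = []
        index: dict[str, int] = {}
        stripped = 0
        for rec in records:
            residues = rec.residues
            if "*" in residues:
                residues = residues.replace("*", "")
                stripped += 1
            desc = _tag_description(rec.description, source) if source else rec.description
            if residues != rec.residues or desc != rec.description:
                rec = SequenceRecord(id=rec.id, description=desc, residues=residues)
            if not rec.residues:
                raise ValueError(f"record {rec.id!r} has zero length")
            if rec.id in index:
                raise ValueError(f"duplicate record id {rec.id!r}")
            index[rec.id] = len(cleaned)
            cleaned.append(rec)
        if stripped:
            warnings.warn(f"stripped '*' characters from {stripped} record(s)")
        self._records = cleaned
        self._index = index

    # -- container protocol -------------------------------------------------
    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self._records)

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, rec_id: str) -> bool:
        return rec_id in self._index

    def __getitem__(self, rec_id: str) -> SequenceRecord:
        return self._records[self._index[rec_id]]

    @property
    def records(self) -> list[SequenceRecord]:
        return list(self._records)

    @property
    def n_sequences(self) -> int:
        return len(self._records)

    @property
    def n_residues(self) -> int:
        return sum(len(r) for r in self._records)

    def provenance(self, rec_id: str) -> str:
        return record_provenance(self[rec_id])

    def subject_ids(self) -> set[str]:
        """Ids of non-padding records (the sequences under comparison)."""
        return {r.id for r in self._records if record_provenance(r) == "subject"}

    # -- I/O ----------------------------------------------------------------
    @classmethod
    def from_fasta(cls, path, source: str | None = None) -> "ProteinDatabase":
        return cls(read_fasta(path, alphabet="aa"), source=source)

    def to_fasta(self, path, line_width: int = 60) -> None:
        write_fasta(self._records, path, line_width=line_width)


@dataclass(frozen=True)
class DbStats:
    n_sequences: int
    n_residues: int
    length_histogram: dict[int, int]  # bin start (aa) -> count


def dedup_exact(
    db: ProteinDatabase, absorb_substrings: bool = False
) -> tuple[ProteinDatabase, dict[str, str]]:
    """Remove records whose residue strings duplicate an earlier record.

    Among byte-identical sequences only the first in input order is kept;
    order is otherwise preserved.  Returns the deduplicated database and a
    ``removed_id -> kept_id`` mapping.  With ``absorb_substrings``, records
    that are exact substrings of a longer kept record are also absorbed
    (quadratic scan; mirrors 100%-identity clustering that collapses
    contained sequences).
    """
    kept: list[SequenceRecord] = []
    first_by_seq: dict[str, str] = {}
    mapping: dict[str, str] = {}
    for rec in db:
        if rec.residues in first_by_seq:
            mapping[rec.id] = first_by_seq[rec.residues]
        else:
            first_by_seq[rec.residues] = rec.id
            kept.append(rec)
    if absorb_substrings:
        by_len = sorted(kept, key=len, reverse=True)
        survivors: list[SequenceRecord] = []
        for rec in by_len:
            host = next(
                (s for s in survivors if rec.residues in s.residues), None
            )
            if host is not None:
                mapping[rec.id] = host.id
            else:
                survivors.append(rec)
        keep_ids = {r.id for r in survivors}
        kept = [r for r in kept if r.id in keep_ids]
    return ProteinDatabase(kept), mapping


def concat_databases(
    dbs: Iterable[ProteinDatabase], id_collision: str = "error"
) -> ProteinDatabase:
    """Concatenate databases in argument order; residue counts are additive.

    ``id_collision`` is ``error`` (raise, naming the id) or ``suffix``
    (rename the later record ``<id>_2``, ``<id>_3``, ...).
    """
    if id_collision not in ("error", "suffix"):
        raise ValueError(f"unknown id_collision policy {id_collision!r}")
    seen: dict[str, int] = {}
    out: list[SequenceRecord] = []
    for db in dbs:
        for rec in db:
            rec_id = rec.id
            if rec_id in seen:
                if id_collision == "error":
                    raise ValueError(f"id collision: {rec_id!r}")
                seen[rec_id] += 1
                new_id = f"{rec_id}_{seen[rec_id]}"
                while new_id in seen:
                    seen[rec_id] += 1
                    new_id = f"{rec_id}_{seen[rec_id]}"
                seen[new_id] = 1
                rec = SequenceRecord(
                    id=new_id, description=rec.description, residues=rec.residues
                )
            else:
                seen[rec_id] = 1
            out.append(rec)
    return ProteinDatabase(out)


def pad_to_target(
    db: ProteinDatabase,
    filler: ProteinDatabase,
    target_residues: int,
    exact: bool = True,
) -> ProteinDatabase:
    """Append filler records until the database holds exactly ``target_residues``.

    Filler records are appended in filler order while they fit whole; the
    record that would overshoot is truncated to the exact remaining deficit
    (id suffixed ``_trunc``).  Appended records are tagged ``src=filler`` so
    peptide-comparison accounting excludes them.  With ``exact=False`` no
    truncation is done and the final shortfall is left (and reported in a
    warning).
    """
    current = db.n_residues
    if target_residues < current:
        raise ValueError(
            f"target_residues ({target_residues}) < current residues ({current}); "
            "sizing only grows databases"
        )
    deficit = target_residues - current
    if deficit == 0:
        return ProteinDatabase(db.records)
    if filler.n_residues < deficit:
        raise ValueError(
            f"insufficient filler: need {deficit} residues, have {filler.n_residues}"
        )
    added: list[SequenceRecord] = []
    for rec in filler:
        if deficit == 0:
            break
        if len(rec) <= deficit:
            added.append(
                SequenceRecord(
                    id=rec.id,
                    description=_tag_description(rec.description, "filler"),
                    residues=rec.residues,
                )
            )
            deficit -= len(rec)
        else:
            if exact:
                added.append(
                    SequenceRecord(
                        id=f"{rec.id}_trunc",
                        description=_tag_description(rec.description, "filler"),
                        residues=rec.residues[:deficit],
                    )
                )
                deficit = 0
            break
    if deficit and not exact:
        warnings.warn(f"padding left a shortfall of {deficit} residues")
    return concat_databases([db, ProteinDatabase(added)], id_collision="suffix")


def db_stats(db: ProteinDatabase, bin_width: int = 100) -> DbStats:
    """Sequence/residue counts and a sequence-length histogram."""
    lengths = np.array([len(r) for r in db], dtype=int)
    hist: dict[int, int] = {}
    if lengths.size:
        bins = (lengths // bin_width) * bin_width
        starts, counts = np.unique(bins, return_counts=True)
        hist = {int(s): int(c) for s, c in zip(starts, counts)}
    return DbStats(
        n_sequences=int(lengths.size),
        n_residues=int(lengths.sum()) if lengths.size else 0,
        length_histogram=hist,
    )
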