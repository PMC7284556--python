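"""Identification filtering, parsimony inference, and peptide-set comparison.

This module evaluates a database search at the peptide level.  Observations
(peptide sequence + spectral count) pooled across runs are filtered with two
stringency rules applied once, in order:

1. peptides with fewer than two spectral counts are removed;
2. the most parsimonious protein set explaining the remaining peptides is
   computed, and peptides all of whose parsimony-assigned proteins have
   fewer than two distinct supporting peptides are removed.

Database-unique peptides are then explained: a peptide absent from a
reference database is classified as carrying an internal single amino acid
variant (SAV, Hamming distance 1 to a same-length reference tryptic
peptide), a variant at an adjacent tryptic cleavage site (exact substring of
a reference protein but failing the tryptic boundary test), or absent; and
peptides from fragmented transcripts are flagged when they abut a terminus
of their source sequence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .dbbuild import ProteinDatabase
from .digest import (
    DigestConfig,
    classify_tryptic,
    cleavage_sites,
    digest_database,
)

__all__ = [
    "PeptideObservation",
    "IdentificationSet",
    "ComparisonResult",
    "SavCall",
    "SavDetector",
    "read_identifications_tsv",
    "filter_identifications",
    "parsimony_proteins",
    "compare_peptide_sets",
    "peptide_presence",
    "detect_sav",
    "terminal_fragment_check",
]


@dataclass(frozen=True)
class PeptideObservation:
    """One identified peptide with its pooled spectral count."""

    sequence: str
    spectral_count: int
    source_search: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        if self.spectral_count < 1:
            raise ValueError("spectral_count must be >= 1")


@dataclass
class IdentificationSet:
    """Filtered or raw peptide observations from one database search."""

    observations: list[PeptideObservation]
    index: Mapping[str, set[str]]
    label: str = ""

    @classmethod
    def from_counts(
        cls, counts: Mapping[str, int], index: Mapping[str, set[str]], label: str = ""
    ) -> "IdentificationSet":
        obs = [
            PeptideObservation(sequence=s, spectral_count=c, source_search=label)
            for s, c in counts.items()
        ]
        return cls(observations=obs, index=index, label=label)

    def counts(self) -> dict[str, int]:
        """Spectral counts pooled per unique peptide sequence."""
        pooled: dict[str, int] = {}
        for ob in self.observations:
            pooled[ob.sequence] = pooled.get(ob.sequence, 0) + ob.spectral_count
        return pooled

    def peptides(self) -> set[str]:
        return {ob.sequence for ob in self.observations}


def read_identifications_tsv(
    path, index: Mapping[str, set[str]], label: str = ""
) -> IdentificationSet:
    """Load a search export TSV with columns ``peptide`` and ``spectral_count``."""
    df = pd.read_csv(path, sep="\t")
    missing = {"peptide", "spectral_count"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    obs = [
        PeptideObservation(
            sequence=str(row.peptide),
            spectral_count=int(row.spectral_count),
            source_search=label,
        )
        for row in df.itertuples()
    ]
    return IdentificationSet(observations=obs, index=index, label=label)


def parsimony_proteins(
    peptides: Iterable[str],
    index: Mapping[str, set[str]],
    exact_limit: int = 20,
) -> tuple[set[str], dict[str, set[str]], set[str]]:
    """Minimum set cover: the smallest protein set explaining the peptides.

    Instances with at most ``exact_limit`` candidate proteins are solved
    exactly (bounded subset search, first lexicographic optimum wins); larger
    instances use the greedy cover, picking the protein covering the most
    uncovered peptides with ties broken by more total matched peptides, then
    lexicographically smallest id.  Returns ``(retained proteins, peptide ->
    retained proteins containing it, orphan peptides with no protein)``.
    """
    peptides = set(peptides)
    orphans = {p for p in peptides if not index.get(p)}
    to_cover = peptides - orphans
    protein_peps: dict[str, set[str]] = {}
    for pep in to_cover:
        for prot in index[pep]:
            protein_peps.setdefault(prot, set()).add(pep)
    if len(protein_peps) <= exact_limit:
        retained = exhaustive_min_cover(to_cover, index)
    else:
        retained = set()
        uncovered = set(to_cover)
        while uncovered:
            best_score = max(
                (len(peps & uncovered), len(peps)) for peps in protein_peps.values()
            )
            # among proteins with the best (gain, total) score, smallest id wins
            best = min(
                pr
                for pr, peps in protein_peps.items()
                if (len(peps & uncovered), len(peps)) == best_score
            )
            gain = protein_peps[best] & uncovered
            assert gain, "uncovered peptides must have a covering protein"
            retained.add(best)
            uncovered -= gain
    assignment = {
        pep: {pr for pr in index[pep] if pr in retained} for pep in to_cover
    }
    return retained, assignment, orphans


def exhaustive_min_cover(
    peptides: Iterable[str], index: Mapping[str, set[str]]
) -> set[str]:
    """Smallest protein set covering all peptides, by exhaustive search.

    Exponential in the number of proteins; intended for small instances as
    an independent check of the greedy cover.  Ties are broken toward the
    lexicographically smallest protein tuple.
    """
    peptides = {p for p in peptides if index.get(p)}
    proteins = sorted({pr for pep in peptides for pr in index[pep]})
    cover_of = {pr: {pep for pep in peptides if pr in index[pep]} for pr in proteins}
    for size in range(len(proteins) + 1):
        for combo in itertools.combinations(proteins, size):
            covered = set()
            for pr in combo:
                covered |= cover_of[pr]
            if covered >= peptides:
                return set(combo)
    raise AssertionError("unreachable: full protein set always covers")


def filter_identifications(
    idset: IdentificationSet,
    min_spectral_count: int = 2,
    min_supporting_peptides: int = 2,
    iterate: bool = False,
    count_all_mapped: bool = False,
) -> tuple[IdentificationSet, dict[str, str]]:
    """Apply the two stringency filters; returns (filtered set, removal log).

    Step 1 removes peptides below ``min_spectral_count``.  Step 2 computes
    the parsimonious protein set over the survivors and removes peptides all
    of whose assigned proteins fall below ``min_supporting_peptides``
    distinct peptides; peptides absent from the index are removed as
    ``unmatched``.  Steps run once, in that order (``iterate=True`` repeats
    step 2 to a fixpoint).  ``count_all_mapped`` counts protein support over
    all mapped proteins instead of parsimony-retained ones.
    """
    log: dict[str, str] = {}
    counts = idset.counts()
    surviving = {}
    for seq, c in counts.items():
        if c < min_spectral_count:
            log[seq] = f"spectral_count {c} < {min_spectral_count}"
        else:
            surviving[seq] = c

    def support_pass(peps: dict[str, int]) -> dict[str, int]:
        if count_all_mapped:
            assignment = {p: set(idset.index.get(p, set())) for p in peps}
            orphans = {p for p, prots in assignment.items() if not prots}
        else:
            _, assignment, orphans = parsimony_proteins(peps, idset.index)
        support: dict[str, set[str]] = {}
        for pep, prots in assignment.items():
            for pr in prots:
                support.setdefault(pr, set()).add(pep)
        kept = {}
        for pep, c in peps.items():
            if pep in orphans:
                log[pep] = "unmatched"
                continue
            if any(
                len(support[pr]) >= min_supporting_peptides for pr in assignment[pep]
            ):
                kept[pep] = c
            else:
                log[pep] = f"all proteins have < {min_supporting_peptides} peptides"
        return kept

    surviving = support_pass(surviving)
    if iterate:
        while True:
            after = support_pass(surviving)
            if set(after) == set(surviving):
                break
            surviving = after
    filtered = IdentificationSet.from_counts(surviving, idset.index, idset.label)
    return filtered, log


@dataclass(frozen=True)
class ComparisonResult:
    """Exact set-algebra partition of peptides across 2-3 searches."""

    labels: tuple[str, ...]
    region_counts: dict[frozenset, int]
    unique: dict[str, list[str]]
    all_shared: int

    @property
    def union_size(self) -> int:
        return sum(self.region_counts.values())


def compare_peptide_sets(
    idsets: Sequence[IdentificationSet],
) -> ComparisonResult:
    """Partition peptide sequences into exclusive membership regions.

    ``region_counts`` is keyed by the frozenset of labels a peptide appears
    in (Venn regions); region counts sum to the size of the union.
    """
    if not 2 <= len(idsets) <= 3:
        raise ValueError("compare_peptide_sets takes 2 or 3 identification sets")
    labels = tuple(s.label for s in idsets)
    if len(set(labels)) != len(labels):
        raise ValueError("identification sets must carry distinct labels")
    sets = {s.label: s.peptides() for s in idsets}
    union = set().union(*sets.values())
    regions: dict[frozenset, int] = {}
    for pep in union:
        key = frozenset(lbl for lbl in labels if pep in sets[lbl])
        regions[key] = regions.get(key, 0) + 1
    unique = {
        lbl: sorted(
            p for p in sets[lbl] if all(p not in sets[o] for o in labels if o != lbl)
        )
        for lbl in labels
    }
    return ComparisonResult(
        labels=labels,
        region_counts=regions,
        unique=unique,
        all_shared=regions.get(frozenset(labels), 0),
    )


def peptide_presence(
    peptide: str,
    db: ProteinDatabase,
    cfg: DigestConfig | None = None,
    mode: str = "tryptic",
) -> tuple[bool, list[tuple[str, int]]]:
    """Whether a peptide occurs in a database, with its occurrence locations.

    ``substring`` mode reports any exact occurrence; ``tryptic`` mode only
    occurrences that are fully tryptic under ``cfg`` with at most
    ``cfg.max_missed`` internal missed cleavages.
    """
    if mode not in ("substring", "tryptic"):
        raise ValueError(f"unknown mode {mode!r}")
    cfg = cfg or DigestConfig()
    hits: list[tuple[str, int]] = []
    for rec in db:
        start = rec.residues.find(peptide)
        while start != -1:
            ok = True
            if mode == "tryptic":
                status = classify_tryptic(peptide, rec.residues, start, cfg)
                internal = [
                    s
                    for s in cleavage_sites(rec.residues, cfg)
                    if start < s < start + len(peptide)
                ]
                ok = status == "full" and len(internal) <= cfg.max_missed
            if ok:
                hits.append((rec.id, start))
            start = rec.residues.find(peptide, start + 1)
    return bool(hits), hits


@dataclass(frozen=True)
class SavCall:
    """Classification of a peptide against a reference database."""

    peptide: str
    sav_class: str  # exact | internal_sav | flanking_cleavage_sav | absent
    reference_protein_id: str | None = None
    reference_peptide_or_region: str | None = None
    variant_position: int | None = None


class SavDetector:
    """Classifies peptides against a digested reference database.

    Precomputes the reference's fully tryptic peptide index and a wildcard
    lookup (peptide with one position masked) so that distance-1 queries are
    O(peptide length).
    """

    def __init__(self, reference_db: ProteinDatabase, cfg: DigestConfig | None = None):
        self.db = reference_db
        self.cfg = cfg or DigestConfig()
        self.index = digest_database(reference_db, self.cfg)
        self._masked: dict[tuple[int, str], tuple[str, str]] = {}
        for pep, prots in self.index.items():
            prot = min(prots)
            for pos in range(len(pep)):
                key = (pos, pep[:pos] + "\x00" + pep[pos + 1 :])
                self._masked.setdefault(key, (pep, prot))

    def detect(self, peptide: str) -> SavCall:
        if peptide in self.index:
            return SavCall(
                peptide=peptide,
                sav_class="exact",
                reference_protein_id=min(self.index[peptide]),
                reference_peptide_or_region=peptide,
            )
        for pos in range(len(peptide)):
            key = (pos, peptide[:pos] + "\x00" + peptide[pos + 1 :])
            hit = self._masked.get(key)
            if hit is not None and hit[0] != peptide:
                ref_pep, ref_prot = hit
                return SavCall(
                    peptide=peptide,
                    sav_class="internal_sav",
                    reference_protein_id=ref_prot,
                    reference_peptide_or_region=ref_pep,
                    variant_position=pos,
                )
        present, hits = peptide_presence(peptide, self.db, self.cfg, mode="substring")
        if present:
            prot_id, start = hits[0]
            return SavCall(
                peptide=peptide,
                sav_class="flanking_cleavage_sav",
                reference_protein_id=prot_id,
                reference_peptide_or_region=self.db[prot_id].residues[
                    max(0, start - 1) : start + len(peptide) + 1
                ],
            )
        return SavCall(peptide=peptide, sav_class="absent")


def detect_sav(
    peptide: str, reference_db: ProteinDatabase, cfg: DigestConfig | None = None
) -> SavCall:
    """Classify one peptide against a reference database.

    Precedence: ``exact`` (fully tryptic in the reference) >
    ``internal_sav`` (Hamming distance exactly 1 to a same-length reference
    tryptic peptide) > ``flanking_cleavage_sav`` (exact substring of a
    reference protein that fails the tryptic boundary test, implying a
    variant at the adjacent cleavage site) > ``absent``.  For classifying
    many peptides against one reference, build a :class:`SavDetector` once.
    """
    return SavDetector(reference_db, cfg).detect(peptide)


def terminal_fragment_check(
    peptide: str, source_protein: str
) -> tuple[bool, list[str]]:
    """Whether any occurrence of the peptide abuts a terminus of its source.

    Returns ``(at_terminus, ends)`` where ends lists 'N' and/or 'C'.
    Raises if the peptide does not occur at all.
    """
    ends = []
    start = source_protein.find(peptide)
    if start == -1:
        raise ValueError("peptide does not occur in source protein")
    found_n = found_c = False
    while start != -1:
        if start == 0:
            found_n = True
        if start + len(peptide) == len(source_protein):
            found_c = True
        start = source_protein.find(peptide, start + 1)
    if found_n:
        ends.append("N")
    if found_c:
        ends.append("C")
    return bool(ends), ends
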