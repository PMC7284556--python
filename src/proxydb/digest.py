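"""In-silico tryptic digestion, tryptic-status classification, peptide masses.

Trypsin cleaves C-terminal of lysine (K) and arginine (R); by default the cut
is suppressed when the next residue is proline (Mascot-style trypsin).  A
peptide is *fully tryptic* when both its termini are enzymatic boundaries or
protein termini, *semi-tryptic* when exactly one is.

Monoisotopic peptide masses use the standard residue-mass table from
pyteomics, with carbamidomethyl-cysteine as a fixed modification
(+57.02146 Da) and oxidized methionine as a variable one (+15.99491 Da),
matching common search-engine settings for reduced/alkylated digests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from pyteomics import mass as _pyt_mass

from .seqio import SequenceRecord

__all__ = [
    "DigestConfig",
    "Peptide",
    "ModSpec",
    "cleavage_sites",
    "tryptic_digest",
    "classify_tryptic",
    "peptide_mass",
    "digest_database",
]

WATER_MONO = 18.010565
CARBAMIDOMETHYL = 57.02146
OXIDATION = 15.99491

RESIDUE_MASSES: Mapping[str, float] = dict(_pyt_mass.std_aa_mass)


@dataclass(frozen=True)
class DigestConfig:
    """Tryptic digestion parameters.

    ``max_missed`` allows peptides spanning up to that many uncut internal
    K/R sites.  Length bounds default to 6-60 aa, the range search engines
    score effectively; set ``min_len=1`` and a large ``max_len`` to disable.
    """

    enzyme: str = "trypsin"
    suppress_proline: bool = True
    max_missed: int = 2
    min_len: int = 6
    max_len: int = 60

    def __post_init__(self) -> None:
        if self.enzyme != "trypsin":
            raise ValueError(f"unsupported enzyme {self.enzyme!r}")
        if self.max_missed < 0:
            raise ValueError("max_missed must be >= 0")
        if not 1 <= self.min_len <= self.max_len:
            raise ValueError("need 1 <= min_len <= max_len")


@dataclass(frozen=True)
class ModSpec:
    """Fixed and variable per-residue modification masses (Da)."""

    fixed: Mapping[str, float] = field(
        default_factory=lambda: {"C": CARBAMIDOMETHYL}
    )
    variable: Mapping[str, float] = field(
        default_factory=lambda: {"M": OXIDATION}
    )


@dataclass(frozen=True)
class Peptide:
    """A tryptic peptide with source coordinates (0-based half-open)."""

    sequence: str
    protein_id: str
    start: int
    end: int
    missed: int
    tryptic_status: str = "full"


def cleavage_sites(protein: str, cfg: DigestConfig | None = None) -> list[int]:
    """Internal cut positions: indices after each cleavable K/R.

    A position ``p`` means the bond between residues ``p-1`` and ``p`` is
    cut.  Cuts after a K/R followed by P are suppressed when configured.
    The protein termini (0 and len) are implicit boundaries, not listed.
    """
    if not protein:
        raise ValueError("protein must be non-empty")
    cfg = cfg or DigestConfig()
    sites = []
    for i in range(len(protein) - 1):
        if protein[i] in "KR":
            if cfg.suppress_proline and protein[i + 1] == "P":
                continue
            sites.append(i + 1)
    return sites


def tryptic_digest(
    protein: SequenceRecord | str,
    cfg: DigestConfig | None = None,
    protein_id: str | None = None,
) -> list[Peptide]:
    """All fully tryptic peptides with 0..max_missed missed cleavages.

    Peptides containing 'X' or '*' are excluded (they cannot be matched
    exactly), as are peptides outside the configured length bounds.
    """
    cfg = cfg or DigestConfig()
    if isinstance(protein, SequenceRecord):
        seq = protein.residues
        pid = protein.id
    else:
        seq = protein
        pid = protein_id or ""
    if not seq:
        return []
    bounds = [0] + cleavage_sites(seq, cfg) + [len(seq)]
    peptides = []
    for i in range(len(bounds) - 1):
        for m in range(cfg.max_missed + 1):
            j = i + 1 + m
            if j >= len(bounds):
                break
            start, end = bounds[i], bounds[j]
            pep = seq[start:end]
            if not cfg.min_len <= len(pep) <= cfg.max_len:
                continue
            if "X" in pep or "*" in pep:
                continue
            peptides.append(
                Peptide(sequence=pep, protein_id=pid, start=start, end=end, missed=m)
            )
    return peptides


def classify_tryptic(
    peptide_seq: str,
    protein: str,
    position: int,
    cfg: DigestConfig | None = None,
) -> str:
    """Classify a peptide occurrence as ``full``, ``semi`` or ``non`` tryptic.

    An N-terminal boundary is enzymatic when the peptide starts at the
    protein N-terminus or the preceding residue is a cleavable K/R; a
    C-terminal boundary when the peptide ends at the protein C-terminus or
    its last residue is a cleavable K/R.  Peptides abutting the end of a
    truncated transcript's translation therefore count as enzymatic at that
    end, which is how fragment-terminal peptides pass a fully-tryptic filter.
    """
    cfg = cfg or DigestConfig()
    end = position + len(peptide_seq)
    if position < 0 or end > len(protein) or protein[position:end] != peptide_seq:
        raise ValueError(
            f"peptide {peptide_seq!r} does not occur at position {position}"
        )
    n_ok = position == 0 or (
        protein[position - 1] in "KR"
        and not (cfg.suppress_proline and peptide_seq[0] == "P")
    )
    c_ok = end == len(protein) or (
        peptide_seq[-1] in "KR"
        and not (cfg.suppress_proline and protein[end] == "P")
    )
    if n_ok and c_ok:
        return "full"
    if n_ok or c_ok:
        return "semi"
    return "non"


def peptide_mass(
    seq: str, mods: ModSpec | None = None, n_oxidations: int = 0
) -> float:
    """Monoisotopic peptide mass in Da, fixed mods always applied.

    ``n_oxidations`` counts variably oxidized methionines and must not
    exceed the number of M residues.
    """
    mods = mods or ModSpec()
    if n_oxidations < 0 or n_oxidations > seq.count("M"):
        raise ValueError("n_oxidations exceeds methionine count")
    total = WATER_MONO
    for c in seq:
        try:
            total += RESIDUE_MASSES[c]
        except KeyError:
            raise ValueError(f"unknown residue {c!r} in peptide") from None
        total += mods.fixed.get(c, 0.0)
    total += OXIDATION * n_oxidations if "M" in mods.variable else 0.0
    if n_oxidations and "M" not in mods.variable:
        raise ValueError("oxidation requested but not configured")
    return total


def digest_database(
    db, cfg: DigestConfig | None = None
) -> dict[str, set[str]]:
    """Map each fully tryptic peptide to the set of protein ids containing it.

    ``db`` is a :class:`~proxydb.dbbuild.ProteinDatabase` or any iterable of
    protein :class:`SequenceRecord` objects.
    """
    cfg = cfg or DigestConfig()
    index: dict[str, set[str]] = {}
    for rec in db:
        for pep in tryptic_digest(rec, cfg):
            index.setdefault(pep.sequence, set()).add(rec.id)
    return index
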