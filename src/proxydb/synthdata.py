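"""Seeded generators for every input the pipeline consumes.

The generators emulate the statistical structure of a seed-tissue proteomics
experiment on a non-model plant: a proteome dominated by a few highly
abundant storage-protein families (the vicilin/legumin-like proteins that
dominate nut MS identifications), transcript sets bearing single amino acid
variants and truncations (standing in for de-novo assembly output of varying
quality), Illumina-like paired reads with ~0.1% substitution errors, and
spectral-count observations emulating a pooled database search.

Everything is deterministic given a seed, so end-to-end experiments run at
desk scale with no downloads and verifiable truth tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .dbbuild import ProteinDatabase
from .digest import DigestConfig, digest_database, tryptic_digest
from .idcompare import IdentificationSet
from .seqio import ReadRecord, SequenceRecord
from .translate import reverse_complement, translate_frame

__all__ = [
    "SimConfig",
    "TranscriptTruth",
    "GeneTruth",
    "SimulatedReads",
    "simulate_proteome",
    "simulate_genome",
    "simulate_transcriptome",
    "simulate_reads",
    "simulate_observations",
    "write_identifications_tsv",
]

# Amino-acid composition used for random proteins: roughly Swiss-Prot-like,
# with K+R = 11% so tryptic peptides of useful length always exist.
AA_FREQS = {
    "A": 0.080, "C": 0.015, "D": 0.054, "E": 0.067, "F": 0.039,
    "G": 0.070, "H": 0.023, "I": 0.059, "K": 0.060, "L": 0.095,
    "M": 0.024, "N": 0.041, "P": 0.047, "Q": 0.039, "R": 0.050,
    "S": 0.066, "T": 0.054, "V": 0.068, "W": 0.011, "Y": 0.038,
}
_AA = list(AA_FREQS)
_AA_P = np.array(list(AA_FREQS.values()))
_AA_P = _AA_P / _AA_P.sum()

# Synonymous codons of the standard nuclear code, for back-translation.
_CODONS_BY_AA: dict[str, list[str]] = {}
for _c in ("".join((a, b, c)) for a in "TCAG" for b in "TCAG" for c in "TCAG"):
    _aa = translate_frame(_c, 1)
    _CODONS_BY_AA.setdefault(_aa, []).append(_c)
STOP_CODONS = _CODONS_BY_AA.pop("*")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic experiment.

    Defaults mirror a seed-tissue RNA-Seq/proteomics setting: 85 bp reads,
    0.1% per-base substitution error, a log-normal protein length
    distribution (median ~250 aa), a few 10x-abundant storage families, and
    moderate transcript truncation.
    """

    seed: int = 0
    n_proteins: int = 300
    length_log_mean: float = 5.5
    length_log_sigma: float = 0.45
    n_storage_families: int = 3
    storage_family_size: int = 2
    storage_length_scale: float = 2.0
    storage_abundance: float = 10.0
    sav_rate: float = 0.002
    fragmentation_rate: float = 0.3
    read_length: int = 85
    error_rate: float = 0.001
    coverage: float = 30.0

    def __post_init__(self) -> None:
        for name in ("sav_rate", "fragmentation_rate", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if min(self.n_proteins, self.read_length) < 1 or self.coverage <= 0:
            raise ValueError("counts must be positive")


def _random_protein(rng: np.random.Generator, length: int) -> str:
    body = rng.choice(_AA, size=length - 1, p=_AA_P)
    return "M" + "".join(body)


def simulate_proteome(cfg: SimConfig) -> tuple[ProteinDatabase, dict[str, float]]:
    """A random proteome plus per-protein abundance weights.

    Storage-family proteins are drawn ~``storage_length_scale`` times longer
    than the log-normal background and weighted ``storage_abundance``-fold;
    each family holds near-identical paralogs (2% divergence) so shared
    peptides exercise parsimony inference downstream.
    """
    rng = np.random.default_rng(cfg.seed)
    records: list[SequenceRecord] = []
    abundance: dict[str, float] = {}
    n_storage = cfg.n_storage_families * cfg.storage_family_size
    if n_storage > cfg.n_proteins:
        raise ValueError("more storage proteins than proteins requested")
    for fam in range(cfg.n_storage_families):
        length = int(
            cfg.storage_length_scale
            * np.clip(rng.lognormal(cfg.length_log_mean, cfg.length_log_sigma), 100, 1500)
        )
        base = _random_protein(rng, length)
        for member in range(cfg.storage_family_size):
            seq = base
            if member > 0:
                chars = list(base)
                n_sub = max(1, int(0.02 * length))
                pos = rng.choice(np.arange(1, length), size=n_sub, replace=False)
                for p in pos:
                    chars[p] = str(rng.choice(_AA, p=_AA_P))
                seq = "".join(chars)
            rec_id = f"storage{fam:02d}_{member}"
            records.append(
                SequenceRecord(id=rec_id, description="family=storage", residues=seq)
            )
            abundance[rec_id] = cfg.storage_abundance
    for i in range(cfg.n_proteins - n_storage):
        length = int(
            np.clip(rng.lognormal(cfg.length_log_mean, cfg.length_log_sigma), 50, 2000)
        )
        rec_id = f"prot{i:05d}"
        records.append(
            SequenceRecord(id=rec_id, description="", residues=_random_protein(rng, length))
        )
        abundance[rec_id] = 1.0
    return ProteinDatabase(records), abundance


def _back_translate(protein: str, rng: np.random.Generator) -> str:
    codons = [
        _CODONS_BY_AA[aa][rng.integers(len(_CODONS_BY_AA[aa]))] for aa in protein
    ]
    return "".join(codons)


def _random_nt(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


@dataclass(frozen=True)
class GeneTruth:
    gene_id: str
    protein_id: str
    contig_id: str
    exons: tuple[tuple[int, int], ...]  # 0-based half-open contig coordinates


def simulate_genome(
    proteome: ProteinDatabase,
    intron_rate: float = 0.0,
    intron_length: tuple[int, int] = (60, 300),
    genes_per_contig: int = 25,
    seed: int = 0,
) -> tuple[list[SequenceRecord], list[GeneTruth]]:
    """Back-translate the proteome into contigs with optional introns.

    Each protein becomes a CDS (uniform synonymous codons) terminated by a
    stop codon; GT..AG-bounded introns are inserted at codon junctions with
    probability ``intron_rate``; genes are concatenated (forward strand) with
    random intergenic spacers.  The truth table records exon coordinates, so
    peptides spanning annotated exon-exon junctions can be checked against
    the six-frame translation.
    """
    rng = np.random.default_rng(seed)
    contigs: list[SequenceRecord] = []
    truths: list[GeneTruth] = []
    parts: list[str] = []
    pos = 0
    contig_idx = 0
    genes_in_contig = 0

    def _flush() -> None:
        nonlocal parts, pos, contig_idx, genes_in_contig
        if parts:
            contigs.append(
                SequenceRecord(id=f"contig{contig_idx:03d}", residues="".join(parts))
            )
            contig_idx += 1
        parts = []
        pos = 0
        genes_in_contig = 0

    for rec in proteome:
        spacer = _random_nt(rng, int(rng.integers(50, 200)))
        parts.append(spacer)
        pos += len(spacer)
        cds = _back_translate(rec.residues, rng) + STOP_CODONS[
            rng.integers(len(STOP_CODONS))
        ]
        exons: list[tuple[int, int]] = []
        exon_start = pos
        gene_parts: list[str] = []
        for j in range(0, len(cds), 3):
            codon = cds[j : j + 3]
            if j > 0 and intron_rate > 0 and rng.random() < intron_rate:
                exons.append((exon_start, pos))
                intron = (
                    "GT"
                    + _random_nt(rng, int(rng.integers(*intron_length)))
                    + "AG"
                )
                gene_parts.append(intron)
                pos += len(intron)
                exon_start = pos
            gene_parts.append(codon)
            pos += 3
        exons.append((exon_start, pos))
        parts.extend(gene_parts)
        truths.append(
            GeneTruth(
                gene_id=f"gene_{rec.id}",
                protein_id=rec.id,
                contig_id=f"contig{contig_idx:03d}",
                exons=tuple(exons),
            )
        )
        genes_in_contig += 1
        if genes_in_contig >= genes_per_contig:
            _flush()
    _flush()
    return contigs, truths


@dataclass(frozen=True)
class TranscriptTruth:
    transcript_id: str
    protein_id: str
    sav_positions: tuple[int, ...]  # 0-based aa positions mutated in the CDS
    truncated: bool
    kept_nt: tuple[int, int]  # half-open interval of the full CDS retained


def simulate_transcriptome(
    proteome: ProteinDatabase,
    cfg: SimConfig,
    seed: int | None = None,
) -> tuple[list[SequenceRecord], list[TranscriptTruth]]:
    """One CDS-derived transcript per protein, with SAVs and truncation.

    SAVs are introduced per residue at ``cfg.sav_rate`` as single-nucleotide
    changes that alter the encoded amino acid (never to a stop).  With
    probability ``cfg.fragmentation_rate`` a transcript is truncated: a
    fraction uniform(0.2, 0.8) of its length is removed from a random end,
    emulating fragmented or incompletely assembled transcripts.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    transcripts: list[SequenceRecord] = []
    truths: list[TranscriptTruth] = []
    for rec in proteome:
        cds = _back_translate(rec.residues, rng)
        sav_positions: list[int] = []
        if cfg.sav_rate > 0:
            codons = [cds[3 * i : 3 * i + 3] for i in range(len(rec.residues))]
            for i, codon in enumerate(codons):
                if rng.random() >= cfg.sav_rate:
                    continue
                variants = []
                for p in range(3):
                    for b in "ACGT":
                        if b == codon[p]:
                            continue
                        var = codon[:p] + b + codon[p + 1 :]
                        aa = translate_frame(var, 1)
                        if aa not in ("*", rec.residues[i]):
                            variants.append(var)
                if variants:
                    codons[i] = variants[rng.integers(len(variants))]
                    sav_positions.append(i)
            cds = "".join(codons)
        cds += STOP_CODONS[rng.integers(len(STOP_CODONS))]
        start, end = 0, len(cds)
        truncated = rng.random() < cfg.fragmentation_rate
        if truncated:
            frac = rng.uniform(0.2, 0.8)
            cut = int(round(frac * len(cds)))
            cut = min(max(cut, 1), len(cds) - 1)
            if rng.random() < 0.5:
                start = cut
            else:
                end = len(cds) - cut
        tid = f"trans_{rec.id}"
        transcripts.append(SequenceRecord(id=tid, residues=cds[start:end]))
        truths.append(
            TranscriptTruth(
                transcript_id=tid,
                protein_id=rec.id,
                sav_positions=tuple(sav_positions),
                truncated=truncated,
                kept_nt=(start, end),
            )
        )
    return transcripts, truths


@dataclass
class SimulatedReads:
    """Paired reads plus per-read error truth (read id -> error count)."""

    pairs: list[tuple[ReadRecord, ReadRecord]]
    n_errors: dict[str, int]

    def reads(self) -> list[ReadRecord]:
        return [r for pair in self.pairs for r in pair]


def _apply_errors(
    seq: str, rng: np.random.Generator, error_rate: float
) -> tuple[str, tuple[int, ...], int]:
    chars = list(seq)
    n_err = 0
    quals = []
    for i, c in enumerate(chars):
        if error_rate > 0 and rng.random() < error_rate:
            choices = [b for b in "ACGT" if b != c]
            chars[i] = choices[rng.integers(3)]
            quals.append(int(rng.integers(2, 21)))
            n_err += 1
        else:
            quals.append(int(rng.integers(30, 41)))
    return "".join(chars), tuple(quals), n_err


def simulate_reads(
    transcripts: Sequence[SequenceRecord],
    cfg: SimConfig,
    abundance: Mapping[str, float] | None = None,
    seed: int | None = None,
) -> SimulatedReads:
    """Paired-end reads with substitution errors and error-aware qualities.

    Fragments are sampled per transcript in proportion to length x abundance
    at mean depth ``cfg.coverage``; each yields an R1/R2 pair of
    ``cfg.read_length`` bases (R2 on the reverse strand).  Erroneous bases
    receive low phred scores (uniform 2-20) and correct bases high ones
    (uniform 30-40), so phred-threshold trimming discriminates the two.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    pairs: list[tuple[ReadRecord, ReadRecord]] = []
    n_errors: dict[str, int] = {}
    rl = cfg.read_length
    for t in transcripts:
        if len(t) < rl:
            warnings.warn(f"transcript {t.id!r} shorter than read length; skipped")
            continue
        weight = abundance.get(t.id, 1.0) if abundance else 1.0
        n_pairs = int(math.ceil(cfg.coverage * weight * len(t) / (2 * rl)))
        for i in range(n_pairs):
            insert = int(np.clip(rng.normal(2.5 * rl, 0.4 * rl), rl, len(t)))
            start = int(rng.integers(0, len(t) - insert + 1))
            frag = t.residues[start : start + insert]
            r1_seq, r1_q, e1 = _apply_errors(frag[:rl], rng, cfg.error_rate)
            r2_tpl = reverse_complement(frag)[:rl]
            r2_seq, r2_q, e2 = _apply_errors(r2_tpl, rng, cfg.error_rate)
            rid = f"{t.id}_r{i}"
            r1 = ReadRecord(id=f"{rid}/1", bases=r1_seq, quals=r1_q, mate=1)
            r2 = ReadRecord(id=f"{rid}/2", bases=r2_seq, quals=r2_q, mate=2)
            pairs.append((r1, r2))
            n_errors[r1.id] = e1
            n_errors[r2.id] = e2
    return SimulatedReads(pairs=pairs, n_errors=n_errors)


def simulate_observations(
    proteome: ProteinDatabase,
    abundance: Mapping[str, float],
    digest_cfg: DigestConfig | None = None,
    depth: float = 2.0,
    seed: int = 0,
    databases: Mapping[str, Mapping[str, set[str]]] | None = None,
) -> tuple[dict[str, int], dict[str, IdentificationSet]]:
    """Sample peptide observations and project them onto candidate databases.

    Peptides come from the proteome's fully tryptic digest; a peptide from a
    protein of abundance ``a`` is observed with probability ``1 - exp(-a*depth)``
    and, when observed, receives a spectral count ``1 + Poisson(a*depth)``.
    Against each candidate database (given as a peptide -> protein-ids index,
    see :func:`~proxydb.digest.digest_database`) an observation is
    identifiable only if the peptide is present fully tryptically, emulating
    per-database search results.

    Returns the full observed count table and one
    :class:`~proxydb.idcompare.IdentificationSet` per database label.
    """
    digest_cfg = digest_cfg or DigestConfig()
    rng = np.random.default_rng(seed)
    observed: dict[str, int] = {}
    for rec in proteome:
        a = abundance.get(rec.id, 1.0) * depth
        p_detect = 1.0 - math.exp(-a)
        for pep in tryptic_digest(rec, digest_cfg):
            if rng.random() < p_detect:
                count = 1 + int(rng.poisson(a))
                observed[pep.sequence] = max(observed.get(pep.sequence, 0), count)
    idsets: dict[str, IdentificationSet] = {}
    for label, index in (databases or {}).items():
        counts = {s: c for s, c in observed.items() if s in index}
        idsets[label] = IdentificationSet.from_counts(counts, index, label=label)
    return observed, idsets


def write_identifications_tsv(counts: Mapping[str, int], path) -> None:
    """Write a peptide/spectral_count table as the search-export TSV format."""
    with open(path, "w") as fh:
        fh.write("peptide\tspectral_count\n")
        for seq in sorted(counts):
            fh.write(f"{seq}\t{counts[seq]}\n")
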