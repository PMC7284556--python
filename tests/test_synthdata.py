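"""Determinism and statistical fidelity of the synthetic-data generators."""

import math

import numpy as np
import pytest

from proxydb.digest import DigestConfig, digest_database
from proxydb.seqio import write_records
from proxydb.synthdata import (
    SimConfig,
    simulate_genome,
    simulate_observations,
    simulate_proteome,
    simulate_reads,
    simulate_transcriptome,
)
from proxydb.translate import extract_orfs, reverse_complement, six_frame_translate

SMALL = SimConfig(seed=11, n_proteins=40, coverage=5.0)


class TestProteome:
    def test_deterministic_byte_identical(self):
        db1, ab1 = simulate_proteome(SMALL)
        db2, ab2 = simulate_proteome(SMALL)
        assert write_records(db1.records) == write_records(db2.records)
        assert ab1 == ab2

    def test_counts_and_abundance_tiers(self):
        db, ab = simulate_proteome(SimConfig(seed=3, n_proteins=10))
        assert db.n_sequences == 10
        assert sorted(ab.values()).count(10.0) == 6  # 3 families x 2 members
        storage = [r for r in db if r.id.startswith("storage")]
        other = [r for r in db if not r.id.startswith("storage")]
        assert np.mean([len(r) for r in storage]) > np.mean([len(r) for r in other])

    def test_tryptic_peptides_exist_for_every_protein(self):
        from proxydb.digest import tryptic_digest

        db, _ = simulate_proteome(SMALL)
        assert all(len(tryptic_digest(rec)) > 0 for rec in db)


class TestGenome:
    def test_intronless_genome_contains_all_proteins_in_6ft(self):
        db, _ = simulate_proteome(SimConfig(seed=5, n_proteins=15))
        contigs, truth = simulate_genome(db, intron_rate=0.0, seed=5)
        segments = [
            seg.aa_seq for c in contigs for seg in six_frame_translate(c, min_len=1)
        ]
        for rec in db:
            assert any(rec.residues in s for s in segments)

    def test_junction_spanning_peptides_absent_with_introns(self):
        db, _ = simulate_proteome(SimConfig(seed=6, n_proteins=10))
        contigs, truth = simulate_genome(db, intron_rate=0.2, seed=6)
        by_contig = {c.id: c for c in contigs}
        checked = 0
        for gene in truth:
            if len(gene.exons) < 2:
                continue
            protein = db[gene.protein_id].residues
            # peptide of 10 aa straddling the first exon-exon junction
            junction_aa = (gene.exons[0][1] - gene.exons[0][0]) // 3
            if junction_aa < 5 or junction_aa > len(protein) - 5:
                continue
            peptide = protein[junction_aa - 5 : junction_aa + 5]
            segments = six_frame_translate(by_contig[gene.contig_id], min_len=1)
            assert not any(peptide in s.aa_seq for s in segments)
            checked += 1
        assert checked > 0

    def test_deterministic(self):
        db, _ = simulate_proteome(SMALL)
        c1, _ = simulate_genome(db, intron_rate=0.1, seed=2)
        c2, _ = simulate_genome(db, intron_rate=0.1, seed=2)
        assert [c.residues for c in c1] == [c.residues for c in c2]


class TestTranscriptome:
    def test_lossless_case_recovers_every_protein(self):
        cfg = SimConfig(seed=7, n_proteins=15, sav_rate=0.0, fragmentation_rate=0.0)
        db, _ = simulate_proteome(cfg)
        transcripts, truth = simulate_transcriptome(db, cfg)
        for t, tr in zip(transcripts, truth):
            protein = db[tr.protein_id].residues
            orfs = extract_orfs(t, min_aa=len(protein), require_start=True)
            assert protein in {o.aa_seq for o in orfs}
            assert not tr.truncated and tr.sav_positions == ()

    def test_sav_count_within_3_sigma_of_binomial(self):
        cfg = SimConfig(seed=8, n_proteins=60, sav_rate=0.01, fragmentation_rate=0.0)
        db, _ = simulate_proteome(cfg)
        _, truth = simulate_transcriptome(db, cfg)
        n_residues = db.n_residues
        observed = sum(len(t.sav_positions) for t in truth)
        expected = n_residues * cfg.sav_rate
        sigma = math.sqrt(n_residues * cfg.sav_rate * (1 - cfg.sav_rate))
        assert abs(observed - expected) <= 3 * sigma

    def test_fragmentation_truncates_every_transcript(self):
        cfg = SimConfig(seed=9, n_proteins=20, fragmentation_rate=1.0, sav_rate=0.0)
        db, _ = simulate_proteome(cfg)
        transcripts, truth = simulate_transcriptome(db, cfg)
        assert all(t.truncated for t in truth)
        for t, tr in zip(transcripts, truth):
            full_len = 3 * (len(db[tr.protein_id].residues) + 1)
            assert len(t) < full_len

    def test_sav_alters_encoded_amino_acid(self):
        from proxydb.translate import translate_frame

        cfg = SimConfig(seed=10, n_proteins=30, sav_rate=0.02, fragmentation_rate=0.0)
        db, _ = simulate_proteome(cfg)
        transcripts, truth = simulate_transcriptome(db, cfg)
        changed = 0
        for t, tr in zip(transcripts, truth):
            protein = db[tr.protein_id].residues
            translated = translate_frame(t.residues, 1).rstrip("*")
            assert len(translated) == len(protein)
            for pos in tr.sav_positions:
                assert translated[pos] != protein[pos]
                changed += 1
        assert changed > 0


class TestReads:
    def test_error_free_reads_are_substrings(self):
        cfg = SimConfig(seed=12, n_proteins=8, error_rate=0.0, coverage=3.0,
                        fragmentation_rate=0.0, sav_rate=0.0)
        db, _ = simulate_proteome(cfg)
        transcripts, _ = simulate_transcriptome(db, cfg)
        sim = simulate_reads(transcripts, cfg)
        by_id = {t.id: t.residues for t in transcripts}
        for r1, r2 in sim.pairs:
            src = by_id[r1.id.rsplit("_", 1)[0]]
            assert r1.bases in src
            assert reverse_complement(r2.bases) in src
        assert all(v == 0 for v in sim.n_errors.values())

    def test_error_count_within_3_sigma(self):
        cfg = SimConfig(seed=13, n_proteins=10, error_rate=0.002, coverage=10.0,
                        fragmentation_rate=0.0, sav_rate=0.0)
        db, _ = simulate_proteome(cfg)
        transcripts, _ = simulate_transcriptome(db, cfg)
        sim = simulate_reads(transcripts, cfg)
        total_bases = sum(len(r) for pair in sim.pairs for r in pair)
        observed = sum(sim.n_errors.values())
        expected = total_bases * cfg.error_rate
        sigma = math.sqrt(total_bases * cfg.error_rate)
        assert abs(observed - expected) <= 3 * sigma

    def test_same_seed_identical_fastq(self):
        cfg = SimConfig(seed=14, n_proteins=8, coverage=2.0)
        db, _ = simulate_proteome(cfg)
        transcripts, _ = simulate_transcriptome(db, cfg)
        a = simulate_reads(transcripts, cfg)
        b = simulate_reads(transcripts, cfg)
        assert write_records(a.reads(), format="fastq") == write_records(
            b.reads(), format="fastq"
        )

    def test_error_bases_have_low_quality(self):
        cfg = SimConfig(seed=15, n_proteins=8, error_rate=0.05, coverage=3.0,
                        fragmentation_rate=0.0)
        db, _ = simulate_proteome(cfg)
        transcripts, _ = simulate_transcriptome(db, cfg)
        sim = simulate_reads(transcripts, cfg)
        by_id = {t.id: t.residues for t in transcripts}
        for r1, _ in sim.pairs[:50]:
            src = by_id[r1.id.rsplit("_", 1)[0]]
            if sim.n_errors[r1.id] == 0:
                continue
            # any low-quality base should disagree with every matching window
            low = [i for i, q in enumerate(r1.quals) if q <= 20]
            assert len(low) == sim.n_errors[r1.id]


class TestObservations:
    def test_proteome_database_loses_nothing(self):
        cfg = DigestConfig()
        db, ab = simulate_proteome(SMALL)
        index = digest_database(db, cfg)
        observed, idsets = simulate_observations(
            db, ab, cfg, depth=2.0, seed=1, databases={"self": index}
        )
        assert idsets["self"].counts() == observed

    def test_fragmented_orf_database_loses_peptides(self):
        cfg = DigestConfig()
        sim_cfg = SimConfig(seed=21, n_proteins=60, fragmentation_rate=0.6, sav_rate=0.0)
        db, ab = simulate_proteome(sim_cfg)
        transcripts, _ = simulate_transcriptome(db, sim_cfg)
        orf_db = _orf_database(transcripts)
        databases = {
            "proteome": digest_database(db, cfg),
            "orf": digest_database(orf_db, cfg),
        }
        _, idsets = simulate_observations(
            db, ab, cfg, depth=2.0, seed=2, databases=databases
        )
        assert len(idsets["orf"].peptides()) < len(idsets["proteome"].peptides())

    def test_high_depth_gives_repeat_counts(self):
        cfg = DigestConfig()
        db, ab = simulate_proteome(SimConfig(seed=22, n_proteins=10))
        observed, _ = simulate_observations(db, ab, cfg, depth=50.0, seed=3)
        assert observed and all(c >= 2 for c in observed.values())


def _orf_database(transcripts):
    from proxydb.dbbuild import ProteinDatabase
    from proxydb.translate import orf_records

    segs = []
    for t in transcripts:
        segs.extend(extract_orfs(t, min_aa=30, require_start=False))
    return ProteinDatabase(orf_records(segs))
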