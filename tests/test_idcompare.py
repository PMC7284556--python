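"""Identification filtering, parsimony, set comparison, SAV classification."""

import itertools
import random

import pytest

from proxydb.dbbuild import ProteinDatabase
from proxydb.digest import DigestConfig, digest_database
from proxydb.idcompare import (
    IdentificationSet,
    PeptideObservation,
    SavDetector,
    compare_peptide_sets,
    detect_sav,
    exhaustive_min_cover,
    filter_identifications,
    parsimony_proteins,
    peptide_presence,
    read_identifications_tsv,
    terminal_fragment_check,
)
from proxydb.seqio import SequenceRecord

from conftest import AA20, random_protein

UNBOUNDED = DigestConfig(max_missed=2, min_len=1, max_len=10_000)


def _idset(counts, index, label="db"):
    return IdentificationSet.from_counts(counts, index, label=label)


class TestFilter:
    def test_both_kept(self):
        idset = _idset({"a": 3, "b": 2}, {"a": {"X"}, "b": {"X"}})
        out, log = filter_identifications(idset)
        assert out.peptides() == {"a", "b"} and log == {}

    def test_cascade_to_empty(self):
        """b falls at the count filter; a then lacks a second supporting peptide."""
        idset = _idset({"a": 3, "b": 1}, {"a": {"X"}, "b": {"X"}})
        out, log = filter_identifications(idset)
        assert out.peptides() == set()
        assert "spectral_count" in log["b"] and "proteins" in log["a"]

    def test_single_peptide_protein_removed(self):
        idset = _idset(
            {"a": 2, "b": 2, "c": 5}, {"a": {"X"}, "b": {"X"}, "c": {"Y"}}
        )
        out, _ = filter_identifications(idset)
        assert out.peptides() == {"a", "b"}

    def test_refiltering_output_never_grows(self, rng):
        """Filtering is a contraction: re-running it removes or keeps, never adds."""
        proteins = [f"P{i}" for i in range(6)]
        for _ in range(20):
            index = {
                f"pep{j}": set(rng.sample(proteins, rng.randrange(1, 4)))
                for j in range(12)
            }
            counts = {p: rng.randrange(1, 5) for p in index}
            once, _ = filter_identifications(_idset(counts, index))
            twice, _ = filter_identifications(once)
            assert twice.peptides() <= once.peptides()
            iterated, _ = filter_identifications(_idset(counts, index), iterate=True)
            assert iterated.peptides() <= once.peptides()

    def test_unmatched_peptides_logged(self):
        out, log = filter_identifications(_idset({"zz": 5}, {}))
        assert out.peptides() == set() and log["zz"] == "unmatched"

    def test_counts_pooled_per_sequence(self):
        obs = [
            PeptideObservation(sequence="a", spectral_count=1),
            PeptideObservation(sequence="a", spectral_count=1),
            PeptideObservation(sequence="b", spectral_count=2),
        ]
        idset = IdentificationSet(observations=obs, index={"a": {"X"}, "b": {"X"}})
        out, _ = filter_identifications(idset)
        assert out.counts() == {"a": 2, "b": 2}


class TestParsimony:
    def test_spec_cover(self):
        index = {"p1": {"A", "C"}, "p2": {"A"}, "p3": {"B"}}
        retained, assignment, orphans = parsimony_proteins({"p1", "p2", "p3"}, index)
        assert retained == {"A", "B"} and orphans == set()
        assert assignment == {"p1": {"A"}, "p2": {"A"}, "p3": {"B"}}

    def test_lexicographic_tie_break(self):
        retained, _, _ = parsimony_proteins({"p"}, {"p": {"B", "A"}})
        assert retained == {"A"}

    def test_empty(self):
        assert parsimony_proteins(set(), {}) == (set(), {}, set())

    def test_orphans_reported(self):
        retained, assignment, orphans = parsimony_proteins({"p", "q"}, {"p": {"A"}, "q": set()})
        assert orphans == {"q"} and retained == {"A"}

    def test_matches_exhaustive_cover_size(self, rng):
        for _ in range(150):
            n_prot = rng.randrange(1, 9)
            n_pep = rng.randrange(1, 13)
            proteins = [f"P{i}" for i in range(n_prot)]
            index = {}
            for j in range(n_pep):
                owners = set(rng.sample(proteins, rng.randrange(1, n_prot + 1)))
                index[f"pep{j}"] = owners
            retained, _, _ = parsimony_proteins(set(index), index)
            optimal = exhaustive_min_cover(set(index), index)
            assert len(retained) == len(optimal)


class TestCompare:
    def test_two_way(self):
        a = _idset({"a": 2, "b": 2, "c": 2}, {}, "A")
        b = _idset({"b": 2, "c": 2, "d": 2}, {}, "B")
        res = compare_peptide_sets([a, b])
        assert res.unique == {"A": ["a"], "B": ["d"]}
        assert res.region_counts[frozenset({"A", "B"})] == 2
        assert res.union_size == 4

    def test_three_identical(self):
        sets = [_idset({"a": 2, "b": 2}, {}, lbl) for lbl in "ABC"]
        res = compare_peptide_sets(sets)
        assert res.all_shared == 2 and res.union_size == 2

    def test_truth_table_oracle(self, rng):
        peptides = [f"pep{i}" for i in range(60)]
        membership = {p: {lbl for lbl in "ABC" if rng.random() < 0.5} for p in peptides}
        sets = [
            _idset({p: 2 for p in peptides if lbl in membership[p]}, {}, lbl)
            for lbl in "ABC"
        ]
        res = compare_peptide_sets(sets)
        for combo_size in (1, 2, 3):
            for combo in itertools.combinations("ABC", combo_size):
                expected = sum(
                    1 for p in peptides if membership[p] == set(combo)
                )
                assert res.region_counts.get(frozenset(combo), 0) == expected

    def test_region_counts_sum_to_union(self, rng):
        a = _idset({f"p{i}": 2 for i in rng.sample(range(40), 20)}, {}, "A")
        b = _idset({f"p{i}": 2 for i in rng.sample(range(40), 20)}, {}, "B")
        res = compare_peptide_sets([a, b])
        assert res.union_size == len(a.peptides() | b.peptides())


class TestPresence:
    def test_tryptic_and_substring(self):
        db = ProteinDatabase([SequenceRecord(id="A", residues="MKRTEAGEMRLK")])
        for mode in ("substring", "tryptic"):
            present, hits = peptide_presence("TEAGEMR", db, UNBOUNDED, mode)
            assert present and hits == [("A", 3)]

    def test_substring_only(self):
        db = ProteinDatabase([SequenceRecord(id="A", residues="MATEAGEMRLL")])
        assert peptide_presence("TEAGEMR", db, UNBOUNDED, "substring")[0]
        assert not peptide_presence("TEAGEMR", db, UNBOUNDED, "tryptic")[0]

    def test_absent(self):
        db = ProteinDatabase([SequenceRecord(id="A", residues="MKR")])
        for mode in ("substring", "tryptic"):
            assert not peptide_presence("TEAGEMR", db, UNBOUNDED, mode)[0]

    def test_missed_cleavage_bound_enforced(self):
        db = ProteinDatabase([SequenceRecord(id="A", residues="MKAKSKCKTKR")])
        cfg = DigestConfig(max_missed=0, min_len=1, max_len=100)
        assert not peptide_presence("AKSKCK", db, cfg, "tryptic")[0]


class TestSav:
    def test_internal_sav_at_reported_position(self):
        ref = ProteinDatabase(
            [SequenceRecord(id="leg", residues="MKLYDTSNQSNQLDENARCK")]
        )
        call = detect_sav("LYDTSNQANQLDENAR", ref, UNBOUNDED)
        assert call.sav_class == "internal_sav"
        assert call.reference_peptide_or_region == "LYDTSNQSNQLDENAR"
        assert call.variant_position == 7

    def test_flanking_cleavage_sav(self):
        ref = ProteinDatabase([SequenceRecord(id="A", residues="MATEAGEMRLL")])
        call = detect_sav("TEAGEMR", ref, UNBOUNDED)
        assert call.sav_class == "flanking_cleavage_sav"

    def test_exact_takes_precedence(self):
        ref = ProteinDatabase([SequenceRecord(id="A", residues="MKRTEAGEMRLK")])
        assert detect_sav("TEAGEMR", ref, UNBOUNDED).sav_class == "exact"

    def test_absent(self):
        ref = ProteinDatabase([SequenceRecord(id="A", residues="MKR")])
        assert detect_sav("WWWWWWR", ref, UNBOUNDED).sav_class == "absent"

    def test_recovery_on_random_mutations(self, rng):
        proteins = [
            SequenceRecord(id=f"p{i}", residues=random_protein(rng, 120))
            for i in range(20)
        ]
        ref = ProteinDatabase(proteins)
        detector = SavDetector(ref, UNBOUNDED)
        candidates = [p for p in detector.index if len(p) >= 8]
        hits = 0
        trials = 100
        for _ in range(trials):
            pep = rng.choice(candidates)
            pos = rng.randrange(1, len(pep) - 1)
            sub = rng.choice([c for c in AA20 if c not in (pep[pos], "K", "R", "P")])
            mutated = pep[:pos] + sub + pep[pos + 1 :]
            call = detector.detect(mutated)
            if call.sav_class == "internal_sav" and call.variant_position == pos:
                hits += 1
        assert hits >= trials * 0.97


class TestTerminal:
    def test_n_terminus(self):
        assert terminal_fragment_check("MKRTEAGE", "MKRTEAGEMRLK") == (True, ["N"])

    def test_internal_only(self):
        assert terminal_fragment_check("TEAGE", "MKRTEAGEMRLK") == (False, [])

    def test_internal_and_c_terminal_occurrence(self):
        ok, ends = terminal_fragment_check("CAS", "TTCASTTCAS")
        assert ok and ends == ["C"]

    def test_absent_raises(self):
        with pytest.raises(ValueError):
            terminal_fragment_check("WW", "MKR")


class TestTsv:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "ids.tsv"
        path.write_text("peptide\tspectral_count\nTEAGEMR\t4\nLK\t2\n")
        idset = read_identifications_tsv(path, {"TEAGEMR": {"A"}}, label="x")
        assert idset.counts() == {"TEAGEMR": 4, "LK": 2}

    def test_missing_column(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("pep\tcount\na\t1\n")
        with pytest.raises(ValueError, match="missing column"):
            read_identifications_tsv(path, {})
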