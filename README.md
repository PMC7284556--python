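# proxydb

Proxy protein sequence databases for organisms without a curated proteome.

## The problem

Peptide identification from shotgun mass spectrometry requires a protein
sequence database to search against. For most crop and tree species no
curated, sequenced proteome exists, so searches fall back on a related
species' proteome and silently miss peptides that differ by even one residue
— including the single-amino-acid variants (SAVs) that distinguish cultivars
and allergen isoforms. When genomic or transcriptomic reads for the subject
organism *are* available, a practical alternative is to build a **proxy
database**: translate the nucleotide sequence itself into every plausible
protein and search against that.

`proxydb` implements that construction end to end, plus the machinery needed
to evaluate it fairly:

- **Six-frame translation** of genome assemblies, with overlap-aware
  chunking so that no short peptide is lost at chunk boundaries, and
  **ORF extraction** from assembled transcripts.
- **Read preparation** for the transcriptome route: sliding-window Phred
  quality trimming and kmer-coverage normalization, including the
  aberrant-read filter (`max_pct_stdev`) that removes reads whose kmer
  coverage profile mixes very high and very low coverage — a signature of
  sequencing errors and chimeras.
- **Database construction**: exact deduplication, contaminant appending,
  provenance tagging, and exact residue-count equalization across candidate
  databases so identification counts are comparable.
- **In-silico tryptic digestion** with missed cleavages, tryptic-status
  classification, and monoisotopic peptide masses.
- **Identification comparison**: spectral-count and protein-level
  stringency filters, parsimony protein inference (exact minimum set cover
  on small instances, greedy at scale), Venn-style region counts across 2–3
  databases, and classification of database-unique peptides as exact /
  internal SAV / flanking-cleavage SAV / absent.
- **Assembly quality metrics**: N50 and reference-protein contiguity
  coverage (fraction of a protein covered by a single transcript at 100%
  identity).
- **Synthetic data generators** with known ground truth (proteome, genome,
  transcriptome with SAVs and 3'/5' truncation, paired-end reads with
  errors, peptide observations), used by the test suite and the acceptance
  experiment.

## Worked example

Everything below is runnable offline; `proxydb simulate` emits a complete
synthetic input set with known ground truth.

```console
$ proxydb simulate --seed 7 --n-proteins 20 -o demo
wrote synthetic inputs to demo

$ proxydb sixframe demo/genome.fa -o demo/genome_6ft.faa
wrote 2780 segments to demo/genome_6ft.faa

$ proxydb orfs demo/transcripts.fa --min-aa 50 --no-require-start -o demo/orfs.faa
wrote 114 ORFs to demo/orfs.faa

$ proxydb dedup demo/orfs.faa -o demo/orfs_nr.faa
kept 114/114 sequences (0 removed)

$ proxydb digest demo/orfs_nr.faa -o demo/peptides.tsv
wrote 2992 peptides to demo/peptides.tsv

$ proxydb metrics demo/transcripts.fa --reference demo/proteome.faa -o demo/metrics.json
{"n_transcripts": 20, "total_bases": 16404, "n50": 1428, "contiguity_covered": 12, "contiguity_total": 20}

$ proxydb compare demo/ids_proteome.tsv demo/ids_proteome.tsv \
    --dbs demo/proteome.faa --dbs demo/orfs_nr.faa -o demo/cmp
wrote comparison report to demo/cmp

$ head -3 demo/cmp/venn_regions.json
{
  "orfs_nr&proteome": 933,
  "proteome": 84
```

The comparison directory also contains one `unique_<label>.tsv` per
database, classifying each database-unique peptide against the other
databases. The same functionality is available as a library; for example,
SAV detection:

```python
>>> from proxydb.dbbuild import ProteinDatabase
>>> from proxydb.digest import DigestConfig
>>> from proxydb.idcompare import detect_sav
>>> from proxydb.seqio import SequenceRecord
>>> ref = ProteinDatabase([SequenceRecord(id="legumin_like", residues="MKLYDTSNQSNQLDENARCK")])
>>> call = detect_sav("LYDTSNQANQLDENAR", ref, DigestConfig(min_len=1, max_len=100))
>>> (call.sav_class, call.reference_peptide_or_region, call.variant_position)
('internal_sav', 'LYDTSNQSNQLDENAR', 7)
```

The observed peptide matches reference tryptic peptide
`LYDTSNQSNQLDENAR` everywhere except position 7 (S→A): an internal SAV.

## Testing

```
python -m pytest -q tests/
```

The suite pairs every non-trivial algorithm with an independent oracle
(Biopython translation, a `pyteomics` cleavage enumerator, exhaustive set
cover, quadratic longest-common-substring DP) and includes derandomized
property-based tests. `tests/test_acceptance.py` holds the acceptance
criteria, one test per criterion.

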