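# Methods

This note records the algorithmic conventions, default parameters, and
modelling assumptions behind `proxydb`, in the order the pipeline uses them.

## Sequence I/O

FASTA/FASTQ parsing is strict: records are validated against a declared
alphabet (IUPAC nucleotide codes with `U` normalized to `T`, or the 20
amino acids plus `X` and `*`), errors carry line numbers or read ids, and
four-line FASTQ framing is enforced. Paired-end mate numbers are taken from
`/1`/`/2` id suffixes. Gzip input/output is transparent. Writing uses
60-column wrapping for FASTA.

## Six-frame translation and ORFs

Frames are numbered `+1..+3` (forward, offsets 0–2) and `-1..-3`
(reverse-complement, offsets 0–2). Trailing partial codons are dropped.
Codons containing any character outside `ACGT` translate to `X`; `X` is
*not* a stop, so ambiguity never splits a segment. Translations are split
into segments at stop codons only; segments shorter than `min_len`
(default 7, one tryptic peptide's worth) are discarded. Each segment
carries forward-strand nucleotide coordinates (stop codon included when
present) so peptides can be mapped back to the genome.

Genome assemblies are chunked before translation (default chunk 100,000 nt,
overlap 120 nt). A peptide of ≤ 40 residues spans ≤ 120 nt, and a window no
longer than the overlap always lies entirely inside some chunk, so chunking
never loses a search-relevant peptide.

ORF extraction from transcripts scans all six frames and reports segments
of at least `min_aa` residues (default 100 for genome-scale screening;
the acceptance experiment uses 50 with `require_start=False` because
truncated transcripts legitimately lack an initiator methionine).
With `require_start=True`, ORFs are anchored at the first `M` of a segment.

## Read preparation

**Quality trimming** (defaults: Phred threshold 35, window 4, minimum
length 36): leading and trailing bases below threshold are stripped, then
the read is cut at the first 5'-anchored sliding window whose mean quality
falls below threshold; reads shorter than the minimum are dropped.

**Kmer-coverage normalization** (defaults: k = 25, target coverage 50,
`max_pct_stdev` 10,000): kmers are canonicalized against their reverse
complement; kmers containing non-ACGT characters are skipped. For each
read the per-kmer coverages give a median, mean, and percent standard
deviation (100 × sample stdev / mean; defined as 0 for fewer than two
kmers; the median of an even count takes the lower middle value). A read is
*eliminated* if its percent stdev exceeds `max_pct_stdev` — the aberrant
profile of a read mixing abundant and near-unique kmers, typical of errors
and chimeric joins — and otherwise *kept* with probability
`min(1, target/median)`. Pairs are decided jointly (mean of medians,
maximum of percent stdevs). Exactly one RNG draw is consumed per input unit
whatever the decision, so the kept set under a stricter threshold is a
subset of the kept set under a looser one at the same seed. The default
threshold of 10,000 effectively disables the filter; 100 is the strict
setting whose enrichment effect the acceptance experiment measures.

## Database construction

Databases reject duplicate ids and empty sequences and strip terminal
stops. Exact deduplication keeps the first occurrence (optionally absorbing
proper substrings). Records carry a `src=` provenance tag
(subject/contaminant/filler). To make identification counts comparable
across candidate databases, `pad_to_target` equalizes total residue counts
exactly: filler records are appended greedily and the final record is
truncated (id suffixed `_trunc`) to land on the target; shrinking an
existing database is an error (sizing only grows).

## Digestion

Trypsin cleaves C-terminal to K/R, suppressed before proline by default.
Peptides are enumerated with up to `max_missed` missed cleavages (default
2) and length bounds 6–60 (typical MS detectability range); peptides
containing `X` or `*` are excluded. Tryptic status (full/semi/non) treats
protein termini as enzymatic boundaries, so fragments arising from
transcript truncation still classify as fully tryptic at the truncated
end. Monoisotopic masses use standard residue masses with fixed
carbamidomethylation of cysteine (+57.02146) and optional methionine
oxidation (+15.99491); water is 18.010565 Da.

## Identification filtering and comparison

Observed peptides (sequence + spectral count) are filtered in two steps,
applied once in order: (1) peptides with spectral count < 2 are removed;
(2) the parsimonious protein set is computed over the survivors and
peptides all of whose retained proteins have < 2 distinct supporting
peptides are removed. Peptides absent from the database index are logged
as `unmatched`.

Parsimony is minimum set cover. Instances with at most 20 candidate
proteins are solved exactly (bounded subset search; ties go to the
lexicographically smallest protein set); larger instances use the greedy
cover (most uncovered peptides, then most total peptides, then smallest
id). Greedy set cover can exceed the optimum in principle, which is why
small instances — where the exact answer is cheap — bypass it.

Set comparison over 2–3 databases reports exclusive region counts
(Venn-style), per-database unique peptides, and the union. Database-unique
peptides are classified with precedence **exact** (a tryptic peptide of the
other database) > **internal_sav** (Hamming distance 1 from a same-length
tryptic peptide; found by a masked-position hash index in O(length) per
query) > **flanking_cleavage_sav** (substring of the database but not a
tryptic peptide, i.e. a cleavage-site-altering variant) > **absent**.

## Assembly metrics

N50 is the largest length at which the cumulative length of all contigs at
least that long reaches half the assembly total. Contiguity coverage asks,
for each reference protein, for the longest common substring between the
protein and any single transcript's six-frame translation (100% identity
only; computed with `difflib`, verified against a quadratic DP in tests); a
protein is covered when that fraction reaches 0.9. Relaxed-identity
matching is deliberately unsupported: allowing mismatches would require an
alignment model this metric does not define.

## Synthetic data model

The generator produces ground-truthed inputs for testing and the
acceptance experiment. A proteome draws protein lengths log-normally
(log-mean 5.5, log-sigma 0.45 ≈ median 245 aa), forces a leading `M`, and
uses plant-like residue frequencies (6% K, 5% R, giving tryptic peptides
of realistic length). Three "storage-protein" families of two paralogs each
(2% divergence) are longer (2×) and 10× more abundant, mimicking the seed
storage proteins that dominate nut MS data and exercising shared-peptide
parsimony. Back-translation uses uniformly random synonymous codons; a
genome route optionally inserts introns, and a transcriptome route
introduces SAVs as single-nucleotide, amino-acid-changing substitutions
(rate 0.002/residue) and truncates a `fragmentation_rate` fraction of
transcripts by a uniform 20–80% from a random end. Paired 85-bp reads are
sampled in proportion to length × abundance with substitution errors at
`error_rate` (default 0.001); erroneous bases get Phred 2–20, correct
bases 30–40. Peptide observations sample each tryptic peptide with
detection probability 1 − exp(−a·depth) where `a` is the protein's
abundance weight, spectral counts 1 + Poisson(a·depth), and are projected
onto candidate databases by tryptic-index membership.

The model deliberately omits: intron splicing in the read simulator (reads
come from transcripts), indels and quality-dependent error profiles,
chimeric assembly artifacts, peptide ionization/detectability bias, and
decoy-based FDR control — identification here is membership, not search
engine scoring. Conclusions drawn from it are qualitative orderings
(e.g. completeness of databases), not absolute identification counts.

## Numerical and reproducibility choices

All stochastic components take explicit seeds and use
`numpy.random.default_rng`; equal seeds give byte-identical outputs.
Sub-seeds in the acceptance script derive deterministically from the
top-level `--seed` and stay below 2³¹. Masses are plain floats (double
precision) — adequate since nothing downstream matches within ppm
tolerances.
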