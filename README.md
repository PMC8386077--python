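# nullkit

Absent-word analysis toolkit for genomes and proteomes: identification of
nullomers (absent DNA k-mers, k ≤ 15) and nullpeptides (absent amino-acid
words, k ≤ 7), negative-selection scoring, genome-wide maps of single-base
mutations that would materialize absent words, population-variant
resurfacing analysis, and absence-based phylogenetic classification.

## What it does

- **`sequence_io`** — FASTA / GTF / GFF3 / BED / VCF ingestion with explicit
  coordinate conventions (1-based inclusive internally; BED converted at the
  boundary), and derivation of functional compartments: genic, CCDS, exonic,
  intronic, 5′/3′ UTR, and strand-aware promoters (−2500/+500 around the TSS).
- **`kmer_core`** — exhaustive k-mer presence scanning over the full
  `|alphabet|^k` space with a packed bitmap (both-strand or forward-only),
  absent-word extraction, overlapping occurrence counting, Hamming
  neighborhoods, and higher-order classification of absent words.
- **`selection_scores`** — substitution-neighbor occurrence mean (φ1), the
  peptide permutation variant, Monte Carlo shuffle scores with exact
  1/2/3-let-preserving permutations (Euler-path shuffle on the de Bruijn
  multigraph) (φ2), the cross-species absence ratio (φ3), the aggregate
  sum-of-ranks (φN) with min-rank ties, and common-variant exclusion.
- **`mutation_maps`** — every single-base substitution, insertion, and
  deletion that materializes an absent word; expected edit-class
  combinatorics (k, 3k, 4(k−1)); class enrichments; trinucleotide context
  spectra; regional and per-transcript densities; CDS substitution scans
  that materialize absent peptides.
- **`variant_resurfacing`** — intersection of observed variants with the
  absent-word space, aggregate resurfacing probabilities
  (1 − Π(1 − AF)), and population-specific calls (common in exactly one
  population, rare in all others).
- **`phylo_absent`** — Jaccard matrices over species absence profiles, Ward
  dendrograms on 1 − J with Newick export, and clade partitions
  (primes / species-specific / group-specific / sharing histogram).
- **`fixtures`** — seeded synthetic genomes (with N runs and
  guaranteed-absent planted motifs), gene annotations, VCFs, proteomes and
  CDS sets, plus brute-force oracles used by the test suite.
- **`cli`** — subcommands binding the stages into reproducible runs.

## CLI

```bash
# synthetic genome + annotation + VCF triple
nullkit fixtures --seed 1 --genome-length 100000 --out-dir fix/

# absent words per k (TSV: word, k, compartment, order)
nullkit nullomers --fasta fix/genome.fa --k 8:11 --strand both --out-dir out/
nullkit nullpeptides --fasta proteome.fa --k 4 --out-dir out/

# order classification, selection scores, shuffle enrichment
nullkit order --fasta fix/genome.fa --k 8 --max-order 1 --out-dir out/
nullkit score --fasta fix/genome.fa --species-fasta other.fa --k 7 \
    --klet 3 --replicates 100 --seed 0 --out-dir out/
nullkit simulate --fasta fix/genome.fa --k 8 --klet 3 --replicates 100 \
    --seed 0 --out-dir out/

# mutation materialization map and variant intersection
nullkit mutmap --fasta fix/genome.fa --k 8 --out-dir out/
nullkit variants --fasta fix/genome.fa --vcf fix/variants.vcf --k 8 \
    --out-dir out/

# primes and absence-based phylogenetics
nullkit primes --fasta p1.fa --fasta p2.fa --k 4 --out-dir out/
nullkit phylo --fasta sp1.fa --fasta sp2.fa --fasta sp3.fa --k 8 \
    --out-dir out/
```

Every run writes a `manifest.json` with inputs (content digests),
parameters, seeds, and the package version. All randomness flows from a
single `--seed`.

## Notes on conventions

- Both-strand presence is the default for DNA: a word "exists" if it or its
  reverse complement occurs on the forward strand. Forward-only mode is a
  switch on every scan.
- Windows containing N (DNA) or a nonstandard residue (protein) never count.
- Insertions are keyed to the gap before a 1-based position (VCF-style left
  anchoring); the gap after the last base is position len+1.
- CCDS/exonic/UTR compartments are spliced (k-mers may span exon
  junctions); genic/intronic/promoter are genomic.
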