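# upcot

Phylogenetic footprinting — finding cis-regulatory DNA elements as motifs
conserved across species — needs a laborious preparatory step: for every
gene of a genome of interest, collect its orthologs in a set of reference
genomes, work out which genes are co-transcribed in operons, and extract
and group the upstream promoter regions.  `upcot` automates that first
step for prokaryotic genomes.  Its output — one FASTA file of clustered
upstream sequences per target gene — is ready-made input for motif
discovery tools such as MEME, the Gibbs Motif Sampler, MDScan or
BioProspector (which are deliberately *not* part of this package).

It is aimed at microbiologists and regulatory-genomics bioinformaticians
working from the legacy NCBI per-genome bundles: a protein FASTA
(`*.faa`), a genome nucleotide FASTA (`*.fna`) and a tab-separated gene
coordinate table (`*.ptt`).

## What the pipeline computes

1. **Orthologs by bidirectional best hit (BDBH).**  Every target protein
   is compared against every reference proteome with an exact
   Smith–Waterman local aligner (BLOSUM62, affine gaps 11/1).  Scores are
   converted to Karlin–Altschul statistics, bit = (λS − ln K)/ln 2 with
   λ = 0.267, K = 0.041, and E = m·n·2^(−bit); hits with E above the
   cutoff (default 10⁻³) are discarded.  Proteins *t* (target) and *r*
   (reference) are called orthologs iff each is the other's top-scoring
   hit.  Precomputed 12-column tabular hit files from an external search
   tool can be ingested instead (`--hit-tables`).
2. **Ortholog groups (tgCoGs).**  Each target gene's BDBH partners, at
   most one per reference genome, form its group; groups with fewer than
   `min_orthologs` (default 4) reference orthologs are dropped.  One
   protein FASTA per retained group is written to
   `tgCoG_protein_sequences/`.
3. **Transcriptional units from intergenic distance.**  Maximal runs of
   consecutive same-strand genes whose internal gaps are below a
   threshold (default 50 bp) are taken as operons; an opposite-strand
   gene always breaks a run.
4. **Upstream extraction and clustering.**  For each group member with at
   least `min_UP` (default 50) bp of upstream intergenic room, the
   `max_UP` (default 350) bases 5′ of the start codon are extracted
   (reverse-complemented for minus-strand genes) and the set is written
   as one FASTA file, named by the target locus tag, into
   `tu_upstreams/`, together with a manifest of cluster sizes and
   exclusion reasons.

## Worked example

No real genomes are needed to try the tool: the built-in generator
writes a fully annotated synthetic genome set with planted ortholog
families, operon structures and a planted HrcA-type regulatory element
(the 9-bp inverted repeat `TTAGCACTC-N9-GAGTGCTAA`):

```sh
upcot synth --out demo --seed 17
upcot -v run --target demo/target \
      --ref demo/ref1 --ref demo/ref2 --ref demo/ref3 --ref demo/ref4 \
      --out demo_out
```

which prints

```
14 target genes -> 3 ortholog groups -> 2 upstream cluster files
```

Of the six planted families, exactly the three present in all four
references survive the `min_orthologs = 4` filter (14 target genes
include random decoys, which form no groups).  One retained family sits
operon-internal, so all its upstreams are excluded as shorter than 50 bp
and only two cluster files are written — the manifest
`demo_out/tu_upstreams/manifest.tsv` records why.  The cluster file of
the motif-carrying family (`demo_out/tu_upstreams/target_0013` for this
seed) contains five upstream sequences, every one matching the planted
IUPAC pattern.  `demo_out/run_report.json` holds the machine-readable
run summary.

Settings can also come from a legacy-style `settings.txt`
(`E value=1e-3`, `orthologs count=4`, `Min_UP_length=50`,
`Max_UP_length=350`, one `key=value` per line).

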