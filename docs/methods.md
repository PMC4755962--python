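# Methods

## Problem and scope

Given one target prokaryotic genome and N reference genomes, each as a
legacy NCBI bundle (`*.faa` proteins, `*.fna` nucleotide sequence,
`*.ptt` coordinate table), the pipeline emits, per qualifying target
gene, one FASTA file containing the upstream regions of that gene and of
its orthologs — the input format expected by motif-discovery tools.
Motif discovery itself, genome downloading, and any web interface are
out of scope; a small IUPAC scanner is included only to verify planted
motifs in tests.

## Coordinates and file dialects

All genomic coordinates are 1-based inclusive (the PTT convention);
conversions to Python slices happen only at the point of slicing.  The
PTT dialect parsed is: one description line, one "N proteins" line, one
column-header line, then 9 tab-separated columns with Location formatted
`start..end`.  The Length column is recomputed, not trusted.  Rows with
start > end (origin wrap-around) are rejected with a warning rather than
modelled: they are rare in PTT files and genomes are treated as linear
throughout.  Proteins are joined to PTT rows by the `gi|<PID>|` token of
the FASTA header first, then by a locus tag appearing as a header token;
the PID route matches how legacy `.faa` headers carry the PTT PID
column.  Zero successful joins aborts the run, since it indicates
mismatched bundle files.

## Homology search and E-values

The built-in aligner is exact Smith–Waterman (Biopython's C
`PairwiseAligner`, local mode) under BLOSUM62 with affine gap costs
11 (open) + 1 per residue — the standard gapped-BLAST parameterization.
`X` scores 0 against every residue.  Raw scores map to bits via
bit = (λS − ln K)/ln 2 and to expectations via E = m·n·2^(−bit), with
the standard gapped-BLOSUM62 constants λ = 0.267, K = 0.041 and m, n the
two sequence lengths.  No effective-length (edge) correction is applied:
only the ranking and a coarse cutoff matter for reciprocal-best-hit
calling, and the uncorrected form is simpler to reason about.  Under
these statistics, unrelated random 120-mers score ~25–40 raw
(E ≈ 10⁻²–1 per pair), so the default cutoff of 10⁻³ sits in the far
tail of the null: spurious hits slip through only occasionally (an
expected handful per ~10⁵ random comparisons), which is why the desk
fixtures stay clean at group level.

Exhaustive all-vs-all alignment is quadratic in proteome size and is
intended for desk-scale inputs (the fixtures here run in seconds).  For
real genomes the pipeline ingests precomputed 12-column tabular hit
files instead, consuming only query, subject, E-value and bit score; the
two routes share one sort contract — bit score descending, then E-value
ascending, then subject id lexicographic — so best-hit extraction is
deterministic and route-independent.  Best hits are ranked by bit score,
not E-value; with the built-in aligner the two orders coincide, and for
imported tables the tie chain decides.

## Orthology

A target/reference gene pair is orthologous when each is the other's
best hit in the filtered tables (bidirectional best hit).  The result is
one-to-one per genome pair by construction; no paralog resolution beyond
that is attempted.  A group's ortholog count excludes the target gene
itself, so `min_orthologs = 4` retains groups of at least five proteins
including the target — consistent with counting per-reference presence
separately from the target.  Output FASTA files are named with the locus
tag exactly as spelled in the PTT Synonym column.

## Transcription units and upstream gaps

A transcription unit is a maximal run of consecutive same-strand genes
whose internal gaps (next start − previous end − 1; overlaps count as 0)
are all below the TU gap threshold; an opposite-strand gene always
breaks a run, since a divergently transcribed neighbour implies its own
promoter.  Members are stored 5′→3′ in transcription direction, so the
leader of a minus-strand unit is its genomically last gene.

The TU gap threshold defaults to `min_UP_length` (50 bp): a gene with
less than that much upstream room is treated as operon-internal, the
same reasoning that excludes its upstream from extraction.  The two
quantities are separate settings for users who want them decoupled.

Deliberate asymmetry: TU joining measures the gap to the previous
same-strand run member, whereas the upstream room used for extraction
(`upstream_gap`) measures to the nearest annotated gene boundary on
*either* strand — a convergent opposite-strand gene eats into a
promoter region even though it does not join the operon.

## Upstream extraction

A gene qualifies when `upstream_gap ≥ min_UP` (default 50 bp; regions
shorter than 40–50 bp are too short for cis-element prediction).  In the
default `fixed-window` mode the `max_UP` (default 350) bases immediately
5′ of the start codon are taken even if they overlap the upstream gene's
coding sequence; `intergenic-only` mode stops at the upstream gene
boundary, taking `min(upstream_gap, max_UP)` bases.  Windows truncate at
contig edges (a truncated window below `min_UP` would be excluded as
`contig_edge`; with linear genomes and the gap definition above this
branch is defensive — the gap bound already implies enough room).
Minus-strand output is the reverse complement of the forward-strand
span, so every emitted sequence reads 5′→3′ toward the start codon.
Every emitted length L therefore satisfies `min_UP ≤ L ≤ max_UP`.

With `representative_mode = gene-self` (default) each group member
contributes its own upstream and operon-internal members simply drop
out; `tu-leader` mode instead substitutes the upstream of the member's
TU leader, the reading under which whole transcriptional units share a
promoter.  Clusters with fewer than `min_members` (default 2) members
are not written — a single sequence is useless for motif discovery —
and every drop is recorded in the manifest so counts reconcile.

## Synthetic genome sets

The generator emulates exactly the structure the pipeline exploits:

* ortholog families as per-genome mutants of a random seed protein
  (default length 120 aa, each site substituted independently with the
  family's divergence probability) — at divergence ≤ 0.2 any two family
  copies share ≥ ~64% identity and align at raw scores in the hundreds,
  orders of magnitude above the random-score null;
* random decoy proteins, independent per genome, as negative controls
  for BDBH calling;
* an operon layout with intra-operon gaps drawn from 5–30 bp and
  between-unit gaps from 100–400 bp, so any TU threshold in between
  (the default 50 bp included) recovers the planted partition exactly;
  TU strands are drawn at random so both extraction branches are always
  exercised;
* CDS nucleotides back-generated from proteins by a fixed codon choice
  (the pipeline never translates; this only keeps coordinates honest and
  lengths divisible by 3);
* optionally, a concrete instance of an IUPAC consensus planted once in
  the upstream intergenic region of every copy of a designated family,
  within 350 bp of the start codon; the background is redrawn in the
  rare event that a second chance match appears in the same region.

The canonical fixture (`default_genome_set_spec`) uses 4 references and
6 families present in {1, 2, 3, 4, 4, 4} of them, bracketing the
default ortholog-count threshold; two families sit operon-internal to
exercise the exclusion path, and one leader family carries the
HrcA-type inverted repeat `TTAGCACTC-N9-GAGTGCTAA` in all copies.
Everything derives from one integer seed and reruns are byte-identical.

What the fixtures do *not* emulate: indels and rearrangements, codon
usage, paralogous gene families, composition bias, multi-replicon
genomes, or annotation errors.  Passing tests therefore demonstrate the
pipeline logic — reciprocity, thresholding, coordinate arithmetic,
strand handling, determinism — not robustness to real-genome annotation
noise, and BDBH on real paralog-rich proteomes remains subject to the
usual caveats of the method.  Because the decoy null is a genuine
random-score tail, a handful of spurious reciprocal pairs at E just under 10⁻³ can
appear for some seeds — always at pair level, never surviving the
group-count threshold; the acceptance script reports the observed count
rather than suppressing it.

## Determinism and numerics

All cross-genome iteration is over sorted genome ids and locus tags;
hit tables carry a total sort order; the pipeline proper uses no clock
or randomness (wall times appear in the run report but are excluded
from report comparison).  Scores are integers in float containers, so
no floating-point tolerance is needed anywhere in the score path;
E-value comparisons against the cutoff use `<=`.

## Problem sizes

The shipped study conditions are desk-scale by design: 5 genomes of
~10–14 genes each, proteins of 120 residues, giving full pipeline runs
in a few seconds.  The acceptance script runs the pipeline twice plus a
pair-level BDBH audit, all within a minute on one CPU.
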