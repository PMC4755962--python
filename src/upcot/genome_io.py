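"""Readers and writers for the three-file prokaryotic genome bundle.

A genome bundle in the legacy NCBI layout consists of a nucleotide FASTA
(``*.fna``, one replicon record), a protein FASTA (``*.faa``) and a
tab-separated protein coordinate table (``*.ptt``).  This module parses the
three files, cross-links proteins to their gene coordinates, and provides
the FASTA writer used for every sequence file the pipeline emits.

All genomic coordinates are 1-based inclusive, the PTT convention.  Any
slicing into the residue string converts explicitly at the point of use.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

PTT_HEADER_LINES = 3
PTT_COLUMNS = 9


class GenomeBundleError(ValueError):
    """A genome bundle is structurally unusable (mismatched or empty files)."""


class PttParseError(ValueError):
    """A PTT row could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


def reverse_complement(sequence: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC codes preserved)."""
    return str(Seq(sequence).reverse_complement())


@dataclass(frozen=True)
class GenomeSequence:
    """One replicon's nucleotide sequence.

    ``genome_id`` is the first whitespace-delimited token of the FASTA
    header and doubles as the genome's identifier throughout the pipeline.
    """

    genome_id: str
    residues: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("genome sequence must be non-empty")
        if not self.residues.isupper():
            object.__setattr__(self, "residues", self.residues.upper())

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GeneRecord:
    """One PTT row: a protein-coding gene with 1-based inclusive coordinates."""

    locus_tag: str
    pid: str
    start: int
    end: int
    strand: str
    product: str = ""
    gene: str = "-"
    code: str = "-"
    cog: str = "-"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"require 1 <= start <= end, got {self.start}..{self.end}"
            )

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ProteinRecord:
    """One .faa record: amino-acid sequence plus its full FASTA header."""

    protein_id: str
    sequence: str
    header: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.protein_id}: empty sequence")
        if not self.sequence.isupper():
            object.__setattr__(self, "sequence", self.sequence.upper())


@dataclass
class AnnotatedGenome:
    """A genome with its gene list and the proteins linked to the genes.

    ``genes`` are sorted ascending by start (ties by end); ``proteins``
    maps locus_tag -> ProteinRecord for every successfully linked gene.
    """

    genome: GenomeSequence
    genes: list[GeneRecord]
    proteins: dict[str, ProteinRecord]

    @property
    def genome_id(self) -> str:
        return self.genome.genome_id

    def gene_by_locus(self, locus_tag: str) -> GeneRecord:
        for g in self.genes:
            if g.locus_tag == locus_tag:
                return g
        raise KeyError(f"locus {locus_tag!r} not in genome {self.genome_id}")

    def proteome(self) -> dict[str, str]:
        """locus_tag -> amino-acid sequence, for the homology search."""
        return {tag: rec.sequence for tag, rec in self.proteins.items()}


def read_genome_fasta(path: str | Path) -> GenomeSequence:
    """Read a single-record nucleotide FASTA (.fna).

    Multi-record files are refused as a concatenation target: the first
    record is used and a warning is emitted.
    """
    with open(path) as fh:
        records = list(SeqIO.parse(fh, "fasta"))
    if not records:
        raise GenomeBundleError(f"{path}: no FASTA records found")
    if len(records) > 1:
        warnings.warn(
            f"{path}: {len(records)} records found; using the first only "
            "(multi-replicon bundles are not supported)",
            stacklevel=2,
        )
    rec = records[0]
    return GenomeSequence(genome_id=rec.id, residues=str(rec.seq).upper())


_LOCATION_RE = re.compile(r"^(\d+)\.\.(\d+)$")


def read_ptt(path: str | Path) -> list[GeneRecord]:
    """Parse a legacy NCBI PTT table into GeneRecords sorted by start.

    The dialect: line 1 is the genome description, line 2 "N proteins",
    line 3 the column header, then tab-separated rows whose Location column
    reads "start..end".  The Length column is ignored and recomputed.
    Rows with start > end (origin wrap-around) are rejected with a warning.
    """
    records: list[GeneRecord] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if line_no <= PTT_HEADER_LINES:
                continue
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != PTT_COLUMNS:
                raise PttParseError(
                    f"expected {PTT_COLUMNS} tab-separated columns, "
                    f"got {len(fields)}",
                    line_no,
                )
            location, strand, _length, pid, gene, synonym, code, cog, product = fields
            m = _LOCATION_RE.match(location.strip())
            if m is None:
                raise PttParseError(
                    f"malformed Location field {location!r}", line_no
                )
            start, end = int(m.group(1)), int(m.group(2))
            if start > end:
                warnings.warn(
                    f"{path} line {line_no}: start > end ({location}); "
                    "wrap-around genes are not modelled, row rejected",
                    stacklevel=2,
                )
                continue
            records.append(
                GeneRecord(
                    locus_tag=synonym,
                    pid=pid,
                    start=start,
                    end=end,
                    strand=strand,
                    product=product,
                    gene=gene,
                    code=code,
                    cog=cog,
                )
            )
    records.sort(key=lambda g: (g.start, g.end))
    return records


def write_ptt(
    records: Sequence[GeneRecord], path: str | Path, description: str = "synthetic"
) -> None:
    """Write GeneRecords back out in the legacy PTT dialect.

    The Length column is the amino-acid length implied by the coordinates,
    (end - start + 1) / 3 - 1, as in NCBI's original tables.
    """
    with open(path, "w") as fh:
        fh.write(f"{description}\n")
        fh.write(f"{len(records)} proteins\n")
        fh.write(
            "Location\tStrand\tLength\tPID\tGene\tSynonym\tCode\tCOG\tProduct\n"
        )
        for g in records:
            aa_len = g.length_bp // 3 - 1
            fh.write(
                f"{g.start}..{g.end}\t{g.strand}\t{aa_len}\t{g.pid}\t"
                f"{g.gene}\t{g.locus_tag}\t{g.code}\t{g.cog}\t{g.product}\n"
            )


def read_protein_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a .faa file; the record id is kept as protein_id, the full
    header line (id + description) is retained for locus-tag matching."""
    proteins = []
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            proteins.append(
                ProteinRecord(
                    protein_id=rec.id,
                    sequence=str(rec.seq).upper(),
                    header=rec.description,
                )
            )
    if not proteins:
        raise GenomeBundleError(f"{path}: no protein records found")
    return proteins


_GI_RE = re.compile(r"gi\|(\d+)\|")


def link_annotations(
    seq: GenomeSequence,
    genes: Iterable[GeneRecord],
    proteins: Iterable[ProteinRecord],
) -> AnnotatedGenome:
    """Cross-link proteins to gene coordinates.

    Matching is by PID first (the ``gi|<PID>|`` token of legacy .faa
    headers), then by locus_tag appearing as a token of the header.
    Genes extending past the genome end are rejected; unmatched proteins
    and protein-less genes are counted and logged.  Zero matches is fatal:
    it almost always means the .faa and .ptt are from different genomes.
    """
    kept_genes = []
    for g in genes:
        if g.end > seq.length:
            warnings.warn(
                f"{seq.genome_id}: gene {g.locus_tag} end {g.end} exceeds "
                f"genome length {seq.length}; rejected",
                stacklevel=2,
            )
            continue
        kept_genes.append(g)
    kept_genes.sort(key=lambda g: (g.start, g.end))

    by_pid = {g.pid: g for g in kept_genes}
    by_locus = {g.locus_tag: g for g in kept_genes}

    linked: dict[str, ProteinRecord] = {}
    n_orphan_proteins = 0
    for prot in proteins:
        gene = None
        m = _GI_RE.search(prot.header or prot.protein_id)
        if m is not None and m.group(1) in by_pid:
            gene = by_pid[m.group(1)]
        elif prot.protein_id in by_pid:
            gene = by_pid[prot.protein_id]
        else:
            tokens = re.split(r"[|\s]+", prot.header or prot.protein_id)
            for tok in tokens:
                if tok in by_locus:
                    gene = by_locus[tok]
                    break
        if gene is None or gene.locus_tag in linked:
            n_orphan_proteins += 1
            continue
        linked[gene.locus_tag] = prot

    if not linked:
        raise GenomeBundleError(
            f"{seq.genome_id}: no protein could be matched to a gene "
            "(mismatched .faa/.ptt files?)"
        )
    n_orphan_genes = len(kept_genes) - len(linked)
    if n_orphan_proteins or n_orphan_genes:
        logger.info(
            "%s: %d unmatched proteins, %d protein-less genes",
            seq.genome_id,
            n_orphan_proteins,
            n_orphan_genes,
        )
    return AnnotatedGenome(genome=seq, genes=kept_genes, proteins=linked)


def write_fasta(
    records: Sequence[tuple[str, str]], path: str | Path, wrap: int = 70
) -> None:
    """Write (header, sequence) pairs as FASTA, 70-column wrapped.

    Record order is preserved; duplicate headers within one file are an
    error because downstream motif tools key on them.
    """
    seen: set[str] = set()
    seq_records = []
    for header, sequence in records:
        if header in seen:
            raise ValueError(f"duplicate FASTA header {header!r}")
        seen.add(header)
        seq_records.append(SeqRecord(Seq(sequence), id=header, description=""))
    with open(path, "w") as fh:
        writer = FastaWriter(fh, wrap=wrap)
        writer.write_file(seq_records)
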