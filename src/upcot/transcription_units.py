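"""Transcriptional-unit prediction from intergenic distance.

Prokaryotic operons show characteristically short gaps between
co-transcribed genes, so a maximal run of consecutive same-strand genes
whose internal intergenic gaps stay below a threshold is taken as one
transcriptional unit (TU).  An intervening opposite-strand gene always
breaks a run: a divergent neighbour implies its own promoter region.

Two distinct gap notions are used, deliberately:

* TU joining looks only at the gap to the previous *same-strand run
  member* (genes are consecutive, so this is the previous gene);
* :func:`upstream_gap`, which decides whether a gene has enough room for
  upstream-sequence extraction, measures to the nearest annotated gene
  boundary on *either* strand.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .genome_io import AnnotatedGenome, GeneRecord


@dataclass(frozen=True)
class TranscriptionUnit:
    """A maximal same-strand gene run; members are ordered 5'->3' in the
    direction of transcription, so the leader is always the first member."""

    genome_id: str
    member_loci: tuple[str, ...]
    strand: str

    @property
    def leader_locus(self) -> str:
        return self.member_loci[0]


def upstream_gap(gene: GeneRecord, genome: AnnotatedGenome) -> int:
    """Distance in bp from the gene's 5' boundary to the nearest annotated
    gene boundary upstream (either strand), clamped at zero.

    For a plus-strand gene this is ``start - 1 - max(end of genes ending
    before start)``, or ``start - 1`` when nothing precedes it; for a
    minus-strand gene, ``min(start of genes starting after end) - end -
    1``, or ``genome_length - end`` at the 3' contig edge.
    """
    if gene.strand == "+":
        ends = sorted(g.end for g in genome.genes if g is not gene)
        i = bisect_left(ends, gene.start)
        prev_end = ends[i - 1] if i > 0 else 0
        return max(0, gene.start - 1 - prev_end)
    starts = sorted(g.start for g in genome.genes if g is not gene)
    i = bisect_right(starts, gene.end)
    next_start = starts[i] if i < len(starts) else genome.genome.length + 1
    return max(0, next_start - gene.end - 1)


def predict_tus(
    genome: AnnotatedGenome, gap_threshold: int = 50
) -> list[TranscriptionUnit]:
    """Partition the gene list into transcriptional units.

    A new unit starts whenever the strand changes or the same-strand
    intergenic gap (next.start - prev.end - 1; overlaps count as zero)
    reaches ``gap_threshold``.  Every gene lands in exactly one unit.
    """
    if gap_threshold < 0:
        raise ValueError("gap_threshold must be >= 0")
    units: list[TranscriptionUnit] = []
    run: list[GeneRecord] = []

    def flush() -> None:
        if not run:
            return
        strand = run[0].strand
        loci = [g.locus_tag for g in run]
        if strand == "-":
            loci.reverse()  # transcription direction is rightmost-first
        units.append(
            TranscriptionUnit(
                genome_id=genome.genome_id,
                member_loci=tuple(loci),
                strand=strand,
            )
        )

    for g in genome.genes:
        if run and (
            g.strand != run[-1].strand
            or g.start - run[-1].end - 1 >= gap_threshold
        ):
            flush()
            run = []
        run.append(g)
    flush()
    return units


def tu_leader_of(locus: str, tus: Iterable[TranscriptionUnit]) -> str:
    """The leader (first gene in transcription direction) of the TU that
    contains ``locus``."""
    for tu in tus:
        if locus in tu.member_loci:
            return tu.leader_locus
    raise KeyError(f"locus {locus!r} is in no transcription unit")


def write_tu_table(
    tus: Sequence[TranscriptionUnit], path: str | Path
) -> None:
    """Export TUs as TSV (genome_id, leader, strand, comma-joined members)."""
    with open(path, "w") as fh:
        fh.write("genome_id\tleader\tstrand\tmembers\n")
        for tu in tus:
            fh.write(
                f"{tu.genome_id}\t{tu.leader_locus}\t{tu.strand}\t"
                + ",".join(tu.member_loci)
                + "\n"
            )
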