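"""Bidirectional-best-hit orthology and per-target-gene ortholog groups.

Two proteins in different genomes are called orthologs when each is the
other's top-scoring similarity hit (bidirectional best hit, BDBH).  For a
chosen target genome, every target gene's BDBH partners across the
reference genomes form its cluster of orthologous genes (tgCoG); groups
with fewer reference-genome orthologs than ``min_orthologs`` are dropped.
The ortholog count excludes the target gene itself: a "minimum 4
orthologs" group has at least five members once the target is included.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .genome_io import AnnotatedGenome, write_fasta
from .homology_search import HitTable, top_hit_per_query

COG_DIR_NAME = "tgCoG_protein_sequences"


@dataclass(frozen=True)
class OrthologGroup:
    """One target gene plus its BDBH ortholog per reference genome."""

    target_locus: str
    orthologs: Mapping[str, str]  # reference_genome_id -> locus_tag

    def __post_init__(self) -> None:
        if self.target_locus in self.orthologs.values():
            raise ValueError(
                f"{self.target_locus}: target locus listed as its own ortholog"
            )

    @property
    def count(self) -> int:
        return len(self.orthologs)


def bdbh_pairs(
    forward: HitTable, reverse: HitTable
) -> set[tuple[str, str]]:
    """Reciprocal best hits between a target->reference table and its
    reference->target counterpart.

    A pair (t, r) is emitted iff t's best subject is r and r's best
    subject is t; the result is one-to-one in both coordinates.
    """
    if (
        forward.query_genome_id != reverse.subject_genome_id
        or forward.subject_genome_id != reverse.query_genome_id
    ):
        raise ValueError(
            "hit tables are not mutual transposes: "
            f"{forward.query_genome_id}->{forward.subject_genome_id} vs "
            f"{reverse.query_genome_id}->{reverse.subject_genome_id}"
        )
    fwd_best = top_hit_per_query(forward)
    rev_best = top_hit_per_query(reverse)
    return {
        (t, r) for t, r in fwd_best.items() if rev_best.get(r) == t
    }


def ortholog_counts(
    per_reference: Mapping[str, Iterable[tuple[str, str]]]
) -> dict[str, int]:
    """Number of reference genomes in which each target gene has a BDBH."""
    counts: dict[str, int] = {}
    for pairs in per_reference.values():
        for target_locus, _ref_locus in pairs:
            counts[target_locus] = counts.get(target_locus, 0) + 1
    return counts


def build_cogs(
    per_reference: Mapping[str, Iterable[tuple[str, str]]],
    min_orthologs: int = 4,
) -> list[OrthologGroup]:
    """Assemble ortholog groups and keep those with >= min_orthologs.

    ``per_reference`` maps reference genome id -> BDBH pair set from
    :func:`bdbh_pairs`.  Groups are sorted by target locus.
    """
    if min_orthologs < 1:
        raise ValueError("min_orthologs must be >= 1")
    by_target: dict[str, dict[str, str]] = {}
    for ref_id in sorted(per_reference):
        for target_locus, ref_locus in per_reference[ref_id]:
            by_target.setdefault(target_locus, {})[ref_id] = ref_locus
    return [
        OrthologGroup(target_locus=t, orthologs=dict(sorted(orths.items())))
        for t, orths in sorted(by_target.items())
        if len(orths) >= min_orthologs
    ]


def write_cog_sequences(
    groups: Iterable[OrthologGroup],
    genomes: Mapping[str, AnnotatedGenome],
    target_genome_id: str,
    outdir: str | Path,
) -> int:
    """Write one protein FASTA per group into ``outdir``.

    The file is named by the target locus tag and lists the target
    protein first, then the orthologs in sorted reference-genome order;
    headers read ``<genome_id>|<locus_tag>``.  Returns the file count.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n_written = 0
    for group in groups:
        target = genomes[target_genome_id]
        records = []
        try:
            records.append(
                (
                    f"{target_genome_id}|{group.target_locus}",
                    target.proteins[group.target_locus].sequence,
                )
            )
            for ref_id in sorted(group.orthologs):
                locus = group.orthologs[ref_id]
                records.append(
                    (f"{ref_id}|{locus}", genomes[ref_id].proteins[locus].sequence)
                )
        except KeyError as exc:
            raise RuntimeError(
                f"group {group.target_locus}: unresolvable locus {exc} "
                "(inconsistent pipeline state)"
            ) from exc
        write_fasta(records, outdir / group.target_locus)
        n_written += 1
    return n_written
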