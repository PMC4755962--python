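"""Upstream-sequence extraction and per-target-gene clustering.

For every retained ortholog group the pipeline extracts the region
immediately 5' of each member gene's start codon (reverse-complemented
for minus-strand genes) and writes the set as one FASTA file — the
clustered upstream sequences fed to motif-discovery tools.

Genes whose upstream intergenic room falls below ``min_up`` are excluded:
regions shorter than roughly 40-50 bp carry too little signal for
cis-element prediction.  When there is room, at most ``max_up`` bases are
taken.  Two window policies exist:

* ``fixed-window`` (default): always take the ``max_up`` bases 5' of the
  start codon, which may reach into the upstream gene's coding sequence;
* ``intergenic-only``: stop at the upstream gene boundary, i.e. take
  ``min(upstream_gap, max_up)`` bases.

Genomes are treated as linear; windows truncate at the contig edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .genome_io import AnnotatedGenome, reverse_complement, write_fasta
from .transcription_units import TranscriptionUnit, tu_leader_of, upstream_gap

CLUSTER_DIR_NAME = "tu_upstreams"
MANIFEST_NAME = "manifest.tsv"

EXCL_SHORT = "short_upstream"
EXCL_EDGE = "contig_edge"
EXCL_BELOW_MIN = "below_min_members"

WINDOW_MODES = ("fixed-window", "intergenic-only")
REPRESENTATIVE_MODES = ("gene-self", "tu-leader")


@dataclass(frozen=True)
class UpstreamSequence:
    """An extracted upstream region, 5'->3' in the gene's transcription
    direction; ``genomic_span`` is 1-based inclusive on the forward strand."""

    genome_id: str
    locus_tag: str
    sequence: str
    genomic_span: tuple[int, int]

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class CoTCluster:
    """Per target gene: the upstream sequences of the target and its
    orthologs (target first, then references in sorted genome order),
    plus the per-locus reasons for any members that were excluded."""

    target_locus: str
    members: list[UpstreamSequence] = field(default_factory=list)
    exclusions: dict[str, str] = field(default_factory=dict)


def extract_upstream(
    locus: str,
    genome: AnnotatedGenome,
    min_up: int = 50,
    max_up: int = 350,
    mode: str = "fixed-window",
) -> UpstreamSequence | str:
    """Extract one gene's upstream sequence, or return an exclusion reason.

    Returns the string ``"short_upstream"`` when the upstream intergenic
    room is below ``min_up``, and ``"contig_edge"`` when a fixed window
    truncated at the contig edge falls below ``min_up``.
    """
    if min_up > max_up:
        raise ValueError("require min_up <= max_up")
    if mode not in WINDOW_MODES:
        raise ValueError(f"unknown window mode {mode!r}")
    gene = genome.gene_by_locus(locus)
    gap = upstream_gap(gene, genome)
    if gap < min_up:
        return EXCL_SHORT
    residues = genome.genome.residues
    glen = genome.genome.length
    if mode == "fixed-window":
        take = max_up
    else:
        take = min(gap, max_up)
    if gene.strand == "+":
        hi = gene.start - 1
        lo = max(1, gene.start - take)
        seq = residues[lo - 1 : hi]
    else:
        lo = gene.end + 1
        hi = min(glen, gene.end + take)
        seq = reverse_complement(residues[lo - 1 : hi])
    if hi - lo + 1 < min_up:
        return EXCL_EDGE
    return UpstreamSequence(
        genome_id=genome.genome_id,
        locus_tag=locus,
        sequence=seq,
        genomic_span=(lo, hi),
    )


def cluster_upstreams(
    groups: Iterable,
    genomes: Mapping[str, AnnotatedGenome],
    target_genome_id: str,
    tus_by_genome: Mapping[str, Sequence[TranscriptionUnit]],
    min_up: int = 50,
    max_up: int = 350,
    window_mode: str = "fixed-window",
    representative_mode: str = "gene-self",
) -> list[CoTCluster]:
    """Build one upstream cluster per ortholog group.

    With ``representative_mode="gene-self"`` each member gene contributes
    its own upstream (operon-internal genes are typically excluded as
    short); with ``"tu-leader"`` a member is represented by the upstream
    of its transcription unit's leader gene.
    """
    if representative_mode not in REPRESENTATIVE_MODES:
        raise ValueError(f"unknown representative mode {representative_mode!r}")
    clusters: list[CoTCluster] = []
    for group in sorted(groups, key=lambda g: g.target_locus):
        cluster = CoTCluster(target_locus=group.target_locus)
        member_plan = [(target_genome_id, group.target_locus)]
        member_plan += [
            (ref_id, group.orthologs[ref_id]) for ref_id in sorted(group.orthologs)
        ]
        for genome_id, locus in member_plan:
            rep_locus = locus
            if representative_mode == "tu-leader":
                rep_locus = tu_leader_of(locus, tus_by_genome[genome_id])
            result = extract_upstream(
                rep_locus, genomes[genome_id], min_up, max_up, window_mode
            )
            if isinstance(result, str):
                cluster.exclusions[locus] = result
            else:
                cluster.members.append(result)
        clusters.append(cluster)
    return clusters


def write_clusters(
    clusters: Sequence[CoTCluster],
    outdir: str | Path,
    min_members: int = 2,
) -> int:
    """Write one FASTA per cluster with >= min_members members.

    Files are named by the target locus tag; record headers read
    ``<genome_id>|<locus_tag>|len=<L>``.  A ``manifest.tsv`` beside the
    cluster files records every cluster's size, exclusions, and whether
    it was written, so the totals always reconcile.  Returns the number
    of cluster files written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seen_names: set[str] = set()
    n_written = 0
    manifest_rows = []
    for cluster in clusters:
        if cluster.target_locus in seen_names:
            raise ValueError(f"duplicate cluster name {cluster.target_locus!r}")
        seen_names.add(cluster.target_locus)
        reasons = ";".join(
            f"{locus}:{reason}" for locus, reason in sorted(cluster.exclusions.items())
        )
        if len(cluster.members) >= min_members:
            records = [
                (f"{m.genome_id}|{m.locus_tag}|len={m.length}", m.sequence)
                for m in cluster.members
            ]
            write_fasta(records, outdir / cluster.target_locus)
            n_written += 1
            status = "written"
        else:
            status = EXCL_BELOW_MIN
        manifest_rows.append(
            (
                cluster.target_locus,
                len(cluster.members),
                len(cluster.exclusions),
                status,
                reasons or "-",
            )
        )
    with open(outdir / MANIFEST_NAME, "w") as fh:
        fh.write("target_locus\tn_members\tn_excluded\tstatus\treasons\n")
        for row in manifest_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    return n_written
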