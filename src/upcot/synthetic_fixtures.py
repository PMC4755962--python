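"""Deterministic synthetic genome bundles with planted ground truth.

The generator emits one target and N reference genome bundles in the same
three-file layout the pipeline reads (.faa/.fna/.ptt), with three kinds of
planted structure recorded in truth tables:

* **ortholog families** — a random seed protein per family, mutated
  independently per genome at a chosen per-site divergence, placed in a
  chosen subset of the reference genomes (always in the target);
* **operon structure** — genes are laid out in transcription units whose
  internal gaps are drawn from a short-range interval and whose
  between-unit gaps from a long-range interval, so the intended TU
  partition is unambiguous for any threshold between the two ranges;
* **IUPAC motifs** — a concrete instance of a degenerate consensus
  planted once, at a recorded position, in the upstream intergenic region
  of every copy of a designated family.

Decoy genes carry independent random proteins in every genome; at the
default lengths their best cross-genome local-alignment scores sit far
above the 1e-3 E-value cutoff, so they act as negative controls for
reciprocal-best-hit calling.

Everything is reproducible from the spec's single integer seed; a rerun
writes byte-identical bundles.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome_io import GeneRecord, reverse_complement, write_fasta, write_ptt

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

# one fixed codon per residue; the pipeline never translates, this only
# keeps CDS coordinates honest (length divisible by 3, strand-consistent)
_CODON = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "CTT", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCT",
    "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
}
_STOP = "TAA"

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def iupac_scan(sequence: str, pattern: str) -> list[int]:
    """All 1-based positions where an IUPAC pattern matches a sequence.

    Degenerate codes match their base sets only: pattern N matches any of
    A/C/G/T but never an ambiguity letter (e.g. N) in the subject.
    Matches may overlap.
    """
    pattern = pattern.upper()
    try:
        regex = "".join(
            IUPAC[c] if c in "ACGT" else f"[{IUPAC[c]}]" for c in pattern
        )
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC code {exc} in pattern {pattern!r}") from exc
    return [m.start() + 1 for m in re.finditer(f"(?=({regex}))", sequence.upper())]


def mutate_protein(
    seed_sequence: str, divergence: float, rng: np.random.Generator
) -> str:
    """Substitute each site independently with probability ``divergence``
    to a uniformly chosen *different* residue; length is preserved."""
    if not 0.0 <= divergence <= 0.5:
        raise ValueError("divergence must be in [0, 0.5]")
    out = []
    for aa in seed_sequence:
        if rng.random() < divergence:
            choices = [c for c in AMINO_ACIDS if c != aa]
            out.append(choices[rng.integers(len(choices))])
        else:
            out.append(aa)
    return "".join(out)


def _random_protein(length: int, rng: np.random.Generator) -> str:
    body = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length - 1))
    return "M" + body


def _back_translate(protein: str) -> str:
    return "".join(_CODON[aa] for aa in protein) + _STOP


def _iupac_instance(pattern: str, rng: np.random.Generator) -> str:
    out = []
    for c in pattern.upper():
        bases = IUPAC[c]
        out.append(bases[rng.integers(len(bases))])
    return "".join(out)


@dataclass(frozen=True)
class FamilySpec:
    """One planted ortholog family.

    ``n_genomes_present`` counts *reference* genomes carrying the family;
    the target genome always carries it.  ``operon_position`` places the
    family gene either as its own transcription unit's leader or behind a
    decoy leader inside a two-gene operon (so its own upstream is short).
    """

    family_id: str
    n_genomes_present: int
    protein_length: int = 120
    divergence: float = 0.1
    motif: str | None = None
    operon_position: str = "leader"

    def __post_init__(self) -> None:
        if not 0.0 <= self.divergence <= 0.5:
            raise ValueError(f"{self.family_id}: divergence must be in [0, 0.5]")
        if self.operon_position not in ("leader", "internal"):
            raise ValueError(f"{self.family_id}: bad operon_position")
        if self.motif is not None and self.operon_position == "internal":
            raise ValueError(
                f"{self.family_id}: a motif can only be planted for an "
                "operon-leader family (internal genes have no long upstream)"
            )


@dataclass(frozen=True)
class GenomeSetSpec:
    """Study conditions for one synthetic genome set.

    Gap ranges are inclusive.  ``assumed_tu_gap_threshold`` and
    ``assumed_min_up`` document the pipeline settings the layout is built
    for: the intra-operon range must sit entirely below the threshold and
    the inter-unit range entirely above ``min_up``, otherwise the planted
    TU partition and upstream qualifications would be ambiguous.
    ``motif_plant_window`` bounds how far upstream of a start codon a
    motif may be planted, so it stays inside any extraction window of at
    least that size.
    """

    n_references: int
    families: tuple[FamilySpec, ...]
    intra_operon_gap_range: tuple[int, int] = (5, 30)
    inter_tu_gap_range: tuple[int, int] = (100, 400)
    seed: int = 17
    decoy_tu_sizes: tuple[int, ...] = (1, 2, 3)
    decoy_protein_length: int = 120
    assumed_tu_gap_threshold: int = 50
    assumed_min_up: int = 50
    motif_plant_window: int = 350

    def __post_init__(self) -> None:
        if self.n_references < 1:
            raise ValueError("need at least one reference genome")
        lo_i, hi_i = self.intra_operon_gap_range
        lo_e, hi_e = self.inter_tu_gap_range
        if not (0 <= lo_i <= hi_i < self.assumed_tu_gap_threshold):
            raise ValueError(
                "intra-operon gap range must lie entirely below the "
                "TU gap threshold"
            )
        if not (lo_e <= hi_e) or lo_e < max(self.assumed_min_up, self.assumed_tu_gap_threshold):
            raise ValueError(
                "inter-TU gap range must lie entirely above min_up and "
                "the TU gap threshold"
            )
        for fam in self.families:
            if fam.n_genomes_present > self.n_references:
                raise ValueError(
                    f"{fam.family_id}: present in {fam.n_genomes_present} "
                    f"of only {self.n_references} references"
                )
            if fam.motif is not None and len(fam.motif) > lo_e:
                raise ValueError(
                    f"{fam.family_id}: motif longer than the shortest "
                    "planted upstream gap"
                )


@dataclass
class SyntheticGenomeSet:
    """Generated bundle directories plus the planted ground truth."""

    root: Path
    target_dir: Path
    reference_dirs: list[Path]
    genome_ids: list[str]
    # (family_id, target_locus, reference_genome_id, reference_locus)
    ortholog_truth: list[tuple[str, str, str, str]]
    # genome_id -> list of (strand, member loci in transcription order)
    tu_truth: dict[str, list[tuple[str, tuple[str, ...]]]]
    # one row per planted motif copy
    motif_truth: list[dict]
    family_locus: dict[tuple[str, str], str]  # (genome_id, family_id) -> locus

    @property
    def target_genome_id(self) -> str:
        return self.genome_ids[0]


def default_genome_set_spec(seed: int = 17) -> GenomeSetSpec:
    """The canonical test fixture: 4 references, 6 families.

    Presence counts {1, 2, 3, 4, 4, 4} bracket the default ortholog-count
    threshold of 4, so exactly three families survive group filtering.
    Two families sit operon-internal to exercise the short-upstream
    exclusion path, and one leader family carries the HrcA-type 9-bp
    inverted repeat (TTAGCACTC-N9-GAGTGCTAA) in every upstream copy.
    """
    families = (
        FamilySpec("fam1", 1, divergence=0.05),
        FamilySpec("fam2", 2, divergence=0.10),
        FamilySpec("fam3", 3, divergence=0.15, operon_position="internal"),
        FamilySpec("fam4", 4, divergence=0.10),
        FamilySpec("fam5", 4, divergence=0.20, operon_position="internal"),
        FamilySpec("fam6", 4, divergence=0.10,
                   motif="TTAGCACTCNNNNNNNNNGAGTGCTAA"),
    )
    return GenomeSetSpec(n_references=4, families=families, seed=seed)


def generate_genome_set(spec: GenomeSetSpec, outdir: str | Path) -> SyntheticGenomeSet:
    """Write one target + N reference bundles plus truth tables.

    Fully reproducible from ``spec.seed``: reruns are byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome_ids = ["target"] + [f"ref{i}" for i in range(1, spec.n_references + 1)]

    master = np.random.default_rng([spec.seed, 1])
    # seed protein and reference membership per family
    seed_proteins: dict[str, str] = {}
    present_in: dict[str, list[int]] = {}
    for fi, fam in enumerate(spec.families):
        fam_rng = np.random.default_rng([spec.seed, 100 + fi])
        seed_proteins[fam.family_id] = _random_protein(fam.protein_length, fam_rng)
        refs = sorted(
            master.choice(spec.n_references, size=fam.n_genomes_present,
                          replace=False).tolist()
        )
        present_in[fam.family_id] = [r + 1 for r in refs]  # 1-based ref index

    ortholog_truth: list[tuple[str, str, str, str]] = []
    tu_truth: dict[str, list[tuple[str, tuple[str, ...]]]] = {}
    motif_truth: list[dict] = []
    family_locus: dict[tuple[str, str], str] = {}
    bundle_dirs: dict[str, Path] = {}

    for gi, gid in enumerate(genome_ids):
        rng = np.random.default_rng([spec.seed, 200 + gi])
        families_here = [
            fam for fam in spec.families
            if gi == 0 or gi in present_in[fam.family_id]
        ]

        # assemble TU templates: per-family units plus decoy units
        templates: list[tuple[str, object]] = [("family", f) for f in families_here]
        templates += [("decoy", size) for size in spec.decoy_tu_sizes]
        order = rng.permutation(len(templates))
        templates = [templates[i] for i in order]

        # lay out genes left to right; _PlannedGene in transcription order per TU
        @dataclass
        class _Gene:
            protein: str
            start: int = 0
            end: int = 0
            strand: str = "+"
            family_id: str | None = None
            locus: str = ""
            product: str = "hypothetical protein"

        planned_tus: list[dict] = []
        pos = 0
        for kind, payload in templates:
            strand = "+" if rng.random() < 0.5 else "-"
            if kind == "family":
                fam: FamilySpec = payload
                fam_rng = np.random.default_rng(
                    [spec.seed, 300 + gi, spec.families.index(fam)]
                )
                fam_gene = _Gene(
                    protein=mutate_protein(
                        seed_proteins[fam.family_id], fam.divergence, fam_rng
                    ),
                    family_id=fam.family_id,
                    product=f"{fam.family_id} family protein",
                )
                if fam.operon_position == "internal":
                    host = _Gene(
                        protein=_random_protein(spec.decoy_protein_length, rng)
                    )
                    tx_genes = [host, fam_gene]
                else:
                    tx_genes = [fam_gene]
                motif = fam.motif
            else:
                tx_genes = [
                    _Gene(protein=_random_protein(spec.decoy_protein_length, rng))
                    for _ in range(int(payload))
                ]
                motif = None

            gap_before = int(rng.integers(spec.inter_tu_gap_range[0],
                                          spec.inter_tu_gap_range[1] + 1))
            pos += gap_before
            genomic_genes = tx_genes if strand == "+" else list(reversed(tx_genes))
            for j, gene in enumerate(genomic_genes):
                if j > 0:
                    pos += int(rng.integers(spec.intra_operon_gap_range[0],
                                            spec.intra_operon_gap_range[1] + 1))
                gene.strand = strand
                gene.start = pos + 1
                gene.end = pos + 3 * (len(gene.protein) + 1)
                pos = gene.end
            planned_tus.append(
                {"strand": strand, "tx_genes": tx_genes, "motif": motif,
                 "gap_before": gap_before}
            )
        tail_gap = int(rng.integers(spec.inter_tu_gap_range[0],
                                    spec.inter_tu_gap_range[1] + 1))
        genome_length = pos + tail_gap

        # record each TU's upstream intergenic room (5' of its leader)
        for i, tu in enumerate(planned_tus):
            if tu["strand"] == "+":
                tu["upstream_room"] = tu["gap_before"]
            else:
                tu["upstream_room"] = (
                    planned_tus[i + 1]["gap_before"]
                    if i + 1 < len(planned_tus) else tail_gap
                )

        # assign locus tags in genomic order
        all_genes = sorted(
            (g for tu in planned_tus for g in tu["tx_genes"]),
            key=lambda g: g.start,
        )
        for idx, gene in enumerate(all_genes, start=1):
            gene.locus = f"{gid}_{idx:04d}"
            if gene.family_id is not None:
                family_locus[(gid, gene.family_id)] = gene.locus

        # background sequence, then overwrite CDS spans
        seq = rng.choice(list("ACGT"), size=genome_length)
        for gene in all_genes:
            cds = _back_translate(gene.protein)
            if gene.strand == "-":
                cds = reverse_complement(cds)
            seq[gene.start - 1 : gene.end] = list(cds)

        # plant motifs in leader upstream regions, exactly once per region
        for tu in planned_tus:
            if tu["motif"] is None:
                continue
            pattern = tu["motif"]
            leader = tu["tx_genes"][0]
            room = min(tu["upstream_room"], spec.motif_plant_window)
            plant_len = len(pattern)
            for _attempt in range(100):
                d = int(rng.integers(plant_len, room + 1))
                instance = _iupac_instance(pattern, rng)
                if leader.strand == "+":
                    m_start = leader.start - d
                    m_end = m_start + plant_len - 1
                    seq[m_start - 1 : m_end] = list(instance)
                    gap_lo = leader.start - tu["upstream_room"]
                    gap_seq = "".join(seq[gap_lo - 1 : leader.start - 1])
                else:
                    m_end = leader.end + d
                    m_start = m_end - plant_len + 1
                    seq[m_start - 1 : m_end] = list(reverse_complement(instance))
                    gap_hi = leader.end + tu["upstream_room"]
                    gap_seq = reverse_complement(
                        "".join(seq[leader.end : gap_hi])
                    )
                if len(iupac_scan(gap_seq, pattern)) == 1:
                    break
                # chance second match in the random background: redraw it
                fresh = rng.choice(list("ACGT"), size=tu["upstream_room"])
                if leader.strand == "+":
                    seq[gap_lo - 1 : leader.start - 1] = fresh
                else:
                    seq[leader.end : gap_hi] = fresh
            else:  # pragma: no cover - astronomically unlikely
                raise RuntimeError("could not plant motif uniquely")
            motif_truth.append(
                {
                    "genome_id": gid,
                    "locus": leader.locus,
                    "pattern": pattern,
                    "genomic_start": m_start,
                    "genomic_end": m_end,
                    "strand": leader.strand,
                    "offset_from_start_codon": d,
                }
            )

        # truth tables
        tu_truth[gid] = [
            (tu["strand"], tuple(g.locus for g in tu["tx_genes"]))
            for tu in sorted(
                planned_tus, key=lambda tu: min(g.start for g in tu["tx_genes"])
            )
        ]
        if gi > 0:
            for fam in families_here:
                ortholog_truth.append(
                    (
                        fam.family_id,
                        family_locus[("target", fam.family_id)],
                        gid,
                        family_locus[(gid, fam.family_id)],
                    )
                )

        # write the bundle
        gdir = outdir / gid
        gdir.mkdir(parents=True, exist_ok=True)
        bundle_dirs[gid] = gdir
        residues = "".join(seq)
        with open(gdir / f"{gid}.fna", "w") as fh:
            fh.write(f">{gid} synthetic chromosome, complete genome\n")
            for i in range(0, len(residues), 70):
                fh.write(residues[i : i + 70] + "\n")
        gene_records = [
            GeneRecord(
                locus_tag=g.locus,
                pid=str(10000 * (gi + 1) + i),
                start=g.start,
                end=g.end,
                strand=g.strand,
                product=g.product,
            )
            for i, g in enumerate(all_genes, start=1)
        ]
        write_ptt(
            gene_records,
            gdir / f"{gid}.ptt",
            description=f"{gid} synthetic chromosome - 1..{genome_length}",
        )
        faa_records = [
            (
                f"gi|{rec.pid}|ref|{rec.locus_tag}.1| {gene.product} [{gid}]",
                gene.protein,
            )
            for rec, gene in zip(gene_records, all_genes)
        ]
        write_fasta(faa_records, gdir / f"{gid}.faa")

    _write_truth_tables(outdir, ortholog_truth, tu_truth, motif_truth)
    return SyntheticGenomeSet(
        root=outdir,
        target_dir=bundle_dirs["target"],
        reference_dirs=[bundle_dirs[g] for g in genome_ids[1:]],
        genome_ids=genome_ids,
        ortholog_truth=ortholog_truth,
        tu_truth=tu_truth,
        motif_truth=motif_truth,
        family_locus=family_locus,
    )


def _write_truth_tables(
    outdir: Path,
    ortholog_truth: list[tuple[str, str, str, str]],
    tu_truth: dict[str, list[tuple[str, tuple[str, ...]]]],
    motif_truth: list[dict],
) -> None:
    with open(outdir / "truth_orthologs.tsv", "w") as fh:
        fh.write("family_id\ttarget_locus\treference_genome\treference_locus\n")
        for row in ortholog_truth:
            fh.write("\t".join(row) + "\n")
    with open(outdir / "truth_tus.tsv", "w") as fh:
        fh.write("genome_id\tstrand\tmembers\n")
        for gid, tus in tu_truth.items():
            for strand, members in tus:
                fh.write(f"{gid}\t{strand}\t{','.join(members)}\n")
    with open(outdir / "truth_motifs.tsv", "w") as fh:
        fh.write(
            "genome_id\tlocus\tpattern\tgenomic_start\tgenomic_end\t"
            "strand\toffset_from_start_codon\n"
        )
        for row in motif_truth:
            fh.write(
                "\t".join(
                    str(row[k])
                    for k in (
                        "genome_id", "locus", "pattern", "genomic_start",
                        "genomic_end", "strand", "offset_from_start_codon",
                    )
                )
                + "\n"
            )
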