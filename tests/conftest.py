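from __future__ import annotations

import pytest

from upcot.genome_io import AnnotatedGenome, GeneRecord, GenomeSequence, ProteinRecord
from upcot.synthetic_fixtures import default_genome_set_spec, generate_genome_set

FIXTURE_SEED = 17


@pytest.fixture(scope="session")
def genome_set(tmp_path_factory):
    """The canonical synthetic set: 1 target + 4 references, 6 families."""
    outdir = tmp_path_factory.mktemp("genome_set")
    return generate_genome_set(default_genome_set_spec(FIXTURE_SEED), outdir)


def make_annotated(genes, genome_length=None, genome_id="g", residues=None):
    """Hand-build an AnnotatedGenome from (locus, start, end, strand) tuples;
    each gene gets a placeholder protein."""
    records = [
        GeneRecord(locus_tag=t, pid=str(1000 + i), start=s, end=e, strand=st)
        for i, (t, s, e, st) in enumerate(genes)
    ]
    records.sort(key=lambda g: (g.start, g.end))
    if residues is None:
        length = genome_length or (max(g.end for g in records) + 100)
        residues = "A" * length
    seq = GenomeSequence(genome_id=genome_id, residues=residues)
    proteins = {
        g.locus_tag: ProteinRecord(protein_id=g.pid, sequence="M" + "A" * 9)
        for g in records
    }
    return AnnotatedGenome(genome=seq, genes=records, proteins=proteins)
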