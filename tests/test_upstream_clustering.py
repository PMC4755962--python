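from __future__ import annotations

import random

import pytest
from Bio import SeqIO

from _oracles import brute_force_upstream_slice
from conftest import make_annotated
from upcot.orthology import OrthologGroup, build_cogs
from upcot.pipeline import load_bundle
from upcot.transcription_units import predict_tus, upstream_gap
from upcot.upstream_clustering import (
    CoTCluster,
    UpstreamSequence,
    cluster_upstreams,
    extract_upstream,
    write_clusters,
)

TEN_BP = "AAAACGTTTT"


class TestExtractUpstream:
    def _genome(self, genes, residues):
        return make_annotated(genes, residues=residues)

    def test_plus_strand_forward_slice(self):
        ann = self._genome([("g", 7, 10, "+")], TEN_BP)
        up = extract_upstream("g", ann, min_up=1, max_up=6)
        assert isinstance(up, UpstreamSequence)
        assert up.sequence == "AAAACG" and up.genomic_span == (1, 6)

    def test_minus_strand_reverse_complement(self):
        ann = self._genome([("g", 1, 4, "-")], TEN_BP)
        up = extract_upstream("g", ann, min_up=1, max_up=6)
        assert up.sequence == "AAAACG" and up.genomic_span == (5, 10)

    def test_short_upstream_excluded(self):
        # gap of 40 < min_up of 50
        ann = make_annotated([("a", 10, 60, "+"), ("b", 101, 400, "+")])
        assert extract_upstream("b", ann, min_up=50, max_up=350) == "short_upstream"

    def test_short_room_at_contig_edge_is_excluded(self):
        # only 6 bp between contig start and the start codon
        ann = self._genome([("g", 7, 10, "+")], TEN_BP)
        assert extract_upstream("g", ann, min_up=8, max_up=350) == "short_upstream"

    def test_intergenic_only_stops_at_neighbour(self):
        ann = make_annotated(
            [("a", 1, 60, "+"), ("b", 161, 400, "+")],
            residues="C" * 60 + "ACGT" * 25 + "A" * 300,
        )
        up = extract_upstream("b", ann, min_up=50, max_up=350,
                              mode="intergenic-only")
        assert up.length == 100 and up.genomic_span == (61, 160)

    def test_fixed_window_may_cover_upstream_cds(self):
        ann = make_annotated(
            [("a", 1, 60, "+"), ("b", 161, 400, "+")],
            residues="C" * 60 + "G" * 100 + "A" * 300,
        )
        up = extract_upstream("b", ann, min_up=50, max_up=350)
        assert up.genomic_span == (1, 160)
        assert up.sequence == "C" * 60 + "G" * 100

    def test_unknown_locus_is_error(self):
        ann = self._genome([("g", 7, 10, "+")], TEN_BP)
        with pytest.raises(KeyError):
            extract_upstream("nope", ann, 1, 6)

    def test_min_above_max_is_error(self):
        ann = self._genome([("g", 7, 10, "+")], TEN_BP)
        with pytest.raises(ValueError):
            extract_upstream("g", ann, min_up=10, max_up=5)

    @pytest.mark.parametrize("mode", ["fixed-window", "intergenic-only"])
    def test_window_law_and_independent_slicer(self, genome_set, mode):
        """Every emitted length is within [min_up, max_up] and the sequence
        matches a literal slicer, for both strands and both modes."""
        min_up, max_up = 50, 350
        for d in [genome_set.target_dir] + genome_set.reference_dirs:
            ann = load_bundle(d)
            for gene in ann.genes:
                result = extract_upstream(gene.locus_tag, ann, min_up, max_up, mode)
                if isinstance(result, str):
                    continue
                assert min_up <= result.length <= max_up
                take = (
                    max_up if mode == "fixed-window"
                    else min(upstream_gap(gene, ann), max_up)
                )
                expected_seq, expected_span = brute_force_upstream_slice(
                    gene, ann.genome.residues, take
                )
                assert result.sequence == expected_seq
                assert result.genomic_span == expected_span


@pytest.fixture()
def fixture_state(genome_set):
    genomes = {
        d.name: load_bundle(d)
        for d in [genome_set.target_dir] + genome_set.reference_dirs
    }
    truth_by_ref: dict[str, set] = {}
    for _, t, g, r in genome_set.ortholog_truth:
        truth_by_ref.setdefault(g, set()).add((t, r))
    groups = build_cogs(truth_by_ref, min_orthologs=4)
    tus = {gid: predict_tus(g, 50) for gid, g in genomes.items()}
    return genomes, groups, tus


class TestClusterUpstreams:
    def test_all_leader_members_retained(self, genome_set, fixture_state):
        genomes, groups, tus = fixture_state
        clusters = cluster_upstreams(groups, genomes, "target", tus)
        by_target = {c.target_locus: c for c in clusters}
        leader_locus = genome_set.family_locus[("target", "fam6")]
        cluster = by_target[leader_locus]
        assert len(cluster.members) == 5 and not cluster.exclusions
        assert cluster.members[0].genome_id == "target"

    def test_operon_internal_family_excluded_in_gene_self_mode(
        self, genome_set, fixture_state
    ):
        genomes, groups, tus = fixture_state
        clusters = cluster_upstreams(groups, genomes, "target", tus)
        by_target = {c.target_locus: c for c in clusters}
        internal = by_target[genome_set.family_locus[("target", "fam5")]]
        assert internal.members == []
        assert set(internal.exclusions.values()) == {"short_upstream"}

    def test_tu_leader_mode_rescues_operon_internal_genes(
        self, genome_set, fixture_state
    ):
        genomes, groups, tus = fixture_state
        clusters = cluster_upstreams(
            groups, genomes, "target", tus, representative_mode="tu-leader"
        )
        by_target = {c.target_locus: c for c in clusters}
        internal = by_target[genome_set.family_locus[("target", "fam5")]]
        assert len(internal.members) == 5

    def test_no_cluster_holds_two_sequences_from_one_genome(self, fixture_state):
        genomes, groups, tus = fixture_state
        for cluster in cluster_upstreams(groups, genomes, "target", tus):
            gids = [m.genome_id for m in cluster.members]
            assert len(gids) == len(set(gids))


class TestWriteClusters:
    def _cluster(self, name, n_members):
        return CoTCluster(
            target_locus=name,
            members=[
                UpstreamSequence(f"g{i}", f"{name}_l{i}", "ACGT" * 20, (1, 80))
                for i in range(n_members)
            ],
        )

    def test_file_named_by_target_locus_with_all_records(self, tmp_path):
        write_clusters([self._cluster("slr2075", 10)], tmp_path)
        records = list(SeqIO.parse(str(tmp_path / "slr2075"), "fasta"))
        assert len(records) == 10
        assert records[0].id == "g0|slr2075_l0|len=80"

    def test_single_member_cluster_dropped_to_manifest(self, tmp_path):
        n = write_clusters([self._cluster("x", 1)], tmp_path, min_members=2)
        assert n == 0 and not (tmp_path / "x").exists()
        manifest = (tmp_path / "manifest.tsv").read_text()
        assert "below_min_members" in manifest

    def test_duplicate_cluster_name_is_error(self, tmp_path):
        with pytest.raises(ValueError, match="duplicate"):
            write_clusters([self._cluster("x", 2), self._cluster("x", 3)], tmp_path)

    def test_rerun_is_byte_identical(self, tmp_path, fixture_state):
        genomes, groups, tus = fixture_state
        clusters = cluster_upstreams(groups, genomes, "target", tus)
        for sub in ("a", "b"):
            write_clusters(clusters, tmp_path / sub)
        files_a = sorted((tmp_path / "a").iterdir())
        files_b = sorted((tmp_path / "b").iterdir())
        assert [f.name for f in files_a] == [f.name for f in files_b]
        for fa, fb in zip(files_a, files_b):
            assert fa.read_bytes() == fb.read_bytes()
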