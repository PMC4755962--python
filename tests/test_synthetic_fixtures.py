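from __future__ import annotations

import filecmp

import numpy as np
import pytest

from upcot.genome_io import read_ptt, reverse_complement
from upcot.pipeline import load_bundle
from upcot.synthetic_fixtures import (
    FamilySpec,
    GenomeSetSpec,
    default_genome_set_spec,
    generate_genome_set,
    iupac_scan,
    mutate_protein,
)
from upcot.transcription_units import upstream_gap

HRCA = "TTAGCACTCNNNNNNNNNGAGTGCTAA"


class TestIupacScan:
    def test_hrca_inverted_repeat_matches_n9_spacer(self):
        assert iupac_scan("TTAGCACTCAAAAAAAAAGAGTGCTAA", HRCA) == [1]

    def test_pattern_longer_than_subject(self):
        assert iupac_scan("ACGT", "ACGTA") == []

    def test_degenerate_codes_match_their_sets_only(self):
        assert iupac_scan("CAACGGGGGGGTTG", "CAACNNNNNNGTTG") == [1]
        assert iupac_scan("GTAAAAAAAAATAC", "GTANNNNNNNNTAC") == [1]
        assert iupac_scan("AG", "R") == [1, 2]
        assert iupac_scan("CT", "R") == []

    def test_subject_n_is_never_matched(self):
        # pattern N matches any base, but not an ambiguity letter in the subject
        assert iupac_scan("ANAT", "N") == [1, 3, 4]
        assert iupac_scan("NNNN", "N") == []

    def test_overlapping_matches_reported(self):
        assert iupac_scan("AAAA", "AA") == [1, 2, 3]

    def test_invalid_code_is_error(self):
        with pytest.raises(ValueError, match="IUPAC"):
            iupac_scan("ACGT", "AQ")

    def test_plant_and_recover_at_random_offsets(self):
        rng = np.random.default_rng(23)
        bases = "ACGT"
        for _ in range(30):
            background = "".join(bases[i] for i in rng.integers(0, 4, 200))
            instance = "TTAGCACTC" + "".join(
                bases[i] for i in rng.integers(0, 4, 9)
            ) + "GAGTGCTAA"
            pos = int(rng.integers(0, 200 - len(instance)))
            planted = background[:pos] + instance + background[pos + len(instance):]
            assert pos + 1 in iupac_scan(planted, HRCA)


class TestMutateProtein:
    def test_zero_divergence_is_identity(self):
        rng = np.random.default_rng(1)
        assert mutate_protein("MKVLAT", 0.0, rng) == "MKVLAT"

    def test_half_divergence_within_binomial_bound(self):
        rng = np.random.default_rng(2)
        seed = "M" + "A" * 999
        mutated = mutate_protein(seed, 0.5, rng)
        n_sub = sum(a != b for a, b in zip(seed, mutated))
        # 5 s.d. of Binomial(1000, 0.5)
        assert abs(n_sub - 500) <= 5 * (1000 * 0.25) ** 0.5
        assert len(mutated) == 1000

    def test_fixed_seed_reproducible(self):
        out1 = mutate_protein("MKVLAT" * 10, 0.3, np.random.default_rng(5))
        out2 = mutate_protein("MKVLAT" * 10, 0.3, np.random.default_rng(5))
        assert out1 == out2

    def test_divergence_out_of_range_is_error(self):
        with pytest.raises(ValueError):
            mutate_protein("MKV", 0.7, np.random.default_rng(0))

    def test_higher_divergence_lowers_identity(self):
        rng = np.random.default_rng(8)
        seed = "M" + "K" * 499
        low = mutate_protein(seed, 0.1, rng)
        high = mutate_protein(seed, 0.4, rng)
        ident = lambda s: sum(a == b for a, b in zip(seed, s)) / len(seed)
        assert ident(low) > ident(high)


class TestSpecValidation:
    def test_family_present_in_more_refs_than_exist(self):
        with pytest.raises(ValueError, match="of only"):
            GenomeSetSpec(n_references=2, families=(FamilySpec("f", 3),))

    def test_intra_range_must_sit_below_threshold(self):
        with pytest.raises(ValueError, match="below"):
            GenomeSetSpec(
                n_references=2,
                families=(FamilySpec("f", 1),),
                intra_operon_gap_range=(10, 80),
            )

    def test_motif_on_internal_family_is_error(self):
        with pytest.raises(ValueError, match="leader"):
            FamilySpec("f", 1, motif=HRCA, operon_position="internal")


class TestGenerateGenomeSet:
    def test_rerun_is_byte_identical(self, tmp_path):
        spec = default_genome_set_spec(17)
        a = generate_genome_set(spec, tmp_path / "a")
        b = generate_genome_set(spec, tmp_path / "b")
        for gid in a.genome_ids:
            for ext in (".fna", ".faa", ".ptt"):
                assert filecmp.cmp(
                    tmp_path / "a" / gid / f"{gid}{ext}",
                    tmp_path / "b" / gid / f"{gid}{ext}",
                    shallow=False,
                )

    def test_different_seed_changes_output(self, tmp_path):
        a = generate_genome_set(default_genome_set_spec(17), tmp_path / "a")
        b = generate_genome_set(default_genome_set_spec(18), tmp_path / "b")
        assert not filecmp.cmp(
            a.target_dir / "target.fna", b.target_dir / "target.fna",
            shallow=False,
        )

    def test_family_presence_matches_spec_counts(self, genome_set):
        per_family = {}
        for fam_id, _, ref, _ in genome_set.ortholog_truth:
            per_family.setdefault(fam_id, set()).add(ref)
        assert {f: len(refs) for f, refs in per_family.items()} == {
            "fam1": 1, "fam2": 2, "fam3": 3, "fam4": 4, "fam5": 4, "fam6": 4,
        }

    def test_divergence_controls_pairwise_identity(self, tmp_path):
        fams = (
            FamilySpec("low", 2, divergence=0.1),
            FamilySpec("high", 2, divergence=0.4),
        )
        spec = GenomeSetSpec(n_references=2, families=fams, seed=3)
        gs = generate_genome_set(spec, tmp_path / "d")
        genomes = {
            d.name: load_bundle(d) for d in [gs.target_dir] + gs.reference_dirs
        }

        def mean_identity(fam_id):
            seqs = [
                genomes[gid].proteins[locus].sequence
                for (gid, f), locus in gs.family_locus.items()
                if f == fam_id
            ]
            idents = [
                sum(x == y for x, y in zip(a, b)) / len(a)
                for i, a in enumerate(seqs) for b in seqs[i + 1:]
            ]
            return sum(idents) / len(idents)

        assert mean_identity("low") > mean_identity("high")

    def test_generated_bundles_parse_with_zero_warnings(self, genome_set, recwarn):
        for d in [genome_set.target_dir] + genome_set.reference_dirs:
            ann = load_bundle(d)
            assert len(ann.proteins) == len(ann.genes)
        assert not recwarn.list

    def test_truth_tables_written(self, genome_set):
        for name in ("truth_orthologs.tsv", "truth_tus.tsv", "truth_motifs.tsv"):
            lines = (genome_set.root / name).read_text().splitlines()
            assert len(lines) > 1

    def test_motif_planted_once_at_recorded_position(self, genome_set):
        """Each planted motif instance appears exactly once in the upstream
        intergenic region, at the genomic coordinates the truth table records."""
        genomes = {
            d.name: load_bundle(d)
            for d in [genome_set.target_dir] + genome_set.reference_dirs
        }
        assert len(genome_set.motif_truth) == 5  # fam6 in target + 4 refs
        for row in genome_set.motif_truth:
            ann = genomes[row["genome_id"]]
            gene = ann.gene_by_locus(row["locus"])
            room = upstream_gap(gene, ann)
            residues = ann.genome.residues
            if gene.strand == "+":
                gap_seq = residues[gene.start - 1 - room : gene.start - 1]
                expected_pos = row["genomic_start"] - (gene.start - room)
            else:
                gap_seq = reverse_complement(
                    residues[gene.end : gene.end + room]
                )
                expected_pos = gene.end + room - row["genomic_end"]
            positions = iupac_scan(gap_seq, row["pattern"])
            assert positions == [expected_pos + 1]
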