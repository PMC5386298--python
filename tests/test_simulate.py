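"""Generators: reference/family construction, planting, reads, tables."""

import math

import numpy as np
import pandas as pd
import pytest

import vectrace as vt
from vectrace.simulate import mate_truth_interval, parse_truth_tag
from vectrace._kmer import revcomp


class TestGenerateReference:
    def test_gene_model_layout(self):
        ref = vt.generate_reference(1_000_000, vt.GeneSpec(), seed=1)
        gene = ref.gene_models[0]
        assert gene.n_exons() == 27
        assert gene.end - gene.start == 380_000
        assert len(gene.introns) == 26
        # first intron is the long one, large enough for a +15 kb breakpoint
        assert gene.introns[0][1] - gene.introns[0][0] > 15_000

    def test_footprint_overflow_is_named(self):
        with pytest.raises(ValueError, match="exceeds contig"):
            vt.generate_reference(100_000, vt.GeneSpec(span=380_000), seed=1)

    def test_deterministic(self):
        a = vt.generate_reference(50_000, vt.GeneSpec(span=20_000, n_exons=5), seed=9)
        b = vt.generate_reference(50_000, vt.GeneSpec(span=20_000, n_exons=5), seed=9)
        assert a.contigs == b.contigs
        assert a.gene_models[0].exons == b.gene_models[0].exons

    def test_family_zero_divergence_copies_identical(self):
        ref = vt.generate_reference(
            20_000, None, vt.FamilySpec(1, 0.0, copy_len=300), seed=3
        )
        (contig, s, e), = ref.repeat_regions
        assert ref.contigs[contig][s:e] == ref.family_master

    def test_family_divergence_matches_rate(self):
        """Mean per-base identity of copies vs the master ~ 1 - rate,
        verified by exhaustive base-wise comparison."""
        ref = vt.generate_reference(
            200_000, None, vt.FamilySpec(180, 0.02, copy_len=300), seed=7
        )
        master = ref.family_master
        idents = []
        for contig, s, e in ref.repeat_regions:
            copy = ref.contigs[contig][s:e]
            idents.append(sum(a == b for a, b in zip(copy, master)) / len(master))
        assert abs(np.mean(idents) - 0.98) < 0.005

    def test_family_avoids_gene_footprint(self):
        ref = vt.generate_reference(
            100_000,
            vt.GeneSpec(span=30_000, n_exons=5, start=30_000),
            vt.FamilySpec(40, 0.02, copy_len=200),
            seed=5,
        )
        for _, s, e in ref.repeat_regions:
            assert e <= 30_000 or s >= 60_000


class TestPlantInsertions:
    def test_deletion_length_recorded(self, tiny_ref, vector):
        sample, truth = vt.plant_insertions(
            tiny_ref, vector, [vt.InsertionSpec("chr5", 1000, 1204)]
        )
        (p,) = truth.insertions
        assert p.deletion_length == 204
        assert sample["chr5"][p.sample_start : p.sample_end] == vector.full_sequence

    def test_clean_insertion(self, tiny_ref, vector):
        _, truth = vt.plant_insertions(
            tiny_ref, vector, [vt.InsertionSpec("chr5", 500, 500)]
        )
        assert truth.insertions[0].deletion_length == 0

    def test_length_conservation_two_contigs(self, vector):
        """Sample genome length follows the closed-form arithmetic."""
        contigs = {"a": "ACGT" * 2500, "b": "TTGCA" * 3000}
        specs = [
            vt.InsertionSpec("a", 100, 350),
            vt.InsertionSpec("b", 2000, 2000, copies=2),
        ]
        sample, truth = vt.plant_insertions(contigs, vector, specs)
        vlen = len(vector)
        assert len(sample["a"]) == 10_000 - 250 + vlen
        assert len(sample["b"]) == 15_000 + 2 * vlen
        total_expected = (
            sum(len(s) for s in contigs.values())
            - sum(p.deletion_length for p in truth.insertions)
            + sum(p.copies * vlen for p in truth.insertions)
        )
        assert sum(len(s) for s in sample.values()) == total_expected

    def test_overlapping_specs_rejected(self, tiny_ref, vector):
        with pytest.raises(ValueError, match="overlapping"):
            vt.plant_insertions(
                tiny_ref,
                vector,
                [vt.InsertionSpec("chr5", 100, 300), vt.InsertionSpec("chr5", 200, 400)],
            )


class TestSimulateReadPairs:
    def test_error_free_reads_are_substrings(self, tiny_sim):
        """With err_rate 0, mate 1 and the reverse complement of mate 2 are
        exact substrings of the sample genome (exhaustive check)."""
        genome = tiny_sim["sample"]["chr5"]
        reads = tiny_sim["reads"]
        for s1, s2 in zip(reads.r1[:500], reads.r2[:500]):
            assert s1 in genome
            assert revcomp(s2) in genome

    def test_truth_tags_match_sequences(self, tiny_sim):
        genome = tiny_sim["sample"]["chr5"]
        reads = tiny_sim["reads"]
        for name, s1, s2 in zip(reads.names[:200], reads.r1[:200], reads.r2[:200]):
            contig, fs, fe = parse_truth_tag(name)
            assert s1 == genome[fs : fs + 100]
            assert s2 == revcomp(genome[fe - 100 : fe])

    def test_fragment_length_distribution(self):
        sample = {"c": "ACGT" * 10_000}
        reads = vt.simulate_read_pairs(
            sample, 50_000, read_len=100, frag_mean=300, frag_sd=30, seed=3
        )
        lens = [fe - fs for _, fs, fe in map(parse_truth_tag, reads.names)]
        assert abs(np.mean(lens) - 300) < 3  # within 1 %
        assert min(lens) >= 100

    def test_junction_spanning_pair_exists(self, tiny_sim):
        """At least one pair has one mate fully inside the vector and its
        mate fully in host, by coordinate arithmetic on truth tags."""
        truth = tiny_sim["truth"]
        (p,) = truth.insertions
        found = 0
        for name in tiny_sim["reads"].names:
            ivs = [mate_truth_interval(name, m, 100) for m in (1, 2)]
            inside = [p.sample_start <= s and e <= p.sample_end for _, s, e, _ in ivs]
            outside = [e <= p.sample_start or s >= p.sample_end for _, s, e, _ in ivs]
            if (inside[0] and outside[1]) or (inside[1] and outside[0]):
                found += 1
        assert found >= 1

    def test_reproducible_byte_identical(self, tmp_path):
        sample = {"c": "ACGTTGCA" * 2000}
        out = []
        for _ in range(2):
            reads = vt.simulate_read_pairs(sample, 500, err_rate=0.01, seed=42)
            p1, p2 = tmp_path / "a_R1.fastq", tmp_path / "a_R2.fastq"
            reads.write_fastq(p1, p2)
            out.append((p1.read_bytes(), p2.read_bytes()))
        assert out[0] == out[1]

    def test_invalid_args(self):
        sample = {"c": "ACGT" * 1000}
        with pytest.raises(ValueError):
            vt.simulate_read_pairs(sample, 0, seed=1)
        with pytest.raises(ValueError):
            vt.simulate_read_pairs(sample, 10, err_rate=1.0, seed=1)

    def test_fastq_round_trip(self, tmp_path, tiny_sim):
        reads = tiny_sim["reads"]
        p1, p2 = tmp_path / "r_R1.fastq", tmp_path / "r_R2.fastq"
        reads.write_fastq(p1, p2)
        back = vt.ReadPairs.from_fastq(p1, p2)
        assert back.names == reads.names
        assert back.r1 == reads.r1
        assert back.r2 == reads.r2


class TestSimulateCtTable:
    def test_noise_free_baseline(self):
        design = [vt.AnimalDesign("a1", "het", {"assay": 1.0})]
        tab = vt.simulate_ct_table(design, baseline_ct=26.0, ct_sd=0.0, seed=1)
        assert np.allclose(tab["ct_target"], 26.0)

    def test_zero_expression_all_nondetect(self):
        design = [vt.AnimalDesign("a1", "hom", {"assay": 0.0})]
        tab = vt.simulate_ct_table(design, seed=1)
        assert tab["ct_target"].isna().all()
        assert tab["ct_control"].notna().all()

    def test_nineteen_fold_delta_ct_closed_form(self):
        """With no noise, the dCt gap between groups equals log2(19)."""
        design = [
            vt.AnimalDesign("h1", "het", {"assay": 1.0}),
            vt.AnimalDesign("m1", "hom", {"assay": 1 / 19}),
        ]
        tab = vt.simulate_ct_table(design, ct_sd=0.0, seed=1)
        d = tab.groupby("group").apply(
            lambda g: (g["ct_target"] - g["ct_control"]).mean(), include_groups=False
        )
        assert d["hom"] - d["het"] == pytest.approx(math.log2(19), abs=1e-12)

    def test_negative_expression_rejected(self):
        with pytest.raises(ValueError, match="negative expression"):
            vt.simulate_ct_table([vt.AnimalDesign("a", "g", {"x": -1.0})], seed=1)


class TestSimulateMeasurements:
    def test_zero_sd_exact(self):
        df = vt.simulate_measurements([("g", 5.0, 0.0, 10)], seed=1)
        assert (df["value"] == 5.0).all() and len(df) == 10

    def test_sample_mean_near_parameter(self):
        df = vt.simulate_measurements([("normal", 61.2, 10.1, 245)], seed=1)
        sem = 10.1 / math.sqrt(245)
        assert abs(df["value"].mean() - 61.2) < 3 * sem

    def test_empty_group_list(self):
        df = vt.simulate_measurements([], seed=1)
        assert df.empty and list(df.columns) == ["cell_id", "group", "metric", "value"]

    def test_nonpositive_n_rejected(self):
        with pytest.raises(ValueError):
            vt.simulate_measurements([("g", 1.0, 1.0, 0)], seed=1)
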