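from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gsize import fileio
from gsize import simgenome as sim


def spec_with_family(kind: str, unit: int, copies: int, unique: int = 90_000, **kw):
    fam = sim.RepeatFamilySpec("fam", kind, unit, copies, kw.pop("divergence", 0.0))
    return sim.GenomeSpec(unique_length=unique, families=(fam,), **kw)


class TestSpecs:
    def test_family_validation(self):
        with pytest.raises(ValueError):
            sim.RepeatFamilySpec("f", "scattered", 10, 1)
        with pytest.raises(ValueError):
            sim.RepeatFamilySpec("f", "tandem", 0, 1)
        with pytest.raises(ValueError):
            sim.RepeatFamilySpec("f", "tandem", 10, 0)
        with pytest.raises(ValueError):
            sim.RepeatFamilySpec("f", "dispersed", 10, 1, divergence=0.5)

    def test_true_size_is_deterministic_sum(self):
        spec = spec_with_family("dispersed", 1000, 10)
        assert spec.true_size == 100_000
        spec2 = spec_with_family("tandem", 50, 100, unique=0, sex_pair=(300, 200))
        assert spec2.true_size == 50 * 100 + 500

    def test_bad_composition_rejected(self):
        with pytest.raises(ValueError):
            sim.GenomeSpec(unique_length=10, base_composition=(0.5, 0.5, 0.5, 0.5))


class TestSimulateGenome:
    def test_no_repeats_single_unique_annotation(self):
        g = sim.simulate_genome(sim.GenomeSpec(unique_length=100_000, seed=1))
        assert g.true_size == 100_000
        assert sum(len(s) for s in g.contigs.values()) == 100_000
        assert [iv.label for iv in g.annotations] == [sim.UNIQUE_LABEL]

    def test_dispersed_zero_divergence_copies_identical(self):
        g = sim.simulate_genome(spec_with_family("dispersed", 1000, 10, seed=2))
        assert g.true_size == 100_000
        copies = [
            g.contigs[iv.contig][iv.start : iv.end]
            for iv in g.annotations
            if iv.label == "fam"
        ]
        assert len(copies) == 10
        assert all(len(c) == 1000 for c in copies)
        assert len(set(copies)) == 1  # zero divergence -> identical
        assert copies[0] == g.consensus["fam"]

    def test_repeat_fraction_exact_by_construction(self):
        # 60% of a 1 Mb genome annotated as repeats, exactly
        fams = (
            sim.RepeatFamilySpec("d1", "dispersed", 2000, 150),
            sim.RepeatFamilySpec("d2", "dispersed", 500, 400),
            sim.RepeatFamilySpec("t1", "tandem", 200, 500),
        )
        spec = sim.GenomeSpec(unique_length=400_000, families=fams, seed=3)
        g = sim.simulate_genome(spec)
        assert g.true_size == 1_000_000
        assert g.repeat_bases / g.true_size == pytest.approx(0.60, abs=0)

    def test_annotations_partition_contigs(self):
        g = sim.simulate_genome(spec_with_family("tandem", 50, 100, seed=4))
        for contig, seq in g.contigs.items():
            ivs = sorted(g.annotations_for(contig), key=lambda iv: iv.start)
            assert ivs[0].start == 0
            assert ivs[-1].end == len(seq)
            for a, b in zip(ivs, ivs[1:]):
                assert a.end == b.start

    def test_tandem_copies_adjacent(self):
        g = sim.simulate_genome(spec_with_family("tandem", 50, 100, seed=4))
        reps = sorted(
            (iv for iv in g.annotations if iv.label == "fam"), key=lambda iv: iv.start
        )
        assert len(reps) == 100
        for a, b in zip(reps, reps[1:]):
            assert a.end == b.start  # one contiguous array

    def test_divergence_rate_matches_expectation(self):
        g = sim.simulate_genome(
            spec_with_family("dispersed", 5000, 20, divergence=0.05, seed=5)
        )
        cons = g.consensus["fam"]
        diffs = [
            sum(
                1
                for x, y in zip(cons, g.contigs[iv.contig][iv.start : iv.end])
                if x != y
            )
            for iv in g.annotations
            if iv.label == "fam"
        ]
        mean_diff = np.mean(diffs)
        assert mean_diff == pytest.approx(0.05 * 5000, rel=0.15)

    def test_placement_failure_raises(self):
        # 99% repeat density in final coordinates: rejection sampling cannot fit
        spec = spec_with_family("dispersed", 1000, 99, unique=1000, seed=6)
        with pytest.raises(sim.PlacementError):
            sim.simulate_genome(spec, max_attempts_per_copy=30)

    def test_sex_pair_contigs_and_average(self):
        spec = sim.GenomeSpec(unique_length=10_000, sex_pair=(4000, 3000), seed=7)
        g = sim.simulate_genome(spec)
        assert len(g.contigs["Z"]) == 4000
        assert len(g.contigs["W"]) == 3000
        assert g.true_size == 17_000
        assert g.sex_average == pytest.approx(3500.0)

    def test_seeded_determinism_byte_identical_fasta(self, tmp_path):
        spec = spec_with_family("dispersed", 500, 20, divergence=0.02, seed=42)
        paths = []
        for i in range(2):
            g = sim.simulate_genome(spec)
            p = tmp_path / f"g{i}.fa"
            fileio.write_fasta(g.contigs, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()


class TestSimulateReads:
    def test_read_count_formula(self, repeat_free_genome):
        rs = sim.simulate_reads(repeat_free_genome, 10, 100, seed=1)
        # N = ceil(C * G / L) = 10 * 50000 / 100
        assert rs.count == 5000
        assert rs.read_length == 100

    def test_error_free_reads_are_exact_substrings(self, repeat_free_genome):
        rs = sim.simulate_reads(repeat_free_genome, 1, 150, error_rate=0.0, seed=2)
        for read, (contig, start) in zip(rs.reads[:100], rs.origins[:100]):
            assert repeat_free_genome.contigs[contig][start : start + 150] == read

    def test_mean_interior_depth_near_target(self, repeat_free_genome):
        rs = sim.simulate_reads(repeat_free_genome, 30, 240, seed=3)
        depth = sim.pileup_depth(rs, repeat_free_genome.contig_lengths)["chr1"]
        interior = depth[240:-240]
        assert interior.mean() == pytest.approx(30.0, rel=0.03)

    def test_error_rate_applied(self, repeat_free_genome):
        rs = sim.simulate_reads(repeat_free_genome, 2, 200, error_rate=0.02, seed=4)
        mismatches = 0
        total = 0
        for read, (contig, start) in zip(rs.reads, rs.origins):
            ref = repeat_free_genome.contigs[contig][start : start + 200]
            mismatches += sum(1 for a, b in zip(read, ref) if a != b)
            total += 200
        assert mismatches / total == pytest.approx(0.02, rel=0.15)

    def test_rejects_bad_parameters(self, repeat_free_genome):
        with pytest.raises(ValueError):
            sim.simulate_reads(repeat_free_genome, 0, 100)
        with pytest.raises(ValueError):
            sim.simulate_reads(repeat_free_genome, 5, 0)
        with pytest.raises(ValueError):
            sim.simulate_reads(repeat_free_genome, 5, 60_000)  # longer than contig

    def test_seeded_determinism(self, repeat_free_genome):
        a = sim.simulate_reads(repeat_free_genome, 2, 100, 0.01, seed=9)
        b = sim.simulate_reads(repeat_free_genome, 2, 100, 0.01, seed=9)
        assert a.reads == b.reads
        assert a.origins == b.origins


class TestCollapseAssembly:
    def test_no_repeats_identity_on_length(self, repeat_free_genome):
        ca = sim.collapse_assembly(repeat_free_genome)
        assert ca.length == repeat_free_genome.true_size

    def test_dispersed_retain_one(self, repeat_genome):
        ca = sim.collapse_assembly(repeat_genome, retained_copies_per_family=1)
        assert ca.length == 91_000
        assert ca.collapse_map == {"rep1": [10]}

    def test_tandem_retain_two(self):
        g = sim.simulate_genome(spec_with_family("tandem", 50, 100, unique=0, seed=1))
        ca = sim.collapse_assembly(g, retained_copies_per_family=2)
        assert ca.length == 100
        assert ca.collapse_map == {"fam": [50, 50]}

    def test_retain_more_than_copies(self, repeat_genome):
        ca = sim.collapse_assembly(repeat_genome, retained_copies_per_family=20)
        assert ca.length == repeat_genome.true_size

    def test_unique_sequence_untouched(self, repeat_genome):
        ca = sim.collapse_assembly(repeat_genome)
        collapsed = ca.contigs["chr1"]
        uniques = [
            repeat_genome.contigs[iv.contig][iv.start : iv.end]
            for iv in repeat_genome.annotations
            if iv.label == sim.UNIQUE_LABEL
        ]
        for u in uniques:
            assert u in collapsed

    def test_retained_dispersed_copy_is_consensus(self):
        g = sim.simulate_genome(
            spec_with_family("dispersed", 800, 5, divergence=0.05, seed=10)
        )
        ca = sim.collapse_assembly(g)
        assert g.consensus["fam"] in ca.contigs["chr1"]

    def test_rejects_nonpositive_retain(self, repeat_genome):
        with pytest.raises(ValueError):
            sim.collapse_assembly(repeat_genome, retained_copies_per_family=0)

    @settings(max_examples=15, deadline=None)
    @given(copies=st.integers(min_value=1, max_value=30))
    def test_length_monotone_in_copy_number(self, copies):
        spec = spec_with_family("dispersed", 200, copies, unique=20_000, seed=3)
        g = sim.simulate_genome(spec)
        ca = sim.collapse_assembly(g)
        assert ca.length == 20_000 + 200  # independent of copy number
        assert ca.length <= g.true_size


class TestPileups:
    def test_pileup_totals(self, repeat_free_genome):
        rs = sim.simulate_reads(repeat_free_genome, 5, 100, seed=5)
        depth = sim.pileup_depth(rs, repeat_free_genome.contig_lengths)
        assert sum(int(v.sum()) for v in depth.values()) == rs.count * 100

    def test_pileup_on_collapsed_conserves_bases(self, repeat_genome):
        rs = sim.simulate_reads(repeat_genome, 5, 100, seed=6)
        ca = sim.collapse_assembly(repeat_genome)
        depth = sim.pileup_on_collapsed(rs, repeat_genome, ca)
        assert sum(int(v.sum()) for v in depth.values()) == rs.count * 100

    def test_collapsed_repeat_has_depth_excess(self, repeat_genome):
        rs = sim.simulate_reads(repeat_genome, 20, 100, seed=7)
        ca = sim.collapse_assembly(repeat_genome)
        depth = sim.pileup_on_collapsed(rs, repeat_genome, ca)["chr1"]
        rep_iv = next(
            iv for iv in repeat_genome.annotations if iv.label == "rep1"
        )
        # locate the retained copy in collapsed coordinates via the segment map
        seg = next(
            s for s in ca.segment_map if s[1] == rep_iv.start and s[2] == rep_iv.end
        )
        rep_depth = depth[seg[3] + 200 : seg[3] + 800].mean()
        assert rep_depth == pytest.approx(10 * 20, rel=0.25)


class TestDiploidize:
    def test_doubles_size_and_mutates(self, repeat_free_genome):
        dip = sim.diploidize(repeat_free_genome, 0.01, seed=8)
        assert dip.true_size == 2 * repeat_free_genome.true_size
        a = dip.contigs["chr1_hapA"]
        b = dip.contigs["chr1_hapB"]
        diff = sum(1 for x, y in zip(a, b) if x != y)
        assert diff / len(a) == pytest.approx(0.01, rel=0.2)
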