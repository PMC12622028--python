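"""Generator invariants: determinism, truth bookkeeping, file validity."""

from __future__ import annotations

import numpy as np
import pytest

from teinvader import synthetic
from teinvader.io_formats import (
    read_alignments,
    read_sequences,
    write_fastq,
    write_sam,
)


class TestSimulateGenome:
    def test_length_and_determinism(self):
        a = synthetic.simulate_genome(10_000, seed=5)
        b = synthetic.simulate_genome(10_000, seed=5)
        assert len(a.residues) == 10_000
        assert a.residues == b.residues
        assert a.residues != synthetic.simulate_genome(10_000, seed=6).residues

    def test_gc_extremes(self):
        gc1 = synthetic.simulate_genome(1000, gc_fraction=1.0, seed=1)
        assert set(gc1.residues) <= {"G", "C"}
        at = synthetic.simulate_genome(1000, gc_fraction=0.0, seed=1)
        assert set(at.residues) <= {"A", "T"}

    def test_gc_fraction_approximate(self):
        g = synthetic.simulate_genome(50_000, gc_fraction=0.42, seed=2)
        gc = sum(c in "GC" for c in g.residues) / 50_000
        assert gc == pytest.approx(0.42, abs=0.01)


class TestPlantCopies:
    def test_zero_copies_unchanged(self, reference, element):
        spec = synthetic.TePlantingSpec(element.element, copy_count=0)
        planted = synthetic.plant_te_copies(reference, spec, seed=1)
        assert planted.genome.residues == reference.residues
        assert planted.truth.empty

    def test_genome_grows_by_copy_length(self, reference, element):
        spec = synthetic.TePlantingSpec(element.element, copy_count=5)
        planted = synthetic.plant_te_copies(reference, spec, seed=2)
        assert len(planted.genome.residues) == len(reference.residues) + 5 * len(
            element.element.residues
        )
        for row in planted.truth.itertuples(index=False):
            assert planted.genome.residues[row.start : row.end] == element.element.residues

    def test_fragment_fraction(self, reference, element):
        frac = 4000 / len(element.element.residues)
        spec = synthetic.TePlantingSpec(element.element, 1, fragment_fraction=frac)
        planted = synthetic.plant_te_copies(reference, spec, seed=3)
        row = planted.truth.iloc[0]
        assert row.end - row.start == pytest.approx(4000, abs=5)
        assert row.source_end - row.source_start == row.end - row.start

    def test_divergence_bookkeeping_exact(self, reference, element):
        spec = synthetic.TePlantingSpec(element.element, 3, per_copy_divergence=0.05)
        planted = synthetic.plant_te_copies(reference, spec, seed=4)
        for row in planted.truth.itertuples(index=False):
            copy = planted.genome.residues[row.start : row.end]
            mismatches = sum(a != b for a, b in zip(copy, element.element.residues))
            assert mismatches == row.n_substitutions


class TestSimulateReads:
    def make(self, seed=0, error_rate=0.0):
        genome = synthetic.simulate_genome(10_000, seed=8, name="g")
        frag = synthetic.Fragment(
            "g", genome.residues, [synthetic.Segment(0, 10_000, "g", 0)]
        )
        return genome, synthetic.simulate_reads(
            [frag], {"g": genome.residues}, coverage=20, read_length=100,
            error_rate=error_rate, seed=seed,
        )

    def test_read_count_matches_coverage(self):
        _, (reads, _) = self.make()
        assert len(reads) == 2000  # 20x * 10 kb / 100 nt

    def test_error_free_reads_are_substrings(self):
        genome, (reads, alns) = self.make()
        from teinvader.io_formats import reverse_complement

        for read in reads[:50]:
            assert (
                read.residues in genome.residues
                or reverse_complement(read.residues) in genome.residues
            )
        assert all(a.edit_distance == 0 for a in alns)

    def test_seed_determinism_byte_identical(self, tmp_path):
        _, (reads1, _) = self.make(seed=3)
        _, (reads2, _) = self.make(seed=3)
        p1, p2 = tmp_path / "a.fastq", tmp_path / "b.fastq"
        write_fastq(reads1, p1)
        write_fastq(reads2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_nm_counts_sequencing_errors(self):
        _, (reads, alns) = self.make(error_rate=0.01)
        mean_nm = np.mean([a.edit_distance for a in alns if a.is_mapped])
        assert mean_nm == pytest.approx(1.0, abs=0.2)

    def test_reads_over_insertions_unmapped(self, element):
        sample = synthetic.simulate_invasion_sample(
            element.element, reference_length=30_000, copy_count=2, seed=9
        )
        n_unmapped = sum(1 for a in sample.alignments if not a.is_mapped)
        te_bases = 2 * len(element.element.residues)
        expected = 20 * (te_bases + 2 * 99) / 100  # insertions plus junction windows
        assert n_unmapped == pytest.approx(expected, rel=0.2)

    def test_emitted_files_parse_cleanly(self, tmp_path, element):
        sample = synthetic.simulate_invasion_sample(
            element.element, reference_length=20_000, copy_count=1, seed=10
        )
        fq = tmp_path / "r.fastq"
        sam = tmp_path / "a.sam"
        write_fastq(sample.reads, fq)
        write_sam(sample.alignments, sam, {"ref": 20_000},
                  {r.id: r for r in sample.reads})
        assert len(list(read_sequences(fq))) == len(sample.reads)
        parsed = list(read_alignments(sam))
        assert len(parsed) == len(sample.alignments)
        for orig, back in zip(sample.alignments, parsed):
            assert (orig.is_mapped, orig.position, orig.edit_distance) == (
                back.is_mapped, back.position, back.edit_distance
            )


class TestSmallRnaGenerator:
    def test_full_pingpong_all_mass_at_10(self, element):
        from teinvader.pirna import map_small_rnas, ping_pong_signature

        cons = synthetic.simulate_genome(2000, seed=11, name="c")
        reads = synthetic.simulate_small_rnas(cons, 100, 1.0, seed=12)
        profile = ping_pong_signature(map_small_rnas(reads, cons), 2000)
        assert profile.count(10) == max(profile.overlap_counts)
        assert profile.fraction_at_10 > 0.5

    def test_zero_pairs_empty(self):
        cons = synthetic.simulate_genome(2000, seed=13, name="c")
        assert synthetic.simulate_small_rnas(cons, 0, 0.5, seed=1) == []

    def test_lengths_within_window(self):
        cons = synthetic.simulate_genome(2000, seed=14, name="c")
        reads = synthetic.simulate_small_rnas(cons, 50, 0.5, seed=2)
        assert all(23 <= len(r.residues) <= 29 for r in reads)


class TestCohortGenerator:
    def scenario(self):
        return synthetic.InvasionScenario(
            origin_year=2010,
            origin_region="Africa",
            arrival_year={"Africa": 2010, "Europe": 2017},
            logistic_rate={"Africa": 5.0, "Europe": 5.0},
            sampling_plan=[(y, r, 3) for y in (2005, 2009, 2012, 2018)
                           for r in ("Africa", "Europe")],
        )

    def test_absent_before_arrival(self):
        _, truth = synthetic.simulate_invasion_cohort(self.scenario(), seed=1)
        before = truth[(truth.year < 2010)]
        assert not before.present.any()
        europe_early = truth[(truth.region == "Europe") & (truth.year < 2017)]
        assert not europe_early.present.any()

    def test_high_rate_approaches_step_function(self):
        _, truth = synthetic.simulate_invasion_cohort(self.scenario(), seed=2)
        africa_late = truth[(truth.region == "Africa") & (truth.year >= 2012)]
        assert africa_late.present.mean() > 0.9

    def test_arrival_order_respected(self):
        with pytest.raises(ValueError):
            synthetic.InvasionScenario(
                2010, "Africa", {"Africa": 2009}, {"Africa": 1.0}, []
            )
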