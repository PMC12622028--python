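"""Discovery chain: divergence filter, contaminant filter, assembly, protein search."""

from __future__ import annotations

import numpy as np
import pytest

from teinvader import readscan, synthetic
from teinvader.io_formats import ReadAlignment, SequenceRecord, parse_cigar, reverse_complement
from teinvader.readscan import (
    BLOSUM62,
    GAP_EXTEND,
    GAP_OPEN,
    ContaminantIndex,
    DivergenceUndefinedError,
    MissingReadError,
    PipelineThresholds,
    alignment_divergence,
    assemble_contigs,
    filter_contaminants,
    filter_te_candidates,
    make_protein_aligner,
    search_te_proteins,
    select_candidate_reads,
)

from conftest import tiling_reads


def mapped(qid, cigar, nm, strand="+"):
    return ReadAlignment(qid, "ref", 0, strand, parse_cigar(cigar), nm, True)


def unmapped(qid):
    return ReadAlignment(qid, None, None, "+", [], None, False)


class TestDivergence:
    @pytest.mark.parametrize(
        "cigar,nm,expected",
        [
            ("100M", 0, 0.0),
            ("100M", 6, 0.06),
            ("90M5I5D", 10, 0.10),
            ("10S90M", 9, 0.10),  # clipped bases excluded from the denominator
        ],
    )
    def test_formula(self, cigar, nm, expected):
        assert alignment_divergence(mapped("r", cigar, nm)) == pytest.approx(expected)

    def test_undefined_cases(self):
        with pytest.raises(DivergenceUndefinedError):
            alignment_divergence(unmapped("u"))
        with pytest.raises(DivergenceUndefinedError):
            alignment_divergence(mapped("r", "100M", None))


class TestSelectCandidateReads:
    def test_selection_rule_is_strict(self, thresholds):
        store = {q: SequenceRecord(q, "A" * 100) for q in ("u", "a", "b")}
        alns = [
            unmapped("u"),
            mapped("a", "100M", 5),  # divergence exactly 0.05 -> kept with reference
            mapped("b", "100M", 7),  # 0.07 -> selected
        ]
        got = {r.id for r in select_candidate_reads(alns, store, thresholds)}
        assert got == {"u", "b"}

    def test_each_read_emitted_once_and_secondary_ignored(self, thresholds):
        store = {"x": SequenceRecord("x", "A" * 100)}
        secondary = ReadAlignment("x", "ref", 0, "+", parse_cigar("100M"), 50, True,
                                  is_secondary=True)
        alns = [unmapped("x"), unmapped("x"), secondary]
        assert len(list(select_candidate_reads(alns, store, thresholds))) == 1

    def test_missing_read_raises(self, thresholds):
        with pytest.raises(MissingReadError):
            list(select_candidate_reads([unmapped("ghost")], {}, thresholds))


class TestContaminantFilter:
    def test_exact_substring_dropped_random_kept(self, thresholds):
        contaminant = synthetic.simulate_genome(2000, seed=1, name="wolbachia")
        index = ContaminantIndex.build([contaminant], k=31)
        inside = SequenceRecord("in", contaminant.residues[500:600])
        outside = SequenceRecord("out", synthetic.simulate_genome(100, seed=2).residues)
        kept = [r.id for r in filter_contaminants([inside, outside], index, thresholds)]
        assert kept == ["out"]

    def test_partial_hit_below_threshold_kept(self, thresholds):
        contaminant = synthetic.simulate_genome(2000, seed=3, name="c")
        index = ContaminantIndex.build([contaminant], k=31)
        # 100 nt read: first 50 nt contaminant, rest random -> 20/70 kmers clean
        hybrid = contaminant.residues[100:150] + synthetic.simulate_genome(50, seed=4).residues
        frac = index.hit_fraction(hybrid)
        # brute-force oracle for the hit fraction
        kmers = [hybrid[i : i + 31] for i in range(len(hybrid) - 30)]
        canon = [min(k, reverse_complement(k)) for k in kmers]
        expected = sum(1 for k in canon if k in index.kmer_set) / len(canon)
        assert frac == pytest.approx(expected)
        assert frac < 0.5
        kept = list(filter_contaminants([SequenceRecord("h", hybrid)], index, thresholds))
        assert len(kept) == 1

    def test_short_read_passes(self, thresholds):
        index = ContaminantIndex.build([SequenceRecord("c", "ACGT" * 20)], k=31)
        short = SequenceRecord("s", "ACGTACGTAC")
        assert list(filter_contaminants([short], index, thresholds)) == [short]

    def test_filter_order_invariance(self, thresholds):
        """Contaminant filtering before or after divergence selection commutes."""
        contaminant = synthetic.simulate_genome(3000, seed=5, name="c")
        index = ContaminantIndex.build([contaminant], k=31)
        rng = np.random.default_rng(6)
        store = {}
        alns = []
        for i in range(50):
            rid = f"r{i}"
            if i % 3 == 0:
                seq = contaminant.residues[i * 10 : i * 10 + 100]
            else:
                seq = synthetic.simulate_genome(100, seed=100 + i).residues
            store[rid] = SequenceRecord(rid, seq)
            alns.append(unmapped(rid) if rng.random() < 0.5 else mapped(rid, "100M", int(rng.integers(0, 12))))
        a = [r.id for r in filter_contaminants(
            select_candidate_reads(alns, store, thresholds), index, thresholds)]
        pre = list(filter_contaminants(store.values(), index, thresholds))
        pre_ids = {r.id for r in pre}
        b = [r.id for r in select_candidate_reads(
            (x for x in alns if x.query_id in pre_ids), {r.id: r for r in pre}, thresholds)]
        assert sorted(a) == sorted(b)


class TestAssembler:
    def test_planted_source_recovered(self, thresholds):
        src = synthetic.simulate_genome(500, seed=5, name="src").residues
        contigs = assemble_contigs(tiling_reads(src), thresholds)
        assert len(contigs) == 1
        c = contigs[0].residues
        assert src in c or reverse_complement(src) in c

    def test_two_sources_two_contigs(self, thresholds):
        a = synthetic.simulate_genome(500, seed=5).residues
        b = synthetic.simulate_genome(500, seed=9).residues
        reads = tiling_reads(a, prefix="a") + tiling_reads(b, prefix="b")
        assert len(assemble_contigs(reads, thresholds)) == 2

    def test_single_read_below_coverage_floor(self, thresholds):
        read = SequenceRecord("x", synthetic.simulate_genome(100, seed=1).residues)
        assert assemble_contigs([read], thresholds) == []

    def test_empty_input(self, thresholds):
        assert assemble_contigs([], thresholds) == []

    def test_deterministic_order(self, thresholds):
        src = synthetic.simulate_genome(500, seed=5).residues
        reads = tiling_reads(src)
        first = [c.residues for c in assemble_contigs(reads, thresholds)]
        second = [c.residues for c in assemble_contigs(list(reversed(reads)), thresholds)]
        assert first == second


def sw_oracle(a: str, b: str) -> float:
    """Brute-force Gotoh local alignment score (affine: L-gap costs 11 + L)."""
    neg = float("-inf")
    n, m = len(a), len(b)
    best = 0.0
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[neg] * (m + 1) for _ in range(n + 1)]
    F = [[neg] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - (GAP_OPEN + GAP_EXTEND), E[i][j - 1] - GAP_EXTEND)
            F[i][j] = max(H[i - 1][j] - (GAP_OPEN + GAP_EXTEND), F[i - 1][j] - GAP_EXTEND)
            s = BLOSUM62[a[i - 1]][b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


AA20 = list("ACDEFGHIKLMNPQRSTVWY")


class TestProteinSearch:
    def test_exact_back_translation(self, element):
        pol = element.proteins["pol"].residues[:100]
        # back-translate with a fixed codon choice
        codon = {"A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
                 "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
                 "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
                 "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT"}
        contig = SequenceRecord("c1", "".join(codon[aa] for aa in pol))
        hits = search_te_proteins([contig], [element.proteins["pol"]])
        best = hits[0]
        assert best.identity == pytest.approx(100.0)
        assert best.span_nt == 300
        assert best.frame == 1
        rc_hits = search_te_proteins(
            [SequenceRecord("c2", reverse_complement(contig.residues))],
            [element.proteins["pol"]],
        )
        assert rc_hits[0].identity == pytest.approx(100.0)
        assert rc_hits[0].frame < 0
        assert rc_hits[0].score == best.score

    def test_poly_a_has_no_hit(self, element):
        hits = search_te_proteins(
            [SequenceRecord("pa", "A" * 300)], [element.proteins["pol"]]
        )
        assert hits == []

    def test_scores_match_dp_oracle(self):
        """Aligner scores equal an independent brute-force Gotoh DP on 50 pairs."""
        rng = np.random.default_rng(42)
        aligner = make_protein_aligner()
        for _ in range(50):
            a = "".join(rng.choice(AA20, size=int(rng.integers(10, 51))))
            b = "".join(rng.choice(AA20, size=int(rng.integers(10, 51))))
            assert aligner.score(a, b) == sw_oracle(a, b)


class TestCandidateFilter:
    def make_hit(self, identity, span, score=500.0, cid="c1"):
        return readscan.ProteinHit(cid, "pol", identity, span, 1, score)

    def test_strict_boundaries(self, thresholds):
        assert filter_te_candidates([self.make_hit(80.0, 400)], thresholds) == []
        assert filter_te_candidates([self.make_hit(95.0, 250)], thresholds) == []
        kept = filter_te_candidates([self.make_hit(95.0, 300)], thresholds)
        assert len(kept) == 1 and kept[0].best_hit == "pol"

    def test_sorted_by_score(self, thresholds):
        hits = [
            self.make_hit(95.0, 300, score=100.0, cid="low"),
            self.make_hit(95.0, 300, score=900.0, cid="high"),
        ]
        out = filter_te_candidates(hits, thresholds)
        assert [c.contig.id for c in out] == ["high", "low"]


class TestPlantedTruthRecovery:
    @pytest.mark.parametrize("seed", [3, 4])
    def test_planted_invasion_recovered(self, element, thresholds, seed):
        """End-to-end: 5 planted copies at 20x / 1% error yield a pol candidate."""
        sample = synthetic.simulate_invasion_sample(element.element, seed=seed)
        store = {r.id: r for r in sample.reads}
        selected = list(select_candidate_reads(sample.alignments, store, thresholds))
        contigs = assemble_contigs(selected, thresholds)
        hits = search_te_proteins(contigs, list(element.proteins.values()))
        candidates = filter_te_candidates(hits, thresholds, contigs={c.id: c for c in contigs})
        assert candidates
        assert any(c.best_hit == "pol" for c in candidates)

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_negative_control_reference_only(self, thresholds, seed):
        """Reads purely from the reference produce zero candidates."""
        ref = synthetic.simulate_genome(50_000, seed=seed, name="ref")
        frag = synthetic.Fragment("s", ref.residues,
                                  [synthetic.Segment(0, len(ref.residues), "ref", 0)])
        reads, alns = synthetic.simulate_reads(
            [frag], {"ref": ref.residues}, coverage=20, error_rate=0.01, seed=seed + 50
        )
        store = {r.id: r for r in reads}
        selected = list(select_candidate_reads(alns, store, thresholds))
        contigs = assemble_contigs(selected, thresholds)
        assert contigs == []
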