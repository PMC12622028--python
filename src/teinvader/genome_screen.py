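"""Screen genome assemblies for insertions of a TE consensus.

A seed-extend-chain homology search in the RepeatMasker spirit: exact
k-mer seeds between the consensus and both strands of each contig are
extended without gaps under an X-drop rule, segments are chained when
collinear and close, and each chain becomes one insertion hit with an
identity, the number of distinct consensus positions covered, and a
full-length flag (more than 80% of the consensus covered). Donor-species
style analyses then extract hits with flanking sequence and keep only
insertions bounded by a terminal-repeat pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .consensus_annot import detect_terminal_repeats
from .io_formats import SequenceRecord, reverse_complement

FULL_LENGTH_FRACTION = 0.8

# ungapped X-drop extension scores
_MATCH = 1
_MISMATCH = -3
_XDROP = 15


@dataclass
class InsertionHit:
    assembly_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    matched_length: int
    identity: float
    full_length: bool
    has_two_ltrs: bool = False
    consensus_start: int = 0
    consensus_end: int = 0


@dataclass
class FlankedInsertion:
    """A hit extracted with flanks; core_start/core_end locate the hit
    inside ``record`` (the record is already strand-normalized)."""

    record: SequenceRecord
    core_start: int
    core_end: int


@dataclass
class _Segment:
    cons_start: int
    cons_end: int
    seq_start: int
    seq_end: int
    matches: int

    @property
    def length(self) -> int:
        return self.cons_end - self.cons_start


def _extend_seed(cons: str, seq: str, ci: int, si: int, k: int) -> _Segment:
    """Ungapped X-drop extension of an exact seed, trimmed to best score."""
    score = k
    best = score
    right = 0
    best_right = 0
    a, b = ci + k, si + k
    while a < len(cons) and b < len(seq):
        score += _MATCH if cons[a] == seq[b] else _MISMATCH
        right += 1
        if score > best:
            best, best_right = score, right
        elif best - score > _XDROP:
            break
        a += 1
        b += 1
    score = best
    left = 0
    best_left = 0
    a, b = ci - 1, si - 1
    while a >= 0 and b >= 0:
        score += _MATCH if cons[a] == seq[b] else _MISMATCH
        left += 1
        if score > best:
            best, best_left = score, left
        elif best - score > _XDROP:
            break
        a -= 1
        b -= 1
    cs, ce = ci - best_left, ci + k + best_right
    ss = si - best_left
    matches = sum(1 for t in range(ce - cs) if cons[cs + t] == seq[ss + t])
    return _Segment(cs, ce, ss, ss + (ce - cs), matches)


def _segments_for_strand(cons: str, seq: str, seed_k: int, min_segment: int) -> list[_Segment]:
    index: dict[str, list[int]] = {}
    for i in range(len(cons) - seed_k + 1):
        index.setdefault(cons[i : i + seed_k], []).append(i)
    covered: dict[int, int] = {}  # diagonal -> rightmost seq_end already extended
    segments: list[_Segment] = []
    for j in range(len(seq) - seed_k + 1):
        for i in index.get(seq[j : j + seed_k], ()):
            diag = j - i
            if covered.get(diag, -1) >= j + seed_k:
                continue
            seg = _extend_seed(cons, seq, i, j, seed_k)
            covered[diag] = seg.seq_end
            if seg.length >= min_segment:
                segments.append(seg)
    # dedupe identical extents reached from different seeds
    unique = {(s.cons_start, s.cons_end, s.seq_start): s for s in segments}
    return sorted(unique.values(), key=lambda s: (s.seq_start, s.cons_start))


def _can_follow(a: _Segment, b: _Segment, merge_gap: int) -> bool:
    return (
        b.seq_start > a.seq_start
        and b.cons_start > a.cons_start
        and -merge_gap <= b.seq_start - a.seq_end <= merge_gap
        and -merge_gap <= b.cons_start - a.cons_end <= merge_gap
    )


def _chain(segments: list[_Segment], merge_gap: int) -> list[list[_Segment]]:
    """Collinear chaining by dynamic programming.

    Repeatedly extracts the match-maximizing chain (collinear order on
    both sequences, gaps within ``merge_gap``) from the remaining
    segments. Score-optimal chaining keeps self-homology of the consensus
    (LTR pairs, internal tandem repeats) from hijacking the main chain of
    a diverged insertion, which a greedy left-to-right pass is prone to.
    """
    remaining = sorted(segments, key=lambda s: (s.seq_start, s.cons_start))
    chains: list[list[_Segment]] = []
    while remaining:
        n = len(remaining)
        score = [s.matches for s in remaining]
        parent = [-1] * n
        for j in range(1, n):
            for i in range(j):
                if _can_follow(remaining[i], remaining[j], merge_gap):
                    cand = score[i] + remaining[j].matches
                    if cand > score[j]:
                        score[j] = cand
                        parent[j] = i
        j = max(range(n), key=lambda t: (score[t], -remaining[t].seq_start))
        chain: list[_Segment] = []
        while j != -1:
            chain.append(remaining[j])
            j = parent[j]
        chain.reverse()
        used = {id(s) for s in chain}
        remaining = [s for s in remaining if id(s) not in used]
        chains.append(chain)
    return chains


def _union_length(intervals: Iterable[tuple[int, int]]) -> int:
    total = 0
    last_end = -1
    for start, end in sorted(intervals):
        start = max(start, last_end)
        if end > start:
            total += end - start
            last_end = end
        last_end = max(last_end, end)
    return total


def screen_assembly(
    assembly: Sequence[SequenceRecord],
    consensus: SequenceRecord,
    assembly_id: str = "assembly",
    seed_k: int = 13,
    min_segment: int = 50,
    merge_gap: int = 1000,
) -> list[InsertionHit]:
    """All chained insertion hits of the consensus in an assembly.

    Identity is matches over aligned (ungapped) columns of the chained
    segments; interior unaligned gaps reduce matched_length but not
    identity. Hit order is deterministic (contig, start).
    """
    cons = consensus.residues
    hits: list[InsertionHit] = []
    for contig in assembly:
        length = len(contig.residues)
        for strand in "+-":
            seq = contig.residues if strand == "+" else reverse_complement(contig.residues)
            segments = _segments_for_strand(cons, seq, seed_k, min_segment)
            for chain in _chain(segments, merge_gap):
                matches = sum(s.matches for s in chain)
                cols = sum(s.length for s in chain)
                seq_start = min(s.seq_start for s in chain)
                seq_end = max(s.seq_end for s in chain)
                if strand == "+":
                    start, end = seq_start, seq_end
                else:
                    start, end = length - seq_end, length - seq_start
                matched = _union_length((s.cons_start, s.cons_end) for s in chain)
                hits.append(
                    InsertionHit(
                        assembly_id=assembly_id,
                        contig_id=contig.id,
                        start=start,
                        end=end,
                        strand=strand,
                        matched_length=matched,
                        identity=100.0 * matches / cols if cols else 0.0,
                        full_length=matched > FULL_LENGTH_FRACTION * len(cons),
                        consensus_start=min(s.cons_start for s in chain),
                        consensus_end=max(s.cons_end for s in chain),
                    )
                )
    hits = _suppress_contained(hits)
    hits.sort(key=lambda h: (h.contig_id, h.start, h.strand))
    return hits


def _suppress_contained(hits: list[InsertionHit]) -> list[InsertionHit]:
    """Drop shadow hits whose contig span lies inside a larger hit.

    Internal self-homology of the consensus (LTR pairs, tandem repeats)
    produces secondary matches inside an already-reported insertion; only
    the dominant hit per locus is kept.
    """
    kept: list[InsertionHit] = []
    for hit in sorted(hits, key=lambda h: -(h.end - h.start)):
        span = hit.end - hit.start
        dominated = any(
            k.contig_id == hit.contig_id
            and (k.end - k.start) >= 2 * span
            and min(k.end, hit.end) - max(k.start, hit.start) >= 0.9 * span
            for k in kept
        )
        if not dominated:
            kept.append(hit)
    return kept


def extract_with_flanks(
    assembly: Mapping[str, SequenceRecord],
    hit: InsertionHit,
    flank: int = 3000,
) -> FlankedInsertion:
    """Extract a hit with up to ``flank`` bp of context on each side.

    Flanks are clipped at contig boundaries; minus-strand hits are
    reverse-complemented so the returned record reads in consensus
    orientation (flanks swap sides accordingly).
    """
    contig = assembly[hit.contig_id]
    left = max(0, hit.start - flank)
    right = min(len(contig.residues), hit.end + flank)
    sub = contig.residues[left:right]
    core_start, core_end = hit.start - left, hit.end - left
    if hit.strand == "-":
        sub = reverse_complement(sub)
        core_start, core_end = len(sub) - (hit.end - left), len(sub) - (hit.start - left)
    rid = f"{hit.assembly_id}|{hit.contig_id}:{left}-{right}({hit.strand})"
    return FlankedInsertion(SequenceRecord(rid, sub), core_start, core_end)


def require_two_ltrs(
    insertion: FlankedInsertion,
    min_length: int = 100,
    min_identity: float = 85.0,
    pad: int = 200,
) -> tuple[bool, Optional[SequenceRecord]]:
    """Keep only insertions bounded by a terminal-repeat pair.

    Terminal-repeat detection runs on a window spanning the hit plus a
    small pad; on success the insertion is trimmed to LTR-to-LTR extent
    (flanks removed). Solo LTRs and fragments fail.
    """
    seq = insertion.record.residues
    w_start = max(0, insertion.core_start - pad)
    w_end = min(len(seq), insertion.core_end + pad)
    window = SequenceRecord(insertion.record.id + "|window", seq[w_start:w_end])
    ltrs = detect_terminal_repeats(window, min_length=min_length, min_identity=min_identity)
    if ltrs is None or ltrs.length < min_length or ltrs.identity < min_identity:
        return False, None
    trimmed = window.residues[ltrs.left_start : ltrs.right_end]
    return True, SequenceRecord(insertion.record.id + "|ltr2ltr", trimmed)


def count_insertions(hits: Sequence[InsertionHit], merge_gap: int = 1000) -> int:
    """Insertion count with fragmented hits collapsed.

    Hits on the same contig within ``merge_gap`` whose consensus
    projections overlap by no more than 50% of the shorter projection are
    treated as fragments of one insertion.
    """
    remaining = sorted(hits, key=lambda h: (h.contig_id, h.start))
    count = 0
    cluster_end: Optional[tuple[str, int, int, int]] = None  # contig, end, cs, ce
    for hit in remaining:
        if cluster_end is not None:
            contig, end, cs, ce = cluster_end
            overlap = min(ce, hit.consensus_end) - max(cs, hit.consensus_start)
            shorter = min(ce - cs, hit.consensus_end - hit.consensus_start)
            if (
                hit.contig_id == contig
                and hit.start - end <= merge_gap
                and (shorter <= 0 or overlap <= 0.5 * shorter)
            ):
                cluster_end = (
                    contig,
                    max(end, hit.end),
                    min(cs, hit.consensus_start),
                    max(ce, hit.consensus_end),
                )
                continue
        count += 1
        cluster_end = (hit.contig_id, hit.end, hit.consensus_start, hit.consensus_end)
    return count


def best_match_table(hits_by_assembly: Mapping[str, Sequence[InsertionHit]]) -> pd.DataFrame:
    """Per assembly, the hit maximizing matched_length (ties: higher identity).

    Assemblies with no hits appear with zeros, mirroring how cross-species
    screens report best alignment length and similarity per genome.
    """
    rows = []
    for assembly_id in sorted(hits_by_assembly):
        hits = hits_by_assembly[assembly_id]
        if hits:
            best = max(hits, key=lambda h: (h.matched_length, h.identity))
            rows.append(
                {
                    "assembly_id": assembly_id,
                    "best_matched_length": best.matched_length,
                    "best_identity": best.identity,
                }
            )
        else:
            rows.append(
                {"assembly_id": assembly_id, "best_matched_length": 0, "best_identity": 0.0}
            )
    return pd.DataFrame(rows, columns=["assembly_id", "best_matched_length", "best_identity"])
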