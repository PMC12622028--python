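"""Small-RNA profiling against a TE consensus and the ping-pong signature.

piRNA-sized reads (23-29 nt by default) are placed on both strands of the
consensus with up to two mismatches; multi-mapping reads are shared
fractionally across placements. The ping-pong signature is the histogram of
5'-5' overlap offsets between sense and antisense hits: germline ping-pong
amplification enriches the 10 nt offset, summarized here as a z-score of
the offset-10 count against offsets 1..20.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .io_formats import SequenceRecord, reverse_complement

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}

MAX_OFFSET = 20


@dataclass
class SmallRnaHit:
    """One placement of a small RNA; five_prime is on consensus coordinates.

    For antisense hits the 5' end is the rightmost covered position. The
    weight is 1/(number of placements of that read).
    """

    read_id: str
    five_prime: int
    strand: str  # "sense" | "antisense"
    length: int
    weight: float = 1.0


@dataclass
class PingPongProfile:
    overlap_counts: np.ndarray  # weighted counts at offsets 1..MAX_OFFSET
    zscore_at_10: Optional[float]
    fraction_at_10: Optional[float]

    def count(self, offset: int) -> float:
        return float(self.overlap_counts[offset - 1])


def encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def map_small_rnas(
    reads: Iterable[SequenceRecord],
    consensus: SequenceRecord,
    min_len: int = 23,
    max_len: int = 29,
    max_mismatches: int = 2,
) -> list[SmallRnaHit]:
    """Place length-filtered reads at every position with <= max_mismatches.

    The scan is seed-free (all consensus windows are checked on both
    strands), which is exact and fast at consensus scale. N in either
    sequence never matches.
    """
    fwd = encode(consensus.residues)
    rev = encode(reverse_complement(consensus.residues))
    n = fwd.size
    windows: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    hits: list[SmallRnaHit] = []
    for read in reads:
        length = len(read.residues)
        if not min_len <= length <= max_len or length > n:
            continue
        if length not in windows:
            windows[length] = (
                np.lib.stride_tricks.sliding_window_view(fwd, length),
                np.lib.stride_tricks.sliding_window_view(rev, length),
            )
        wf, wr = windows[length]
        encoded = encode(read.residues)
        ambiguous = encoded == ord("N")
        sense_mm = ((wf != encoded) | (wf == ord("N")) | ambiguous).sum(axis=1)
        anti_mm = ((wr != encoded) | (wr == ord("N")) | ambiguous).sum(axis=1)
        sense_pos = np.nonzero(sense_mm <= max_mismatches)[0]
        anti_pos = np.nonzero(anti_mm <= max_mismatches)[0]
        total = sense_pos.size + anti_pos.size
        if total == 0:
            continue
        w = 1.0 / total
        for p in sense_pos:
            hits.append(SmallRnaHit(read.id, int(p), "sense", length, w))
        for p in anti_pos:
            # position p on the reverse strand corresponds to forward-strand
            # match interval [n-p-length, n-p); the antisense 5' end is its
            # rightmost base.
            hits.append(SmallRnaHit(read.id, n - int(p) - 1, "antisense", length, w))
    return hits


def strand_counts(hits: Sequence[SmallRnaHit], consensus_length: int) -> tuple[np.ndarray, np.ndarray]:
    """Weighted 5'-end counts per consensus position, (sense, antisense)."""
    sense = np.zeros(consensus_length)
    anti = np.zeros(consensus_length)
    for hit in hits:
        (sense if hit.strand == "sense" else anti)[hit.five_prime] += hit.weight
    return sense, anti


def ping_pong_signature(
    hits: Sequence[SmallRnaHit],
    consensus_length: Optional[int] = None,
) -> PingPongProfile:
    """Histogram of sense/antisense 5'-5' overlap offsets 1..20 plus z-score.

    An offset of o means the antisense 5' end sits o-1 positions downstream
    of a sense 5' end (overlap length o nt). Pair counts are products of
    the fractional weights, so doubling every read doubles counts but
    leaves the z-score unchanged. With an all-zero histogram or zero
    variance the z-score is undefined (None).
    """
    if consensus_length is None:
        consensus_length = max((h.five_prime for h in hits), default=0) + 1
    sense, anti = strand_counts(hits, consensus_length)
    counts = np.zeros(MAX_OFFSET)
    for o in range(1, MAX_OFFSET + 1):
        if consensus_length > o - 1:
            counts[o - 1] = float(np.dot(sense[: consensus_length - (o - 1)], anti[o - 1 :]))
    total = counts.sum()
    if total == 0:
        return PingPongProfile(counts, None, None)
    others = np.delete(counts, 9)
    sd = float(np.std(others, ddof=1))
    if sd == 0:
        # degenerate background: all signal at 10 is maximal, none is flat-zero
        z = float("inf") if counts[9] > others.mean() else None
    else:
        z = float((counts[9] - others.mean()) / sd)
    return PingPongProfile(counts, z, float(counts[9] / total))
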