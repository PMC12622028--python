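"""Family consensus construction and structural annotation of LTR elements.

Given a multiple alignment of insertions, ``majority_consensus`` produces an
ungapped family consensus; the annotation helpers then locate the hallmark
structure of an LTR retroelement: the terminal repeat pair, internal tandem
repeats (via a self dot plot), and long open reading frames (gag/pol/env
sized).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio.Seq import Seq

from .io_formats import MultipleAlignment, SequenceRecord, reverse_complement

logger = logging.getLogger(__name__)

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class LTRAnnotation:
    """A pair of terminal repeats on the consensus (0-based half-open)."""

    left_start: int
    left_end: int
    right_start: int
    right_end: int
    identity: float

    def __post_init__(self) -> None:
        if self.left_end - self.left_start != self.right_end - self.right_start:
            raise ValueError("LTR copies must have equal length")
        if self.left_end > self.right_start:
            raise ValueError("LTR copies overlap")

    @property
    def length(self) -> int:
        return self.left_end - self.left_start


@dataclass
class ORFAnnotation:
    start: int
    end: int
    strand: str
    frame: int
    product_label: str = ""

    @property
    def aa_length(self) -> int:
        return (self.end - self.start) // 3


@dataclass
class TandemRepeat:
    start: int
    end: int
    unit_length: int
    copy_count: int


@dataclass
class ElementModel:
    """A TE consensus with its structural annotation."""

    consensus: SequenceRecord
    ltrs: Optional[LTRAnnotation] = None
    orfs: list[ORFAnnotation] = field(default_factory=list)
    internal_repeats: list[TandemRepeat] = field(default_factory=list)


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------


def majority_consensus(msa: MultipleAlignment) -> SequenceRecord:
    """Majority-rule consensus; gap-majority columns are dropped.

    Per column the most frequent base among {A,C,G,T} wins (N never votes),
    with ties broken in alphabet order. A column where the gap strictly
    outnumbers the best base is omitted entirely, so presence/absence
    variants among insertions fall out of the consensus rather than
    padding it. Columns carrying only N/gap symbols emit N.
    """
    out: list[str] = []
    for i in range(msa.column_count):
        col = msa.column(i)
        counts = {b: 0 for b in "ACGT"}
        gaps = 0
        for c in col:
            if c in counts:
                counts[c] += 1
            elif c == "-":
                gaps += 1
        best = max("ACGT", key=lambda b: (counts[b], -ord(b)))
        if counts[best] == 0:
            if gaps == len(col):
                continue
            logger.warning("consensus column %d has only N/gap symbols; emitting N", i)
            out.append("N")
        elif gaps > counts[best]:
            continue
        else:
            out.append(best)
    return SequenceRecord("consensus", "".join(out))


def column_occupancy(msa: MultipleAlignment) -> list[float]:
    """Fraction of non-gap rows per alignment column (structural-variant view)."""
    n = len(msa.rows)
    return [
        sum(1 for c in msa.column(i) if c != "-") / n for i in range(msa.column_count)
    ]


# ---------------------------------------------------------------------------
# terminal repeats
# ---------------------------------------------------------------------------


def _anchored_extension(
    seq: str,
    i: int,
    j: int,
    k: int,
    min_identity: float,
    anchor: int = 10,
) -> tuple[int, int, int, int]:
    """Extend an exact seed (i..i+k vs j..j+k) outwards without gaps.

    A mismatch column is absorbed only when at least ``anchor - 1`` of the
    next ``anchor`` columns match and cumulative identity stays at or above
    the threshold; this pins the extension to the true repeat boundary
    instead of drifting into random flanking sequence. Returns
    (left_offset, right_offset, matches, length) where the repeat copies are
    seq[i-left : i+k+right] and seq[j-left : j+k+right].
    """
    thr = min_identity / 100.0

    def matches_ahead(a: int, b: int, step: int) -> int:
        got = 0
        for t in range(1, anchor + 1):
            x, y = a + step * t, b + step * t
            if not (0 <= x < len(seq) and 0 <= y < len(seq)):
                break
            if seq[x] == seq[y]:
                got += 1
        return got

    matches = k
    length = k
    right = 0
    a, b = i + k, j + k
    while b < len(seq) and a < j:  # keep copies disjoint
        if seq[a] == seq[b]:
            matches += 1
        elif matches_ahead(a, b, +1) < anchor - 1 or (matches / (length + 1)) < thr:
            break
        length += 1
        right += 1
        a += 1
        b += 1
    while right > 0 and seq[i + k + right - 1] != seq[j + k + right - 1]:
        right -= 1
        length -= 1
    left = 0
    a, b = i - 1, j - 1
    while a >= 0 and b >= i + k + right:
        if seq[a] == seq[b]:
            matches += 1
        elif matches_ahead(a, b, -1) < anchor - 1 or (matches / (length + 1)) < thr:
            break
        length += 1
        left += 1
        a -= 1
        b -= 1
    while left > 0 and seq[i - left] != seq[j - left]:
        left -= 1
        length -= 1
    matches = sum(
        1
        for t in range(length)
        if seq[i - left + t] == seq[j - left + t]
    )
    return left, right, matches, length


def detect_terminal_repeats(
    seq: SequenceRecord,
    min_length: int = 100,
    min_identity: float = 95.0,
    seed_k: int = 15,
) -> Optional[LTRAnnotation]:
    """Find the longest qualifying terminal repeat pair (both + strand).

    Seeds are exact k-mers shared between the first and last quarters of the
    sequence, extended without gaps under the anchored rule. Returns None if
    no pair of at least ``min_length`` with identity >= ``min_identity``
    exists.
    """
    s = seq.residues
    n = len(s)
    if n < 2 * min_length:
        return None
    head_end = max(n // 4, seed_k)
    tail_start = min(n - n // 4, n - seed_k)
    head_kmers: dict[str, list[int]] = {}
    for i in range(0, head_end - seed_k + 1):
        head_kmers.setdefault(s[i : i + seed_k], []).append(i)
    best: Optional[tuple[int, int, int, float]] = None  # (length, i, j, identity)
    seen_diagonals: set[int] = set()
    for j in range(tail_start, n - seed_k + 1):
        km = s[j : j + seed_k]
        for i in head_kmers.get(km, ()):
            diag = j - i
            if diag in seen_diagonals:
                continue
            seen_diagonals.add(diag)
            left, right, matches, length = _anchored_extension(
                s, i, j, seed_k, min_identity
            )
            identity = 100.0 * matches / length
            if length >= min_length and identity >= min_identity:
                cand = (length, i - left, j - left, identity)
                if best is None or (cand[0], -cand[1]) > (best[0], -best[1]):
                    best = cand
    if best is None:
        return None
    length, i0, j0, identity = best
    return LTRAnnotation(
        left_start=i0,
        left_end=i0 + length,
        right_start=j0,
        right_end=j0 + length,
        identity=identity,
    )


# ---------------------------------------------------------------------------
# self dot plot and tandem repeats
# ---------------------------------------------------------------------------


@dataclass
class DotPlotSegment:
    """A merged collinear run of exact k-mer self matches."""

    x_start: int
    x_end: int
    y_start: int
    y_end: int
    strand: str


@dataclass
class DotPlot:
    points: list[tuple[int, int, str]]
    segments: list[DotPlotSegment]
    repeats: list[TandemRepeat]


def self_dotplot(seq: SequenceRecord, k: int = 10) -> DotPlot:
    """Exact k-mer self matches (both strands) with the main diagonal removed.

    Collinear runs are merged into segments, and forward off-diagonal
    segments long enough to wrap their own offset are summarized as tandem
    repeats (unit_length = offset).
    """
    s = seq.residues
    if k > len(s):
        raise ValueError("k exceeds sequence length")
    positions: dict[str, list[int]] = {}
    for i in range(len(s) - k + 1):
        positions.setdefault(s[i : i + k], []).append(i)
    points: list[tuple[int, int, str]] = []
    for km, pos in positions.items():
        for x in pos:
            for y in pos:
                if x != y:
                    points.append((x, y, "+"))
            for y in positions.get(reverse_complement(km), ()):
                points.append((x, y, "-"))
    points.sort()

    segments: list[DotPlotSegment] = []
    fwd = sorted(
        ((y - x, x) for x, y, st in points if st == "+"),
    )
    run_start = None
    prev = None
    for diag, x in fwd:
        if prev is not None and diag == prev[0] and x == prev[1] + 1:
            prev = (diag, x)
            continue
        if run_start is not None:
            d0, x0 = run_start
            segments.append(
                DotPlotSegment(x0, prev[1] + k, x0 + d0, prev[1] + d0 + k, "+")
            )
        run_start = (diag, x)
        prev = (diag, x)
    if run_start is not None:
        d0, x0 = run_start
        segments.append(DotPlotSegment(x0, prev[1] + k, x0 + d0, prev[1] + d0 + k, "+"))
    rev = sorted(((x + y, x) for x, y, st in points if st == "-"))
    run_start = prev = None
    for anti, x in rev:
        if prev is not None and anti == prev[0] and x == prev[1] + 1:
            prev = (anti, x)
            continue
        if run_start is not None:
            a0, x0 = run_start
            segments.append(
                DotPlotSegment(x0, prev[1] + k, a0 - prev[1], a0 - x0 + k, "-")
            )
        run_start = (anti, x)
        prev = (anti, x)
    if run_start is not None:
        a0, x0 = run_start
        segments.append(DotPlotSegment(x0, prev[1] + k, a0 - prev[1], a0 - x0 + k, "-"))

    repeats: list[TandemRepeat] = []
    tandem = [
        seg
        for seg in segments
        if seg.strand == "+"
        and 0 < seg.y_start - seg.x_start
        and (seg.x_end - seg.x_start) >= (seg.y_start - seg.x_start)
    ]
    tandem.sort(key=lambda seg: (seg.x_start, seg.y_start - seg.x_start))
    for seg in tandem:
        unit = seg.y_start - seg.x_start
        start, end = seg.x_start, seg.y_end
        merged = False
        for rep in repeats:
            if start < rep.end and rep.start < end:
                rep_start = min(rep.start, start)
                rep_end = max(rep.end, end)
                rep_unit = min(rep.unit_length, unit)
                rep.start, rep.end, rep.unit_length = rep_start, rep_end, rep_unit
                rep.copy_count = round((rep_end - rep_start) / rep_unit)
                merged = True
                break
        if not merged:
            repeats.append(TandemRepeat(start, end, unit, round((end - start) / unit)))
    return DotPlot(points=points, segments=segments, repeats=repeats)


# ---------------------------------------------------------------------------
# open reading frames
# ---------------------------------------------------------------------------


def _scan_orfs_forward(s: str, min_aa: int) -> Iterable[tuple[int, int, int]]:
    """Yield (start, end, frame) for ATG..stop ORFs on the given strand."""
    for offset in range(3):
        start: Optional[int] = None
        for p in range(offset, len(s) - 2, 3):
            codon = s[p : p + 3]
            if codon in _STOPS:
                if start is not None and (p - start) // 3 >= min_aa:
                    yield start, p, offset + 1
                start = None
            elif codon == "ATG" and start is None:
                start = p


def find_orfs(
    seq: SequenceRecord,
    min_aa: int = 200,
    protein_db: Optional[Sequence[SequenceRecord]] = None,
    min_label_score: float = 50.0,
) -> list[ORFAnnotation]:
    """All six-frame ATG-to-stop ORFs of at least ``min_aa`` codons.

    Within each stop-to-stop interval the first ATG wins (maximal span); the
    stop codon is excluded from the reported coordinates. Coordinates are
    always on the forward strand of ``seq``. When ``protein_db`` is given,
    each ORF's translation is searched against it and the best-scoring
    protein id becomes the product label.
    """
    s = seq.residues
    n = len(s)
    orfs: list[ORFAnnotation] = []
    for start, end, frame in _scan_orfs_forward(s, min_aa):
        orfs.append(ORFAnnotation(start, end, "+", frame))
    rc = reverse_complement(s)
    for start, end, frame in _scan_orfs_forward(rc, min_aa):
        orfs.append(ORFAnnotation(n - end, n - start, "-", -frame))
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    if protein_db:
        from .readscan import make_protein_aligner

        aligner = make_protein_aligner()
        for orf in orfs:
            sub = s[orf.start : orf.end] if orf.strand == "+" else reverse_complement(
                s[orf.start : orf.end]
            )
            peptide = str(Seq(sub).translate())
            best_id, best_score = "", min_label_score
            for protein in protein_db:
                score = aligner.score(peptide, protein.residues)
                if score > best_score:
                    best_id, best_score = protein.id, score
            orf.product_label = best_id
    return orfs


def annotate_element(
    consensus: SequenceRecord,
    protein_db: Optional[Sequence[SequenceRecord]] = None,
    min_orf_aa: int = 200,
    ltr_min_length: int = 100,
    ltr_min_identity: float = 95.0,
    dotplot_k: int = 12,
) -> ElementModel:
    """Full structural annotation: LTR pair, ORFs, internal tandem repeats."""
    ltrs = detect_terminal_repeats(consensus, ltr_min_length, ltr_min_identity)
    orfs = find_orfs(consensus, min_orf_aa, protein_db)
    plot = self_dotplot(consensus, dotplot_k)
    internal = [
        rep
        for rep in plot.repeats
        if ltrs is None or (rep.start >= ltrs.left_end and rep.end <= ltrs.right_start)
    ]
    return ElementModel(consensus=consensus, ltrs=ltrs, orfs=orfs, internal_repeats=internal)
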