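"""Reference-absent TE discovery from short reads.

The discovery chain mirrors how a very recent transposable-element invasion
betrays itself in resequencing data: reads sampled from element copies that
are missing from the reference either fail to map or map with unusually high
divergence. Those reads are pulled out, cleaned of laboratory contaminants,
assembled, and screened against a TE protein library:

    select_candidate_reads -> filter_contaminants -> assemble_contigs
        -> search_te_proteins -> filter_te_candidates

Assembly is a unitig-only canonical de Bruijn graph (maximal unambiguous
paths after a k-mer coverage floor); the protein search is a six-frame
translated Smith-Waterman with BLOSUM62 and affine gaps. Both are small,
deterministic stand-ins for SPAdes/BLASTx-class tools: real deployments can
inject externally assembled contigs through the same candidate filters.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .io_formats import (
    ALIGNED_OPS,
    ReadAlignment,
    SequenceRecord,
    reverse_complement,
)

logger = logging.getLogger(__name__)

BLOSUM62 = substitution_matrices.load("BLOSUM62")

#: Gap of length L costs GAP_OPEN + L * GAP_EXTEND (existence/extension style).
GAP_OPEN = 11
GAP_EXTEND = 1


class DivergenceUndefinedError(ValueError):
    """Divergence requested for an unmapped read or one without NM."""


class MissingReadError(KeyError):
    """An alignment's query id is absent from the read store."""


@dataclass
class PipelineThresholds:
    """All numeric knobs of the discovery chain, in one auditable place.

    Defaults encode the published filter settings: reads with more than 5%
    divergence are candidates, and contigs are retained only with a protein
    hit above 80% identity spanning more than 250 nt.
    """

    max_divergence: float = 0.05
    min_protein_identity: float = 80.0
    min_alignment_span_nt: int = 250
    assembler_k: int = 31
    assembler_min_kmer_coverage: int = 2
    #: raise the coverage floor to the first valley of the k-mer count
    #: histogram when one exists (solid-k-mer error thresholding); the
    #: valley only exists when an error slope is present, so clean
    #: low-coverage data keeps the base floor.
    assembler_auto_floor: bool = True
    contaminant_k: int = 31
    contaminant_hit_fraction: float = 0.5
    #: optional extra rule: treat reads with >= this fraction of soft-clipped
    #: bases as poorly mapped; disabled (None) by default.
    min_softclip_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0 < self.max_divergence < 1:
            raise ValueError("max_divergence must be in (0,1)")
        if not 0 < self.min_protein_identity <= 100:
            raise ValueError("min_protein_identity must be in (0,100]")
        for k in (self.assembler_k, self.contaminant_k):
            if k < 11 or k % 2 == 0:
                raise ValueError("k values must be odd and >= 11")


# ---------------------------------------------------------------------------
# divergence filter
# ---------------------------------------------------------------------------


def alignment_divergence(read: ReadAlignment) -> float:
    """Edit distance over aligned-plus-indel bases (M,=,X,I,D); clips excluded."""
    if not read.is_mapped:
        raise DivergenceUndefinedError(f"read {read.query_id!r} is unmapped")
    if read.edit_distance is None:
        raise DivergenceUndefinedError(f"read {read.query_id!r} lacks an NM tag")
    denom = sum(n for op, n in read.cigar if op in ALIGNED_OPS)
    if denom == 0:
        raise DivergenceUndefinedError(f"read {read.query_id!r} aligns zero bases")
    return read.edit_distance / denom


def _softclip_fraction(read: ReadAlignment) -> float:
    clipped = sum(n for op, n in read.cigar if op == "S")
    total = read.query_span
    return clipped / total if total else 0.0


def select_candidate_reads(
    alignments: Iterable[ReadAlignment],
    reads: Mapping[str, SequenceRecord],
    thresholds: PipelineThresholds,
) -> Iterator[SequenceRecord]:
    """Emit each unmapped or highly diverged read once.

    A mapped read is selected iff its divergence strictly exceeds
    ``max_divergence`` ("more than 5%"); secondary/supplementary records are
    ignored, and mapped reads lacking an NM tag are conservatively kept with
    the reference (not emitted).
    """
    emitted: set[str] = set()
    for aln in alignments:
        if aln.is_secondary or aln.is_supplementary or aln.query_id in emitted:
            continue
        take = False
        if not aln.is_mapped:
            take = True
        elif aln.edit_distance is not None and alignment_divergence(aln) > thresholds.max_divergence:
            take = True
        elif (
            thresholds.min_softclip_fraction is not None
            and _softclip_fraction(aln) >= thresholds.min_softclip_fraction
        ):
            take = True
        if take:
            if aln.query_id not in reads:
                raise MissingReadError(aln.query_id)
            emitted.add(aln.query_id)
            yield reads[aln.query_id]


# ---------------------------------------------------------------------------
# contaminant filter
# ---------------------------------------------------------------------------


def canonical_kmer(kmer: str) -> str:
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def _kmers(seq: str, k: int) -> Iterator[str]:
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if "N" not in km:
            yield canonical_kmer(km)


@dataclass
class ContaminantIndex:
    """Canonical k-mer membership over known contaminant genomes."""

    k: int
    kmer_set: set[str] = field(default_factory=set)
    source_labels: list[str] = field(default_factory=list)

    @classmethod
    def build(cls, genomes: Iterable[SequenceRecord], k: int = 31) -> "ContaminantIndex":
        idx = cls(k=k)
        for g in genomes:
            idx.source_labels.append(g.id)
            idx.kmer_set.update(_kmers(g.residues, k))
        return idx

    def hit_fraction(self, seq: str) -> float:
        kmers = list(_kmers(seq, self.k))
        if not kmers:
            return 0.0
        hits = sum(1 for km in kmers if km in self.kmer_set)
        return hits / len(kmers)


def filter_contaminants(
    reads: Iterable[SequenceRecord],
    index: ContaminantIndex,
    thresholds: PipelineThresholds,
) -> Iterator[SequenceRecord]:
    """Drop reads whose canonical k-mer hit fraction reaches the threshold.

    Reads shorter than k carry no k-mers and pass through.
    """
    for read in reads:
        if len(read.residues) < index.k:
            yield read
        elif index.hit_fraction(read.residues) < thresholds.contaminant_hit_fraction:
            yield read


# ---------------------------------------------------------------------------
# de Bruijn unitig assembly
# ---------------------------------------------------------------------------


def solid_kmer_floor(counts: Counter, cap: int = 200) -> int:
    """First valley of the k-mer count histogram, or 2 when none exists.

    Sequencing errors produce a steep descending slope at low counts while
    genuine sequence forms a peak near the true coverage; the valley
    between them is the classic solid-k-mer cutoff. When the histogram is
    not descending at count 2 there is no error slope to cut away.
    """
    if not counts:
        return 2
    hist: Counter[int] = Counter()
    for c in counts.values():
        hist[min(c, cap)] += 1
    if hist[1] <= hist[2]:  # no descending error slope at the base
        return 2
    for c in range(2, cap):
        if hist[c] <= hist[c + 1]:
            return c
    return 2


def assemble_contigs(
    reads: Iterable[SequenceRecord],
    thresholds: PipelineThresholds,
) -> list[SequenceRecord]:
    """Assemble unitigs from the canonical de Bruijn graph of the reads.

    k-mers below the coverage floor are removed first. The floor is the
    configured minimum, optionally raised to the first valley of the
    count histogram (see :func:`solid_kmer_floor`): at high redundancy the
    same sequencing error recurs and would otherwise survive a fixed
    floor and shatter the graph. Maximal unambiguous paths are then walked
    out; contigs shorter than 2k are dropped, contig orientation is
    canonicalized, and output order is deterministic (length descending,
    then sequence).
    """
    k = thresholds.assembler_k
    counts: Counter[str] = Counter()
    for read in reads:
        counts.update(_kmers(read.residues, k))
    floor = thresholds.assembler_min_kmer_coverage
    if thresholds.assembler_auto_floor:
        floor = max(floor, solid_kmer_floor(counts))
    kmers = {km for km, c in counts.items() if c >= floor}

    def fwd(node: str) -> list[str]:
        suffix = node[1:]
        return [suffix + b for b in "ACGT" if canonical_kmer(suffix + b) in kmers]

    def bwd(node: str) -> list[str]:
        prefix = node[:-1]
        return [b + prefix for b in "ACGT" if canonical_kmer(b + prefix) in kmers]

    visited: set[str] = set()
    raw: list[str] = []
    for start in sorted(kmers):
        if start in visited:
            continue
        visited.add(start)
        seq = start
        cur = start
        while True:  # extend right
            nxt = fwd(cur)
            if len(nxt) != 1 or len(bwd(nxt[0])) != 1:
                break
            cn = canonical_kmer(nxt[0])
            if cn in visited:
                break
            visited.add(cn)
            seq += nxt[0][-1]
            cur = nxt[0]
        cur = start
        while True:  # extend left
            prv = bwd(cur)
            if len(prv) != 1 or len(fwd(prv[0])) != 1:
                break
            cn = canonical_kmer(prv[0])
            if cn in visited:
                break
            visited.add(cn)
            seq = prv[0][0] + seq
            cur = prv[0]
        if len(seq) >= 2 * k:
            raw.append(min(seq, reverse_complement(seq)))

    raw.sort(key=lambda s: (-len(s), s))
    return [SequenceRecord(f"contig_{i + 1}", s) for i, s in enumerate(raw)]


def count_supporting_reads(
    contigs: Sequence[SequenceRecord],
    reads: Iterable[SequenceRecord],
    k: int,
) -> dict[str, int]:
    """Number of reads sharing at least one canonical k-mer with each contig."""
    kmer_to_contigs: dict[str, set[str]] = {}
    for contig in contigs:
        for km in _kmers(contig.residues, k):
            kmer_to_contigs.setdefault(km, set()).add(contig.id)
    support: dict[str, int] = {c.id: 0 for c in contigs}
    for read in reads:
        seen: set[str] = set()
        for km in _kmers(read.residues, k):
            seen.update(kmer_to_contigs.get(km, ()))
        for cid in seen:
            support[cid] += 1
    return support


# ---------------------------------------------------------------------------
# translated protein search
# ---------------------------------------------------------------------------


@dataclass
class ProteinHit:
    """One local alignment of a translated contig frame to a library protein."""

    contig_id: str
    protein_id: str
    identity: float
    span_nt: int
    frame: int
    score: float


@dataclass
class CandidateContig:
    contig: SequenceRecord
    supporting_read_count: int
    best_hit: str
    identity: float
    span_nt: int
    frame: int
    score: float


def make_protein_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = BLOSUM62
    aligner.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner


def six_frame_peptides(seq: str) -> Iterator[tuple[int, str]]:
    """Yield (frame, peptide) for stop-split translations of all six frames."""
    for strand, s in ((1, seq), (-1, reverse_complement(seq))):
        for offset in range(3):
            frame = strand * (offset + 1)
            sub = s[offset : offset + 3 * ((len(s) - offset) // 3)]
            if not sub:
                continue
            translation = str(Seq(sub).translate())
            for pep in translation.split("*"):
                if pep:
                    yield frame, pep


def _alignment_stats(alignment) -> tuple[int, int, int]:
    """(matches, columns, aligned query residues) of a PairwiseAligner hit."""
    qa, ta = alignment.aligned
    query, target = alignment.sequences
    matches = 0
    q_res = 0
    columns = 0
    prev_q = prev_t = None
    for (qs, qe), (ts, te) in zip(qa, ta):
        if prev_q is not None:
            columns += (qs - prev_q) + (ts - prev_t)
        matches += sum(1 for a, b in zip(query[qs:qe], target[ts:te]) if a == b)
        q_res += qe - qs
        columns += qe - qs
        prev_q, prev_t = qe, te
    return matches, columns, q_res


def search_te_proteins(
    contigs: Iterable[SequenceRecord],
    protein_db: Sequence[SequenceRecord],
    min_score: float = 50.0,
    min_peptide_aa: int = 15,
) -> list[ProteinHit]:
    """Six-frame translated local search of contigs against a protein library.

    Scoring is BLOSUM62 with affine gaps (gap of length L costs
    ``GAP_OPEN + L * GAP_EXTEND``); identity is matched residues over
    alignment columns, span is 3x the aligned query residues. All hits at or
    above ``min_score`` are returned; use :func:`best_hits_per_contig` to
    reduce to one hit per contig.
    """
    if not protein_db:
        raise ValueError("protein database is empty")
    aligner = make_protein_aligner()
    hits: list[ProteinHit] = []
    for contig in contigs:
        if len(contig.residues) < 3:
            logger.warning("contig %s shorter than 3 nt; skipped", contig.id)
            continue
        for frame, peptide in six_frame_peptides(contig.residues):
            if len(peptide) < min_peptide_aa:
                continue
            for protein in protein_db:
                score = aligner.score(peptide, protein.residues)
                if score < min_score:
                    continue
                alignment = aligner.align(peptide, protein.residues)[0]
                matches, columns, q_res = _alignment_stats(alignment)
                hits.append(
                    ProteinHit(
                        contig_id=contig.id,
                        protein_id=protein.id,
                        identity=100.0 * matches / columns if columns else 0.0,
                        span_nt=3 * q_res,
                        frame=frame,
                        score=float(score),
                    )
                )
    hits.sort(key=lambda h: (-h.score, h.contig_id, h.protein_id, h.frame))
    return hits


def best_hits_per_contig(hits: Iterable[ProteinHit]) -> dict[str, ProteinHit]:
    best: dict[str, ProteinHit] = {}
    for hit in hits:
        cur = best.get(hit.contig_id)
        if (
            cur is None
            or hit.score > cur.score
            or (hit.score == cur.score and hit.protein_id < cur.protein_id)
        ):
            best[hit.contig_id] = hit
    return best


def filter_te_candidates(
    hits: Sequence[ProteinHit],
    thresholds: PipelineThresholds,
    contigs: Optional[Mapping[str, SequenceRecord]] = None,
    support: Optional[Mapping[str, int]] = None,
) -> list[CandidateContig]:
    """Retain contigs whose best passing hit exceeds both filters strictly.

    Identity must be > ``min_protein_identity`` and nucleotide span
    > ``min_alignment_span_nt`` (both strict, mirroring the published
    "> 80%" / "> 250 bp" wording). Output sorted by score descending, then
    contig id.
    """
    passing = [
        h
        for h in hits
        if h.identity > thresholds.min_protein_identity
        and h.span_nt > thresholds.min_alignment_span_nt
    ]
    best = best_hits_per_contig(passing)
    candidates = []
    for cid, hit in best.items():
        contig = (contigs or {}).get(cid) or SequenceRecord(cid, "N")
        candidates.append(
            CandidateContig(
                contig=contig,
                supporting_read_count=(support or {}).get(cid, 0),
                best_hit=hit.protein_id,
                identity=hit.identity,
                span_nt=hit.span_nt,
                frame=hit.frame,
                score=hit.score,
            )
        )
    candidates.sort(key=lambda c: (-c.score, c.contig.id))
    return candidates
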