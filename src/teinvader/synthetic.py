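"""Synthetic data with exact ground truth for every pipeline stage.

Everything downstream — discovery, copy number, timeline, piRNA profiling,
assembly screening — can be exercised on data generated here: genomes with
planted TE copies at known coordinates and divergence, sequencing reads
with a truth alignment against a caller-designated reference, small-RNA
libraries with a controllable ping-pong fraction, and sample cohorts with a
programmed invasion schedule. All generators are seed-deterministic, and
truth is produced by exact bookkeeping rather than by running an aligner.

The model element built by :func:`make_test_element` mirrors the structure
of an insect endogenous retrovirus: two identical long terminal repeats, an
internal low-complexity tandem repeat in the 5' non-coding region, and
gag / pol / env open reading frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io_formats import ReadAlignment, SequenceRecord, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in {"TAA", "TAG", "TGA"}
]


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


# ---------------------------------------------------------------------------
# genomes and mutation
# ---------------------------------------------------------------------------


def simulate_genome(
    length: int,
    gc_fraction: float = 0.42,
    seed: int = 0,
    name: str = "genome",
) -> SequenceRecord:
    """i.i.d. random DNA at the stated GC content (Drosophila-like default)."""
    rng = np.random.default_rng(seed)
    p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    codes = rng.choice(4, size=length, p=p)
    return SequenceRecord(name, _decode(codes.astype(np.uint8)))


def mutate_sequence(seq: str, divergence: float, rng: np.random.Generator) -> tuple[str, int]:
    """Substitution-only mutation at the given per-base rate; returns count."""
    codes = _encode(seq)
    mask = rng.random(codes.size) < divergence
    n = int(mask.sum())
    if n:
        codes = codes.copy()
        codes[mask] = (codes[mask] + rng.integers(1, 4, size=n)) % 4
    return _decode(codes), n


# ---------------------------------------------------------------------------
# the model LTR retroelement
# ---------------------------------------------------------------------------


@dataclass
class ElementTruth:
    """A synthetic LTR retroelement and the ground truth of its structure."""

    element: SequenceRecord
    ltr_length: int
    repeat_region: tuple[int, int, int, int]  # start, end, unit_length, copies
    orf_coords: dict[str, tuple[int, int]]  # name -> (start, end) on + strand
    proteins: dict[str, SequenceRecord]  # name -> amino-acid record


def _random_orf(rng: np.random.Generator, aa: int) -> tuple[str, str]:
    """(nucleotide ORF incl. stop, protein) of ``aa`` codons starting at ATG."""
    body = "".join(rng.choice(_SENSE_CODONS, size=aa - 1))
    stop = str(rng.choice(["TAA", "TAG", "TGA"]))
    nt = "ATG" + body + stop
    protein = str(Seq("ATG" + body).translate())
    return nt, protein


def make_test_element(
    seed: int = 0,
    ltr_length: int = 514,
    utr5_length: int = 400,
    repeat_unit: int = 270,
    repeat_copies: int = 3,
    gag_aa: int = 400,
    pol_aa: int = 1100,
    env_aa: int = 450,
    utr3_length: int = 200,
    name: str = "synthetic_erv",
) -> ElementTruth:
    """Build an iERV-like element: LTR pair, 5' tandem repeat, gag/pol/env.

    Defaults give an element of roughly 8.4 kb with 514 bp identical LTRs,
    the size class of a full-length errantivirus.
    """
    rng = np.random.default_rng(seed)

    def rand(n: int) -> str:
        return _decode(rng.integers(0, 4, size=n).astype(np.uint8))

    ltr = rand(ltr_length)
    utr5 = rand(utr5_length)
    unit = rand(repeat_unit)
    repeat = unit * repeat_copies
    spacer1, spacer2 = rand(50), rand(50)
    parts: list[str] = [ltr, utr5, repeat]
    orf_coords: dict[str, tuple[int, int]] = {}
    proteins: dict[str, SequenceRecord] = {}
    pos = sum(len(p) for p in parts)
    for orf_name, aa in (("gag", gag_aa), ("pol", pol_aa), ("env", env_aa)):
        nt, protein = _random_orf(rng, aa)
        orf_coords[orf_name] = (pos, pos + len(nt) - 3)  # stop codon excluded
        proteins[orf_name] = SequenceRecord(orf_name, protein)
        parts.append(nt)
        pos += len(nt)
        if orf_name != "env":
            parts.append(spacer1 if orf_name == "gag" else spacer2)
            pos += 50
    parts.append(rand(utr3_length))
    parts.append(ltr)
    seq = "".join(parts)
    repeat_start = ltr_length + utr5_length
    return ElementTruth(
        element=SequenceRecord(name, seq),
        ltr_length=ltr_length,
        repeat_region=(repeat_start, repeat_start + len(repeat), repeat_unit, repeat_copies),
        orf_coords=orf_coords,
        proteins=proteins,
    )


# ---------------------------------------------------------------------------
# planting copies
# ---------------------------------------------------------------------------


@dataclass
class TePlantingSpec:
    te_sequence: SequenceRecord
    copy_count: int = 5
    per_copy_divergence: float = 0.0
    include_ltrs: bool = True
    fragment_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0 <= self.per_copy_divergence <= 0.2:
            raise ValueError("per_copy_divergence must be in [0, 0.2]")
        if self.copy_count < 0:
            raise ValueError("copy_count must be >= 0")


@dataclass
class Segment:
    """Maps fragment interval [start, end) onto reference ``ref_id`` at
    ``ref_start`` (same strand, same length)."""

    start: int
    end: int
    ref_id: str
    ref_start: int


@dataclass
class Fragment:
    name: str
    sequence: str
    segments: list[Segment] = field(default_factory=list)


@dataclass
class PlantResult:
    genome: SequenceRecord
    truth: pd.DataFrame  # copy_id, start, end, source_start, source_end, divergence, n_substitutions
    reference_segments: list[Segment]  # unmodified stretches -> input genome
    te_segments: list[Segment]  # planted copies -> TE coordinates


def plant_te_copies(
    genome: SequenceRecord,
    spec: TePlantingSpec,
    seed: int = 0,
    min_spacing: int = 2000,
) -> PlantResult:
    """Insert independently mutated element copies at spaced random sites.

    The truth table records exact coordinates (on the modified genome) and
    realized substitution counts; segment maps expose, for the read
    simulator, which stretches of the new genome still correspond to the
    original reference and which correspond to element coordinates.
    """
    rng = np.random.default_rng(seed)
    length = len(genome.residues)
    te = spec.te_sequence.residues
    src_start, src_end = 0, len(te)
    if spec.fragment_fraction is not None:
        span = int(len(te) * spec.fragment_fraction)
        src_start = (len(te) - span) // 2
        src_end = src_start + span
    insert_template = te[src_start:src_end]

    sites: list[int] = []
    guard = 0
    while len(sites) < spec.copy_count:
        cand = int(rng.integers(0, length + 1))
        if all(abs(cand - s) >= min_spacing for s in sites):
            sites.append(cand)
        guard += 1
        if guard > 100000:
            raise ValueError("cannot place copies with the requested spacing")
    sites.sort()

    pieces: list[str] = []
    ref_segments: list[Segment] = []
    te_segments: list[Segment] = []
    rows = []
    cursor = 0
    out_pos = 0
    for idx, site in enumerate(sites):
        chunk = genome.residues[cursor:site]
        if chunk:
            ref_segments.append(Segment(out_pos, out_pos + len(chunk), genome.id, cursor))
        pieces.append(chunk)
        out_pos += len(chunk)
        mutated, n_subs = mutate_sequence(insert_template, spec.per_copy_divergence, rng)
        pieces.append(mutated)
        te_segments.append(
            Segment(out_pos, out_pos + len(mutated), spec.te_sequence.id, src_start)
        )
        rows.append(
            {
                "copy_id": idx,
                "start": out_pos,
                "end": out_pos + len(mutated),
                "source_start": src_start,
                "source_end": src_end,
                "divergence": spec.per_copy_divergence,
                "n_substitutions": n_subs,
            }
        )
        out_pos += len(mutated)
        cursor = site
    tail = genome.residues[cursor:]
    if tail:
        ref_segments.append(Segment(out_pos, out_pos + len(tail), genome.id, cursor))
    pieces.append(tail)
    new_genome = SequenceRecord(genome.id + "_sample", "".join(pieces), genome.description)
    columns = [
        "copy_id", "start", "end", "source_start", "source_end",
        "divergence", "n_substitutions",
    ]
    return PlantResult(new_genome, pd.DataFrame(rows, columns=columns), ref_segments, te_segments)


# ---------------------------------------------------------------------------
# short reads with a truth alignment
# ---------------------------------------------------------------------------


def simulate_reads(
    fragments: Sequence[Fragment],
    reference: dict[str, str],
    coverage: float = 20.0,
    read_length: int = 100,
    error_rate: float = 0.005,
    seed: int = 0,
    id_prefix: str = "read",
) -> tuple[list[SequenceRecord], list[ReadAlignment]]:
    """Uniform single-end reads plus their truth alignment to ``reference``.

    A read is mapped iff it falls entirely within a single segment of its
    source fragment; its CIGAR is then all-M at the mapped position with NM
    equal to the actual mismatch count against the reference (copy
    divergence plus sequencing errors). Reads touching inserted sequence
    that has no reference counterpart come out unmapped — exactly what a
    reference-absent invasion looks like. Read count per fragment is
    deterministic: round(coverage * length / read_length).
    """
    rng = np.random.default_rng(seed)
    ref_codes = {rid: _encode(seq) for rid, seq in reference.items()}
    reads: list[SequenceRecord] = []
    alignments: list[ReadAlignment] = []
    counter = 0
    for frag in fragments:
        codes = _encode(frag.sequence)
        n_positions = codes.size - read_length + 1
        if n_positions <= 0:
            continue
        n_reads = int(round(coverage * codes.size / read_length))
        starts = rng.integers(0, n_positions, size=n_reads)
        strands = rng.random(n_reads) < 0.5
        offsets = np.arange(read_length)
        windows = codes[starts[:, None] + offsets]
        err_mask = rng.random(windows.shape) < error_rate
        n_err = int(err_mask.sum())
        if n_err:
            windows = windows.copy()
            windows[err_mask] = (windows[err_mask] + rng.integers(1, 4, size=n_err)) % 4
        seg_starts = np.array([s.start for s in frag.segments], dtype=np.int64)
        for i in range(n_reads):
            start = int(starts[i])
            counter += 1
            rid = f"{id_prefix}{counter}"
            fwd_codes = windows[i]
            minus = bool(strands[i])
            read_codes = (3 - fwd_codes[::-1]) if minus else fwd_codes
            reads.append(
                SequenceRecord(rid, _decode(read_codes), quality=[40] * read_length)
            )
            seg = None
            if seg_starts.size:
                j = int(np.searchsorted(seg_starts, start, side="right")) - 1
                if j >= 0:
                    cand = frag.segments[j]
                    if start >= cand.start and start + read_length <= cand.end:
                        seg = cand
            if seg is None:
                alignments.append(
                    ReadAlignment(rid, None, None, "+", [], None, False, seq=_decode(read_codes))
                )
            else:
                ref_pos = seg.ref_start + (start - seg.start)
                ref_window = ref_codes[seg.ref_id][ref_pos : ref_pos + read_length]
                nm = int((fwd_codes != ref_window).sum())
                alignments.append(
                    ReadAlignment(
                        rid,
                        seg.ref_id,
                        ref_pos,
                        "-" if minus else "+",
                        [("M", read_length)],
                        nm,
                        True,
                        seq=_decode(read_codes),
                    )
                )
    return reads, alignments


# ---------------------------------------------------------------------------
# composite scenarios
# ---------------------------------------------------------------------------


@dataclass
class InvasionSample:
    """A discovery scenario: reference, invaded sample genome, reads, truth."""

    reference: SequenceRecord
    sample_genome: SequenceRecord
    reads: list[SequenceRecord]
    alignments: list[ReadAlignment]
    truth: pd.DataFrame


def simulate_invasion_sample(
    element: SequenceRecord,
    reference_length: int = 100_000,
    copy_count: int = 5,
    coverage: float = 20.0,
    read_length: int = 100,
    error_rate: float = 0.01,
    per_copy_divergence: float = 0.0,
    seed: int = 0,
) -> InvasionSample:
    """Reference genome + sample genome carrying planted copies + reads.

    The truth alignment is computed against the *reference*, so reads from
    the planted element are unmapped, feeding the discovery filters.
    """
    reference = simulate_genome(reference_length, seed=seed, name="ref")
    spec = TePlantingSpec(te_sequence=element, copy_count=copy_count,
                          per_copy_divergence=per_copy_divergence)
    planted = plant_te_copies(reference, spec, seed=seed + 1)
    frag = Fragment("sample", planted.genome.residues, planted.reference_segments)
    reads, alignments = simulate_reads(
        [frag],
        {reference.id: reference.residues},
        coverage=coverage,
        read_length=read_length,
        error_rate=error_rate,
        seed=seed + 2,
    )
    return InvasionSample(reference, planted.genome, reads, alignments, planted.truth)


def simulate_copy_number_dataset(
    element: SequenceRecord,
    copy_count: int,
    coverage: float = 30.0,
    read_length: int = 100,
    error_rate: float = 0.005,
    per_copy_divergence: float = 0.0,
    scg_length: int = 3000,
    n_scg: int = 3,
    seed: int = 0,
) -> tuple[list[ReadAlignment], str, int, dict[str, int]]:
    """Reads mapped to a TE-consensus + single-copy-gene database.

    The sample genome holds ``copy_count`` element copies and one copy of
    each single-copy gene; ``coverage`` is the per-haploid-copy depth, so
    the expected normalized TE depth equals ``copy_count``. Returns
    (alignments, te_id, te_length, scg_lengths).
    """
    rng = np.random.default_rng(seed)
    fragments: list[Fragment] = []
    reference: dict[str, str] = {element.id: element.residues}
    for c in range(copy_count):
        mutated, _ = mutate_sequence(element.residues, per_copy_divergence, rng)
        fragments.append(
            Fragment(f"copy{c}", mutated, [Segment(0, len(mutated), element.id, 0)])
        )
    scg_lengths: dict[str, int] = {}
    for g in range(n_scg):
        scg = simulate_genome(scg_length, seed=seed + 100 + g, name=f"scg{g}")
        reference[scg.id] = scg.residues
        scg_lengths[scg.id] = scg_length
        fragments.append(
            Fragment(scg.id, scg.residues, [Segment(0, scg_length, scg.id, 0)])
        )
    _, alignments = simulate_reads(
        fragments, reference, coverage=coverage, read_length=read_length,
        error_rate=error_rate, seed=seed + 1,
    )
    return alignments, element.id, len(element.residues), scg_lengths


# ---------------------------------------------------------------------------
# small RNAs
# ---------------------------------------------------------------------------


def simulate_small_rnas(
    consensus: SequenceRecord,
    n_pairs: int = 500,
    pingpong_fraction: float = 0.0,
    length_range: tuple[int, int] = (23, 29),
    seed: int = 0,
) -> list[SequenceRecord]:
    """Sense/antisense piRNA-sized reads with a planted ping-pong fraction.

    ``n_pairs`` antisense reads are placed uniformly; each of a fraction
    ``pingpong_fraction`` of them gets a sense partner whose 5'-5' overlap
    is exactly 10 nt, the remaining sense reads are placed uniformly.
    """
    rng = np.random.default_rng(seed)
    seq = consensus.residues
    n = len(seq)
    lo, hi = length_range
    reads: list[SequenceRecord] = []
    for i in range(n_pairs):
        la = int(rng.integers(lo, hi + 1))
        # antisense 5' end a (forward coordinate); keep room for a partner
        a = int(rng.integers(hi + 9, n - hi))
        reads.append(
            SequenceRecord(f"srna{i}_a", reverse_complement(seq[a - la + 1 : a + 1]))
        )
        ls = int(rng.integers(lo, hi + 1))
        if rng.random() < pingpong_fraction:
            s = a - 9  # 5'-5' overlap of exactly 10 nt
        else:
            s = int(rng.integers(0, n - ls + 1))
        reads.append(SequenceRecord(f"srna{i}_s", seq[s : s + ls]))
    return reads


# ---------------------------------------------------------------------------
# invasion cohorts
# ---------------------------------------------------------------------------


@dataclass
class InvasionScenario:
    origin_year: int
    origin_region: str
    arrival_year: dict[str, int]
    logistic_rate: dict[str, float]
    sampling_plan: list[tuple[int, str, int]]  # (year, region, n_samples)

    def __post_init__(self) -> None:
        if self.origin_region not in self.arrival_year:
            raise ValueError("origin region must have an arrival year")
        for region, year in self.arrival_year.items():
            if year < self.origin_year:
                raise ValueError(f"{region} arrives before the origin year")


def simulate_invasion_cohort(
    scenario: InvasionScenario,
    seed: int = 0,
) -> tuple[list, pd.DataFrame]:
    """Sample cohort with logistic regional spread; returns (meta, truth).

    Each sampled individual is element-positive with probability
    ``1 / (1 + exp(-rate * (year - arrival_year)))`` in its region, and 0
    strictly before arrival (probability 0.5 in the arrival year itself).
    """
    from .invasion_timeline import SampleMeta

    rng = np.random.default_rng(seed)
    meta: list[SampleMeta] = []
    rows = []
    counter = 0
    for year, region, n in scenario.sampling_plan:
        arrival = scenario.arrival_year.get(region)
        rate = scenario.logistic_rate.get(region, 1.0)
        for _ in range(n):
            counter += 1
            sid = f"s{counter:04d}"
            if arrival is None or year < arrival:
                p = 0.0
            else:
                p = 1.0 / (1.0 + np.exp(-rate * (year - arrival)))
            present = bool(rng.random() < p)
            meta.append(SampleMeta(sid, year, region, source="simulated"))
            rows.append({"sample_id": sid, "year": year, "region": region, "present": present})
    return meta, pd.DataFrame(rows)
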