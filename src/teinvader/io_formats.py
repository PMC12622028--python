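"""Readers and writers for the plain-text sequence formats used throughout.

FASTA/FASTQ parsing is delegated to Biopython. SAM records are parsed
directly, because headerless SAM fragments must be accepted and only the
11 mandatory columns plus the ``NM`` tag are consumed.

All internal coordinates are 0-based half-open; conversion to the 1-based
closed conventions of SAM and GFF3 happens only at the I/O boundary.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, TextIO, Union

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

PathLike = Union[str, Path]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: CIGAR operations that consume the query sequence.
QUERY_OPS = frozenset("MIS=X")
#: CIGAR operations that consume the reference.
REFERENCE_OPS = frozenset("MD=X")
#: Operations entering the divergence denominator (aligned + indel bases).
ALIGNED_OPS = frozenset("MID=X")

_CIGAR_TOKEN = re.compile(r"(\d+)([MIDNSHP=X])")


class FormatError(ValueError):
    """Raised for malformed input files."""


class CigarError(FormatError):
    """Raised for CIGAR strings violating the SAM grammar."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SequenceRecord:
    """A named sequence, optionally with per-residue phred qualities."""

    id: str
    residues: str
    description: str = ""
    quality: Optional[Sequence[int]] = None

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"sequence id must be non-empty without whitespace: {self.id!r}")
        if len(self.residues) < 1:
            raise ValueError(f"empty sequence for record {self.id!r}")
        if self.quality is not None and len(self.quality) != len(self.residues):
            raise FormatError(
                f"record {self.id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.residues)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self, new_id: Optional[str] = None) -> "SequenceRecord":
        qual = list(self.quality)[::-1] if self.quality is not None else None
        return SequenceRecord(new_id or self.id, reverse_complement(self.residues),
                              self.description, qual)


@dataclass
class ReadAlignment:
    """One SAM record reduced to the fields the pipeline consumes.

    ``position`` is the 0-based leftmost reference coordinate (converted
    from SAM's 1-based POS); ``edit_distance`` is the NM-style count of
    mismatched plus inserted plus deleted bases, or ``None`` when the NM
    tag is absent.
    """

    query_id: str
    reference_id: Optional[str]
    position: Optional[int]
    strand: str
    cigar: list[tuple[str, int]]
    edit_distance: Optional[int]
    is_mapped: bool
    is_secondary: bool = False
    is_supplementary: bool = False
    seq: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.is_mapped and self.cigar:
            raise ValueError(f"unmapped read {self.query_id!r} must carry no CIGAR")

    @property
    def query_span(self) -> int:
        return cigar_query_span(self.cigar)

    @property
    def reference_span(self) -> int:
        return cigar_reference_span(self.cigar)


@dataclass
class MultipleAlignment:
    """Rows of equal-length gapped sequences over {A,C,G,T,N,-}."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("a multiple alignment needs at least 2 rows")
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) != 1:
            raise FormatError(f"alignment rows have unequal lengths: {sorted(lengths)}")

    @property
    def column_count(self) -> int:
        return len(self.rows[0][1])

    def column(self, i: int) -> list[str]:
        return [s[i] for _, s in self.rows]


@dataclass
class GffFeature:
    """One GFF3 feature; start/end are internal 0-based half-open."""

    seqid: str
    type: str
    start: int
    end: int
    strand: str = "."
    source: str = "teinvader"
    score: Optional[float] = None
    attributes: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# CIGAR arithmetic
# ---------------------------------------------------------------------------


def parse_cigar(cigar_text: str) -> list[tuple[str, int]]:
    """Parse a SAM CIGAR string into ``[(op, length), ...]``.

    ``"*"`` (unmapped sentinel) yields the empty list. Malformed input
    raises :class:`CigarError` naming the first offending character offset.
    """
    if cigar_text == "*":
        return []
    ops: list[tuple[str, int]] = []
    pos = 0
    for m in _CIGAR_TOKEN.finditer(cigar_text):
        if m.start() != pos:
            raise CigarError(f"malformed CIGAR {cigar_text!r} at offset {pos}")
        length = int(m.group(1))
        if length < 1:
            raise CigarError(f"zero-length CIGAR op at offset {m.start()} in {cigar_text!r}")
        ops.append((m.group(2), length))
        pos = m.end()
    if pos != len(cigar_text) or not ops:
        raise CigarError(f"malformed CIGAR {cigar_text!r} at offset {pos}")
    return ops


def cigar_query_span(cigar: Sequence[tuple[str, int]]) -> int:
    return sum(n for op, n in cigar if op in QUERY_OPS)


def cigar_reference_span(cigar: Sequence[tuple[str, int]]) -> int:
    return sum(n for op, n in cigar if op in REFERENCE_OPS)


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


def _open_text(path: PathLike, mode: str = "rt") -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _infer_format(path: PathLike) -> str:
    name = Path(path).name
    if name.endswith(".gz"):
        name = name[:-3]
    suffix = Path(name).suffix.lower()
    if suffix in {".fq", ".fastq"}:
        return "fastq"
    if suffix in {".fa", ".fasta", ".fna", ".ffn", ".faa", ".aln"}:
        return "fasta"
    raise FormatError(f"cannot infer sequence format from {path}")


def read_sequences(path: PathLike, fmt: Optional[str] = None) -> Iterator[SequenceRecord]:
    """Stream records from a FASTA or FASTQ file (plain or gzip).

    Residues are upper-cased; FASTQ length mismatches raise
    :class:`FormatError` naming the record.
    """
    fmt = fmt or _infer_format(path)
    if fmt not in {"fasta", "fastq"}:
        raise ValueError(f"unsupported format {fmt!r}")
    with _open_text(path) as handle:
        if fmt == "fasta":
            for rec in SeqIO.parse(handle, "fasta"):
                yield SequenceRecord(rec.id, str(rec.seq).upper(),
                                     rec.description[len(rec.id):].strip())
        else:
            try:
                for title, seq, qual in FastqGeneralIterator(handle):
                    rid = title.split()[0]
                    if len(seq) != len(qual):
                        raise FormatError(
                            f"FASTQ record {rid!r}: sequence length {len(seq)} "
                            f"!= quality length {len(qual)}"
                        )
                    desc = title[len(rid):].strip()
                    yield SequenceRecord(rid, seq.upper(), desc,
                                         [ord(c) - 33 for c in qual])
            except ValueError as exc:  # Biopython's own format errors
                if isinstance(exc, FormatError):
                    raise
                raise FormatError(str(exc)) from None


def write_fasta(records: Iterable[SequenceRecord], path: PathLike, width: int = 70) -> None:
    with _open_text(path, "wt") as out:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            out.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                out.write(rec.residues[i : i + width] + "\n")


def write_fastq(records: Iterable[SequenceRecord], path: PathLike) -> None:
    with _open_text(path, "wt") as out:
        for rec in records:
            qual = rec.quality if rec.quality is not None else [30] * len(rec.residues)
            out.write(f"@{rec.id}\n{rec.residues}\n+\n")
            out.write("".join(chr(q + 33) for q in qual) + "\n")


def read_msa(path: PathLike) -> MultipleAlignment:
    """Read an aligned FASTA into a :class:`MultipleAlignment`."""
    rows = [(rec.id, rec.residues) for rec in read_sequences(path, "fasta")]
    return MultipleAlignment(rows)


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------


def _parse_sam_line(line: str, lineno: int) -> ReadAlignment:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 11:
        raise FormatError(f"SAM line {lineno}: expected >= 11 columns, got {len(fields)}")
    qname, flag_s, rname, pos_s, _mapq, cigar_s = fields[:6]
    seq = fields[9] if fields[9] != "*" else None
    try:
        flag = int(flag_s)
        pos = int(pos_s)
    except ValueError as exc:
        raise FormatError(f"SAM line {lineno}: non-numeric FLAG/POS") from exc
    mapped = not flag & 0x4
    nm: Optional[int] = None
    for tag in fields[11:]:
        if tag.startswith("NM:i:"):
            nm = int(tag[5:])
            break
    return ReadAlignment(
        query_id=qname,
        reference_id=rname if (mapped and rname != "*") else None,
        position=pos - 1 if mapped else None,
        strand="-" if flag & 0x10 else "+",
        cigar=parse_cigar(cigar_s) if mapped else [],
        edit_distance=nm if mapped else None,
        is_mapped=mapped,
        is_secondary=bool(flag & 0x100),
        is_supplementary=bool(flag & 0x800),
        seq=seq,
    )


def read_alignments(path: PathLike) -> Iterator[ReadAlignment]:
    """Stream :class:`ReadAlignment` records from a text SAM file.

    The header is optional; lines starting with ``@`` are skipped.
    """
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            if not line.strip() or line.startswith("@"):
                continue
            yield _parse_sam_line(line, lineno)


def format_sam_record(aln: ReadAlignment, seq: str = "*", qual: str = "*") -> str:
    """Render an alignment as one SAM line (internal 0-based -> SAM 1-based)."""
    flag = 0
    if not aln.is_mapped:
        flag |= 0x4
    if aln.strand == "-":
        flag |= 0x10
    if aln.is_secondary:
        flag |= 0x100
    if aln.is_supplementary:
        flag |= 0x800
    cigar = "".join(f"{n}{op}" for op, n in aln.cigar) if aln.cigar else "*"
    fields = [
        aln.query_id,
        str(flag),
        aln.reference_id or "*",
        str((aln.position or 0) + 1 if aln.is_mapped else 0),
        "60" if aln.is_mapped else "0",
        cigar,
        "*", "0", "0",
        seq,
        qual,
    ]
    if aln.edit_distance is not None:
        fields.append(f"NM:i:{aln.edit_distance}")
    return "\t".join(fields)


def write_sam(
    alignments: Iterable[ReadAlignment],
    path: PathLike,
    reference_lengths: Optional[dict[str, int]] = None,
    reads: Optional[dict[str, SequenceRecord]] = None,
) -> None:
    with _open_text(path, "wt") as out:
        out.write("@HD\tVN:1.6\tSO:unsorted\n")
        for rid, length in (reference_lengths or {}).items():
            out.write(f"@SQ\tSN:{rid}\tLN:{length}\n")
        for aln in alignments:
            seq, qual = "*", "*"
            if reads is not None and aln.query_id in reads:
                rec = reads[aln.query_id]
                seq = rec.residues
                if rec.quality is not None:
                    qual = "".join(chr(q + 33) for q in rec.quality)
            elif aln.seq is not None:
                seq = aln.seq
            out.write(format_sam_record(aln, seq, qual) + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def write_gff3(features: Iterable[GffFeature], path: PathLike) -> None:
    """Write features; internal half-open coordinates become 1-based closed."""
    with _open_text(path, "wt") as out:
        out.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(f"{k}={v}" for k, v in f.attributes.items()) or "."
            score = f"{f.score:g}" if f.score is not None else "."
            out.write(
                "\t".join(
                    [f.seqid, f.source, f.type, str(f.start + 1), str(f.end),
                     score, f.strand, ".", attrs]
                )
                + "\n"
            )
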