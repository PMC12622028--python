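"""Coverage-based TE copy number and presence calling.

Copy number is estimated DeviaTE-style: per-position read depth over the TE
consensus is divided by the mean depth over a set of single-copy genes
(SCGs), so a normalized depth of 1 corresponds to one haploid copy. A
sample carries the element when at least 90% of consensus positions exceed
normalized depth 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .io_formats import ReadAlignment


class NormalizationError(ZeroDivisionError):
    """Pooled single-copy-gene depth is zero."""


@dataclass
class CoverageProfile:
    reference_id: str
    depth: np.ndarray  # per-position integer depth

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)

    @property
    def length(self) -> int:
        return int(self.depth.size)


@dataclass
class NormalizedProfile:
    """TE depth in units of haploid copies (depth / mean SCG depth)."""

    reference_id: str
    normalized_depth: np.ndarray
    scg_factor: float

    @property
    def copy_number(self) -> float:
        return float(np.mean(self.normalized_depth))

    @property
    def copy_number_median(self) -> float:
        return float(np.median(self.normalized_depth))

    @property
    def copy_number_max(self) -> float:
        return float(np.max(self.normalized_depth))


@dataclass
class PresenceCall:
    sample_id: str
    present: bool
    breadth_above_one: float
    copy_number: float


def coverage_profile(
    alignments: Iterable[ReadAlignment],
    reference_lengths: Mapping[str, int],
) -> dict[str, CoverageProfile]:
    """Pileup depth per reference from mapped alignments.

    Depth at p counts reads whose reference-consuming CIGAR span covers p
    (deletions count as covered, clips do not). Implemented with a
    difference array, so streams of any size are linear time.
    """
    diffs = {rid: np.zeros(length + 1, dtype=np.int64) for rid, length in reference_lengths.items()}
    for aln in alignments:
        if not aln.is_mapped or aln.is_secondary or aln.is_supplementary:
            continue
        if aln.reference_id not in diffs:
            raise KeyError(f"alignment of {aln.query_id!r} to unknown reference {aln.reference_id!r}")
        span = aln.reference_span
        end = aln.position + span
        if end > reference_lengths[aln.reference_id]:
            raise ValueError(
                f"read {aln.query_id!r} extends past the end of {aln.reference_id!r}"
            )
        diffs[aln.reference_id][aln.position] += 1
        diffs[aln.reference_id][end] -= 1
    return {
        rid: CoverageProfile(rid, np.cumsum(arr[:-1])) for rid, arr in diffs.items()
    }


def normalize_by_scg(
    te: CoverageProfile,
    scgs: Sequence[CoverageProfile],
    stat: str = "mean",
) -> NormalizedProfile:
    """Divide TE depth by the pooled mean single-copy-gene depth.

    Pooling concatenates all SCG positions before averaging (BUSCO-style
    genes of comparable length make this indistinguishable from a
    gene-wise mean).
    """
    if not scgs:
        raise ValueError("at least one single-copy-gene profile is required")
    pooled = np.concatenate([p.depth for p in scgs])
    factor = float(np.mean(pooled))
    if factor == 0:
        raise NormalizationError("single-copy-gene depth is zero everywhere")
    if stat not in {"mean", "median"}:
        raise ValueError(f"unknown summary statistic {stat!r}")
    return NormalizedProfile(te.reference_id, te.depth / factor, factor)


def call_presence(
    profile: NormalizedProfile,
    sample_id: str = "",
    breadth_threshold: float = 0.9,
    depth_threshold: float = 1.0,
    stat: str = "mean",
) -> PresenceCall:
    """Present iff the breadth above depth 1 reaches 90% of positions.

    The per-position depth comparison is strict (> 1); the breadth
    comparison is inclusive (>= 0.9).
    """
    if profile.normalized_depth.size == 0:
        raise ValueError("empty profile")
    breadth = float(np.mean(profile.normalized_depth > depth_threshold))
    cn = profile.copy_number if stat == "mean" else profile.copy_number_median
    return PresenceCall(
        sample_id=sample_id,
        present=breadth >= breadth_threshold,
        breadth_above_one=breadth,
        copy_number=cn,
    )


def estimate_copy_number(
    alignments: Iterable[ReadAlignment],
    te_id: str,
    te_length: int,
    scg_lengths: Mapping[str, int],
    sample_id: str = "",
) -> tuple[NormalizedProfile, PresenceCall]:
    """Convenience wrapper: pileup, normalize, call presence in one pass."""
    lengths: dict[str, int] = {te_id: te_length, **scg_lengths}
    profiles = coverage_profile(alignments, lengths)
    normalized = normalize_by_scg(
        profiles[te_id], [profiles[rid] for rid in scg_lengths]
    )
    return normalized, call_presence(normalized, sample_id)
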