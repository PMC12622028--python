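"""Spatio-temporal aggregation of per-sample presence calls.

Joins presence calls with collection metadata (year, biogeographic realm)
into a year-by-region summary, recording when the element was first seen
overall and per region. Years inside the sampled range with zero samples
are kept in the table so that detection gaps caused by sparse sampling stay
visible rather than vanishing from plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .copynumber import PresenceCall

CURRENT_YEAR_CAP = 2100


@dataclass
class SampleMeta:
    sample_id: str
    collection_year: int
    region: str
    source: str = ""

    def __post_init__(self) -> None:
        if not 1700 <= self.collection_year <= CURRENT_YEAR_CAP:
            raise ValueError(
                f"sample {self.sample_id!r}: implausible collection year "
                f"{self.collection_year}"
            )


@dataclass
class InvasionSummary:
    """Per-(year, region) counts plus first-detection years.

    ``table`` columns: year, region, samples_total, samples_present,
    fraction_present; rows ordered year ascending then region alphabetical.
    ``first_detection_year`` is None when the element is absent everywhere.
    """

    table: pd.DataFrame
    first_detection_year: Optional[int]
    first_detection_by_region: dict[str, int] = field(default_factory=dict)

    def wide_fraction_matrix(self) -> pd.DataFrame:
        return self.table.pivot(index="year", columns="region", values="fraction_present")


class OrphanSampleError(KeyError):
    """Presence calls without matching metadata."""

    def __init__(self, orphan_ids: Sequence[str]):
        self.orphan_ids = list(orphan_ids)
        super().__init__(f"calls without metadata: {', '.join(self.orphan_ids)}")


def read_sample_metadata(path: Union[str, Path]) -> list[SampleMeta]:
    """Load a metadata TSV with columns sample_id, collection_year, region."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "region": str})
    return [
        SampleMeta(
            row.sample_id,
            int(row.collection_year),
            row.region,
            getattr(row, "source", "") or "",
        )
        for row in df.itertuples(index=False)
    ]


def summarize_invasion(
    calls: Iterable[PresenceCall],
    meta: Iterable[SampleMeta],
) -> InvasionSummary:
    """Aggregate presence calls into the invasion timeline.

    Counts are exact per (year, region); the result is invariant to input
    order. Duplicate sample ids in the metadata and calls lacking metadata
    both raise.
    """
    meta_list = list(meta)
    ids = [m.sample_id for m in meta_list]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sample ids in metadata: {', '.join(dupes)}")
    by_id = {m.sample_id: m for m in meta_list}

    calls_list = list(calls)
    orphans = sorted({c.sample_id for c in calls_list if c.sample_id not in by_id})
    if orphans:
        raise OrphanSampleError(orphans)
    if not calls_list:
        raise ValueError("no presence calls supplied")

    rows = [
        {
            "year": by_id[c.sample_id].collection_year,
            "region": by_id[c.sample_id].region,
            "present": bool(c.present),
        }
        for c in calls_list
    ]
    df = pd.DataFrame(rows)
    grouped = (
        df.groupby(["year", "region"])
        .agg(samples_total=("present", "size"), samples_present=("present", "sum"))
        .reset_index()
    )
    years = range(int(df.year.min()), int(df.year.max()) + 1)
    regions = sorted(df.region.unique())
    full = pd.MultiIndex.from_product([years, regions], names=["year", "region"])
    table = (
        grouped.set_index(["year", "region"])
        .reindex(full, fill_value=0)
        .reset_index()
        .sort_values(["year", "region"], kind="stable")
        .reset_index(drop=True)
    )
    totals = table.samples_total.to_numpy(dtype=float)
    present = table.samples_present.to_numpy(dtype=float)
    table["fraction_present"] = np.divide(
        present, totals, out=np.zeros_like(present), where=totals > 0
    )

    detected = table[table.samples_present > 0]
    first = int(detected.year.min()) if not detected.empty else None
    per_region = {
        region: int(sub.year.min())
        for region, sub in detected.groupby("region")
    }
    return InvasionSummary(table, first, per_region)


def write_summary_tsv(summary: InvasionSummary, path: Union[str, Path]) -> None:
    summary.table.to_csv(path, sep="\t", index=False)
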