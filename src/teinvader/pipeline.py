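"""End-to-end orchestration of the discovery chain with an auditable ledger.

``detect_novel_te`` wires select -> contaminant filter -> assemble ->
protein search -> candidate filter, recording reads in/out at every stage
so that the run is reproducible and the read ledger is conserved
(reads_in = reads_emitted + reads_dropped at each stage).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from . import __version__
from .io_formats import (
    SequenceRecord,
    read_alignments,
    read_sequences,
    write_fasta,
)
from .readscan import (
    CandidateContig,
    ContaminantIndex,
    PipelineThresholds,
    assemble_contigs,
    count_supporting_reads,
    filter_contaminants,
    filter_te_candidates,
    search_te_proteins,
    select_candidate_reads,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


class ConfigurationError(ValueError):
    """A run configuration references missing inputs."""


@dataclass
class RunConfig:
    sam: PathLike
    reads: PathLike
    te_proteins: PathLike
    contaminants: list[PathLike] = field(default_factory=list)
    out_dir: Optional[PathLike] = None
    thresholds: PipelineThresholds = field(default_factory=PipelineThresholds)
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        missing = [
            str(p)
            for p in [self.sam, self.reads, self.te_proteins, *self.contaminants]
            if not Path(p).exists()
        ]
        if missing:
            raise ConfigurationError(f"missing input files: {', '.join(missing)}")

    @classmethod
    def from_file(cls, path: PathLike, **overrides) -> "RunConfig":
        """Flat key=value config file; explicit keyword overrides win."""
        values: dict = {}
        thr: dict = {}
        thr_fields = {f.name for f in dataclasses.fields(PipelineThresholds)}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key in thr_fields:
                thr[key] = float(value) if "." in value else int(value)
            elif key == "contaminants":
                values[key] = value.split(",") if value else []
            elif key == "seed":
                values[key] = int(value)
            else:
                values[key] = value
        values.update(overrides)
        if thr and "thresholds" not in values:
            values["thresholds"] = PipelineThresholds(**thr)
        return cls(**values)


@dataclass
class StageCount:
    stage: str
    reads_in: int
    reads_out: int

    @property
    def reads_dropped(self) -> int:
        return self.reads_in - self.reads_out


@dataclass
class DetectionReport:
    candidates: list[CandidateContig]
    contigs: list[SequenceRecord]
    stage_counts: list[StageCount]

    def as_manifest(self) -> dict:
        return {
            "version": __version__,
            "stages": [
                {"stage": s.stage, "reads_in": s.reads_in, "reads_out": s.reads_out,
                 "reads_dropped": s.reads_dropped}
                for s in self.stage_counts
            ],
            "contigs_assembled": len(self.contigs),
            "candidates_retained": len(self.candidates),
        }


def detect_novel_te(config: RunConfig) -> DetectionReport:
    """Run the full discovery chain on one sample.

    "No candidates" is a clean outcome (empty candidate list); errors in
    any stage propagate with the stage context attached.
    """
    config.validate()
    thr = config.thresholds

    read_store = {rec.id: rec for rec in read_sequences(config.reads)}
    total_reads = len(read_store)

    selected = list(
        select_candidate_reads(read_alignments(config.sam), read_store, thr)
    )
    counts = [StageCount("select_candidate_reads", total_reads, len(selected))]
    logger.info("selected %d/%d reads as unmapped or diverged", len(selected), total_reads)

    if config.contaminants:
        contaminant_genomes = [
            rec for p in config.contaminants for rec in read_sequences(p)
        ]
        index = ContaminantIndex.build(contaminant_genomes, k=thr.contaminant_k)
        cleaned = list(filter_contaminants(selected, index, thr))
    else:
        cleaned = selected
    counts.append(StageCount("filter_contaminants", len(selected), len(cleaned)))

    contigs = assemble_contigs(cleaned, thr)
    counts.append(StageCount("assemble_contigs", len(cleaned), len(contigs)))
    logger.info("assembled %d contigs from %d reads", len(contigs), len(cleaned))

    protein_db = list(read_sequences(config.te_proteins, "fasta"))
    hits = search_te_proteins(contigs, protein_db)
    support = count_supporting_reads(contigs, cleaned, thr.assembler_k)
    candidates = filter_te_candidates(
        hits, thr, contigs={c.id: c for c in contigs}, support=support
    )
    counts.append(StageCount("filter_te_candidates", len(contigs), len(candidates)))
    logger.info("retained %d candidate contigs", len(candidates))

    report = DetectionReport(candidates, contigs, counts)
    if config.out_dir is not None:
        _write_outputs(report, config)
    return report


def _write_outputs(report: DetectionReport, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta((c.contig for c in report.candidates), out / "candidates.fasta")
    pd.DataFrame(
        [
            {
                "contig": c.contig.id,
                "best_hit": c.best_hit,
                "identity": round(c.identity, 2),
                "span_nt": c.span_nt,
                "frame": c.frame,
                "score": c.score,
                "supporting_reads": c.supporting_read_count,
            }
            for c in report.candidates
        ],
        columns=["contig", "best_hit", "identity", "span_nt", "frame", "score",
                 "supporting_reads"],
    ).to_csv(out / "candidates.tsv", sep="\t", index=False)
    manifest = report.as_manifest()
    manifest["thresholds"] = dataclasses.asdict(config.thresholds)
    manifest["inputs"] = {
        "sam": str(config.sam),
        "reads": str(config.reads),
        "te_proteins": str(config.te_proteins),
        "contaminants": [str(p) for p in config.contaminants],
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
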