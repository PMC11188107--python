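"""Pipeline orchestration: match reads, filter, deduplicate, count.

The stages are: stream read pairs -> match cell windows against the
whitelist (Hamming) and tag windows against the oligo reference
(normalized edit ratio) -> keep reads assigned on both sides -> UMI
deduplication -> sparse count matrix. Every read receives exactly one fate
and the run report is checked for conservation at the end.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .dedup import DedupPolicy, MoleculeAssignment, dedup_close, dedup_exact
from .io import (
    BarcodeWhitelist,
    CountMatrix,
    ReadLayout,
    ReadPairRecord,
    TagReference,
    read_fastq_pairs,
    read_tag_reference,
    read_whitelist,
    write_count_matrix,
)
from .matching import MatchPolicy, match_batch

__all__ = [
    "RunReport",
    "RunConfig",
    "PipelineError",
    "assign_reads",
    "build_matrix",
    "run_pipeline",
]

logger = logging.getLogger("adtcount")

_RC = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage that raised it."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class RunReport:
    """Conservation ledger of read fates.

    Every read pair lands in exactly one bucket; for reads failing both
    matches, the cell-side fate is recorded.
    """

    n_reads_total: int = 0
    n_malformed: int = 0
    n_cell_unmatched: int = 0
    n_cell_ambiguous: int = 0
    n_tag_unmatched: int = 0
    n_tag_ambiguous: int = 0
    n_umi_duplicates_removed: int = 0
    n_counted: int = 0

    FIELDS = (
        "n_reads_total",
        "n_malformed",
        "n_cell_unmatched",
        "n_cell_ambiguous",
        "n_tag_unmatched",
        "n_tag_ambiguous",
        "n_umi_duplicates_removed",
        "n_counted",
    )

    def validate(self) -> None:
        parts = sum(getattr(self, f) for f in self.FIELDS[1:])
        if parts != self.n_reads_total:
            raise AssertionError(
                f"read-fate conservation violated: fates sum to {parts}, "
                f"total reads {self.n_reads_total}"
            )
        for f in self.FIELDS:
            if getattr(self, f) < 0:
                raise AssertionError(f"negative report field {f}")

    def as_dict(self) -> dict[str, int]:
        return {f: getattr(self, f) for f in self.FIELDS}

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for key, value in self.as_dict().items():
                fh.write(f"{key}\t{value}\n")

    def log(self) -> None:
        for key, value in self.as_dict().items():
            logger.info("%s: %d", key, value)


@dataclass
class RunConfig:
    """Full run configuration; default-constructible for inspection.

    Defaults: Hamming cutoff 1 for cell barcodes, edit-ratio cutoff 0.93
    for tag oligos, chunk size 100,000, exact UMI dedup.
    """

    cell_fastqs: tuple[str, ...] = ()
    tag_fastqs: tuple[str, ...] = ()
    whitelist_path: str | None = None
    tags_path: str | None = None
    out_dir: str | None = None
    layout: ReadLayout = field(default_factory=ReadLayout)
    match: MatchPolicy = field(default_factory=MatchPolicy)
    dedup: DedupPolicy = field(default_factory=DedupPolicy)
    rc_barcodes: bool = False
    strip_suffix: bool = True
    drop_zero_cells: bool = False

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _tally(report: RunReport, cell_status: str, tag_status: str) -> None:
    if cell_status == "unmatched":
        report.n_cell_unmatched += 1
    elif cell_status == "ambiguous":
        report.n_cell_ambiguous += 1
    elif tag_status == "unmatched":
        report.n_tag_unmatched += 1
    else:
        report.n_tag_ambiguous += 1


def assign_reads(
    records: Iterable[ReadPairRecord],
    whitelist: BarcodeWhitelist,
    tags: TagReference,
    policy: MatchPolicy | None = None,
    rc_barcodes: bool = False,
) -> tuple[list[MoleculeAssignment], RunReport]:
    """Match each read's windows to both references.

    Returns assignments for reads matched on both sides plus a partial
    report tallying the match failures (total/malformed/dedup fields are
    filled by the caller). Cell-side failures take precedence when both
    sides fail.
    """
    policy = policy or MatchPolicy()
    cell_policy = dataclasses.replace(policy, metric="hamming")
    tag_policy = dataclasses.replace(policy, metric="edit_ratio")
    report = RunReport()
    molecules: list[MoleculeAssignment] = []
    read_index = 0
    buffer: list[ReadPairRecord] = []

    def flush() -> None:
        nonlocal read_index
        if not buffer:
            return
        cell_q = [r.cell_window for r in buffer]
        if rc_barcodes:
            cell_q = [reverse_complement(q) for q in cell_q]
        tag_q = [r.tag_window for r in buffer]
        cell_res = match_batch(cell_q, whitelist.sequences, cell_policy)
        tag_res = match_batch(tag_q, tags.sequences, tag_policy)
        for rec, cres, tres in zip(buffer, cell_res, tag_res):
            if cres.status == "assigned" and tres.status == "assigned":
                molecules.append(
                    MoleculeAssignment(
                        order=read_index,
                        cell_index=cres.reference_index,
                        tag_index=tres.reference_index,
                        umi=rec.umi_window,
                    )
                )
            else:
                _tally(report, cres.status, tres.status)
            read_index += 1
        buffer.clear()

    for rec in records:
        buffer.append(rec)
        if len(buffer) >= policy.chunk_size:
            flush()
    flush()
    return molecules, report


def build_matrix(
    molecules: Sequence[MoleculeAssignment],
    whitelist: BarcodeWhitelist,
    tags: TagReference,
    drop_zero_cells: bool = False,
) -> CountMatrix:
    """Tally deduplicated molecules into the sparse cells x tags matrix.

    All whitelist barcodes are retained as rows (the matrix has maximal
    dimensions) unless ``drop_zero_cells`` subsets to observed cells.
    """
    tally = Counter((m.cell_index, m.tag_index) for m in molecules)
    matrix = CountMatrix.from_entries(
        whitelist.sequences,
        tags.names,
        ((c, t, n) for (c, t), n in tally.items()),
    )
    if drop_zero_cells:
        row_nnz = np.asarray(matrix.matrix.getnnz(axis=1)).ravel()
        keep = np.flatnonzero(row_nnz > 0)
        matrix = CountMatrix(
            tuple(matrix.cell_labels[i] for i in keep),
            matrix.tag_labels,
            matrix.matrix[keep],
        )
    return matrix


def _dedup(molecules, policy: DedupPolicy):
    if policy.mode == "close":
        return dedup_close(molecules, policy)
    return dedup_exact(molecules, policy)


def run_pipeline(config: RunConfig) -> tuple[CountMatrix, RunReport]:
    """Execute the full pipeline per ``config``.

    Reads and matches the FASTQ pairs, deduplicates UMIs, builds the count
    matrix, and (when ``config.out_dir`` is set) writes the matrix triplet,
    the report and a config snapshot. Fully deterministic for fixed inputs.
    """
    config.dedup.validate_for_run()
    try:
        whitelist = read_whitelist(config.whitelist_path, config.strip_suffix)
        tags = read_tag_reference(config.tags_path)
    except Exception as exc:
        raise PipelineError("references", exc) from exc

    try:
        reader = read_fastq_pairs(
            config.cell_fastqs, config.tag_fastqs, config.layout
        )
        molecules, report = assign_reads(
            reader, whitelist, tags, config.match, config.rc_barcodes
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("matching", exc) from exc
    report.n_reads_total = reader.n_total
    report.n_malformed = reader.n_malformed

    try:
        kept, removed = _dedup(molecules, config.dedup)
    except Exception as exc:
        raise PipelineError("dedup", exc) from exc
    report.n_umi_duplicates_removed = removed
    report.n_counted = len(kept)
    report.validate()

    try:
        matrix = build_matrix(kept, whitelist, tags, config.drop_zero_cells)
    except Exception as exc:
        raise PipelineError("counting", exc) from exc

    if config.out_dir is not None:
        try:
            out = Path(config.out_dir)
            out.mkdir(parents=True, exist_ok=True)
            write_count_matrix(matrix, out)
            report.write(out / "report.txt")
            (out / "config.json").write_text(config.to_json())
        except Exception as exc:
            report.log()
            raise PipelineError("output", exc) from exc

    report.log()
    return matrix, report
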