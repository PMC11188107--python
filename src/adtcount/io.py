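"""Input parsing and output formats.

Reads paired FASTQ files (plain or gzipped), the tag-oligo reference table
and the cell-barcode whitelist; writes the sparse count matrix in the
CellRanger triplet dialect (``matrix.mtx.gz`` with features as rows,
``features.tsv.gz``, ``barcodes.tsv.gz``).
"""

from __future__ import annotations

import gzip
import io as _io
import os
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import scipy.io
import scipy.sparse as sp
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "ReadLayout",
    "ReadPairRecord",
    "TagReference",
    "BarcodeWhitelist",
    "CountMatrix",
    "PairedFastqReader",
    "read_fastq_pairs",
    "read_tag_reference",
    "read_whitelist",
    "write_count_matrix",
    "read_count_matrix",
    "FastqFormatError",
]

_ACGT_RE = re.compile(r"^[ACGT]+$")
_SUFFIX_RE = re.compile(r"-\d+$")

FEATURE_TYPE = "Antibody Capture"


class FastqFormatError(ValueError):
    """Raised for malformed FASTQ content or mismatched pair files."""


def _open_text(path: str | os.PathLike, mode: str = "rt"):
    path = os.fspath(path)
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass(frozen=True)
class ReadLayout:
    """Positions of the barcode, UMI and tag windows within the read pair.

    Defaults follow the common 10x feature-barcoding arrangement: a 16 bp
    cell barcode at the start of the cellID read; the tag oligo at the
    start of the tag read with a 12 bp UMI immediately after it. Every
    position is overridable. ``umi_offset=None`` means "immediately after
    the tag window" when the UMI lives on the tag read, or
    "immediately after the cell barcode" on the cellID read.
    """

    cell_bc_offset: int = 0
    cell_bc_length: int = 16
    umi_source: str = "tag"  # "cell" or "tag": which read carries the UMI
    umi_offset: int | None = None
    umi_length: int = 12
    tag_offset: int = 0
    tag_length: int = 16

    def __post_init__(self) -> None:
        if self.umi_source not in ("cell", "tag"):
            raise ValueError("umi_source must be 'cell' or 'tag'")
        for name in ("cell_bc_offset", "tag_offset"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.umi_offset is not None and self.umi_offset < 0:
            raise ValueError("umi_offset must be >= 0")
        for name in ("cell_bc_length", "umi_length", "tag_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def effective_umi_offset(self) -> int:
        if self.umi_offset is not None:
            return self.umi_offset
        if self.umi_source == "tag":
            return self.tag_offset + self.tag_length
        return self.cell_bc_offset + self.cell_bc_length

    def extract(self, cell_seq: str, tag_seq: str) -> tuple[str, str, str] | None:
        """Extract (cell, UMI, tag) windows, or None if a read is too short."""
        uo = self.effective_umi_offset
        cell_end = self.cell_bc_offset + self.cell_bc_length
        tag_end = self.tag_offset + self.tag_length
        umi_end = uo + self.umi_length
        if len(cell_seq) < cell_end or len(tag_seq) < tag_end:
            return None
        umi_read = tag_seq if self.umi_source == "tag" else cell_seq
        if len(umi_read) < umi_end:
            return None
        return (
            cell_seq[self.cell_bc_offset : cell_end],
            umi_read[uo:umi_end],
            tag_seq[self.tag_offset : tag_end],
        )


@dataclass(frozen=True)
class ReadPairRecord:
    """One sequenced molecule observation: the three extracted windows."""

    read_id: str
    cell_window: str
    umi_window: str
    tag_window: str


def _validate_dna(seqs: Iterable[str], what: str) -> None:
    bad = [s for s in seqs if not _ACGT_RE.match(s)]
    if bad:
        raise ValueError(f"{what}: non-ACGT sequences: {bad[:5]}")


@dataclass(frozen=True)
class TagReference:
    """Ordered marker names and their oligo barcodes."""

    names: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.names:
            raise ValueError("tag reference is empty")
        if len(self.names) != len(self.sequences):
            raise ValueError("names and sequences differ in length")
        dup_names = _duplicates(self.names)
        if dup_names:
            raise ValueError(f"duplicate tag names: {dup_names}")
        dup_seqs = _duplicates(self.sequences)
        if dup_seqs:
            raise ValueError(f"duplicate tag sequences: {dup_seqs}")
        _validate_dna(self.sequences, "tag reference")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"tag sequences have ragged lengths: {sorted(lengths)}")

    def __len__(self) -> int:
        return len(self.names)

    @property
    def sequence_length(self) -> int:
        return len(self.sequences[0])


@dataclass(frozen=True)
class BarcodeWhitelist:
    """Ordered list of valid cell barcodes, uniform length, unique."""

    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("whitelist is empty")
        dups = _duplicates(self.sequences)
        if dups:
            raise ValueError(f"duplicate whitelist barcodes: {dups}")
        _validate_dna(self.sequences, "whitelist")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"whitelist barcodes have ragged lengths: {sorted(lengths)}")

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def barcode_length(self) -> int:
        return len(self.sequences[0])


def _duplicates(items: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for it in items:
        if it in seen and it not in dups:
            dups.append(it)
        seen.add(it)
    return dups[:5]


@dataclass
class CountMatrix:
    """Sparse cells x tags integer count matrix with row/column labels."""

    cell_labels: tuple[str, ...]
    tag_labels: tuple[str, ...]
    matrix: sp.csr_matrix = field(repr=False)

    def __post_init__(self) -> None:
        self.cell_labels = tuple(self.cell_labels)
        self.tag_labels = tuple(self.tag_labels)
        m = sp.csr_matrix(self.matrix)
        m.eliminate_zeros()
        if m.shape != (len(self.cell_labels), len(self.tag_labels)):
            raise ValueError(
                f"matrix shape {m.shape} does not match labels "
                f"({len(self.cell_labels)}, {len(self.tag_labels)})"
            )
        if m.nnz and m.data.min() < 1:
            raise ValueError("counts must be positive integers")
        self.matrix = m.astype(np.int64)

    @classmethod
    def from_entries(
        cls,
        cell_labels: Sequence[str],
        tag_labels: Sequence[str],
        entries: Iterable[tuple[int, int, int]],
    ) -> "CountMatrix":
        entries = list(entries)
        seen = set()
        rows, cols, data = [], [], []
        for c, t, n in entries:
            if not (0 <= c < len(cell_labels) and 0 <= t < len(tag_labels)):
                raise ValueError(f"entry ({c}, {t}) outside label ranges")
            if (c, t) in seen:
                raise ValueError(f"duplicate entry for cell {c}, tag {t}")
            if n < 1:
                raise ValueError(f"count for ({c}, {t}) must be >= 1, got {n}")
            seen.add((c, t))
            rows.append(c)
            cols.append(t)
            data.append(n)
        m = sp.coo_matrix(
            (data, (rows, cols)),
            shape=(len(cell_labels), len(tag_labels)),
            dtype=np.int64,
        )
        return cls(tuple(cell_labels), tuple(tag_labels), m.tocsr())

    def entries(self) -> set[tuple[int, int, int]]:
        coo = self.matrix.tocoo()
        return {
            (int(r), int(c), int(v))
            for r, c, v in zip(coo.row, coo.col, coo.data)
        }

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.cell_labels == other.cell_labels
            and self.tag_labels == other.tag_labels
            and self.entries() == other.entries()
        )


def _normalize_read_id(title: str) -> str:
    rid = title.split(None, 1)[0] if title else ""
    if rid.endswith("/1") or rid.endswith("/2"):
        rid = rid[:-2]
    return rid


def _fastq_records(path: str | os.PathLike) -> Iterator[tuple[str, str]]:
    with _open_text(path) as handle:
        it = FastqGeneralIterator(handle)
        n = 0
        while True:
            try:
                title, seq, _qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqFormatError(
                    f"{path}: record {n + 1}: {exc}"
                ) from exc
            n += 1
            yield title, seq


class PairedFastqReader:
    """Iterates matched records from paired cellID/tag FASTQ file lists.

    Iteration yields :class:`ReadPairRecord` per read pair, concatenating
    lanes in list order. Reads too short for any configured window are
    skipped and counted in ``n_malformed``; ``n_total`` counts every pair
    seen (yielded or malformed).
    """

    def __init__(
        self,
        cell_fastq_paths: Sequence[str | os.PathLike],
        tag_fastq_paths: Sequence[str | os.PathLike],
        layout: ReadLayout | None = None,
    ) -> None:
        if len(cell_fastq_paths) != len(tag_fastq_paths):
            raise ValueError(
                f"{len(cell_fastq_paths)} cellID FASTQ files but "
                f"{len(tag_fastq_paths)} tag FASTQ files"
            )
        if not cell_fastq_paths:
            raise ValueError("no FASTQ files given")
        self.cell_fastq_paths = list(cell_fastq_paths)
        self.tag_fastq_paths = list(tag_fastq_paths)
        self.layout = layout or ReadLayout()
        self.n_total = 0
        self.n_malformed = 0

    def __iter__(self) -> Iterator[ReadPairRecord]:
        sentinel = object()
        for cpath, tpath in zip(self.cell_fastq_paths, self.tag_fastq_paths):
            cell_it = _fastq_records(cpath)
            tag_it = _fastq_records(tpath)
            rec_no = 0
            while True:
                crec = next(cell_it, sentinel)
                trec = next(tag_it, sentinel)
                if crec is sentinel and trec is sentinel:
                    break
                if crec is sentinel or trec is sentinel:
                    raise FastqFormatError(
                        f"record count mismatch between {cpath} and {tpath}"
                    )
                rec_no += 1
                ctitle, cseq = crec
                ttitle, tseq = trec
                cid = _normalize_read_id(ctitle)
                tid = _normalize_read_id(ttitle)
                if cid != tid:
                    raise FastqFormatError(
                        f"read id mismatch at record {rec_no}: "
                        f"{cid!r} ({cpath}) vs {tid!r} ({tpath})"
                    )
                self.n_total += 1
                windows = self.layout.extract(cseq.upper(), tseq.upper())
                if windows is None:
                    self.n_malformed += 1
                    continue
                cell_w, umi_w, tag_w = windows
                yield ReadPairRecord(cid, cell_w, umi_w, tag_w)


def read_fastq_pairs(
    cell_fastq_paths: Sequence[str | os.PathLike],
    tag_fastq_paths: Sequence[str | os.PathLike],
    layout: ReadLayout | None = None,
) -> PairedFastqReader:
    """Open paired FASTQ lists for streaming; see :class:`PairedFastqReader`."""
    return PairedFastqReader(cell_fastq_paths, tag_fastq_paths, layout)


def read_tag_reference(path: str | os.PathLike) -> TagReference:
    """Parse a 2-column name/sequence table (CSV or TSV, autodetected).

    A header row is recognized (and skipped) when its second field is not
    a pure ACGT sequence.
    """
    names: list[str] = []
    seqs: list[str] = []
    with _open_text(path) as fh:
        rows = [line.rstrip("\n").rstrip("\r") for line in fh]
    rows = [r for r in rows if r.strip()]
    if not rows:
        raise ValueError(f"{path}: tag reference file is empty")
    delim = "\t" if "\t" in rows[0] else ","
    for lineno, row in enumerate(rows, start=1):
        parts = [p.strip() for p in row.split(delim)]
        if len(parts) < 2:
            raise ValueError(
                f"{path}: line {lineno}: expected 2 delimited columns, got {row!r}"
            )
        name, seq = parts[0], parts[1].upper()
        if lineno == 1 and not _ACGT_RE.match(seq):
            continue  # header row
        names.append(name)
        seqs.append(seq)
    try:
        return TagReference(tuple(names), tuple(seqs))
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def read_whitelist(
    path: str | os.PathLike, strip_suffix: bool = True
) -> BarcodeWhitelist:
    """Read one barcode per line, optionally stripping a ``-1``-style suffix."""
    seqs: list[str] = []
    with _open_text(path) as fh:
        for line in fh:
            bc = line.strip()
            if not bc:
                continue
            if strip_suffix:
                bc = _SUFFIX_RE.sub("", bc)
            seqs.append(bc.upper())
    try:
        return BarcodeWhitelist(tuple(seqs))
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def _gzip_write_lines(path: Path, lines: Iterable[str]) -> None:
    # mtime=0 keeps repeated runs byte-identical
    with gzip.GzipFile(path, mode="wb", mtime=0) as gz:
        for line in lines:
            gz.write((line + "\n").encode("ascii"))


def write_count_matrix(matrix: CountMatrix, out_dir: str | os.PathLike) -> dict[str, Path]:
    """Write the CellRanger-dialect triplet to ``out_dir``.

    ``matrix.mtx.gz`` holds a MatrixMarket "coordinate integer general"
    matrix with features as rows and barcodes as columns (1-based indices);
    ``features.tsv.gz`` holds ``id\\tname\\tAntibody Capture`` rows and
    ``barcodes.tsv.gz`` one barcode per line.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    features_first = matrix.matrix.T.tocoo().astype(np.int64)
    buf = _io.BytesIO()
    scipy.io.mmwrite(buf, features_first, field="integer", symmetry="general")
    mtx_path = out / "matrix.mtx.gz"
    with gzip.GzipFile(mtx_path, mode="wb", mtime=0) as gz:
        gz.write(buf.getvalue())
    feat_path = out / "features.tsv.gz"
    _gzip_write_lines(
        feat_path, (f"{n}\t{n}\t{FEATURE_TYPE}" for n in matrix.tag_labels)
    )
    bc_path = out / "barcodes.tsv.gz"
    _gzip_write_lines(bc_path, matrix.cell_labels)
    return {"matrix": mtx_path, "features": feat_path, "barcodes": bc_path}


def read_count_matrix(out_dir: str | os.PathLike) -> CountMatrix:
    """Read a triplet written by :func:`write_count_matrix` back into memory."""
    out = Path(out_dir)
    with gzip.open(out / "matrix.mtx.gz", "rb") as fh:
        m = scipy.io.mmread(fh)
    with gzip.open(out / "features.tsv.gz", "rt") as fh:
        tag_labels = tuple(line.rstrip("\n").split("\t")[0] for line in fh)
    with gzip.open(out / "barcodes.tsv.gz", "rt") as fh:
        cell_labels = tuple(line.rstrip("\n") for line in fh if line.strip())
    cells_first = sp.csr_matrix(m).T.astype(np.int64)
    return CountMatrix(cell_labels, tag_labels, cells_first)
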