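"""Ground-truthed synthetic ASAP/CITE-seq read generator.

Produces paired FASTQ files (cellID read, tag read), a whitelist and a tag
reference that conform to the default :class:`~adtcount.io.ReadLayout`,
together with exact per-read provenance and the truth count matrix of
unique molecules. Molecule counts per (cell, tag) are Poisson; each
molecule can be re-emitted once as a PCR duplicate; per-base substitution
errors are applied independently to every emitted window.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .io import BarcodeWhitelist, CountMatrix, TagReference

__all__ = [
    "SimulationConfig",
    "ReadProvenance",
    "GroundTruth",
    "SimulatedDataset",
    "generate_references",
    "generate_dataset",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_LUT = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _BASE_LUT[_b] = _i
MIN_REFERENCE_DISTANCE = 3  # single-error reads cannot become ambiguous


@dataclass(frozen=True)
class SimulationConfig:
    n_cells: int = 200
    n_tags: int = 20
    barcode_length: int = 16
    umi_length: int = 12
    tag_oligo_length: int = 16
    mean_molecules: float = 5.0
    duplication_rate: float = 0.0
    substitution_error_rate: float = 0.0
    seed: int = 0
    allow_umi_collisions: bool = False  # stress mode, excluded from truth-recovery checks

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.n_tags < 1:
            raise ValueError("n_cells and n_tags must be >= 1")
        for name in ("barcode_length", "umi_length", "tag_oligo_length"):
            if getattr(self, name) < 4:
                raise ValueError(f"{name} must be >= 4")
        for name in ("duplication_rate", "substitution_error_rate"):
            rate = getattr(self, name)
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.mean_molecules <= 0:
            raise ValueError("mean_molecules must be positive")


@dataclass(frozen=True)
class ReadProvenance:
    """True origin of one emitted read."""

    read_id: str
    cell_index: int
    tag_index: int
    umi: str
    is_duplicate: bool
    mutated_positions: tuple[tuple[str, int], ...]  # (window, 0-based position)


@dataclass
class GroundTruth:
    truth_matrix: CountMatrix
    reads: list[ReadProvenance] = field(repr=False)
    n_molecules: int = 0
    n_duplicate_reads: int = 0
    n_substituted_bases: int = 0
    n_emitted_bases: int = 0

    @property
    def n_reads(self) -> int:
        return len(self.reads)


@dataclass
class SimulatedDataset:
    cell_fastq: Path
    tag_fastq: Path
    whitelist_path: Path
    tag_reference_path: Path
    whitelist: BarcodeWhitelist
    tags: TagReference
    truth: GroundTruth


def _decode(row: np.ndarray) -> str:
    return _BASES[row].tobytes().decode("ascii")


def _random_distinct_sequences(
    rng: np.random.Generator,
    n: int,
    length: int,
    min_distance: int = MIN_REFERENCE_DISTANCE,
    max_tries: int | None = None,
) -> list[str]:
    """Rejection-sample DNA sequences with pairwise Hamming >= min_distance."""
    if n > 4**length:
        raise ValueError(
            f"cannot draw {n} distinct sequences of length {length} "
            f"(only {4**length} exist); use longer sequences"
        )
    max_tries = max_tries or max(10_000, 200 * n)
    accepted = np.empty((0, length), dtype=np.uint8)
    tries = 0
    while accepted.shape[0] < n:
        if tries >= max_tries:
            raise ValueError(
                f"could not place {n} sequences of length {length} at pairwise "
                f"Hamming >= {min_distance} within {max_tries} tries; "
                "use longer sequences or fewer references"
            )
        tries += 1
        cand = rng.integers(0, 4, size=length, dtype=np.uint8)
        if accepted.shape[0]:
            dists = (accepted != cand[None, :]).sum(axis=1)
            if dists.min() < min_distance:
                continue
        accepted = np.vstack([accepted, cand[None, :]])
    return [_decode(row) for row in accepted]


def generate_references(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[BarcodeWhitelist, TagReference]:
    """Draw the whitelist and tag reference; deterministic under the seed."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    barcodes = _random_distinct_sequences(rng, config.n_cells, config.barcode_length)
    oligos = _random_distinct_sequences(rng, config.n_tags, config.tag_oligo_length)
    names = tuple(f"marker{i:03d}" for i in range(config.n_tags))
    return BarcodeWhitelist(tuple(barcodes)), TagReference(names, tuple(oligos))


def _draw_umis(
    rng: np.random.Generator, n: int, length: int, unique: bool
) -> list[str]:
    space = 4**length
    if unique and n > space:
        raise ValueError(f"cannot draw {n} unique UMIs of length {length}")
    codes: list[int] = []
    seen: set[int] = set()
    while len(codes) < n:
        batch = rng.integers(0, space, size=max(16, n - len(codes)))
        for code in batch:
            if len(codes) >= n:
                break
            code = int(code)
            if unique:
                if code in seen:
                    continue
                seen.add(code)
            codes.append(code)
    out = []
    for code in codes:
        digits = [(code >> (2 * k)) & 3 for k in range(length)]
        out.append(_BASES[digits].tobytes().decode("ascii"))
    return out


def _mutate(
    rng: np.random.Generator, seq: str, rate: float
) -> tuple[str, tuple[int, ...]]:
    """Independent per-base substitutions; a mutated base always changes."""
    if rate <= 0.0:
        return seq, ()
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    mask = rng.random(arr.size) < rate
    positions = np.flatnonzero(mask)
    if positions.size:
        orig = _BASE_LUT[arr[positions]]
        shift = rng.integers(1, 4, size=positions.size)
        arr[positions] = _BASES[(orig + shift) % 4]
    return arr.tobytes().decode("ascii"), tuple(int(p) for p in positions)


def _open_out(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "wt")
    return open(path, "w")


def generate_dataset(
    config: SimulationConfig, out_dir: str | os.PathLike
) -> SimulatedDataset:
    """Generate FASTQ pairs plus references and exact ground truth.

    Layout matches the default ReadLayout: the cellID read is exactly the
    (possibly mutated) cell barcode; the tag read is tag oligo followed by
    UMI. Each molecule emits one read, plus one duplicate read with
    probability ``duplication_rate``; substitutions are applied per emitted
    read.
    """
    rng = np.random.default_rng(config.seed)
    whitelist, tags = generate_references(config, rng)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    counts = rng.poisson(config.mean_molecules, size=(config.n_cells, config.n_tags))
    truth_matrix = CountMatrix(
        whitelist.sequences,
        tags.names,
        sp.csr_matrix(counts.astype(np.int64)),
    )

    reads: list[ReadProvenance] = []
    cell_lines: list[str] = []
    tag_lines: list[str] = []
    n_dup = 0
    n_sub = 0
    err = config.substitution_error_rate
    read_idx = 0

    for c in range(config.n_cells):
        m_c = int(counts[c].sum())
        umis = _draw_umis(
            rng, m_c, config.umi_length, unique=not config.allow_umi_collisions
        )
        u = 0
        for t in range(config.n_tags):
            for _ in range(int(counts[c, t])):
                umi = umis[u]
                u += 1
                n_copies = 1 + int(rng.random() < config.duplication_rate)
                for copy in range(n_copies):
                    bc_mut, bc_pos = _mutate(rng, whitelist.sequences[c], err)
                    tag_mut, tag_pos = _mutate(rng, tags.sequences[t], err)
                    umi_mut, umi_pos = _mutate(rng, umi, err)
                    mutated = (
                        tuple(("cell", p) for p in bc_pos)
                        + tuple(("tag", p) for p in tag_pos)
                        + tuple(("umi", p) for p in umi_pos)
                    )
                    n_sub += len(mutated)
                    is_dup = copy > 0
                    n_dup += int(is_dup)
                    rid = f"sim{read_idx:08d}"
                    read_idx += 1
                    reads.append(
                        ReadProvenance(rid, c, t, umi, is_dup, mutated)
                    )
                    cell_lines.append(
                        f"@{rid}\n{bc_mut}\n+\n{'I' * len(bc_mut)}"
                    )
                    tag_seq = tag_mut + umi_mut
                    tag_lines.append(
                        f"@{rid}\n{tag_seq}\n+\n{'I' * len(tag_seq)}"
                    )

    cell_fastq = out / "cell_reads.fastq"
    tag_fastq = out / "tag_reads.fastq"
    with _open_out(cell_fastq) as fh:
        fh.write("\n".join(cell_lines) + ("\n" if cell_lines else ""))
    with _open_out(tag_fastq) as fh:
        fh.write("\n".join(tag_lines) + ("\n" if tag_lines else ""))

    whitelist_path = out / "whitelist.txt"
    with open(whitelist_path, "w") as fh:
        for bc in whitelist.sequences:
            fh.write(bc + "\n")
    tag_reference_path = out / "tag_reference.csv"
    with open(tag_reference_path, "w") as fh:
        fh.write("name,sequence\n")
        for name, seq in zip(tags.names, tags.sequences):
            fh.write(f"{name},{seq}\n")

    window_bases = (
        config.barcode_length + config.tag_oligo_length + config.umi_length
    )
    truth = GroundTruth(
        truth_matrix=truth_matrix,
        reads=reads,
        n_molecules=int(counts.sum()),
        n_duplicate_reads=n_dup,
        n_substituted_bases=n_sub,
        n_emitted_bases=len(reads) * window_bases,
    )
    return SimulatedDataset(
        cell_fastq=cell_fastq,
        tag_fastq=tag_fastq,
        whitelist_path=whitelist_path,
        tag_reference_path=tag_reference_path,
        whitelist=whitelist,
        tags=tags,
        truth=truth,
    )
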