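"""UMI deduplication and duplication-profile statistics.

Two modes: ``exact`` drops reads whose dedup key (cell barcode + UMI, plus
the tag when configured) has been seen before; ``close`` additionally drops
reads whose UMI is within a Hamming radius of any already-kept UMI in the
same group. Both keep the first occurrence, so results are deterministic
for a fixed input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .matching import hamming_distance

__all__ = [
    "MoleculeAssignment",
    "DedupPolicy",
    "dedup_exact",
    "dedup_close",
    "duplication_profile",
    "exact_vs_close_difference",
    "DuplicationProfile",
]


@dataclass(frozen=True)
class MoleculeAssignment:
    """A read resolved to (cell, tag) with its UMI; ``order`` is the
    original read index."""

    order: int
    cell_index: int
    tag_index: int
    umi: str


@dataclass(frozen=True)
class DedupPolicy:
    """How duplicated molecules are identified.

    ``mode`` is ``exact`` (identical key) or ``close`` (UMI within
    ``max_mismatch`` Hamming distance). The dedup key is (cell, UMI) by
    default; ``key_includes_tag`` adds the tag index, the conventional
    feature-barcoding key.
    """

    mode: str = "exact"
    max_mismatch: int = 1
    key_includes_tag: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("exact", "close"):
            raise ValueError(f"unknown dedup mode: {self.mode!r}")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")

    def validate_for_run(self) -> None:
        """Stricter check applied before a pipeline run."""
        if self.mode == "close" and self.max_mismatch < 1:
            raise ValueError("close mode requires max_mismatch >= 1")


def _group_key(mol: MoleculeAssignment, include_tag: bool):
    if include_tag:
        return (mol.cell_index, mol.tag_index)
    return mol.cell_index


def dedup_exact(
    molecules: Sequence[MoleculeAssignment], policy: DedupPolicy | None = None
) -> tuple[list[MoleculeAssignment], int]:
    """Keep the first molecule per exact dedup key; return (kept, removed)."""
    policy = policy or DedupPolicy()
    seen: set = set()
    kept: list[MoleculeAssignment] = []
    for mol in molecules:
        key = (_group_key(mol, policy.key_includes_tag), mol.umi)
        if key in seen:
            continue
        seen.add(key)
        kept.append(mol)
    return kept, len(molecules) - len(kept)


def _close_scan(
    molecules: Sequence[MoleculeAssignment], policy: DedupPolicy
) -> tuple[list[MoleculeAssignment], list[int]]:
    """Greedy first-seen-representative scan.

    Returns the kept list plus, for every input molecule, the position (in
    input order) of the kept molecule representing its duplicate cluster.
    """
    kept: list[MoleculeAssignment] = []
    cluster_of: list[int] = []
    # per group: list of (input position, umi) of kept molecules
    groups: dict = {}
    for pos, mol in enumerate(molecules):
        gkey = _group_key(mol, policy.key_includes_tag)
        kept_here = groups.setdefault(gkey, [])
        rep = None
        for kpos, kumi in kept_here:
            if len(kumi) != len(mol.umi):
                raise ValueError(
                    f"ragged UMI lengths within dedup group {gkey!r}: "
                    f"{len(kumi)} vs {len(mol.umi)}"
                )
            if hamming_distance(mol.umi, kumi) <= policy.max_mismatch:
                rep = kpos
                break
        if rep is None:
            kept_here.append((pos, mol.umi))
            kept.append(mol)
            rep = pos
        cluster_of.append(rep)
    return kept, cluster_of


def dedup_close(
    molecules: Sequence[MoleculeAssignment], policy: DedupPolicy | None = None
) -> tuple[list[MoleculeAssignment], int]:
    """Drop molecules whose UMI is within the Hamming radius of any
    already-kept molecule in the same group; return (kept, removed)."""
    policy = policy or DedupPolicy(mode="close")
    kept, _ = _close_scan(molecules, policy)
    return kept, len(molecules) - len(kept)


@dataclass
class DuplicationProfile:
    """Per-key duplicate fractions, as in a duplication histogram."""

    fractions: np.ndarray  # (c - 1) / c per dedup key with total count c
    zero_duplicate_share: float
    hist_counts: np.ndarray = field(repr=False)
    hist_edges: np.ndarray = field(repr=False)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("duplicate_fraction\n")
            for f in self.fractions:
                fh.write(f"{f:.6g}\n")


def duplication_profile(
    molecules: Sequence[MoleculeAssignment],
    policy: DedupPolicy | None = None,
    bins: int = 20,
) -> DuplicationProfile:
    """Histogram the duplicate fraction (c - 1)/c over exact dedup keys.

    Also reports the share of keys with zero duplicates (c == 1).
    """
    if not molecules:
        raise ValueError("duplication_profile requires a nonempty molecule list")
    policy = policy or DedupPolicy()
    counts: dict = {}
    for mol in molecules:
        key = (_group_key(mol, policy.key_includes_tag), mol.umi)
        counts[key] = counts.get(key, 0) + 1
    c = np.array(list(counts.values()), dtype=float)
    fractions = (c - 1.0) / c
    hist_counts, hist_edges = np.histogram(fractions, bins=bins, range=(0.0, 1.0))
    return DuplicationProfile(
        fractions=fractions,
        zero_duplicate_share=float(np.mean(c == 1)),
        hist_counts=hist_counts,
        hist_edges=hist_edges,
    )


def exact_vs_close_difference(
    molecules: Sequence[MoleculeAssignment], policy: DedupPolicy | None = None
) -> np.ndarray:
    """Per-cluster normalized difference between close and exact dedup.

    Molecules are clustered by the close-mode scan; within each cluster of
    total count c, close mode removes c - 1 molecules and exact mode
    removes c - u where u is the number of distinct UMIs, so the
    normalized difference is (duplicates_close - duplicates_exact) / c.
    Never negative. Returned in cluster-representative order.
    """
    policy = policy or DedupPolicy(mode="close")
    if not molecules:
        return np.array([])
    _, cluster_of = _close_scan(molecules, policy)
    totals: dict[int, int] = {}
    umis: dict[int, set] = {}
    order: list[int] = []
    for pos, rep in enumerate(cluster_of):
        if rep not in totals:
            totals[rep] = 0
            umis[rep] = set()
            order.append(rep)
        totals[rep] += 1
        umis[rep].add(molecules[pos].umi)
    diffs = []
    for rep in order:
        c = totals[rep]
        dup_close = c - 1
        dup_exact = c - len(umis[rep])
        diffs.append((dup_close - dup_exact) / c)
    return np.array(diffs)
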