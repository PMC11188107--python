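"""Approximate string matching of read windows against reference lists.

Two metrics are supported: Hamming distance for fixed-length cell barcodes
and a normalized edit-distance similarity ratio for tag oligos. Batches are
processed in chunks; results are independent of the chunk size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "MatchPolicy",
    "MatchResult",
    "hamming_distance",
    "edit_ratio",
    "match_batch",
]

_ACGT = frozenset("ACGT")

# Separate encodings for queries and references so that ambiguous bases can
# never match anything: query non-ACGT -> 5, reference non-ACGT -> 6, hence
# N vs N compares unequal.
_Q_TABLE = np.full(256, 5, dtype=np.uint8)
_R_TABLE = np.full(256, 6, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _Q_TABLE[_b] = _i + 1
    _R_TABLE[_b] = _i + 1

# Cap on simultaneous query x reference DP cells, to bound memory.
_MAX_PAIR_BLOCK = 500_000


@dataclass(frozen=True)
class MatchPolicy:
    """Cutoffs and batching parameters for reference matching.

    ``hamming_cutoff`` is the maximum number of mismatches tolerated for
    barcode matching; ``ratio_cutoff`` the minimum normalized edit
    similarity for tag matching.
    """

    metric: str = "hamming"
    hamming_cutoff: int = 1
    ratio_cutoff: float = 0.93
    chunk_size: int = 100_000

    def __post_init__(self) -> None:
        if self.metric not in ("hamming", "edit_ratio"):
            raise ValueError(f"unknown metric: {self.metric!r}")
        if self.hamming_cutoff < 0:
            raise ValueError("hamming_cutoff must be >= 0")
        if not (0.0 < self.ratio_cutoff <= 1.0):
            raise ValueError("ratio_cutoff must be in (0, 1]")
        if self.chunk_size < 1:
            raise ValueError("chunk_size must be >= 1")


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching one query against a reference list.

    ``status`` is ``assigned`` (exactly one reference within cutoff, index
    in ``reference_index``), ``ambiguous`` (two or more) or ``unmatched``
    (none).
    """

    query_index: int
    status: str
    reference_index: int | None
    n_passing: int

    def __post_init__(self) -> None:
        ok = (
            (self.status == "assigned" and self.n_passing == 1 and self.reference_index is not None)
            or (self.status == "ambiguous" and self.n_passing >= 2 and self.reference_index is None)
            or (self.status == "unmatched" and self.n_passing == 0 and self.reference_index is None)
        )
        if not ok:
            raise ValueError(
                f"inconsistent MatchResult: status={self.status} "
                f"n_passing={self.n_passing} reference_index={self.reference_index}"
            )


def hamming_distance(a: str, b: str) -> int:
    """Number of differing positions between equal-length sequences.

    Any non-ACGT character (notably ``N``) counts as a difference at its
    position, even against an identical character.
    """
    if len(a) != len(b):
        raise ValueError(
            f"Hamming distance undefined for lengths {len(a)} and {len(b)}"
        )
    return sum(1 for x, y in zip(a, b) if x != y or x not in _ACGT)


def _levenshtein(a: str, b: str) -> int:
    # two-row DP; non-ACGT characters never match
    if not a:
        return len(b)
    if not b:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, x in enumerate(a, start=1):
        cur = [i]
        x_ok = x in _ACGT
        for j, y in enumerate(b, start=1):
            cost = 0 if (x == y and x_ok) else 1
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost))
        prev = cur
    return prev[-1]


def edit_ratio(a: str, b: str) -> float:
    """Normalized edit similarity: ``1 - L(a, b) / max(|a|, |b|)``.

    ``L`` is unit-cost Levenshtein distance. Defined as 1.0 when both
    strings are empty and 0.0 when exactly one is.
    """
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    return 1.0 - _levenshtein(a, b) / max(len(a), len(b))


def _encode(seqs: Sequence[str], table: np.ndarray) -> np.ndarray:
    """Encode equal-length sequences as a (n, L) uint8 matrix."""
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    raw = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    return table[raw.reshape(len(seqs), -1)]


def _levenshtein_block(q_enc: np.ndarray, r_enc: np.ndarray) -> np.ndarray:
    """All-pairs Levenshtein distances between encoded query and reference
    matrices, vectorized over the pair dimension. Returns (nq, nr) int32."""
    nq, la = q_enc.shape
    nr, lb = r_enc.shape
    if la == 0:
        return np.full((nq, nr), lb, dtype=np.int32)
    if lb == 0:
        return np.full((nq, nr), la, dtype=np.int32)
    prev = np.empty((lb + 1, nq, nr), dtype=np.int32)
    cur = np.empty_like(prev)
    prev[:] = np.arange(lb + 1, dtype=np.int32)[:, None, None]
    for i in range(1, la + 1):
        cur[0] = i
        qi = q_enc[:, i - 1][:, None]  # (nq, 1)
        for j in range(1, lb + 1):
            cost = (qi != r_enc[:, j - 1][None, :]).astype(np.int32)
            np.minimum(prev[j] + 1, cur[j - 1] + 1, out=cur[j])
            np.minimum(cur[j], prev[j - 1] + cost, out=cur[j])
        prev, cur = cur, prev
    return prev[lb]


def _results_from_pass_matrix(
    passing: np.ndarray, query_offset: int, indices: Sequence[int]
) -> list[MatchResult]:
    n_passing = passing.sum(axis=1)
    first_hit = passing.argmax(axis=1)
    out = []
    for k, qi in enumerate(indices):
        n = int(n_passing[k])
        if n == 0:
            out.append(MatchResult(query_offset + qi, "unmatched", None, 0))
        elif n == 1:
            out.append(MatchResult(query_offset + qi, "assigned", int(first_hit[k]), 1))
        else:
            out.append(MatchResult(query_offset + qi, "ambiguous", None, n))
    return out


def _match_chunk_hamming(
    queries: Sequence[str], reference: Sequence[str], cutoff: int, offset: int
) -> list[MatchResult]:
    ref_len = len(reference[0])
    fit = [i for i, q in enumerate(queries) if len(q) == ref_len]
    results: dict[int, MatchResult] = {}
    for i, q in enumerate(queries):
        if len(q) != ref_len:
            results[i] = MatchResult(offset + i, "unmatched", None, 0)
    if fit:
        q_enc = _encode([queries[i] for i in fit], _Q_TABLE)
        r_enc = _encode(list(reference), _R_TABLE)
        dist = (q_enc[:, None, :] != r_enc[None, :, :]).sum(axis=2)
        for res in _results_from_pass_matrix(dist <= cutoff, offset, fit):
            results[res.query_index - offset] = res
    return [results[i] for i in range(len(queries))]


def _match_chunk_edit_ratio(
    queries: Sequence[str], reference: Sequence[str], cutoff: float, offset: int
) -> list[MatchResult]:
    # Deduplicate queries: tag reads are highly redundant.
    uniq: dict[str, list[int]] = {}
    for i, q in enumerate(queries):
        uniq.setdefault(q, []).append(i)
    uniq_seqs = list(uniq)

    # Group unique queries and references by length so each group encodes
    # to a rectangular matrix.
    by_qlen: dict[int, list[str]] = {}
    for q in uniq_seqs:
        by_qlen.setdefault(len(q), []).append(q)
    by_rlen: dict[int, list[int]] = {}
    for j, r in enumerate(reference):
        by_rlen.setdefault(len(r), []).append(j)

    ref_lengths = np.array([len(r) for r in reference])
    passing_by_seq: dict[str, np.ndarray] = {}
    for qlen, qgroup in by_qlen.items():
        ratio = np.zeros((len(qgroup), len(reference)))
        if qlen == 0:
            # empty query: similarity 0 against nonempty references
            pass
        else:
            for rlen, ridx in by_rlen.items():
                r_enc = _encode([reference[j] for j in ridx], _R_TABLE)
                block = max(1, _MAX_PAIR_BLOCK // max(1, len(ridx)))
                for start in range(0, len(qgroup), block):
                    sub = qgroup[start : start + block]
                    q_enc = _encode(sub, _Q_TABLE)
                    dist = _levenshtein_block(q_enc, r_enc)
                    denom = max(qlen, rlen) if max(qlen, rlen) else 1
                    ratio[start : start + block, ridx] = 1.0 - dist / denom
        passing = ratio >= cutoff
        for k, q in enumerate(qgroup):
            passing_by_seq[q] = passing[k]

    results: list[MatchResult | None] = [None] * len(queries)
    for q, positions in uniq.items():
        row = passing_by_seq[q][None, :]
        for pos in positions:
            results[pos] = _results_from_pass_matrix(row, offset, [pos])[0]
    return results  # type: ignore[return-value]


def match_batch(
    queries: Sequence[str],
    reference: Sequence[str],
    policy: MatchPolicy,
) -> list[MatchResult]:
    """Match every query against the reference list, in chunks.

    A reference *passes* for a query when the Hamming distance is at most
    ``policy.hamming_cutoff`` (hamming metric) or the edit similarity is at
    least ``policy.ratio_cutoff`` (edit_ratio metric). Exactly one passing
    reference assigns the query; two or more mark it ambiguous; none leave
    it unmatched. Output order follows query order and is identical for
    every chunk size.

    Under the hamming metric, queries whose length differs from the
    reference length are reported unmatched rather than raising.
    """
    reference = list(reference)
    if not reference:
        raise ValueError("reference list must be nonempty")
    if policy.metric == "hamming":
        ref_len = len(reference[0])
        if any(len(r) != ref_len for r in reference):
            raise ValueError("hamming metric requires equal-length references")
    queries = list(queries)
    results: list[MatchResult] = []
    for start in range(0, len(queries), policy.chunk_size):
        chunk = queries[start : start + policy.chunk_size]
        if policy.metric == "hamming":
            results.extend(
                _match_chunk_hamming(chunk, reference, policy.hamming_cutoff, start)
            )
        else:
            results.extend(
                _match_chunk_edit_ratio(chunk, reference, policy.ratio_cutoff, start)
            )
    return results


def iter_chunks(items: Sequence, size: int) -> Iterator[Sequence]:
    """Yield successive slices of at most ``size`` items."""
    for start in range(0, len(items), size):
        yield items[start : start + size]
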