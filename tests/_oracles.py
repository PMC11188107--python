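"""Independent brute-force oracles used to check the package's fast paths.

Everything here is deliberately naive: character loops, full dynamic
programming tables, quadratic scans. Nothing imports the implementation
modules being checked.
"""

from __future__ import annotations

ACGT = set("ACGT")


def hamming_oracle(a: str, b: str) -> int:
    assert len(a) == len(b)
    d = 0
    for i in range(len(a)):
        if a[i] != b[i] or a[i] not in ACGT or b[i] not in ACGT:
            d += 1
    return d


def levenshtein_oracle(a: str, b: str) -> int:
    """Full-table unit-cost Levenshtein DP; non-ACGT never matches."""
    n, m = len(a), len(b)
    table = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n + 1):
        table[i][0] = i
    for j in range(m + 1):
        table[0][j] = j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            match = a[i - 1] == b[j - 1] and a[i - 1] in ACGT
            table[i][j] = min(
                table[i - 1][j] + 1,
                table[i][j - 1] + 1,
                table[i - 1][j - 1] + (0 if match else 1),
            )
    return table[n][m]


def edit_ratio_oracle(a: str, b: str) -> float:
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    return 1.0 - levenshtein_oracle(a, b) / max(len(a), len(b))


def match_oracle(queries, reference, metric, hamming_cutoff=1, ratio_cutoff=0.93):
    """Exhaustive all-pairs matcher.

    Returns a list of (status, reference_index_or_None, n_passing).
    """
    out = []
    for q in queries:
        passing = []
        for j, r in enumerate(reference):
            if metric == "hamming":
                if len(q) != len(r):
                    continue
                ok = hamming_oracle(q, r) <= hamming_cutoff
            else:
                ok = edit_ratio_oracle(q, r) >= ratio_cutoff
            if ok:
                passing.append(j)
        if len(passing) == 1:
            out.append(("assigned", passing[0], 1))
        elif not passing:
            out.append(("unmatched", None, 0))
        else:
            out.append(("ambiguous", None, len(passing)))
    return out


def dedup_exact_oracle(molecules, include_tag=False):
    """Group-and-take-first over (cell[, tag], umi) keys."""
    kept, seen = [], set()
    for mol in molecules:
        key = (mol.cell_index, mol.tag_index, mol.umi) if include_tag else (
            mol.cell_index,
            mol.umi,
        )
        if key not in seen:
            seen.add(key)
            kept.append(mol)
    return kept, len(molecules) - len(kept)


def dedup_close_oracle(molecules, max_mismatch, include_tag=False):
    """Quadratic greedy scan: compare each molecule to all kept predecessors."""
    kept = []
    for mol in molecules:
        dup = False
        for prev in kept:
            same_group = prev.cell_index == mol.cell_index and (
                not include_tag or prev.tag_index == mol.tag_index
            )
            if same_group and hamming_oracle(prev.umi, mol.umi) <= max_mismatch:
                dup = True
                break
        if not dup:
            kept.append(mol)
    return kept, len(molecules) - len(kept)


def random_dna(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGT")) for _ in range(length))
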