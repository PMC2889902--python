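"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the library's code paths: the overlap aligner is a
hand-written semi-global dynamic program, the clustering oracle a plain
union-find over all pairs, and the hypergeometric tail a direct sum of
binomial terms.
"""

from __future__ import annotations

from math import comb

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

MATCH, MISMATCH, GAP = 1.0, -1.0, -2.0


def revcomp_oracle(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _dp_overlap(a: str, b: str) -> tuple[float, int, int]:
    """Semi-global (free end gaps) alignment; returns (score, columns, matches).

    Linear gap penalty; columns/matches counted over the overlap region of
    the traceback path, trimmed to the first and last substitution column.
    """
    n, m = len(a), len(b)
    a_arr = np.frombuffer(a.encode(), dtype=np.uint8)
    b_arr = np.frombuffer(b.encode(), dtype=np.uint8)
    H = np.zeros((n + 1, m + 1))
    idx = np.arange(m + 1)
    for i in range(1, n + 1):
        sub = np.where(b_arr == a_arr[i - 1], MATCH, MISMATCH)
        t = np.empty(m + 1)
        t[0] = 0.0  # free leading gap in b
        t[1:] = np.maximum(H[i - 1, :-1] + sub, H[i - 1, 1:] + GAP)
        # resolve the horizontal (left) dependency with a running maximum
        H[i] = np.maximum.accumulate(t - GAP * idx) + GAP * idx
        H[i, 0] = 0.0  # free leading gap in a
    # free trailing gaps: best cell on the last row or column
    end_candidates = [(H[n, j], n, j) for j in range(m + 1)] + [
        (H[i, m], i, m) for i in range(n + 1)
    ]
    score, i, j = max(end_candidates, key=lambda c: (c[0], c[1], c[2]))
    steps: list[tuple[str, bool]] = []
    while i > 0 and j > 0:
        sub = MATCH if a[i - 1] == b[j - 1] else MISMATCH
        if H[i, j] == H[i - 1, j - 1] + sub:
            steps.append(("diag", a[i - 1] == b[j - 1]))
            i, j = i - 1, j - 1
        elif H[i, j] == H[i - 1, j] + GAP:
            steps.append(("up", False))
            i -= 1
        elif H[i, j] == H[i, j - 1] + GAP:
            steps.append(("left", False))
            j -= 1
        else:  # boundary of the free-end-gap region
            break
    steps.reverse()
    while steps and steps[0][0] != "diag":
        steps.pop(0)
    while steps and steps[-1][0] != "diag":
        steps.pop()
    columns = len(steps)
    matches = sum(1 for kind, is_match in steps if kind == "diag" and is_match)
    return float(score), columns, matches


def overlap_oracle(a: str, b: str) -> tuple[float, int, int]:
    """Best overlap alignment over both orientations of ``b``."""
    forward = _dp_overlap(a, b)
    reverse = _dp_overlap(a, revcomp_oracle(b))
    return forward if forward[0] >= reverse[0] else reverse


def cluster_oracle(
    seqs: dict[str, str], min_overlap: int = 40, min_identity: float = 0.90
) -> list[frozenset]:
    """All-pairs overlap alignment + union-find; returns the partition."""
    ids = list(seqs)
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for pos, id_a in enumerate(ids):
        for id_b in ids[pos + 1 :]:
            _score, columns, matches = overlap_oracle(seqs[id_a], seqs[id_b])
            if columns >= min_overlap and columns and matches / columns >= min_identity:
                parent[find(id_b)] = find(id_a)
    groups: dict[str, set[str]] = {}
    for i in ids:
        groups.setdefault(find(i), set()).add(i)
    return sorted((frozenset(g) for g in groups.values()), key=lambda g: sorted(g)[0])


def hypergeom_tail_oracle(k: int, list_total: int, bg_count: int, bg_total: int) -> float:
    """P(X >= k) for X ~ Hypergeom(bg_total, bg_count, list_total), by direct sum."""
    if k <= 0:
        return 1.0
    denom = comb(bg_total, list_total)
    upper = min(list_total, bg_count)
    total = sum(
        comb(bg_count, x) * comb(bg_total - bg_count, list_total - x)
        for x in range(k, upper + 1)
    )
    return total / denom
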