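"""Independent reference implementations used only as test oracles.

These are deliberately simple and structurally different from the
package code: a recursive memoized aligner (plus a path-enumerating
micro-aligner that validates it), a naive quadratic greedy clustering,
and a mid-rank Spearman coefficient computed from first principles.
"""

from __future__ import annotations

import sys
from functools import lru_cache

sys.setrecursionlimit(100_000)


def oracle_global(a: str, b: str, match: int = 2, mismatch: int = 3,
                  gap_open: int = 5, gap_extend: int = 2) -> tuple[int, int, int]:
    """Best (score, matches, columns) over all global alignments.

    Affine gaps cost ``open + extend * L``; maximizes score, then
    matches, then fewest columns (the package's tie conventions).
    """

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: int):
        if i == len(a) and j == len(b):
            return (0, 0, 0)
        cands = []
        if i < len(a) and j < len(b):
            s, m, c = best(i + 1, j + 1, 0)
            if a[i] == b[j] and a[i] != "N":
                cands.append((s + match, m + 1, c - 1))
            else:
                cands.append((s - mismatch, m, c - 1))
        if i < len(a):
            s, m, c = best(i + 1, j, 1)
            cost = gap_extend if state == 1 else gap_open + gap_extend
            cands.append((s - cost, m, c - 1))
        if j < len(b):
            s, m, c = best(i, j + 1, 2)
            cost = gap_extend if state == 2 else gap_open + gap_extend
            cands.append((s - cost, m, c - 1))
        return max(cands)

    s, m, c = best(0, 0, 0)
    best.cache_clear()
    return s, m, -c


def enumerate_global(a: str, b: str, match: int = 2, mismatch: int = 3,
                     gap_open: int = 5, gap_extend: int = 2) -> tuple[int, int, int]:
    """Exhaustive enumeration of every global alignment (tiny inputs only)."""
    results = []

    def rec(i, j, state, score, matches, cols):
        if i == len(a) and j == len(b):
            results.append((score, matches, -cols))
            return
        if i < len(a) and j < len(b):
            if a[i] == b[j] and a[i] != "N":
                rec(i + 1, j + 1, 0, score + match, matches + 1, cols + 1)
            else:
                rec(i + 1, j + 1, 0, score - mismatch, matches, cols + 1)
        if i < len(a):
            cost = gap_extend if state == 1 else gap_open + gap_extend
            rec(i + 1, j, 1, score - cost, matches, cols + 1)
        if j < len(b):
            cost = gap_extend if state == 2 else gap_open + gap_extend
            rec(i, j + 1, 2, score - cost, matches, cols + 1)

    rec(0, 0, 0, 0, 0, 0)
    s, m, c = max(results)
    return s, m, -c


def oracle_identity(a: str, b: str, denominator: str = "shorter_sequence") -> float:
    _s, matches, cols = oracle_global(a, b)
    denom = min(len(a), len(b)) if denominator == "shorter_sequence" else cols
    return matches / denom


def naive_greedy_cluster(records, threshold, identity, mode="first_fit"):
    """Quadratic re-statement of the greedy rule.

    *records* are (id, residues) pairs; *identity* a callable on two
    sequences.  Returns [(representative_id, [(member_id, identity)])]
    in cluster creation order.
    """
    order = sorted(records, key=lambda r: (-len(r[1]), r[0]))
    clusters: list[tuple[tuple[str, str], list[tuple[str, float]]]] = []
    for rid, seq in order:
        chosen = -1
        chosen_ident = -1.0
        for k, (rep, _members) in enumerate(clusters):
            ident = identity(seq, rep[1])
            if ident >= threshold - 1e-9:
                if mode == "first_fit":
                    chosen, chosen_ident = k, ident
                    break
                if ident > chosen_ident + 1e-9:
                    chosen, chosen_ident = k, ident
        if chosen >= 0:
            clusters[chosen][1].append((rid, chosen_ident))
        else:
            clusters.append(((rid, seq), [(rid, 1.0)]))
    return [(rep[0], members) for rep, members in clusters]


def midrank_spearman(x, y) -> float:
    """Spearman rho as the Pearson correlation of mid-ranks."""

    def midranks(values):
        order = sorted(range(len(values)), key=lambda i: values[i])
        ranks = [0.0] * len(values)
        i = 0
        while i < len(order):
            j = i
            while j < len(order) and values[order[j]] == values[order[i]]:
                j += 1
            mid = (i + 1 + j) / 2.0
            for k in range(i, j):
                ranks[order[k]] = mid
            i = j
        return ranks

    rx = midranks(list(x))
    ry = midranks(list(y))
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = sum((a - mx) ** 2 for a in rx)
    vy = sum((b - my) ** 2 for b in ry)
    return cov / (vx * vy) ** 0.5
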