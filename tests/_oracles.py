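"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package implementation: the
aligner oracle is a direct memoized recursion over alignment moves, the
consensus oracle a naive per-column recount, and the additive-matrix
generator builds random trees and measures leaf-path lengths directly.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

GAP_STATE_NONE, GAP_STATE_A, GAP_STATE_B = 0, 1, 2


def brute_force_global(a: str, b: str, match: int, mismatch: int,
                       gap_open: int, gap_extend: int) -> int:
    """Optimal affine-gap global alignment score by recursion over moves."""

    @lru_cache(maxsize=None)
    def go(i: int, j: int, state: int) -> int:
        if i == len(a) and j == len(b):
            return 0
        best = None
        if i < len(a) and j < len(b):
            s = (match if a[i] == b[j] else mismatch) + go(i + 1, j + 1, GAP_STATE_NONE)
            best = s if best is None else max(best, s)
        if i < len(a):  # gap in b, consume a
            cost = gap_extend if state == GAP_STATE_B else gap_open + gap_extend
            s = cost + go(i + 1, j, GAP_STATE_B)
            best = s if best is None else max(best, s)
        if j < len(b):  # gap in a, consume b
            cost = gap_extend if state == GAP_STATE_A else gap_open + gap_extend
            s = cost + go(i, j + 1, GAP_STATE_A)
            best = s if best is None else max(best, s)
        return best

    result = go(0, 0, GAP_STATE_NONE)
    go.cache_clear()
    return result


def brute_force_local(a: str, b: str, match: int, mismatch: int,
                      gap_open: int, gap_extend: int) -> int:
    """Optimal local score = best global score over all substring pairs
    (the empty alignment scores 0)."""
    best = 0
    for i0 in range(len(a)):
        for i1 in range(i0 + 1, len(a) + 1):
            for j0 in range(len(b)):
                for j1 in range(j0 + 1, len(b) + 1):
                    s = brute_force_global(a[i0:i1], b[j0:j1],
                                           match, mismatch, gap_open, gap_extend)
                    if s > best:
                        best = s
    return best


def naive_majority(rows: list[str], threshold: float = 0.5) -> str:
    """Naive per-column majority recount mirroring the 50%-rule contract."""
    out = []
    for k in range(len(rows[0])):
        col = [r[k] for r in rows]
        bases = [c for c in col if c != "-"]
        gaps = len(col) - len(bases)
        if gaps > len(bases):
            continue
        tally: dict[str, int] = {}
        for c in bases:
            tally[c] = tally.get(c, 0) + 1
        top = sorted(tally.items(), key=lambda kv: -kv[1])
        if (len(top) == 1 or top[0][1] > top[1][1]) \
                and top[0][1] / len(bases) >= threshold \
                and 2 * len(bases) >= len(col):
            out.append(top[0][0])
        else:
            out.append("N")
    return "".join(out)


def random_additive_matrix(rng: np.random.Generator, n: int):
    """A random tree with random branch lengths, its leaf labels, and the
    exact additive leaf-to-leaf distance matrix (path lengths)."""
    # sequential attachment: start from a 3-leaf star, attach each new
    # leaf to a random existing edge
    edges = {}  # node -> list of (node, length)

    def add_edge(u, v, w):
        edges.setdefault(u, []).append((v, w))
        edges.setdefault(v, []).append((u, w))

    def del_edge(u, v):
        edges[u] = [(x, w) for x, w in edges[u] if x != v]
        edges[v] = [(x, w) for x, w in edges[v] if x != u]

    center = "i0"
    for i in range(3):
        add_edge(center, f"L{i}", float(rng.uniform(0.1, 1.0)))
    next_internal = 1
    for i in range(3, n):
        # pick a random edge
        all_edges = sorted(
            {tuple(sorted((u, v))) for u in edges for v, _ in edges[u]}
        )
        u, v = all_edges[rng.integers(0, len(all_edges))]
        w = dict(edges[u])[v]
        mid = f"i{next_internal}"
        next_internal += 1
        t = float(rng.uniform(0.2, 0.8))
        del_edge(u, v)
        add_edge(u, mid, w * t)
        add_edge(mid, v, w * (1 - t))
        add_edge(mid, f"L{i}", float(rng.uniform(0.1, 1.0)))
    labels = [f"L{i}" for i in range(n)]
    D = np.zeros((n, n))
    for i, src in enumerate(labels):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            node = stack.pop()
            for nxt, w in edges.get(node, []):
                if nxt not in dist:
                    dist[nxt] = dist[node] + w
                    stack.append(nxt)
        for j, dst in enumerate(labels):
            D[i, j] = dist[dst]
    return D, labels
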