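"""Independent oracles used by the test suite.

Each oracle computes its quantity by a different route than the library
(exhaustive enumeration, closed forms, or construction) and was written
before the code it checks.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


# ---------------------------------------------------------------------------
# brute-force local alignment
#
# Any gapped local alignment is fully described by its set of aligned columns:
# an increasing sequence of (query position, subject position) pairs.  Residues
# lying between consecutive aligned columns must sit in gaps, with an affine
# cost of open + (g - 1) * extend per run.  Enumerating every pair of
# equal-size position subsets (as bitmasks) therefore enumerates every local
# alignment exactly.


@njit(cache=False)
def _popcount(x: int) -> int:
    c = 0
    while x:
        x &= x - 1
        c += 1
    return c


@njit(cache=False)
def _mask_positions(mask: int, out: np.ndarray) -> int:
    k = 0
    pos = 0
    while mask:
        if mask & 1:
            out[k] = pos
            k += 1
        mask >>= 1
        pos += 1
    return k


@njit(cache=False)
def brute_force_local_score(q: np.ndarray, s: np.ndarray, sub: np.ndarray,
                            gap_open: int, gap_extend: int) -> int:
    """Exhaustive best local alignment score (sequences as residue indices)."""
    m, n = len(q), len(s)
    best = 0
    qpos = np.empty(m, dtype=np.int64)
    spos = np.empty(n, dtype=np.int64)
    for qmask in range(1, 1 << m):
        kq = _popcount(qmask)
        _mask_positions(qmask, qpos)
        for smask in range(1, 1 << n):
            if _popcount(smask) != kq:
                continue
            _mask_positions(smask, spos)
            score = 0
            for t in range(kq):
                score += sub[q[qpos[t]], s[spos[t]]]
                if t:
                    dq = qpos[t] - qpos[t - 1] - 1
                    ds = spos[t] - spos[t - 1] - 1
                    if dq > 0:
                        score -= gap_open + (dq - 1) * gap_extend
                    if ds > 0:
                        score -= gap_open + (ds - 1) * gap_extend
            if score > best:
                best = score
    return best


# ---------------------------------------------------------------------------
# hypergeometric enumeration for Fisher's one-sided test


def hypergeom_tail(a: int, b: int, c: int, d: int) -> float:
    """P[X >= a] by direct enumeration of the hypergeometric mass.

    Margins: term total K = a + b, test-set total n = a + c, population
    N = a + b + c + d.
    """
    K, n, N = a + b, a + c, a + b + c + d
    if N == 0:
        return 1.0
    denom = math.comb(N, n)
    total = 0
    for x in range(a, min(K, n) + 1):
        total += math.comb(K, x) * math.comb(N - K, n - x)
    return total / denom


# ---------------------------------------------------------------------------
# random additive trees (the NJ oracle)


def random_additive_tree(n_leaves: int, rng: np.random.Generator):
    """A random unrooted binary tree and its (additive) leaf distance matrix.

    Built by sequential leaf insertion on an explicit edge list; path
    lengths come from breadth-first traversal of that graph, independent of
    any tree library.
    """
    labels = [f"L{i}" for i in range(n_leaves)]
    # adjacency: node -> list of (neighbor, branch length); leaves are labels
    adj: dict = {labels[0]: [], labels[1]: []}
    w = float(rng.uniform(0.1, 1.0))
    adj[labels[0]].append((labels[1], w))
    adj[labels[1]].append((labels[0], w))
    next_internal = 0
    for leaf in labels[2:]:
        # pick a random existing edge and subdivide it
        edges = [(u, v, w) for u in adj for v, w in adj[u] if str(u) < str(v)]
        u, v, w = edges[rng.integers(0, len(edges))]
        mid = ("I", next_internal)
        next_internal += 1
        split = float(rng.uniform(0.2, 0.8)) * w
        adj[u] = [(x, y) for x, y in adj[u] if x != v] + [(mid, split)]
        adj[v] = [(x, y) for x, y in adj[v] if x != u] + [(mid, w - split)]
        wl = float(rng.uniform(0.1, 1.0))
        adj[mid] = [(u, split), (v, w - split), (leaf, wl)]
        adj[leaf] = [(mid, wl)]
    dist = np.zeros((n_leaves, n_leaves))
    for i, src in enumerate(labels):
        seen = {src: 0.0}
        queue = [src]
        while queue:
            node = queue.pop()
            for nb, w in adj[node]:
                if nb not in seen:
                    seen[nb] = seen[node] + w
                    queue.append(nb)
        for j, dst in enumerate(labels):
            dist[i, j] = seen[dst]
    return labels, dist, adj
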