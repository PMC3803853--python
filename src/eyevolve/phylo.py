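"""Trimmed-fragment distances and neighbor-joining trees.

Contigs are trimmed to the translated region of their best hit, pairwise
protein distances are computed from global alignments (observed mismatch
fraction ``d`` over gap-free columns, optionally Kimura-corrected as
``D = -ln(1 - d - 0.2 d^2)``, the ClustalW protein default), and trees are
built with Saitou-Nei neighbor joining.  Tie-breaks are deterministic
(lexicographically smallest label pair on equal Q) and negative branch
estimates are clamped to zero with the deficit pushed to the sibling branch
and logged.  Trees are :class:`dendropy.Tree` objects serialized as newick;
distance matrices are written in PHYLIP square format.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .align import ScoringScheme, global_align
from .io import logger
from .translate import translate_frame_interval

#: Kimura's protein correction is undefined at and beyond this raw distance
KIMURA_MAX_D = 0.85


def trim_to_hit(contig_seq: str, hit) -> str:
    """Translated fragment of a contig restricted to its hit interval.

    ``hit`` is a hit-table row (needs ``frame``, ``qstart``, ``qend``).
    """
    return translate_frame_interval(contig_seq, int(hit.frame),
                                    int(hit.qstart), int(hit.qend))


def pairwise_distance(a_aligned: str, b_aligned: str, kimura: bool = True) -> float:
    """Distance between two rows of an alignment.

    Columns with a gap in either row are excluded; ``d`` is the mismatch
    fraction over the compared columns.  With ``kimura`` the corrected
    distance ``-ln(1 - d - 0.2 d^2)`` is returned; raw distances of 0.85 or
    more make the correction undefined and raise.
    """
    if len(a_aligned) != len(b_aligned):
        raise ValueError("aligned sequences must have equal length")
    pairs = [(x, y) for x, y in zip(a_aligned, b_aligned)
             if x != "-" and y != "-"]
    if not pairs:
        raise ValueError("no gap-free columns to compare")
    d = sum(1 for x, y in pairs if x != y) / len(pairs)
    if not kimura:
        return d
    if d >= KIMURA_MAX_D:
        raise ValueError(f"raw distance {d:.3f} >= {KIMURA_MAX_D}; Kimura "
                         "correction undefined")
    return -math.log(1.0 - d - 0.2 * d * d)


@dataclass
class DistanceMatrix:
    """Symmetric non-negative matrix with a zero diagonal and leaf labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate leaf labels")
        if not np.allclose(v, v.T) or np.any(np.diag(v) != 0) or np.any(v < 0) \
                or not np.all(np.isfinite(v)):
            raise ValueError("matrix must be symmetric, finite, non-negative "
                             "with zero diagonal")
        self.values = v

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def to_phylip(self) -> str:
        lines = [f"{len(self.labels)}"]
        for label, row in zip(self.labels, self.values):
            lines.append("  ".join([f"{label:<10s}"]
                                   + [f"{x:.6f}" for x in row]))
        return "\n".join(lines) + "\n"


def distances_from_sequences(seqs: Mapping[str, str],
                             scheme: ScoringScheme | None = None,
                             kimura: bool = True) -> DistanceMatrix:
    """All-pairs corrected distances via pairwise global alignment.

    Pairwise global alignment (BLOSUM62, same gap costs as the search)
    stands in for a progressive MSA: candidates involve at most a handful
    of short fragments.
    """
    labels = sorted(seqs)
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            rows = global_align(seqs[labels[i]], seqs[labels[j]], scheme)
            values[i, j] = values[j, i] = pairwise_distance(*rows, kimura=kimura)
    return DistanceMatrix(labels, values)


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei NJ tree from a distance matrix (>= 3 leaves).

    Iteratively joins the pair minimizing
    ``Q(i,j) = (n-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k)``; equal Q values
    are broken by the lexicographically smallest (cluster label) pair, where
    a cluster is labeled by its smallest leaf.  Branch lengths come from the
    standard two-point formulas; negative estimates are clamped to zero with
    the deficit moved to the sibling branch.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 leaves")
    D = dm.values.astype(float).copy()
    # each active cluster: (tie-break label, newick fragment)
    nodes: list[tuple[str, str]] = [(lab, lab) for lab in dm.labels]

    def _clamp(la: float, lb: float) -> tuple[float, float]:
        if la < 0:
            logger.debug("clamping negative branch %.3g", la)
            lb += la
            la = 0.0
        if lb < 0:
            logger.debug("clamping negative branch %.3g", lb)
            la += lb
            lb = 0.0
        return max(la, 0.0), max(lb, 0.0)

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                pair = tuple(sorted((nodes[i][0], nodes[j][0])))
                key = (q, pair)
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        li, lj = _clamp(li, lj)
        label = min(nodes[i][0], nodes[j][0])
        newick = f"({nodes[i][1]}:{li:.17g},{nodes[j][1]}:{lj:.17g})"
        d_new = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.zeros((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = d_new[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [(label, newick)]

    # final three clusters join at the central node
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    l0 = 0.5 * (d01 + d02 - d12)
    l1 = 0.5 * (d01 + d12 - d02)
    l2 = 0.5 * (d02 + d12 - d01)
    lens = [max(x, 0.0) for x in (l0, l1, l2)]
    if any(x < 0 for x in (l0, l1, l2)):
        logger.debug("clamped negative terminal branch in 3-point step")
    order = sorted(range(3), key=lambda k: nodes[k][0])
    newick = "(" + ",".join(
        f"{nodes[k][1]}:{lens[k]:.17g}" for k in order) + ");"
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = False
    return tree


def leaf_distance(tree: dendropy.Tree, a: str, b: str) -> float:
    """Sum of branch lengths on the unique path between two leaves."""
    if a == b:
        if tree.taxon_namespace.get_taxon(a) is None:
            raise KeyError(f"unknown leaf {a!r}")
        return 0.0
    pdm = tree.phylogenetic_distance_matrix()
    ta = tree.taxon_namespace.get_taxon(a)
    tb = tree.taxon_namespace.get_taxon(b)
    if ta is None or tb is None:
        raise KeyError(f"unknown leaf {a if ta is None else b!r}")
    return float(pdm.patristic_distance(ta, tb))


def has_cherry(tree: dendropy.Tree, a: str, b: str) -> bool:
    """True iff some edge of the (unrooted) tree splits {a, b} from the rest."""
    want = {a, b}
    for node in tree.preorder_node_iter():
        leaves = {lf.taxon.label for lf in node.leaf_iter()}
        if leaves == want:
            return True
    all_leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    return bool((all_leaves - want) in
                [{lf.taxon.label for lf in n.leaf_iter()}
                 for n in tree.preorder_node_iter()])


def to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True,
                          unquoted_underscores=True,
                          real_value_format_specifier=".6f").strip()
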