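"""Tamura-Nei distances, UPGMA trees and bootstrap support.

The TN93 model separates the two transition classes (A<->G within purines,
C<->T within pyrimidines) from transversions and allows unequal base
frequencies; frequencies are estimated from the two sequences pooled, with
pairwise deletion of gap/N columns. No gamma rate correction is applied.

UPGMA is plain average-linkage agglomeration: the height of a joined node
is half the joined distance, so the result is rooted and ultrametric. Ties
are broken deterministically by the lexicographic order of the merged leaf
name sets. Bootstrap support of an internal node is the percentage of
column-resampled replicates whose UPGMA tree contains the same leaf set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "PhyloNode",
    "PhyloTree",
    "tn93_distance",
    "p_distance",
    "upgma",
    "bootstrap_tree",
]


@dataclass
class PhyloNode:
    name: str | None
    height: float = 0.0
    children: list["PhyloNode"] = field(default_factory=list)
    support: float | None = None   # percent, internal nodes only

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out: list[str] = []
        for child in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class PhyloTree:
    root: PhyloNode

    def leaf_names(self) -> list[str]:
        return self.root.leaves()

    def clades(self) -> list[frozenset[str]]:
        """Leaf sets of all internal nodes (including the root)."""
        out = []

        def walk(node: PhyloNode) -> None:
            if not node.is_leaf:
                out.append(frozenset(node.leaves()))
                for child in node.children:
                    walk(child)

        walk(self.root)
        return out

    def internal_nodes(self) -> list[PhyloNode]:
        out = []

        def walk(node: PhyloNode) -> None:
            if not node.is_leaf:
                out.append(node)
                for child in node.children:
                    walk(child)

        walk(self.root)
        return out

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        """All leaves equidistant from the root and no height inversions."""
        ok = True

        def check(node: PhyloNode) -> None:
            nonlocal ok
            for child in node.children:
                if child.height > node.height + tol:
                    ok = False
                check(child)

        check(self.root)
        depths = self._leaf_depths()
        return ok and max(depths) - min(depths) <= tol

    def _leaf_depths(self) -> list[float]:
        out = []

        def walk(node: PhyloNode, acc: float) -> None:
            if node.is_leaf:
                out.append(acc)
            for child in node.children:
                walk(child, acc + (node.height - child.height))

        walk(self.root, 0.0)
        return out

    def to_newick(self, *, digits: int = 6) -> str:
        def fmt(node: PhyloNode, parent_height: float | None) -> str:
            if node.is_leaf:
                body = node.name
            else:
                inner = ",".join(fmt(c, node.height) for c in node.children)
                label = "" if node.support is None else f"{node.support:g}"
                body = f"({inner}){label}"
            if parent_height is None:
                return body
            return f"{body}:{parent_height - node.height:.{digits}f}"

        return fmt(self.root, None) + ";"


# ---------------------------------------------------------------------------
# Distances

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3}


def encode_alignment(rows: Sequence[str]) -> np.ndarray:
    """Rows of a gapped alignment as a (n, L) uint8 matrix; anything other
    than A/C/G/T (gaps, N, ambiguity letters) becomes 255 and is excluded
    from distance computations."""
    n, L = len(rows), len(rows[0])
    M = np.full((n, L), 255, dtype=np.uint8)
    for i, row in enumerate(rows):
        arr = np.frombuffer(row.upper().encode(), dtype=np.uint8)
        for base, code in _ENC.items():
            M[i, arr == ord(base)] = code
    return M


def _pair_props(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, float, float, float, int]:
    ok = (a != 255) & (b != 255)
    m = int(ok.sum())
    if m == 0:
        raise ValueError("no comparable columns between sequences")
    x, y = a[ok], b[ok]
    freqs = np.bincount(np.concatenate([x, y]), minlength=4) / (2 * m)
    diff = x != y
    purine = ((x == 0) & (y == 2)) | ((x == 2) & (y == 0))
    pyrim = ((x == 1) & (y == 3)) | ((x == 3) & (y == 1))
    P1 = float(purine.sum()) / m
    P2 = float(pyrim.sum()) / m
    Q = float(diff.sum()) / m - P1 - P2
    return freqs, P1, P2, Q, m


def tn93_from_encoded(a: np.ndarray, b: np.ndarray) -> float:
    freqs, P1, P2, Q, _ = _pair_props(a, b)
    if P1 == P2 == Q == 0.0:
        return 0.0
    gA, gC, gG, gT = (float(f) for f in freqs)
    gR, gY = gA + gG, gC + gT
    if gR <= 0 or gY <= 0:
        raise ValueError("distance undefined (missing purines or pyrimidines)")
    k1 = 2.0 * gA * gG / gR
    k2 = 2.0 * gC * gT / gY
    k3 = 2.0 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY)
    w3 = 1.0 - Q / (2.0 * gR * gY)
    if w3 <= 0:
        raise ValueError("distance undefined (saturation)")
    d = -k3 * math.log(w3)
    for k, P, g2 in ((k1, P1, gR), (k2, P2, gY)):
        if k == 0.0:
            if P > 0.0:
                raise ValueError("distance undefined (saturation)")
            continue
        w = 1.0 - P / k - Q / (2.0 * g2)
        if w <= 0:
            raise ValueError("distance undefined (saturation)")
        d += -k * math.log(w)
    return d


def tn93_distance(a: str, b: str) -> float:
    """TN93 substitutions/site between two aligned sequences (pairwise
    deletion of gap/N columns; frequencies from the pooled pair)."""
    a = a if isinstance(a, str) else a.residues
    b = b if isinstance(b, str) else b.residues
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    M = encode_alignment([a, b])
    return tn93_from_encoded(M[0], M[1])


def p_distance(a: str, b: str) -> float:
    """Plain proportion of differing comparable columns."""
    M = encode_alignment([a, b])
    _, P1, P2, Q, _ = _pair_props(M[0], M[1])
    return P1 + P2 + Q


# ---------------------------------------------------------------------------
# UPGMA

def upgma(D: np.ndarray, labels: Sequence[str] | None = None) -> PhyloTree:
    """Average-linkage agglomeration of a symmetric zero-diagonal distance
    matrix into a rooted ultrametric tree."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T) or np.any(np.diag(D) != 0):
        raise ValueError("distance matrix must be square, symmetric, zero-diagonal")
    if labels is None:
        labels = [f"t{i}" for i in range(n)]
    if n == 1:
        return PhyloTree(PhyloNode(labels[0]))

    clusters: dict[int, PhyloNode] = {
        i: PhyloNode(labels[i], height=0.0) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    leafsets = {i: tuple(sorted([labels[i]])) for i in range(n)}
    dist = {(i, j): float(D[i, j]) for i in range(n) for j in range(i + 1, n)}
    next_id = n

    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for ai in range(len(keys)):
            for bi in range(ai + 1, len(keys)):
                i, j = keys[ai], keys[bi]
                d = dist[(min(i, j), max(i, j))]
                tie_key = tuple(sorted((leafsets[i], leafsets[j])))
                cand = (d, tie_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        d, _, i, j = best
        node = PhyloNode(None, height=d / 2.0,
                         children=[clusters[i], clusters[j]])
        si, sj = sizes[i], sizes[j]
        merged_leafset = tuple(sorted(leafsets[i] + leafsets[j]))
        for k in clusters:
            if k in (i, j):
                continue
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            dist[(min(k, next_id), max(k, next_id))] = (si * dik + sj * djk) / (si + sj)
        del clusters[i], clusters[j]
        clusters[next_id] = node
        sizes[next_id] = si + sj
        leafsets[next_id] = merged_leafset
        next_id += 1

    return PhyloTree(clusters.popitem()[1])


def bootstrap_tree(consensus_msa, reps: int = 1000, seed: int = 0,
                   distance: Callable[[np.ndarray, np.ndarray], float]
                   = tn93_from_encoded) -> PhyloTree:
    """UPGMA tree from the full alignment, with internal-node supports from
    ``reps`` column-resampling replicates.

    ``consensus_msa`` is any alignment object with ``rows`` carrying
    ``id``/``residues``. Replicates where a distance is undefined
    (saturation after resampling) are skipped; supports are percentages of
    the evaluable replicates.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rows = consensus_msa.rows
    labels = [r.id for r in rows]
    if len(rows) < 3:
        raise ValueError("bootstrap needs at least 3 leaves")
    M = encode_alignment([r.residues for r in rows])
    n, L = M.shape

    def dist_matrix(cols: np.ndarray) -> np.ndarray:
        sub = M[:, cols]
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = distance(sub[i], sub[j])
        return D

    tree = upgma(dist_matrix(np.arange(L)), labels)
    counts: dict[frozenset[str], int] = {c: 0 for c in tree.clades()}
    rng = np.random.default_rng(seed)
    evaluable = 0
    for _ in range(reps):
        cols = rng.integers(0, L, size=L)
        try:
            rep_tree = upgma(dist_matrix(cols), labels)
        except ValueError:
            continue
        evaluable += 1
        rep_clades = set(rep_tree.clades())
        for clade in counts:
            if clade in rep_clades:
                counts[clade] += 1
    for node in tree.internal_nodes():
        clade = frozenset(node.leaves())
        node.support = 100.0 * counts[clade] / max(evaluable, 1)
    return tree
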