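"""Tamura-Nei distances, UPGMA agglomeration and bootstrap support."""

import math

import numpy as np
import pytest

import mitomarkers as mm
from mitomarkers.alignment import Msa
from mitomarkers.io_formats import LabeledSequence
from mitomarkers.phylo import (
    PhyloTree, bootstrap_tree, p_distance, tn93_distance, upgma,
)


def balanced_pair(n_per_type=3, length=600):
    """A 600-bp equal-composition pair with 36 differences spread evenly
    (and direction-balanced) over all six unordered substitution types."""
    base = "ACGT" * (length // 4)
    other = list(base)
    idx = {b: [i for i, c in enumerate(base) if c == b] for b in "ACGT"}
    ptr = {b: 0 for b in "ACGT"}

    def sub(x, y, k):
        for _ in range(k):
            i = idx[x][ptr[x]]
            ptr[x] += 1
            other[i] = y

    for x, y in [("A", "G"), ("C", "T"), ("A", "C"),
                 ("A", "T"), ("C", "G"), ("G", "T")]:
        sub(x, y, n_per_type)
        sub(y, x, n_per_type)
    return base, "".join(other)


def test_tn93_identical_sequences():
    assert tn93_distance("ACGTACGT", "ACGTACGT") == 0.0


def test_tn93_reduces_to_jc69_in_symmetric_limit():
    a, b = balanced_pair()
    d = tn93_distance(a, b)
    jc = -0.75 * math.log(1 - 4 / 3 * 0.06)
    assert d == pytest.approx(jc, abs=1e-9)


def test_tn93_frozen_external_oracle_value():
    """Frozen reference computed independently with ape::dist.dna
    (model="TN93") on the same constructed pair."""
    rng = np.random.default_rng(42)
    a = "".join(rng.choice(list("ACGT"), 400, p=[0.4, 0.1, 0.1, 0.4]))
    b = list(a)
    for i in rng.choice(400, 30, replace=False):
        b[i] = rng.choice([c for c in "ACGT" if c != a[i]])
    assert tn93_distance(a, "".join(b)) == pytest.approx(
        0.0795677231099, abs=1e-10)


def test_tn93_dominates_p_distance():
    rng = np.random.default_rng(17)
    for _ in range(30):
        a = "".join(rng.choice(list("ACGT"), 500))
        b = list(a)
        for i in rng.choice(500, int(rng.integers(1, 80)), replace=False):
            b[i] = rng.choice([c for c in "ACGT" if c != a[i]])
        b = "".join(b)
        assert tn93_distance(a, b) >= p_distance(a, b) - 1e-12


def test_tn93_gap_columns_excluded_and_saturation_error():
    assert tn93_distance("AC-T", "ACGT") == 0.0
    with pytest.raises(ValueError, match="saturation|undefined"):
        tn93_distance("ACACACACAC" * 5, "GTGTGTGTGT" * 5)


def test_upgma_hand_agglomeration():
    tree = upgma(np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0.0]]),
                 labels=["A", "B", "C"])
    assert tree.to_newick() == "(C:2.000000,(A:1.000000,B:1.000000):1.000000);"
    assert tree.root.height == 2.0
    inner = [n for n in tree.internal_nodes() if n is not tree.root][0]
    assert inner.height == 1.0


def test_upgma_two_taxa_and_validation():
    tree = upgma(np.array([[0, 3.0], [3.0, 0]]), labels=["X", "Y"])
    assert tree.root.height == 1.5
    with pytest.raises(ValueError, match="symmetric"):
        upgma(np.array([[0, 1.0], [2.0, 0]]))


def test_upgma_equal_distances_deterministic_tie_break():
    D = np.ones((4, 4)) - np.eye(4)
    t1 = upgma(D, labels=list("DCBA"))
    t2 = upgma(D, labels=list("DCBA"))
    assert t1.to_newick() == t2.to_newick()
    heights = sorted(n.height for n in t1.internal_nodes())
    assert heights == pytest.approx([0.5, 0.5, 0.5])


def test_upgma_ultrametric_and_reconstructs_ultrametric_input():
    rng = np.random.default_rng(23)
    for _ in range(10):
        n = int(rng.integers(3, 8))
        # build a random ultrametric matrix from a random merge order
        heights = np.sort(rng.uniform(0.1, 1.0, n - 1))
        clusters = [[i] for i in range(n)]
        D = np.zeros((n, n))
        for h in heights:
            i, j = rng.choice(len(clusters), 2, replace=False)
            for a in clusters[i]:
                for b in clusters[j]:
                    D[a, b] = D[b, a] = 2 * h
            clusters[min(i, j)] = clusters[i] + clusters[j]
            clusters.pop(max(i, j))
        tree = upgma(D, labels=[f"t{i}" for i in range(n)])
        assert tree.is_ultrametric(tol=1e-9)
        # cophenetic distances reproduce D exactly
        coph = _cophenetic(tree, n)
        assert np.allclose(coph, D, atol=1e-9)


def _cophenetic(tree: PhyloTree, n: int) -> np.ndarray:
    names = sorted(tree.leaf_names(), key=lambda s: int(s[1:]))
    D = np.zeros((n, n))

    def walk(node):
        if node.is_leaf:
            return [node.name]
        groups = [walk(c) for c in node.children]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for a in groups[gi]:
                    for b in groups[gj]:
                        ia, ib = names.index(a), names.index(b)
                        D[ia, ib] = D[ib, ia] = 2 * node.height
        return [x for g in groups for x in g]

    walk(tree.root)
    return D


def test_bootstrap_deterministic_and_validated(diversity0):
    msa = diversity0.consensus_msa
    t1 = bootstrap_tree(msa, reps=25, seed=7)
    t2 = bootstrap_tree(msa, reps=25, seed=7)
    assert t1.to_newick() == t2.to_newick()
    with pytest.raises(ValueError, match="reps"):
        bootstrap_tree(msa, reps=0, seed=1)


def test_bootstrap_invariant_alignment_full_support():
    rows = [LabeledSequence(f"P{i}", f"P{i}", "ACGT" * 30, aligned=True)
            for i in range(4)]
    tree = bootstrap_tree(Msa(rows), reps=20, seed=3)
    assert all(n.support == 100.0 for n in tree.internal_nodes())


def test_bootstrap_recovers_deep_clades():
    """Two clearly divergent clades get near-full support."""
    rng = np.random.default_rng(31)
    anc1 = rng.choice(list("ACGT"), 800)
    anc2 = anc1.copy()
    for i in rng.choice(800, 120, replace=False):   # deep split
        anc2[i] = rng.choice([c for c in "ACGT" if c != anc1[i]])

    def tip(anc, name):
        t = anc.copy()
        for i in rng.choice(800, 6, replace=False):
            t[i] = rng.choice([c for c in "ACGT" if c != anc[i]])
        return LabeledSequence(name, name, "".join(t), aligned=True)

    rows = [tip(anc1, "a1"), tip(anc1, "a2"), tip(anc2, "b1"), tip(anc2, "b2")]
    tree = bootstrap_tree(Msa(rows), reps=200, seed=5)
    supports = {frozenset(n.leaves()): n.support for n in tree.internal_nodes()}
    assert supports[frozenset(["a1", "a2"])] >= 95.0
    assert supports[frozenset(["b1", "b2"])] >= 95.0
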