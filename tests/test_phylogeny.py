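"""Jukes-Cantor correction, neighbor joining against an additive-tree oracle,
and bootstrap supports."""

import itertools
import math

import numpy as np
import pytest

from opsinconv.phylogeny import (
    AmongGroupTree,
    among_group_distance_matrix,
    bootstrap_supports,
    jukes_cantor_correct,
    neighbor_joining,
)

# ---------------------------------------------------------------------------
# oracle: random additive (tree) distance matrices with known topology


def random_additive_tree(rng: np.random.Generator, n_taxa: int):
    """Random binary tree; returns (label list, distance matrix, bipartitions)."""
    labels = [f"t{i}" for i in range(n_taxa)]
    # start from a star over 3 nodes and attach remaining taxa to random edges
    # represent the tree as an edge list over node ids with lengths
    next_node = n_taxa
    edges = {}  # id -> (id, length) adjacency
    adj: dict[int, list[tuple[int, float]]] = {i: [] for i in range(n_taxa)}

    def link(u, v, w):
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))

    def rand_len():
        return float(rng.uniform(0.05, 1.0))

    center = next_node
    next_node += 1
    for i in range(3):
        link(center, i, rand_len())
    for leaf in range(3, n_taxa):
        # pick a random existing edge (u,v), split it with a new node
        all_edges = [
            (u, v, w) for u in adj for v, w in adj[u] if u < v
        ]
        u, v, w = all_edges[rng.integers(0, len(all_edges))]
        mid = next_node
        next_node += 1
        adj[u] = [(x, y) for x, y in adj[u] if x != v]
        adj[v] = [(x, y) for x, y in adj[v] if x != u]
        cut = float(rng.uniform(0.2, 0.8)) * w
        link(u, mid, cut)
        link(mid, v, w - cut)
        link(mid, leaf, rand_len())

    def path_len(a, b):
        stack = [(a, 0.0, -1)]
        while stack:
            node, dist, prev = stack.pop()
            if node == b:
                return dist
            for nxt, w in adj[node]:
                if nxt != prev:
                    stack.append((nxt, dist + w, node))
        raise AssertionError("disconnected")

    mat = np.zeros((n_taxa, n_taxa))
    for i, j in itertools.combinations(range(n_taxa), 2):
        mat[i, j] = mat[j, i] = path_len(i, j)

    # bipartitions: for each internal edge, the leaf set on one side
    full = frozenset(labels)
    bips = set()

    def leaves_beyond(node, prev):
        if node < n_taxa:
            return {node}
        out = set()
        for nxt, _ in adj[node]:
            if nxt != prev:
                out |= leaves_beyond(nxt, node)
        return out

    for u in adj:
        for v, _ in adj[u]:
            if u < v and u >= n_taxa and v >= n_taxa:
                side = frozenset(labels[i] for i in leaves_beyond(u, v))
                if 1 < len(side) < n_taxa - 1:
                    bips.add(min(side, full - side, key=sorted))
    return labels, mat, bips


class TestJukesCantor:
    def test_zero(self):
        assert jukes_cantor_correct(0.0) == 0.0

    def test_closed_form_at_six_percent(self):
        assert jukes_cantor_correct(0.06) == pytest.approx(
            -0.75 * math.log(1 - 0.08), rel=1e-9
        )
        assert jukes_cantor_correct(0.06) == pytest.approx(0.06254, abs=5e-5)

    def test_saturation_rejected(self):
        with pytest.raises(ValueError, match="saturat"):
            jukes_cantor_correct(0.75)


class TestDistanceMatrix:
    def test_identical_groups_give_zero_matrix(self):
        gs = {g: ["ACGTACGT"] for g in "abc"}
        _, mat = among_group_distance_matrix(gs, range(8))
        assert np.allclose(mat, 0.0)

    def test_corrected_value_and_symmetry(self):
        a = "A" * 100
        b = "C" * 6 + "A" * 94
        c = "A" * 94 + "C" * 6
        _, mat = among_group_distance_matrix({"a": [a], "b": [b], "c": [c]}, range(100))
        assert mat[0, 1] == pytest.approx(jukes_cantor_correct(0.06))
        assert np.allclose(mat, mat.T)


class TestNeighborJoining:
    def test_recovers_random_additive_trees(self):
        """Topology and branch lengths from 100 random 4-8 taxon trees."""
        rng = np.random.default_rng(2024)
        for case in range(100):
            n = int(rng.integers(4, 9))
            labels, mat, true_bips = random_additive_tree(rng, n)
            tree = neighbor_joining(labels, mat, clamp_negative=False)
            assert tree.bipartitions() == true_bips, f"case {case}"
            # additivity: leaf-to-leaf path lengths reproduce the input matrix
            dists = _tree_path_lengths(tree)
            for i, j in itertools.combinations(range(n), 2):
                assert dists[frozenset((labels[i], labels[j]))] == pytest.approx(
                    mat[i, j], abs=1e-8
                )

    def test_three_taxa_three_point_formulas(self):
        mat = np.array([[0, 0.3, 0.4], [0.3, 0, 0.5], [0.4, 0.5, 0]])
        tree = neighbor_joining(["a", "b", "c"], mat)
        lengths = {c.label: l for c, l in tree.root.children}
        assert lengths["a"] == pytest.approx(0.1)
        assert lengths["b"] == pytest.approx(0.2)
        assert lengths["c"] == pytest.approx(0.3)

    def test_tie_break_is_deterministic(self):
        mat = np.full((4, 4), 0.5)
        np.fill_diagonal(mat, 0.0)
        t1 = neighbor_joining(list("abcd"), mat)
        t2 = neighbor_joining(list("abcd"), mat)
        assert t1.newick() == t2.newick()

    def test_agrees_with_skbio_on_random_matrices(self):
        from skbio import DistanceMatrix
        from skbio.tree import nj

        rng = np.random.default_rng(5)
        for _ in range(10):
            labels, mat, _ = random_additive_tree(rng, 6)
            ours = neighbor_joining(labels, mat)
            ref = nj(DistanceMatrix(mat, labels))
            ref_bips = set()
            full = frozenset(labels)
            for node in ref.non_tips():
                side = frozenset(t.name for t in node.tips())
                if 1 < len(side) < len(labels) - 1:
                    ref_bips.add(min(side, full - side, key=sorted))
            assert ours.bipartitions() == ref_bips

    def test_asymmetric_matrix_rejected(self):
        mat = np.array([[0, 1, 2], [1, 0, 3], [2, 3.5, 0]])
        with pytest.raises(ValueError):
            neighbor_joining(list("abc"), mat)


def _tree_path_lengths(tree: AmongGroupTree):
    adj: dict[int, list[tuple[int, float]]] = {}
    leaf_of = {}

    def walk(node):
        nid = id(node)
        adj.setdefault(nid, [])
        if node.is_leaf:
            leaf_of[node.label] = nid
        for child, length in node.children:
            cid = walk(child)
            adj[nid].append((cid, length))
            adj.setdefault(cid, []).append((nid, length))
        return nid

    walk(tree.root)
    out = {}
    labels = list(leaf_of)
    for a, b in itertools.combinations(labels, 2):
        stack = [(leaf_of[a], 0.0, -1)]
        while stack:
            node, dist, prev = stack.pop()
            if node == leaf_of[b]:
                out[frozenset((a, b))] = dist
                break
            for nxt, w in adj[node]:
                if nxt != prev:
                    stack.append((nxt, dist + w, node))
    return out


class TestBootstrapSupports:
    def _clean_groups(self):
        """Two clades separated by many fixed differences, light noise."""
        rng = np.random.default_rng(11)
        base = rng.integers(0, 4, 400)
        other = base.copy()
        other[:80] = (other[:80] + 1) % 4
        code = "ACGT"

        def noisy(arr, k):
            arr = arr.copy()
            idx = rng.integers(0, len(arr), k)
            arr[idx] = (arr[idx] + 1) % 4
            return "".join(code[x] for x in arr)

        return {
            "a1": [noisy(base, 3)],
            "a2": [noisy(base, 3)],
            "b1": [noisy(other, 3)],
            "b2": [noisy(other, 3)],
        }

    def test_deep_split_gets_high_support(self):
        tree = bootstrap_supports(self._clean_groups(), range(400), reps=100, seed=1)
        bips = tree.bipartitions()
        key = frozenset(("a1", "a2"))
        assert key in bips
        supports = _collect_supports(tree)
        assert supports[key] >= 95

    def test_same_seed_identical_supports(self):
        t1 = bootstrap_supports(self._clean_groups(), range(400), reps=50, seed=4)
        t2 = bootstrap_supports(self._clean_groups(), range(400), reps=50, seed=4)
        assert _collect_supports(t1) == _collect_supports(t2)


def _collect_supports(tree: AmongGroupTree):
    full = frozenset(tree.labels)
    out = {}

    def walk(node):
        below = frozenset()
        if node.is_leaf:
            return frozenset([node.label])
        for child, _ in node.children:
            below |= walk(child)
        if node.support is not None:
            out[min(below, full - below, key=sorted)] = node.support
        return below

    walk(tree.root)
    return out
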