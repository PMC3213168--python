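"""Among-group neighbor-joining trees from Jukes-Cantor-corrected divergences.

Groups (one gene type in one species, or a single outgroup sequence) are the
tree's taxa; pairwise distances are JC-corrected mean between-group
p-distances on jointly gap-free columns.  Supports are bipartition
frequencies over column-bootstrap replicates of the whole
matrix-plus-NJ procedure.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from opsinconv.diversity import nucleotide_divergence


def jukes_cantor_correct(p: float) -> float:
    """Jukes-Cantor distance -(3/4) ln(1 - 4p/3); saturates at p = 0.75."""
    if not 0.0 <= p:
        raise ValueError(f"p-distance {p} negative")
    if p >= 0.75:
        raise ValueError(f"p-distance {p} >= 0.75: Jukes-Cantor correction saturated")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass
class TreeNode:
    """Node of an (arbitrarily rooted) tree; leaves carry group labels."""

    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None  # percent, internal edges only

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def newick(self, with_support: bool = False) -> str:
        return self._newick(with_support) + ";"

    def _newick(self, with_support: bool) -> str:
        if self.is_leaf:
            return self.label
        parts = ",".join(
            f"{child._newick(with_support)}:{length:.6f}" for child, length in self.children
        )
        sup = ""
        if with_support and self.support is not None:
            sup = f"{self.support:.0f}"
        return f"({parts}){sup}"


@dataclass
class AmongGroupTree:
    """An unrooted among-group tree with branch lengths and supports."""

    root: TreeNode
    labels: tuple[str, ...]
    outgroup: str | None = None
    raw_negative_lengths: dict[frozenset, float] = field(default_factory=dict)

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions, each as the frozenset of labels on one side."""
        full = frozenset(self.labels)
        out = set()

        def walk(node: TreeNode) -> frozenset:
            if node.is_leaf:
                return frozenset([node.label])
            below = frozenset()
            for child, _ in node.children:
                side = walk(child)
                if 1 < len(side) < len(full) - 1:
                    out.add(min(side, full - side, key=sorted))
                below = below | side
            return below

        walk(self.root)
        return out

    def newick(self, with_support: bool = False) -> str:
        return self.root.newick(with_support)


def among_group_distance_matrix(
    group_seqs: Mapping[str, Sequence[str]], columns: Sequence[int]
) -> tuple[list[str], np.ndarray]:
    """JC-corrected between-group divergence for every pair of groups.

    Columns must already be gap-free across the union of all groups (joint
    complete deletion).
    """
    labels = list(group_seqs)
    if len(labels) < 3:
        raise ValueError("need at least 3 groups for a tree")
    n = len(labels)
    mat = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        p = nucleotide_divergence(group_seqs[labels[i]], group_seqs[labels[j]], columns).value
        try:
            dist = jukes_cantor_correct(p)
        except ValueError as exc:
            raise ValueError(f"pair ({labels[i]}, {labels[j]}): {exc}") from exc
        mat[i, j] = mat[j, i] = dist
    return labels, mat


def neighbor_joining(
    labels: Sequence[str],
    matrix: np.ndarray,
    outgroup: str | None = None,
    clamp_negative: bool = True,
) -> AmongGroupTree:
    """Classic Saitou-Nei neighbor joining.

    Ties in the Q criterion are broken toward the lowest index pair, making
    the result deterministic.  Negative branch lengths are clamped to zero
    for output; the raw values are retained on the returned tree.
    """
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (n, n) or not np.allclose(matrix, matrix.T):
        raise ValueError("distance matrix must be square and symmetric")
    if outgroup is not None and outgroup not in labels:
        raise ValueError(f"outgroup {outgroup!r} not among taxa")

    raw_neg: dict[frozenset, float] = {}

    def edge_len(node: TreeNode, length: float) -> float:
        if length < 0:
            raw_neg[frozenset(node.leaves())] = length
            if clamp_negative:
                return 0.0
        return length

    nodes = [TreeNode(label=l) for l in labels]
    D = matrix.copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                q = (m - 2) * sub[a, b] - r[a] - r[b]
                if best is None or q < best[0] - 1e-12:
                    best = (q, a, b)
        _, a, b = best
        ia, ib = active[a], active[b]
        dab = sub[a, b]
        la = 0.5 * dab + (r[a] - r[b]) / (2 * (m - 2))
        lb = dab - la
        new = TreeNode(
            children=[
                (nodes[ia], edge_len(nodes[ia], la)),
                (nodes[ib], edge_len(nodes[ib], lb)),
            ]
        )
        # distances from the new node to the others
        new_idx = len(nodes)
        nodes.append(new)
        D = np.pad(D, ((0, 1), (0, 1)))
        for c in active:
            if c in (ia, ib):
                continue
            D[new_idx, c] = D[c, new_idx] = 0.5 * (D[ia, c] + D[ib, c] - dab)
        active = [c for c in active if c not in (ia, ib)] + [new_idx]

    # resolve the final three nodes with the three-point formulas
    i, j, k = active
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    root = TreeNode(
        children=[
            (nodes[i], edge_len(nodes[i], li)),
            (nodes[j], edge_len(nodes[j], lj)),
            (nodes[k], edge_len(nodes[k], lk)),
        ]
    )
    tree = AmongGroupTree(root=root, labels=tuple(labels), outgroup=outgroup,
                          raw_negative_lengths=raw_neg)
    if outgroup is not None:
        tree = _root_on(tree, outgroup)
    return tree


def _root_on(tree: AmongGroupTree, outgroup: str) -> AmongGroupTree:
    """Display-only rooting: split the outgroup's pendant edge at the root.

    The outgroup ends up a direct child of the trifurcating NJ root whenever
    it was joined last (typical for a distant outgroup); otherwise the tree
    is returned unrooted with a log message — the bipartitions, lengths and
    supports are unaffected either way.
    """
    for idx, (child, length) in enumerate(tree.root.children):
        if child.is_leaf and child.label == outgroup:
            rest = [e for i, e in enumerate(tree.root.children) if i != idx]
            inner = TreeNode(children=rest, support=tree.root.support)
            new_root = TreeNode(children=[(child, length / 2), (inner, length / 2)])
            return AmongGroupTree(new_root, tree.labels, outgroup, tree.raw_negative_lengths)
    logging.getLogger(__name__).info(
        "outgroup %r not adjacent to the NJ root; leaving the tree unrooted", outgroup
    )
    return tree


def bootstrap_supports(
    group_seqs: Mapping[str, Sequence[str]],
    columns: Sequence[int],
    reps: int = 1000,
    seed: int | None = None,
    outgroup: str | None = None,
) -> AmongGroupTree:
    """NJ tree with bipartition bootstrap supports (percent of replicates).

    Columns are resampled with replacement; the distance matrix and NJ tree
    are recomputed per replicate, and each original internal bipartition is
    scored by the fraction of replicates that contain it.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    columns = list(columns)
    labels, mat = among_group_distance_matrix(group_seqs, columns)
    tree = neighbor_joining(labels, mat, outgroup=outgroup)
    target = {bp: 0 for bp in tree.bipartitions()}
    rng = np.random.default_rng(seed)
    cols_arr = np.asarray(columns)
    for _ in range(reps):
        resampled = cols_arr[rng.integers(0, len(cols_arr), size=len(cols_arr))]
        try:
            lab_r, mat_r = among_group_distance_matrix(group_seqs, resampled)
        except ValueError:  # saturated replicate: contributes no support
            continue
        rep_bps = neighbor_joining(lab_r, mat_r).bipartitions()
        for bp in target:
            if bp in rep_bps:
                target[bp] += 1
    supports = {bp: 100.0 * cnt / reps for bp, cnt in target.items()}
    _annotate_supports(tree, supports)
    return tree


def _annotate_supports(tree: AmongGroupTree, supports: dict[frozenset, float]) -> None:
    full = frozenset(tree.labels)

    def walk(node: TreeNode) -> frozenset:
        if node.is_leaf:
            return frozenset([node.label])
        below = frozenset()
        for child, _ in node.children:
            below |= walk(child)
        key = min(below, full - below, key=sorted)
        if key in supports:
            node.support = supports[key]
        return below

    walk(tree.root)
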