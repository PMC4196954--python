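"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: alignment scores come
from exhaustive enumeration over all alignments, tree distances from direct
path sums on randomly built trees, split counts from recursive clade
collection on nested-tuple topologies.
"""
from __future__ import annotations

import numpy as np


def brute_force_align_score(a: str, b: str, scheme) -> float:
    """Maximum global alignment score by exhaustive enumeration.

    A gap run of length L costs ``gap_open + L * gap_extend``; gap state is
    tracked explicitly so affine costs are exact.  No memoization — every
    alignment path is enumerated, keeping this independent of any DP
    implementation.  Feasible for sequences up to ~8 residues.
    """
    NEG = float("-inf")

    def rec(i: int, j: int, state: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = NEG
        if i < len(a) and j < len(b):
            s = scheme.pair_score(a[i], b[j]) + rec(i + 1, j + 1, "m")
            best = max(best, s)
        if i < len(a):  # gap in b
            cost = scheme.gap_extend + (0 if state == "gb" else scheme.gap_open)
            best = max(best, -cost + rec(i + 1, j, "gb"))
        if j < len(b):  # gap in a
            cost = scheme.gap_extend + (0 if state == "ga" else scheme.gap_open)
            best = max(best, -cost + rec(i, j + 1, "ga"))
        return best

    return rec(0, 0, "m")


# ---------------------------------------------------------------- trees

def random_binary_topology(labels: list[str], rng: np.random.Generator):
    """Random unrooted binary topology as nested tuples with branch lengths.

    Built by random agglomeration; returns a 3-child root (unrooted shape).
    Leaves are plain strings; internal nodes are tuples of (child, length)
    pairs.
    """
    nodes = [(lab, None) for lab in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        li, lj = rng.uniform(0.5, 2.0, size=2)
        merged = (((nodes[i][0], li), (nodes[j][0], lj)), None)
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    lengths = rng.uniform(0.5, 2.0, size=3)
    return tuple((n[0], l) for n, l in zip(nodes, lengths))


def _leaf_depths(node) -> dict[str, float]:
    if isinstance(node, str):
        return {node: 0.0}
    depths: dict[str, float] = {}
    for child, length in node:
        for leaf, d in _leaf_depths(child).items():
            depths[leaf] = d + length
    return depths


def tree_distances(root) -> dict[frozenset[str], float]:
    """Leaf-pair path lengths by direct summation (post-order accumulation)."""
    dists: dict[frozenset[str], float] = {}

    def walk(node) -> dict[str, float]:
        if isinstance(node, str):
            return {node: 0.0}
        child_maps = []
        for child, length in node:
            m = {leaf: d + length for leaf, d in walk(child).items()}
            child_maps.append(m)
        for x in range(len(child_maps)):
            for y in range(x + 1, len(child_maps)):
                for la, da in child_maps[x].items():
                    for lb, db in child_maps[y].items():
                        dists[frozenset((la, lb))] = da + db
        return {l: d for m in child_maps for l, d in m.items()}

    walk(root)
    return dists


def tree_splits(root) -> set[frozenset[str]]:
    """Nontrivial splits, each keyed by the side without the smallest leaf."""
    all_leaves = frozenset(_leaf_depths(root))
    anchor = min(all_leaves)
    n = len(all_leaves)
    splits: set[frozenset[str]] = set()

    def walk(node) -> frozenset[str]:
        if isinstance(node, str):
            return frozenset((node,))
        mine = frozenset()
        for child, _ in node:
            side = walk(child)
            mine |= side
            canon = all_leaves - side if anchor in side else side
            if 1 < len(canon) < n - 1:
                splits.add(canon)
        return mine

    walk(root)
    return splits


def to_newick(root) -> str:
    def fmt(node, length) -> str:
        if isinstance(node, str):
            core = node
        else:
            core = "(" + ",".join(fmt(c, l) for c, l in node) + ")"
        return core if length is None else f"{core}:{length:.6f}"

    return "(" + ",".join(fmt(c, l) for c, l in root) + ");"
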