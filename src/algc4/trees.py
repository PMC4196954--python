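"""Tree-sample bookkeeping and distance-tree construction.

Covers the machinery around Bayesian tree samples without doing MCMC itself:
sampling-schedule arithmetic, burn-in removal, bipartition (split) frequency
tables, majority-rule consensus, the average standard deviation of split
frequencies (ASDSF) convergence diagnostic, neighbor joining on distance
matrices, and a sister-group origin-assignment procedure for inferring the
prokaryotic donor lineage of a eukaryotic gene family.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import dendropy
import numpy as np
import pandas as pd

from .records import PROKARYOTE_GROUPS, TaxonGroup


def leaf_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in tree.leaf_node_iter())


@dataclass
class TreeSampleSet:
    """An ordered collection of leaf-labeled trees over a common leaf set."""

    trees: list[dendropy.Tree]
    taxon_namespace: dendropy.TaxonNamespace | None = None

    def __post_init__(self) -> None:
        if self.trees:
            first = leaf_labels(self.trees[0])
            for i, t in enumerate(self.trees[1:], 1):
                if leaf_labels(t) != first:
                    raise ValueError(f"tree sample {i} has a different leaf set than sample 0")

    @property
    def leaf_set(self) -> frozenset[str]:
        return leaf_labels(self.trees[0]) if self.trees else frozenset()

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self) -> Iterator[dendropy.Tree]:
        return iter(self.trees)


@dataclass(frozen=True)
class RunSchedule:
    """MCMC sampling-schedule arithmetic (no sampling is performed here)."""

    generations: int = 5_000_000
    sample_every: int = 100
    include_initial: bool = True
    burnin_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.sample_every < 1:
            raise ValueError("sample_every must be >= 1")
        if not 0.0 <= self.burnin_fraction < 1.0:
            raise ValueError("burnin_fraction must be in [0, 1)")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")


def expected_sample_count(sched: RunSchedule) -> int:
    """Number of trees a run of the given schedule writes.

    Sampling every ``sample_every`` generations yields
    ``floor(generations / sample_every)`` trees, plus one for the initial
    state when it is recorded (a 5,000,000-generation run sampled every 100
    generations therefore yields 50,001 trees).
    """
    return sched.generations // sched.sample_every + (1 if sched.include_initial else 0)


def apply_burnin(samples: TreeSampleSet, fraction: float) -> TreeSampleSet:
    """Discard the first ``floor(fraction * n)`` trees, preserving order."""
    if not 0.0 <= fraction < 1.0:
        raise ValueError("burn-in fraction must be in [0, 1)")
    n_discard = math.floor(fraction * len(samples))
    return TreeSampleSet(samples.trees[n_discard:], samples.taxon_namespace)


def nontrivial_splits(tree: dendropy.Tree) -> frozenset[frozenset[str]]:
    """The n-3 nontrivial bipartitions of an unrooted tree.

    Each split is keyed by the side that does not contain the
    lexicographically smallest leaf, so the encoding is canonical and
    byte-stable regardless of how the tree happens to be rooted on disk.
    """
    leaves = leaf_labels(tree)
    n = len(leaves)
    anchor = min(leaves)
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if anchor in side:
            side = leaves - side
        if 1 < len(side) < n - 1:
            splits.add(side)
    return frozenset(splits)


@dataclass
class BipartitionTable:
    """Split -> relative frequency over a tree sample."""

    frequencies: dict[frozenset[str], float]
    n_trees: int
    leaf_set: frozenset[str]

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(
            ((",".join(sorted(s)), f) for s, f in self.frequencies.items()),
            key=lambda r: (-r[1], r[0]),
        )
        return pd.DataFrame(rows, columns=["split", "frequency"])


def bipartition_frequencies(samples: TreeSampleSet) -> BipartitionTable:
    """Count each nontrivial split's occurrence fraction across the sample."""
    if len(samples) < 1:
        raise ValueError("need at least one tree")
    counts: dict[frozenset[str], int] = {}
    for tree in samples:
        for split in nontrivial_splits(tree):
            counts[split] = counts.get(split, 0) + 1
    n = len(samples)
    return BipartitionTable({s: c / n for s, c in counts.items()}, n, samples.leaf_set)


@dataclass
class ConsensusTree:
    """Majority-rule consensus: retained splits with their supports."""

    newick: str
    supports: dict[frozenset[str], float]
    leaf_set: frozenset[str]

    def tree(self) -> dendropy.Tree:
        return dendropy.Tree.get(data=self.newick, schema="newick", preserve_underscores=True)


def majority_rule_consensus(table: BipartitionTable, threshold: float = 0.5) -> ConsensusTree:
    """Consensus of all splits with frequency strictly above ``threshold``.

    ``threshold >= 0.5`` guarantees the retained splits are pairwise
    compatible; regions with no retained split collapse to polytomies.
    """
    if threshold < 0.5:
        raise ValueError("threshold below 0.5 does not guarantee split compatibility")
    leaves = table.leaf_set
    anchor = min(leaves) if leaves else ""
    # Clades relative to the anchor leaf: the split side not containing it.
    clades: dict[frozenset[str], float] = {}
    for split, freq in table.frequencies.items():
        if freq > threshold:
            side = leaves - split if anchor in split else split
            clades[side] = freq

    def build(leafset: frozenset[str], available: list[frozenset[str]]) -> str:
        children = []
        maximal = [c for c in available if c < leafset]
        maximal = [c for c in maximal if not any(c < d for d in maximal)]
        covered: set[str] = set()
        for c in sorted(maximal, key=lambda c: min(c)):
            inner = [d for d in available if d < c]
            children.append(build(c, inner) + f"{clades[c]:.6g}")
            covered |= c
        for leaf in sorted(leafset - covered):
            children.append(leaf)
        return "(" + ",".join(children) + ")"

    newick = build(leaves, list(clades)) + ";"
    return ConsensusTree(newick, clades, leaves)


def asdsf(run_a: TreeSampleSet, run_b: TreeSampleSet, min_freq: float = 0.10) -> float:
    """Average standard deviation of split frequencies across two runs.

    For every split reaching ``min_freq`` in at least one run, the sample
    standard deviation of its two frequencies (``|fa - fb| / sqrt(2)``) is
    averaged.  Values well below 0.01 indicate the two runs sample the same
    split distribution.
    """
    if len(run_a) == 0 or len(run_b) == 0:
        raise ValueError("both runs must be non-empty")
    if run_a.leaf_set != run_b.leaf_set:
        raise ValueError("tree sample sets have different leaf sets")
    fa = bipartition_frequencies(run_a).frequencies
    fb = bipartition_frequencies(run_b).frequencies
    qualifying = {s for s, f in fa.items() if f >= min_freq}
    qualifying |= {s for s, f in fb.items() if f >= min_freq}
    if not qualifying:
        return 0.0
    sds = [abs(fa.get(s, 0.0) - fb.get(s, 0.0)) / math.sqrt(2.0) for s in qualifying]
    return float(np.mean(sds))


def neighbor_joining(dm: pd.DataFrame) -> dendropy.Tree:
    """Neighbor joining on a symmetric zero-diagonal distance matrix.

    Exact on additive matrices.  Ties in the Q criterion are broken by the
    lowest active-index pair; negative branch lengths are clamped to 0, so
    the output Newick is deterministic.
    """
    d = dm.to_numpy(dtype=float)
    labels = [str(x) for x in dm.index]
    n0 = len(labels)
    if n0 < 4:
        raise ValueError("neighbor joining requires >= 4 taxa")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix is not symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix diagonal is not zero")

    # Active nodes keyed by growing integer ids; merged nodes appended.
    dist: dict[tuple[int, int], float] = {}
    for i in range(n0):
        for j in range(i + 1, n0):
            dist[(i, j)] = d[i, j]
    frags = {i: labels[i] for i in range(n0)}
    active = list(range(n0))
    next_id = n0

    def get(i: int, j: int) -> float:
        return 0.0 if i == j else dist[(min(i, j), max(i, j))]

    while len(active) > 3:
        m = len(active)
        r = {i: sum(get(i, k) for k in active) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * get(i, j) - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * get(i, j) + (r[i] - r[j]) / (2 * (m - 2))
        lj = get(i, j) - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        frags[next_id] = f"({frags[i]}:{li:.10g},{frags[j]}:{lj:.10g})"
        for k in active:
            if k in (i, j):
                continue
            dist[(min(k, next_id), max(k, next_id))] = 0.5 * (get(i, k) + get(j, k) - get(i, j))
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    a, b, c = active
    la = max(0.5 * (get(a, b) + get(a, c) - get(b, c)), 0.0)
    lb = max(0.5 * (get(a, b) + get(b, c) - get(a, c)), 0.0)
    lc = max(0.5 * (get(a, c) + get(b, c) - get(a, b)), 0.0)
    newick = f"({frags[a]}:{la:.10g},{frags[b]}:{lb:.10g},{frags[c]}:{lc:.10g});"
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    tree.is_rooted = False
    return tree


MIXED = "mixed"


@dataclass
class OriginCall:
    """Inferred prokaryotic donor lineage for a eukaryotic group."""

    eukaryote_group: TaxonGroup
    inferred_donor: TaxonGroup | str
    support: float


def _donor_for_tree(
    tree: dendropy.Tree, labels: Mapping[str, TaxonGroup], euk_group: TaxonGroup
) -> TaxonGroup | str:
    work = tree.clone(depth=1)
    for edge in work.preorder_edge_iter():
        if edge.length is None:
            edge.length = 1.0
    work.reroot_at_midpoint(update_bipartitions=False)

    def group_of(leaf) -> TaxonGroup:
        name = leaf.taxon.label
        if name not in labels:
            raise ValueError(f"leaf {name!r} has no taxon-group label")
        return labels[name]

    euk_leaves = [lf for lf in work.leaf_node_iter() if group_of(lf) == euk_group]
    prok_present = any(group_of(lf) in PROKARYOTE_GROUPS for lf in work.leaf_node_iter())
    if not euk_leaves:
        raise ValueError(f"tree contains no leaves of group {euk_group.value!r}")
    if not prok_present:
        raise ValueError("tree contains no prokaryote leaves")

    node = work.mrca(taxa=[lf.taxon for lf in euk_leaves])
    while node is not None:
        groups = {group_of(lf) for lf in node.leaf_iter()} & PROKARYOTE_GROUPS
        if groups:
            break
        node = node.parent_node
    if len(groups) == 1:
        return next(iter(groups))
    return MIXED


def assign_origin(
    tree: dendropy.Tree, labels: Mapping[str, TaxonGroup], euk_group: TaxonGroup
) -> OriginCall:
    """Donor lineage of ``euk_group`` from one tree.

    The tree is midpoint-rooted, then the smallest clade containing every
    ``euk_group`` leaf plus at least one prokaryote leaf is located; the
    prokaryotic group(s) inside that clade give the donor (several distinct
    groups -> "mixed").
    """
    donor = _donor_for_tree(tree, labels, euk_group)
    return OriginCall(euk_group, donor, 1.0)


def assign_origin_over_samples(
    samples: TreeSampleSet, labels: Mapping[str, TaxonGroup], euk_group: TaxonGroup
) -> OriginCall:
    """Modal donor over a tree sample; support = fraction of agreeing samples."""
    if len(samples) == 0:
        raise ValueError("empty tree sample set")
    tally: dict[TaxonGroup | str, int] = {}
    for tree in samples:
        donor = _donor_for_tree(tree, labels, euk_group)
        tally[donor] = tally.get(donor, 0) + 1
    donor = max(tally, key=lambda k: (tally[k], str(k)))
    return OriginCall(euk_group, donor, tally[donor] / len(samples))
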