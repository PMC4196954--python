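"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its arguments (the seed included) and
plants a known ground truth — classification motifs, read-quality
composition, tree topology, donor lineage — so recovery can be measured
exactly.  Background residue composition is uniform over the 20 standard
amino acids; mutation is i.i.d. per site and never touches planted positions.
"""
from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import dendropy
import numpy as np

from .records import AMINO_ACIDS, PROKARYOTE_GROUPS, ProteinRecord, ReadRecord, TaxonGroup
from .trees import TreeSampleSet

_AA = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1").astype("U1")

ENZYME_FAMILIES = ("PEPC", "PPDK", "PEPS", "MDH", "ME", "AST", "ALT", "PK", "PCK")
VARIANT_LABELS = ("MDH-NAD", "MDH-NADP", "ME-NAD", "ME-NADP", "AST-cyt", "AST-mit")


def _stable_seed(*parts) -> int:
    """Deterministic 32-bit seed from string parts (stable across sessions)."""
    return zlib.crc32(":".join(str(p) for p in parts).encode())


def family_base_sequence(family: str, length: int) -> str:
    """The fixed ancestral sequence of a synthetic enzyme family.

    Derived from a CRC of the family name, so independently generated panels
    and query sets share the same ancestor.
    """
    rng = np.random.default_rng(_stable_seed("family-base", family, length))
    return "".join(rng.choice(_AA, size=length))


def _mutate(seq: str, rate: float, rng: np.random.Generator, protected: frozenset[int] = frozenset()) -> str:
    """Substitute each non-protected site with probability ``rate``."""
    if rate <= 0.0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    if protected:
        hit[list(protected)] = False
    idx = np.nonzero(hit)[0]
    for i in idx:
        choices = [c for c in AMINO_ACIDS if c != arr[i]]
        arr[i] = choices[rng.integers(len(choices))]
    return "".join(arr)


@dataclass(frozen=True)
class MotifPlantSpec:
    """Recipe for a protein family with planted, classifiable features.

    ``planted_terminal`` is written over the final four residues;
    ``diagnostic_residue`` at 1-based ``diagnostic_position``; ``signature``
    starting at 1-based ``signature_start``.  Planted regions must not
    overlap and survive mutation verbatim.
    """

    family: str
    length: int = 300
    planted_terminal: str | None = None
    diagnostic_residue: str | None = None
    diagnostic_position: int | None = None
    signature: str | None = None
    signature_start: int | None = None
    mutation_rate: float = 0.0
    seed: int = 0
    base_sequence: str | None = None

    def __post_init__(self) -> None:
        if self.family not in ENZYME_FAMILIES and self.family not in VARIANT_LABELS:
            raise ValueError(f"unknown enzyme family {self.family!r}")
        if not 0.0 <= self.mutation_rate < 1.0:
            raise ValueError("mutation_rate must be in [0, 1)")
        if self.length < 8:
            raise ValueError("length must be >= 8")
        if (self.diagnostic_residue is None) != (self.diagnostic_position is None):
            raise ValueError("diagnostic_residue and diagnostic_position go together")
        if (self.signature is None) != (self.signature_start is None):
            raise ValueError("signature and signature_start go together")
        self.protected_positions()  # validates ranges and overlap

    def protected_positions(self) -> frozenset[int]:
        """0-based indices that mutation must not touch."""
        spans: list[tuple[int, int, str]] = []
        if self.planted_terminal is not None:
            if len(self.planted_terminal) != 4:
                raise ValueError("planted_terminal must be a 4-mer")
            spans.append((self.length - 4, self.length, "terminal"))
        if self.diagnostic_position is not None:
            p = self.diagnostic_position - 1
            if not 0 <= p < self.length:
                raise ValueError("diagnostic_position out of range")
            spans.append((p, p + 1, "diagnostic"))
        if self.signature_start is not None:
            s = self.signature_start - 1
            if s < 0 or s + len(self.signature) > self.length:
                raise ValueError("signature does not fit in sequence")
            spans.append((s, s + len(self.signature), "signature"))
        taken: set[int] = set()
        for lo, hi, name in spans:
            span = set(range(lo, hi))
            if span & taken:
                raise ValueError(f"planted feature {name!r} overlaps another planted feature")
            taken |= span
        return frozenset(taken)


def _apply_plants(base: str, spec: MotifPlantSpec) -> str:
    arr = list(base)
    if spec.planted_terminal is not None:
        arr[-4:] = list(spec.planted_terminal.upper())
    if spec.diagnostic_position is not None:
        arr[spec.diagnostic_position - 1] = spec.diagnostic_residue.upper()
    if spec.signature_start is not None:
        s = spec.signature_start - 1
        arr[s : s + len(spec.signature)] = list(spec.signature.upper())
    return "".join(arr)


def gen_protein_family(
    spec: MotifPlantSpec,
    n: int,
    organism: str = "synthetic sp.",
    taxon_group: TaxonGroup = TaxonGroup.other,
) -> list[ProteinRecord]:
    """Generate ``n`` family members around the family's ancestral sequence."""
    if n < 1:
        raise ValueError("n must be >= 1")
    base = spec.base_sequence if spec.base_sequence is not None else family_base_sequence(
        spec.family, spec.length
    )
    if len(base) != spec.length:
        raise ValueError("base_sequence length does not match spec.length")
    planted = _apply_plants(base, spec)
    protected = spec.protected_positions()
    rng = np.random.default_rng(spec.seed)
    records = []
    for i in range(n):
        seq = _mutate(planted, spec.mutation_rate, rng, protected)
        records.append(
            ProteinRecord(
                f"{spec.family}_{i:04d}", organism, taxon_group, seq, enzyme_label=spec.family
            )
        )
    return records


def gen_reads(
    n: int, length: int, low_q_fraction: float, n_fraction: float, seed: int
) -> list[ReadRecord]:
    """Reads with exact planted low-quality and N compositions.

    Each read has exactly ``round(length * low_q_fraction)`` bases below Q20
    (at disjoint positions from the Ns, which are written with Q30 so the two
    counts stay independent) and exactly ``round(length * n_fraction)`` Ns.
    """
    if length < 1:
        raise ValueError("read length must be >= 1")
    for name, v in (("low_q_fraction", low_q_fraction), ("n_fraction", n_fraction)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    n_low = round(length * low_q_fraction)
    n_n = round(length * n_fraction)
    if n_low + n_n > length:
        raise ValueError("planted low-quality and N counts exceed read length")
    rng = np.random.default_rng(seed)
    reads = []
    bases_pool = np.array(list("ACGT"))
    for i in range(n):
        bases = rng.choice(bases_pool, size=length)
        quals = np.full(length, 38, dtype=int)
        pos = rng.permutation(length)[: n_low + n_n]
        quals[pos[:n_low]] = 10
        bases[pos[n_low:]] = "N"
        quals[pos[n_low:]] = 30
        reads.append(ReadRecord(f"read_{i:05d}", "".join(bases), quals.tolist()))
    return reads


def default_base_topology(n_taxa: int) -> str:
    """A fixed caterpillar-with-cherries topology over T1..Tn."""
    if n_taxa < 4:
        raise ValueError("need >= 4 taxa")
    labels = [f"T{i}" for i in range(1, n_taxa + 1)]
    tree = f"({labels[0]},{labels[1]})"
    for lab in labels[2:]:
        tree = f"({tree},{lab})"
    return tree + ";"


@dataclass(frozen=True)
class TreeSimSpec:
    """Synthetic twin of a posterior tree sample: a base topology plus a
    per-sample probability of one random NNI rearrangement."""

    base_topology: str
    n_samples: int
    perturbation_prob: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.perturbation_prob <= 1.0:
            raise ValueError("perturbation_prob must be in [0, 1]")
        if self.n_samples < 0:
            raise ValueError("n_samples must be >= 0")


def _apply_random_nni(tree: dendropy.Tree, rng: np.random.Generator) -> None:
    """One uniformly chosen nearest-neighbor interchange, in place."""
    internal_edges = [
        e
        for e in tree.preorder_edge_iter()
        if e.tail_node is not None and not e.head_node.is_leaf()
    ]
    edge = internal_edges[rng.integers(len(internal_edges))]
    v, u = edge.head_node, edge.tail_node
    sibling = next(c for c in u.child_nodes() if c is not v)
    kids = v.child_nodes()
    child = kids[rng.integers(len(kids))]
    v.remove_child(child)
    u.remove_child(sibling)
    v.add_child(sibling)
    u.add_child(child)


def gen_tree_samples(spec: TreeSimSpec) -> TreeSampleSet:
    """Draw ``n_samples`` trees around the base topology.

    Each sample equals the base with probability ``1 - perturbation_prob``,
    otherwise one random NNI is applied to a copy.
    """
    tns = dendropy.TaxonNamespace()
    try:
        base = dendropy.Tree.get(
            data=spec.base_topology, schema="newick", taxon_namespace=tns,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise ValueError(f"malformed base topology: {exc}") from exc
    if sum(1 for _ in base.leaf_node_iter()) < 4:
        raise ValueError("base topology needs >= 4 leaves")
    base.deroot()
    rng = np.random.default_rng(spec.seed)
    trees = []
    for _ in range(spec.n_samples):
        t = base.clone(depth=1)
        if rng.random() < spec.perturbation_prob:
            _apply_random_nni(t, rng)
        trees.append(t)
    return TreeSampleSet(trees, tns)


@dataclass
class OriginScenario:
    """A mixed prokaryote/eukaryote sequence set with known donor lineage."""

    records: list[ProteinRecord]
    donor: TaxonGroup
    eukaryote_group: TaxonGroup


def gen_origin_scenario(
    n_euk: int = 3,
    donor: TaxonGroup = TaxonGroup.proteobacteria,
    n_per_prok_group: int = 3,
    divergence: float = 0.2,
    seed: int = 0,
    length: int = 300,
    eukaryote_group: TaxonGroup = TaxonGroup.rhodophyta,
) -> OriginScenario:
    """Simulate a gene family where the eukaryotic copies descend from one
    prokaryotic donor group.

    The three prokaryote group ancestors each diverge from a common root by
    ``divergence`` substitutions/site; tips diverge from their group ancestor
    by half that; the eukaryotic ancestor branches off the donor's ancestor
    at a quarter of it.  At ``divergence=0`` every eukaryotic sequence equals
    the donor ancestor.
    """
    donor = TaxonGroup(donor)
    if donor not in PROKARYOTE_GROUPS:
        raise ValueError(f"donor must be a prokaryote group, got {donor.value!r}")
    if n_euk < 1 or n_per_prok_group < 1:
        raise ValueError("need >= 1 eukaryote and >= 1 sequence per prokaryote group")
    if not 0.0 <= divergence < 1.0:
        raise ValueError("divergence must be in [0, 1)")
    if (1.0 - divergence) ** 3 < 0.10:
        warnings.warn(
            "divergence so high that expected identity is below 10%; the "
            "phylogenetic signal is saturated",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    root = "".join(rng.choice(_AA, size=length))
    records: list[ProteinRecord] = []
    ancestors: dict[TaxonGroup, str] = {}
    for group in sorted(PROKARYOTE_GROUPS, key=lambda g: g.value):
        ancestors[group] = _mutate(root, divergence, rng)
        for k in range(n_per_prok_group):
            seq = _mutate(ancestors[group], divergence / 2, rng)
            records.append(
                ProteinRecord(f"{group.value}_{k}", f"{group.value} sp. {k}", group, seq)
            )
    euk_ancestor = _mutate(ancestors[donor], divergence / 4, rng)
    for k in range(n_euk):
        seq = _mutate(euk_ancestor, divergence / 4, rng)
        records.append(
            ProteinRecord(f"euk_{k}", f"{eukaryote_group.value} sp. {k}", eukaryote_group, seq)
        )
    return OriginScenario(records, donor, eukaryote_group)


def gen_reference_panel(length: int = 300) -> list[ProteinRecord]:
    """One reference sequence per enzyme family and variant label.

    Each reference is the family's fixed ancestral sequence, so queries drawn
    from :func:`gen_protein_family` share its ancestry.
    """
    records = []
    for label in ENZYME_FAMILIES + VARIANT_LABELS:
        records.append(
            ProteinRecord(
                f"ref_{label}",
                "reference panel",
                TaxonGroup.other,
                family_base_sequence(label, length),
                enzyme_label=label,
            )
        )
    return records
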