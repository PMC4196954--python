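"""Enzyme-family assignment, gene inventories, and C4-subtype completeness.

A query protein is assigned to the best-matching reference-panel family by
global-alignment identity.  Per-organism counts of assigned enzyme variants
form an inventory matrix; each C4 decarboxylation subtype (NADP-ME, NAD-ME,
PCK) is declared complete for an organism when every enzyme variant in its
required set has a nonzero count.  Cofactor (NAD/NADP) and compartment
(cyt/mit) variants are taken from input labels, not inferred here.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .align import DEFAULT_SCHEME, ScoringScheme, global_align
from .records import ProteinRecord
from .simulate import ENZYME_FAMILIES, VARIANT_LABELS

CONTROLLED_VOCABULARY = frozenset(ENZYME_FAMILIES) | frozenset(VARIANT_LABELS)
UNASSIGNED = "unassigned"

#: Table-1-style column order for family-level inventories.
FAMILY_COLUMN_ORDER = ("ALT", "AST", "MDH", "ME", "PCK", "PEPC", "PK", "PPDK")


@dataclass
class ReferencePanel:
    """Labeled reference sequences covering the eight enzyme families."""

    records: list[ProteinRecord]

    def __post_init__(self) -> None:
        families_seen = set()
        for r in self.records:
            if not r.enzyme_label:
                raise ValueError(f"panel record {r.id!r} has no enzyme label")
            if r.enzyme_label not in CONTROLLED_VOCABULARY:
                raise ValueError(f"panel record {r.id!r}: unknown label {r.enzyme_label!r}")
            families_seen.add(r.enzyme_label.split("-")[0])
        if not self.records:
            raise ValueError("empty reference panel")

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class FamilyAssignment:
    query_id: str
    label: str  # enzyme label or "unassigned"
    best_identity: float
    best_ref_id: str


def assign_family(
    query: ProteinRecord,
    panel: ReferencePanel,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    min_identity: float = 0.35,
) -> FamilyAssignment:
    """Best panel label by alignment identity.

    Ties on identity break by higher raw score, then lexicographic reference
    id; a best identity below ``min_identity`` yields ``unassigned``.
    """
    if not query.residues:
        raise ValueError("empty query")
    best: tuple[float, float, str, str] | None = None
    for ref in panel.records:
        res = global_align(query.residues, ref.residues, scheme)
        # prefer higher identity, then higher raw score, then smaller ref id
        better = (
            best is None
            or res.identity > best[0] + 1e-12
            or (abs(res.identity - best[0]) <= 1e-12 and res.score > best[1] + 1e-9)
            or (
                abs(res.identity - best[0]) <= 1e-12
                and abs(res.score - best[1]) <= 1e-9
                and ref.id < best[2]
            )
        )
        if better:
            best = (res.identity, res.score, ref.id, ref.enzyme_label)
    identity, _, ref_id, label = best
    if identity < min_identity:
        return FamilyAssignment(query.id, UNASSIGNED, identity, ref_id)
    return FamilyAssignment(query.id, label, identity, ref_id)


@dataclass
class InventoryMatrix:
    """Organism x enzyme-variant count matrix.

    ``frame`` is indexed by (taxonomy, organism); every cell is a
    non-negative integer count.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.frame.to_numpy() < 0).any():
            raise ValueError("inventory counts must be non-negative")

    def count(self, organism: str, label: str) -> int:
        if label not in self.frame.columns:
            return 0
        row = self.frame.xs(organism, level="organism")
        return int(row[label].sum())

    @property
    def organisms(self) -> list[str]:
        return list(self.frame.index.get_level_values("organism"))


def build_inventory(
    assignments: list[tuple[str, str]],
    taxonomy: dict[str, str] | None = None,
) -> InventoryMatrix:
    """Count (organism, enzyme label) assignment pairs into a matrix.

    ``unassigned`` pairs are excluded; organisms sort by (taxonomy, name).
    """
    taxonomy = taxonomy or {}
    counts: dict[str, dict[str, int]] = {}
    for organism, label in assignments:
        if label == UNASSIGNED:
            continue
        if label not in CONTROLLED_VOCABULARY:
            raise ValueError(f"label {label!r} outside the controlled vocabulary")
        counts.setdefault(organism, {})
        counts[organism][label] = counts[organism].get(label, 0) + 1
    organisms = sorted(counts, key=lambda o: (taxonomy.get(o, ""), o))
    labels = [c for c in FAMILY_COLUMN_ORDER if any(c in counts[o] for o in organisms)]
    labels += sorted(
        {l for o in organisms for l in counts[o]} - set(FAMILY_COLUMN_ORDER)
    )
    frame = pd.DataFrame(
        [[counts[o].get(l, 0) for l in labels] for o in organisms],
        index=pd.MultiIndex.from_tuples(
            [(taxonomy.get(o, ""), o) for o in organisms], names=["taxonomy", "organism"]
        ),
        columns=labels,
        dtype=int,
    )
    return InventoryMatrix(frame)


@dataclass(frozen=True)
class SubtypeDefinition:
    """The enzyme variants an organism needs for one C4 decarboxylation subtype."""

    name: str
    required: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "required", frozenset(self.required))
        unknown = self.required - CONTROLLED_VOCABULARY
        if unknown:
            raise ValueError(f"subtype {self.name!r}: unknown labels {sorted(unknown)}")
        if not {"PEPC", "PPDK"} <= self.required:
            raise ValueError(f"subtype {self.name!r}: PEPC and PPDK are always required")


def default_subtype_definitions() -> list[SubtypeDefinition]:
    """Standard C4 biochemistry: two shared enzymes (PEPC, PPDK) plus the
    subtype-specific decarboxylation enzymes."""
    return [
        SubtypeDefinition("NADP_ME", frozenset({"PEPC", "PPDK", "MDH-NADP", "ME-NADP"})),
        SubtypeDefinition(
            "NAD_ME",
            frozenset({"PEPC", "PPDK", "AST-cyt", "AST-mit", "MDH-NAD", "ME-NAD", "ALT"}),
        ),
        SubtypeDefinition("PCK", frozenset({"PEPC", "PPDK", "PCK", "AST-cyt"})),
    ]


@dataclass
class CompletenessReport:
    """Per organism x subtype: complete/incomplete plus the missing labels."""

    frame: pd.DataFrame = field(repr=False)  # index organism, columns subtype -> status
    missing: dict[tuple[str, str], list[str]] = field(default_factory=dict)

    def status(self, organism: str, subtype: str) -> str:
        return self.frame.loc[organism, subtype]

    def missing_for(self, organism: str, subtype: str) -> list[str]:
        return self.missing.get((organism, subtype), [])


def assess_subtypes(
    inv: InventoryMatrix, defs: list[SubtypeDefinition] | None = None
) -> CompletenessReport:
    """Mark each subtype complete iff every required label has a nonzero count."""
    defs = defs or default_subtype_definitions()
    organisms = inv.organisms
    statuses = {}
    missing: dict[tuple[str, str], list[str]] = {}
    for d in defs:
        col = []
        for org in organisms:
            absent = sorted(l for l in d.required if inv.count(org, l) == 0)
            if absent:
                missing[(org, d.name)] = absent
                col.append("incomplete")
            else:
                col.append("complete")
        statuses[d.name] = col
    frame = pd.DataFrame(statuses, index=organisms)
    return CompletenessReport(frame, missing)
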