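"""Rule-based enzyme typing.

Three classifiers:

* PEPC bacterial-type vs plant-type by the C-terminal tetrapeptide —
  (R/K)NTG marks a BTPC, QNTG a PTPC; anything else is unclassified.
* C4 vs non-C4 diagnostic-site calling — the residue homologous to a fixed
  reference position (default 774) is serine in C4-type enzymes and alanine
  in non-photosynthetic ones; the site is located by optimal global
  alignment to a reference PEPC.
* PPDK vs PEPS discrimination — PPDK carries an N-terminal
  nucleotide-binding domain that PEPS lacks, represented here as configurable
  sequence signatures searched within an N-terminal window.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources

import yaml

from .align import DEFAULT_SCHEME, GAP, ScoringScheme, map_reference_position
from .records import ProteinRecord


class PepcType(str, Enum):
    BTPC = "BTPC"
    PTPC = "PTPC"
    unclassified = "unclassified"


class C4Status(str, Enum):
    C4_type = "C4_type"
    non_C4 = "non_C4"
    other = "other"
    undetermined = "undetermined"


class PpdkVerdict(str, Enum):
    PPDK = "PPDK"
    PEPS_like = "PEPS_like"
    ambiguous = "ambiguous"


BTPC_TETRAPEPTIDES = frozenset({"RNTG", "KNTG"})
PTPC_TETRAPEPTIDE = "QNTG"


def classify_pepc_terminus(rec: ProteinRecord) -> tuple[PepcType, str]:
    """Type a PEPC by its exact C-terminal tetrapeptide (stop already stripped)."""
    if len(rec.residues) < 4:
        raise ValueError(f"record {rec.id!r}: sequence shorter than 4 residues")
    tail = rec.residues[-4:]
    if tail in BTPC_TETRAPEPTIDES:
        return PepcType.BTPC, tail
    if tail == PTPC_TETRAPEPTIDE:
        return PepcType.PTPC, tail
    return PepcType.unclassified, tail


def _load_packaged_reference() -> ProteinRecord:
    from .io import read_fasta  # local import to avoid a cycle

    with resources.as_file(
        resources.files("algc4.data") / "synthetic_reference_pepc.fasta"
    ) as p:
        return read_fasta(p)[0]


@dataclass
class DiagnosticSiteSpec:
    """Where and how to read the C4-diagnostic residue.

    ``reference_position`` is 1-based on ``reference``; ``window`` > 0 allows
    the nearest mapped residue within +/- window reference positions when the
    exact column is a gap (off by default for determinism).
    """

    reference: ProteinRecord = field(default_factory=_load_packaged_reference)
    reference_position: int = 774
    c4_residues: frozenset[str] = frozenset({"S"})
    non_c4_residues: frozenset[str] = frozenset({"A"})
    window: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.reference_position <= len(self.reference.residues):
            raise ValueError("reference_position outside the reference sequence")
        self.c4_residues = frozenset(r.upper() for r in self.c4_residues)
        self.non_c4_residues = frozenset(r.upper() for r in self.non_c4_residues)
        if self.c4_residues & self.non_c4_residues:
            raise ValueError("c4_residues and non_c4_residues must be disjoint")
        if self.window < 0:
            raise ValueError("window must be >= 0")


def call_c4_site(
    rec: ProteinRecord,
    spec: DiagnosticSiteSpec | None = None,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> tuple[C4Status, str, int | None]:
    """Classify the residue homologous to the reference diagnostic position.

    Returns ``(status, residue, query_position)``; a deletion spanning the
    site yields ``(undetermined, '-', None)`` unless a nonzero window
    rescues a nearby mapped column.
    """
    spec = spec or DiagnosticSiteSpec()
    qpos, residue = map_reference_position(spec.reference, rec, spec.reference_position, scheme)
    if qpos is None and spec.window > 0:
        for k in range(1, spec.window + 1):
            for cand in (spec.reference_position - k, spec.reference_position + k):
                if 1 <= cand <= len(spec.reference.residues):
                    qpos, residue = map_reference_position(spec.reference, rec, cand, scheme)
                    if qpos is not None:
                        break
            if qpos is not None:
                break
    if qpos is None:
        return C4Status.undetermined, GAP, None
    if residue in spec.c4_residues:
        return C4Status.C4_type, residue, qpos
    if residue in spec.non_c4_residues:
        return C4Status.non_C4, residue, qpos
    return C4Status.other, residue, qpos


@dataclass
class PepcCall:
    """Combined PEPC verdict: type by terminus, C4 status by diagnostic site.

    The two calls are independent — a bacterial-type PEPC can carry the
    C4-type serine, as brown-algal BTPCs do.
    """

    record_id: str
    pepc_type: PepcType
    terminal_tetrapeptide: str
    c4_status: C4Status
    diagnostic_residue: str
    diagnostic_query_pos: int | None


def classify_pepc(
    rec: ProteinRecord,
    spec: DiagnosticSiteSpec | None = None,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> PepcCall:
    pepc_type, tail = classify_pepc_terminus(rec)
    status, residue, qpos = call_c4_site(rec, spec, scheme)
    return PepcCall(rec.id, pepc_type, tail, status, residue, qpos)


@dataclass(frozen=True)
class SignatureSpec:
    """A named motif searched within an N-terminal window.

    ``pattern`` is a residue regular expression (plain strings work as exact
    motifs); a match must *start* inside [window_start, window_end] (1-based,
    inclusive).
    """

    name: str
    pattern: str
    window_start: int = 1
    window_end: int = 200

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError(f"signature {self.name!r}: empty pattern")
        if self.window_start < 1 or self.window_start > self.window_end:
            raise ValueError(f"signature {self.name!r}: bad window")
        try:
            re.compile(self.pattern)
        except re.error as exc:
            raise ValueError(f"signature {self.name!r}: bad pattern: {exc}") from exc

    def find(self, residues: str) -> int | None:
        """1-based start of the first in-window match, or None."""
        lo = self.window_start - 1
        m = re.compile(self.pattern).search(residues, lo)
        if m is not None and m.start() + 1 <= self.window_end:
            return m.start() + 1
        return None


@dataclass
class PpdkCall:
    verdict: PpdkVerdict
    matched_signatures: list[tuple[str, int]]


def classify_ppdk_peps(
    rec: ProteinRecord,
    ppdk_sigs: list[SignatureSpec],
    peps_sigs: list[SignatureSpec],
) -> PpdkCall:
    """PPDK iff a PPDK-specific signature matches and no PEPS signature does.

    A sequence matching only PEPS signatures is PEPS-like; matching neither,
    or both classes, is ambiguous (conservative: the re-annotation of a
    putative PPDK is only called on one-sided evidence).
    """
    if not ppdk_sigs or not peps_sigs:
        raise ValueError("both signature lists must be non-empty")
    matches: list[tuple[str, int]] = []
    ppdk_hit = peps_hit = False
    for sig in ppdk_sigs:
        pos = sig.find(rec.residues)
        if pos is not None:
            matches.append((sig.name, pos))
            ppdk_hit = True
    for sig in peps_sigs:
        pos = sig.find(rec.residues)
        if pos is not None:
            matches.append((sig.name, pos))
            peps_hit = True
    if ppdk_hit and not peps_hit:
        verdict = PpdkVerdict.PPDK
    elif peps_hit and not ppdk_hit:
        verdict = PpdkVerdict.PEPS_like
    else:
        verdict = PpdkVerdict.ambiguous
    return PpdkCall(verdict, matches)


def load_signatures(path=None) -> tuple[list[SignatureSpec], list[SignatureSpec]]:
    """Load (ppdk, peps) signature lists from YAML; defaults to the packaged
    synthetic signatures matched to the sequence generator."""
    if path is None:
        text = (resources.files("algc4.data") / "synthetic_signatures.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    out = []
    for key in ("ppdk", "peps"):
        if key not in raw or not raw[key]:
            raise ValueError(f"signature file missing non-empty {key!r} section")
        out.append([SignatureSpec(**entry) for entry in raw[key]])
    return out[0], out[1]
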