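"""Global pairwise alignment, identity/distance computation, and reference
position mapping.

Alignment uses Needleman-Wunsch with affine gaps via Biopython's
:class:`Bio.Align.PairwiseAligner` (global mode, end gaps penalized).  A gap
run of length L costs ``gap_open + L * gap_extend``; a linear scheme is the
special case ``gap_open == 0``.  'X' scores 0 against every residue.

Identity is computed over columns where both sequences carry a residue, so
terminal (and internal) gap columns never enter the denominator.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices

from .records import ProteinRecord

GAP = "-"


@lru_cache(maxsize=8)
def _named_matrix(name: str):
    m = substitution_matrices.load(name)
    if "X" in m.alphabet:
        for c in m.alphabet:
            m["X", c] = 0.0
            m[c, "X"] = 0.0
    return m


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution scoring plus affine gap penalties (applied as subtractions).

    Either a named substitution matrix (``matrix``, e.g. "BLOSUM62") or a
    match/mismatch pair is used; the matrix takes precedence when set.
    """

    matrix: str | None = "BLOSUM62"
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")

    @classmethod
    def simple(cls, match: float = 1.0, mismatch: float = -1.0, gap: float = 2.0) -> "ScoringScheme":
        """Match/mismatch scheme with a linear per-column gap penalty."""
        return cls(matrix=None, match=match, mismatch=mismatch, gap_open=0.0, gap_extend=gap)

    def pair_score(self, x: str, y: str) -> float:
        if self.matrix is not None:
            return float(_named_matrix(self.matrix)[x, y])
        return self.match if x == y else self.mismatch

    def make_aligner(self) -> PairwiseAligner:
        aligner = PairwiseAligner()
        aligner.mode = "global"
        if self.matrix is not None:
            aligner.substitution_matrix = _named_matrix(self.matrix)
        else:
            aligner.match_score = self.match
            aligner.mismatch_score = self.mismatch
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        return aligner


DEFAULT_SCHEME = ScoringScheme()


@dataclass
class AlignmentResult:
    """An optimal global alignment of two sequences.

    ``position_map`` maps 1-based positions of the first sequence to 1-based
    positions of the second, defined only for columns where both carry a
    residue.
    """

    aligned_a: str
    aligned_b: str
    score: float
    identity: float
    position_map: dict[int, int] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("gapped rows differ in length")


def _validate(seq: str, which: str) -> None:
    if not seq:
        raise ValueError(f"sequence {which} is empty")


def global_align(a: str, b: str, scheme: ScoringScheme = DEFAULT_SCHEME) -> AlignmentResult:
    """Optimal global alignment of residue strings ``a`` and ``b``.

    Biopython enumerates co-optimal alignments in a deterministic order; the
    first one is taken, so outputs are byte-stable for fixed inputs.
    """
    _validate(a, "a")
    _validate(b, "b")
    aligner = scheme.make_aligner()
    try:
        aln = aligner.align(a, b)[0]
    except ValueError as exc:  # unknown letter for the substitution matrix
        raise ValueError(f"illegal residue in alignment input: {exc}") from exc
    ga, gb = str(aln[0]), str(aln[1])
    matches = 0
    aligned_cols = 0
    position_map: dict[int, int] = {}
    ia = ib = 0
    for ca, cb in zip(ga, gb):
        if ca != GAP:
            ia += 1
        if cb != GAP:
            ib += 1
        if ca != GAP and cb != GAP:
            aligned_cols += 1
            position_map[ia] = ib
            if ca == cb:
                matches += 1
    identity = matches / aligned_cols if aligned_cols else 0.0
    return AlignmentResult(ga, gb, float(aln.score), identity, position_map)


def map_reference_position(
    ref: ProteinRecord,
    query: ProteinRecord,
    ref_pos: int,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> tuple[int | None, str]:
    """Locate the query column aligned to ``ref_pos`` (1-based) of ``ref``.

    Returns ``(query_pos, residue)``; a deletion in the query at that column
    yields ``(None, '-')``.
    """
    if not 1 <= ref_pos <= len(ref.residues):
        raise ValueError(
            f"ref_pos {ref_pos} out of range 1..{len(ref.residues)} for {ref.id!r}"
        )
    result = global_align(ref.residues, query.residues, scheme)
    qpos = result.position_map.get(ref_pos)
    if qpos is None:
        return None, GAP
    return qpos, query.residues[qpos - 1]


def pairwise_distance_matrix(
    records: list[ProteinRecord], scheme: ScoringScheme = DEFAULT_SCHEME
) -> pd.DataFrame:
    """Symmetric matrix of ``1 - identity`` distances between all record pairs."""
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids in distance matrix input")
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            res = global_align(records[i].residues, records[j].residues, scheme)
            d[i, j] = d[j, i] = 1.0 - res.identity
    return pd.DataFrame(d, index=ids, columns=ids)


def write_phylip(dm: pd.DataFrame, path) -> None:
    """Write a distance matrix in PHYLIP square format (names padded to 10)."""
    with open(path, "w") as fh:
        fh.write(f"{len(dm)}\n")
        for name, row in dm.iterrows():
            fh.write(f"{str(name)[:10]:<10}" + "  ".join(f"{v:.6f}" for v in row) + "\n")
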