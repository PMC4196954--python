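"""Readers and writers for the toolkit's four external formats, plus the
read-quality filter.

Formats: protein FASTA with pipe-delimited header metadata
(``id|organism|taxon_group[|enzyme_label]``), FASTQ with Phred+33 qualities
(fixed encoding, no autodetection), Newick tree samples (one tree per line,
unquoted labels), and delimited gene-inventory tables where blank cells mean
zero.  All writers are byte-stable given equal inputs.
"""
from __future__ import annotations

import logging
from pathlib import Path

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import ProteinRecord, ReadFilterConfig, ReadRecord, TaxonGroup
from .trees import TreeSampleSet, leaf_labels

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Parse protein FASTA with ``id|organism|taxon_group[|enzyme_label]`` headers.

    Unknown taxon-group names are mapped to ``other`` with a logged warning;
    a header with fewer than three fields is a parse error.
    """
    records: list[ProteinRecord] = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), 1):
        fields = rec.description.split("|")
        if len(fields) < 3:
            raise ValueError(
                f"{path}: entry {i} ({rec.description!r}): header needs "
                "id|organism|taxon_group[|enzyme_label]"
            )
        rid, organism, group_name = (f.strip() for f in fields[:3])
        label = fields[3].strip() if len(fields) > 3 and fields[3].strip() else None
        try:
            group = TaxonGroup(group_name)
        except ValueError:
            logger.warning(
                "%s: entry %s: unknown taxon_group %r mapped to 'other'", path, rid, group_name
            )
            group = TaxonGroup.other
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"{path}: entry {rid!r}: empty sequence")
        records.append(ProteinRecord(rid, organism, group, seq, enzyme_label=label))
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dup = next(x for x in ids if ids.count(x) > 1)
        raise ValueError(f"{path}: duplicate record id {dup!r}")
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            header = f"{r.id}|{r.organism}|{r.taxon_group.value}"
            if r.enzyme_label:
                header += f"|{r.enzyme_label}"
            fh.write(f">{header}\n{r.residues}{'*' if r.had_stop else ''}\n")


# ---------------------------------------------------------------- FASTQ

def read_fastq(path: str | Path) -> list[ReadRecord]:
    """Read FASTQ with Phred+33 quality encoding."""
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(
            ReadRecord(rec.id, str(rec.seq).upper(), list(rec.letter_annotations["phred_quality"]))
        )
    return reads


def write_fastq(reads: list[ReadRecord], path: str | Path) -> None:
    seqrecords = []
    for r in reads:
        sr = SeqRecord(Seq(r.bases), id=r.id, description="")
        sr.letter_annotations["phred_quality"] = list(r.quals)
        seqrecords.append(sr)
    SeqIO.write(seqrecords, str(path), "fastq")


def filter_reads(
    reads: list[ReadRecord], cfg: ReadFilterConfig | None = None
) -> tuple[list[ReadRecord], int]:
    """Drop reads whose low-quality or N fraction strictly exceeds the bounds.

    A read is discarded iff the fraction of bases with Phred below
    ``cfg.low_quality_threshold`` exceeds ``cfg.max_low_quality_fraction``, or
    the fraction of Ns exceeds ``cfg.max_n_fraction`` — both comparisons
    strict, so boundary reads are kept.  Input order is preserved.
    """
    cfg = cfg or ReadFilterConfig()
    kept: list[ReadRecord] = []
    for read in reads:
        n = len(read.bases)
        low_frac = sum(q < cfg.low_quality_threshold for q in read.quals) / n
        n_frac = read.bases.count("N") / n
        if low_frac > cfg.max_low_quality_fraction or n_frac > cfg.max_n_fraction:
            continue
        kept.append(read)
    return kept, len(reads) - len(kept)


# ---------------------------------------------------------------- Newick

def read_newick_samples(path: str | Path) -> TreeSampleSet:
    """Read one Newick tree per line into a TreeSampleSet.

    All trees must share one leaf set; quoted labels are rejected (the
    dialect is unquoted labels without whitespace).  An empty file yields an
    empty (valid) sample set.
    """
    tns = dendropy.TaxonNamespace()
    trees: list[dendropy.Tree] = []
    first_leaves: frozenset[str] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if "'" in line or '"' in line:
                raise ValueError(f"{path}:{lineno}: quoted Newick labels are not supported")
            try:
                tree = dendropy.Tree.get(
                    data=line, schema="newick", taxon_namespace=tns, preserve_underscores=True
                )
            except Exception as exc:
                raise ValueError(f"{path}:{lineno}: Newick parse error: {exc}") from exc
            leaves = leaf_labels(tree)
            if first_leaves is None:
                first_leaves = leaves
            elif leaves != first_leaves:
                raise ValueError(
                    f"{path}: sample {len(trees)} has a different leaf set than sample 0"
                )
            trees.append(tree)
    return TreeSampleSet(trees, tns)


def write_newick_samples(samples: TreeSampleSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for tree in samples:
            nwk = tree.as_string(
                schema="newick", suppress_rooting=True, unquoted_underscores=True
            ).strip()
            fh.write(nwk + "\n")


# ---------------------------------------------------------------- Inventory

def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def read_inventory(path: str | Path):
    """Read an organism x enzyme-variant count table (blank cells = 0).

    The first two columns are taxonomy and organism; every remaining column
    is a non-negative integer count.
    """
    from .inventory import InventoryMatrix

    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    if df.shape[1] < 3:
        raise ValueError(f"{path}: need taxonomy, organism and >=1 count column")
    taxonomy_col, organism_col = df.columns[:2]
    counts = {}
    for col in df.columns[2:]:
        vals = []
        for row_i, raw in enumerate(df[col]):
            raw = raw.strip()
            if raw == "":
                vals.append(0)
                continue
            try:
                f = float(raw)
            except ValueError:
                raise ValueError(f"{path}: row {row_i + 1}, column {col!r}: non-numeric {raw!r}")
            if f < 0 or f != int(f):
                raise ValueError(
                    f"{path}: row {row_i + 1}, column {col!r}: count must be a "
                    f"non-negative integer, got {raw!r}"
                )
            vals.append(int(f))
        counts[col] = vals
    out = pd.DataFrame(counts)
    out.insert(0, "organism", df[organism_col].str.strip())
    out.insert(0, "taxonomy", df[taxonomy_col].str.strip())
    return InventoryMatrix(out.set_index(["taxonomy", "organism"]))


def write_inventory(inv, path: str | Path) -> None:
    inv.frame.reset_index().to_csv(path, sep=_sep_for(path), index=False)
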