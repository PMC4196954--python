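"""End-to-end orchestration: simulate -> QC -> classify -> inventory ->
trees -> origin -> report.

A run is driven by one config mapping (usually loaded from YAML).  All
randomness flows from the config seed, so a rerun with the same config
produces byte-identical tables; the manifest records the seed, a config
hash, and per-stage record counts.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .align import ScoringScheme, pairwise_distance_matrix
from .classify import DiagnosticSiteSpec, classify_pepc, classify_ppdk_peps, load_signatures
from .inventory import (
    ReferencePanel,
    assess_subtypes,
    assign_family,
    build_inventory,
    default_subtype_definitions,
)
from .io import (
    filter_reads,
    read_fasta,
    read_fastq,
    read_newick_samples,
    write_fasta,
    write_fastq,
    write_newick_samples,
)
from .records import ReadFilterConfig, TaxonGroup
from .simulate import (
    MotifPlantSpec,
    TreeSimSpec,
    default_base_topology,
    gen_origin_scenario,
    gen_protein_family,
    gen_reads,
    gen_reference_panel,
    gen_tree_samples,
)
from .trees import (
    apply_burnin,
    asdsf,
    assign_origin,
    bipartition_frequencies,
    majority_rule_consensus,
    neighbor_joining,
)

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    """Paths of all emitted artifacts plus provenance."""

    outdir: str
    seed: int
    config_hash: str
    version: str
    outputs: dict[str, str] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def _validate_config(cfg: dict) -> None:
    inputs = cfg.get("inputs", {})
    for key, value in inputs.items():
        paths = value if isinstance(value, list) else [value]
        for p in paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"config inputs.{key}: no such file {p!r}")


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(cfg: dict, outdir: str | Path, seed: int | None = None) -> RunManifest:
    """Execute every configured stage; returns the manifest.

    ``seed`` overrides ``cfg['seed']``; stage sub-seeds are small fixed
    offsets of it so stages stay independently reproducible.
    """
    _validate_config(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0) if seed is None else seed)
    manifest = RunManifest(str(outdir), seed, _config_hash(cfg), __version__)
    sim = cfg.get("simulate", {})
    inputs = cfg.get("inputs", {})
    scheme = ScoringScheme(**cfg.get("scoring", {}))

    # ---- stage: sequence inputs
    proteins = []
    if "proteins" in inputs:
        proteins.extend(read_fasta(inputs["proteins"]))
    for i, fam in enumerate(sim.get("families", [])):
        fam = dict(fam)
        n = fam.pop("n", 10)
        organism = fam.pop("organism", "synthetic sp.")
        group = TaxonGroup(fam.pop("taxon_group", "other"))
        fam.setdefault("seed", (seed + 101 * (i + 1)) % 2**31)
        recs = gen_protein_family(MotifPlantSpec(**fam), n, organism, group)
        for r in recs:
            r.id = f"{organism.replace(' ', '_')}.{r.id}"
        proteins.extend(recs)
    if proteins:
        p = outdir / "proteins.fasta"
        write_fasta(proteins, p)
        manifest.outputs["proteins"] = str(p)
    manifest.counts["proteins_in"] = len(proteins)
    logger.info("sequences: %d records", len(proteins))

    # ---- stage: read QC
    reads = []
    if "reads" in inputs:
        reads = read_fastq(inputs["reads"])
    elif "reads" in sim:
        r = dict(sim["reads"])
        r.setdefault("seed", (seed + 17) % 2**31)
        reads = gen_reads(**r)
    if reads:
        kept, n_discarded = filter_reads(reads, ReadFilterConfig(**cfg.get("read_filter", {})))
        p = outdir / "reads.kept.fastq"
        write_fastq(kept, p)
        manifest.outputs["reads_kept"] = str(p)
        qc = outdir / "qc_summary.tsv"
        pd.DataFrame(
            [{"reads_in": len(reads), "reads_kept": len(kept), "reads_discarded": n_discarded}]
        ).to_csv(qc, sep="\t", index=False)
        manifest.outputs["qc_summary"] = str(qc)
        manifest.counts["reads_in"] = len(reads)
        manifest.counts["reads_kept"] = len(kept)
        logger.info("read QC: %d in, %d kept, %d discarded", len(reads), len(kept), n_discarded)

    # ---- stage: classification
    if proteins:
        site_spec = DiagnosticSiteSpec()
        ppdk_sigs, peps_sigs = load_signatures(cfg.get("signatures"))
        rows = []
        for rec in proteins:
            pepc = classify_pepc(rec, site_spec, scheme)
            ppdk = classify_ppdk_peps(rec, ppdk_sigs, peps_sigs)
            rows.append(
                {
                    "id": rec.id,
                    "organism": rec.organism,
                    "taxon_group": rec.taxon_group.value,
                    "pepc_type": pepc.pepc_type.value,
                    "tetrapeptide": pepc.terminal_tetrapeptide,
                    "c4_status": pepc.c4_status.value,
                    "diagnostic_residue": pepc.diagnostic_residue,
                    "ppdk_verdict": ppdk.verdict.value,
                }
            )
        p = outdir / "classification.tsv"
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
        manifest.outputs["classification"] = str(p)
        manifest.counts["classified"] = len(rows)

    # ---- stage: inventory + completeness
    if proteins:
        panel_path = inputs.get("panel")
        panel = ReferencePanel(
            read_fasta(panel_path) if panel_path else gen_reference_panel()
        )
        min_identity = float(cfg.get("min_identity", 0.35))
        assignments = []
        for rec in proteins:
            a = assign_family(rec, panel, scheme, min_identity)
            assignments.append((rec.organism, a.label))
        taxonomy = {r.organism: r.taxon_group.value for r in proteins}
        inv = build_inventory(
            [(o, l) for o, l in assignments if l != "unassigned"], taxonomy
        )
        p = outdir / "inventory.tsv"
        inv.frame.reset_index().to_csv(p, sep="\t", index=False)
        manifest.outputs["inventory"] = str(p)
        report = assess_subtypes(inv, default_subtype_definitions())
        rows = [
            {
                "organism": org,
                "subtype": sub,
                "status": report.frame.loc[org, sub],
                "missing": ",".join(report.missing_for(org, sub)),
            }
            for org in report.frame.index
            for sub in report.frame.columns
        ]
        p = outdir / "completeness.tsv"
        pd.DataFrame(rows, columns=["organism", "subtype", "status", "missing"]).to_csv(
            p, sep="\t", index=False
        )
        manifest.outputs["completeness"] = str(p)
        manifest.counts["assigned"] = sum(l != "unassigned" for _, l in assignments)
        manifest.counts["unassigned"] = sum(l == "unassigned" for _, l in assignments)

    # ---- stage: tree summarization
    runs = []
    for path in inputs.get("tree_samples", []):
        runs.append(read_newick_samples(path))
    tree_cfg = sim.get("trees")
    if tree_cfg:
        t = dict(tree_cfg)
        n_runs = t.pop("n_runs", 2)
        if "base_topology" not in t:
            t["base_topology"] = default_base_topology(t.pop("n_taxa", 8))
        t.pop("n_taxa", None)
        base_seed = t.pop("seed", seed)
        for k in range(n_runs):
            runs.append(gen_tree_samples(TreeSimSpec(seed=(base_seed + 11 * (k + 1)) % 2**31, **t)))
    if runs:
        burnin = float(cfg.get("burnin_fraction", 0.25))
        threshold = float(cfg.get("consensus_threshold", 0.5))
        kept_runs = [apply_burnin(r, burnin) for r in runs]
        for k, run in enumerate(kept_runs):
            table = bipartition_frequencies(run)
            p = outdir / f"bipartitions.run{k}.tsv"
            table.to_frame().to_csv(p, sep="\t", index=False)
            manifest.outputs[f"bipartitions_run{k}"] = str(p)
            cons = majority_rule_consensus(table, threshold)
            p = outdir / f"consensus.run{k}.nwk"
            Path(p).write_text(cons.newick + "\n")
            manifest.outputs[f"consensus_run{k}"] = str(p)
            p = outdir / f"samples.run{k}.nwk"
            write_newick_samples(run, p)
            manifest.outputs[f"samples_run{k}"] = str(p)
        manifest.counts["tree_samples"] = sum(len(r) for r in kept_runs)
        if len(kept_runs) >= 2:
            value = asdsf(kept_runs[0], kept_runs[1], float(cfg.get("asdsf_min_freq", 0.10)))
            p = outdir / "asdsf.txt"
            Path(p).write_text(f"{value:.6f}\n")
            manifest.outputs["asdsf"] = str(p)

    # ---- stage: origin assignment
    origin_cfg = sim.get("origin")
    if origin_cfg:
        o = dict(origin_cfg)
        o.setdefault("seed", (seed + 29) % 2**31)
        if "donor" in o:
            o["donor"] = TaxonGroup(o["donor"])
        scenario = gen_origin_scenario(**o)
        labels = {r.id: r.taxon_group for r in scenario.records}
        dm = pairwise_distance_matrix(scenario.records, scheme)
        tree = neighbor_joining(dm)
        call = assign_origin(tree, labels, scenario.eukaryote_group)
        p = outdir / "origin.tsv"
        donor_val = call.inferred_donor.value if isinstance(call.inferred_donor, TaxonGroup) else call.inferred_donor
        pd.DataFrame(
            [
                {
                    "eukaryote_group": call.eukaryote_group.value,
                    "inferred_donor": donor_val,
                    "true_donor": scenario.donor.value,
                    "recovered": donor_val == scenario.donor.value,
                    "support": call.support,
                }
            ]
        ).to_csv(p, sep="\t", index=False)
        manifest.outputs["origin"] = str(p)
        manifest.counts["origin_sequences"] = len(scenario.records)

    manifest_path = outdir / "manifest.json"
    manifest.save(manifest_path)
    manifest.outputs["manifest"] = str(manifest_path)
    return manifest


def summary_report(manifest: RunManifest) -> str:
    """Human-readable markdown report over the manifest's tables.

    Section ordering is fixed so a rerun yields identical bytes; a missing
    table is noted rather than an error.
    """
    lines = [
        "# Run report",
        "",
        f"- seed: {manifest.seed}",
        f"- config hash: {manifest.config_hash}",
        f"- toolkit version: {manifest.version}",
        "",
    ]

    def table_or_note(key: str, title: str, render) -> None:
        lines.append(f"## {title}")
        lines.append("")
        path = manifest.outputs.get(key)
        if path and Path(path).exists():
            render(pd.read_csv(path, sep="\t"))
        else:
            lines.append("_no data for this section_")
        lines.append("")

    def render_qc(df: pd.DataFrame) -> None:
        row = df.iloc[0]
        lines.append(
            f"{row['reads_in']} reads in, {row['reads_kept']} kept, "
            f"{row['reads_discarded']} discarded by the Q20/N filter."
        )

    def render_classification(df: pd.DataFrame) -> None:
        tallies = (
            df.groupby(["taxon_group", "pepc_type", "c4_status"]).size().reset_index(name="n")
        )
        for _, r in tallies.iterrows():
            lines.append(
                f"- {r['taxon_group']}: {r['n']} x {r['pepc_type']} / {r['c4_status']}"
            )

    def render_completeness(df: pd.DataFrame) -> None:
        if df.empty:
            lines.append("no organisms")
            return
        for _, r in df.iterrows():
            miss = f" (missing: {r['missing']})" if isinstance(r["missing"], str) and r["missing"] else ""
            lines.append(f"- {r['organism']} / {r['subtype']}: {r['status']}{miss}")

    def render_origin(df: pd.DataFrame) -> None:
        for _, r in df.iterrows():
            lines.append(
                f"- {r['eukaryote_group']}: inferred donor {r['inferred_donor']} "
                f"(true {r['true_donor']}, support {r['support']:.2f})"
            )

    table_or_note("qc_summary", "Read QC", render_qc)
    table_or_note("classification", "Enzyme classification", render_classification)
    table_or_note("completeness", "C4-subtype completeness", render_completeness)
    lines.append("## Tree summaries")
    lines.append("")
    if "asdsf" in manifest.outputs and Path(manifest.outputs["asdsf"]).exists():
        lines.append(f"ASDSF between runs: {Path(manifest.outputs['asdsf']).read_text().strip()}")
    else:
        lines.append("_no data for this section_")
    lines.append("")
    table_or_note("origin", "Origin assignment", render_origin)
    return "\n".join(lines) + "\n"
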