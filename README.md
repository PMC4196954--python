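# algc4

A survey toolkit for C4-photosynthesis (Hatch–Slack cycle) genes in algae.

Algal transcriptome surveys of the C4 pathway hinge on a handful of
reproducible procedures that are usually buried in methods sections:
filtering raw reads by quality composition, typing phosphoenolpyruvate
carboxylases (PEPC) as bacterial-type (BTPC) or plant-type (PTPC) from the
C-terminal tetrapeptide — (R/K)NTG vs QNTG — and as C4-type or
non-photosynthetic from the serine/alanine state of the residue homologous
to PTPC position 774; separating genuine pyruvate orthophosphate dikinase
(PPDK) from phosphoenolpyruvate synthetase (PEPS) by the N-terminal
nucleotide-binding-domain signatures; tallying per-organism enzyme
complements against the three C4 decarboxylation subtypes (NADP-ME, NAD-ME,
PCK); and summarizing Bayesian tree samples — burn-in, bipartition
frequencies, majority-rule consensus, the average standard deviation of
split frequencies (ASDSF) — down to a sister-group reading of which
prokaryotic lineage (archaea, proteobacteria, cyanobacteria) donated each
eukaryotic gene family. `algc4` implements those procedures as a tested,
seedable library with a thin CLI, together with synthetic-data generators
that plant known ground truth so every classifier and estimator can be
validated end to end.

It is aimed at comparative genomicists and molecular evolutionists who want
the classification rules and tree bookkeeping of such surveys as reusable,
deterministic code rather than one-off scripts.

## Worked example

```python
from algc4.classify import DiagnosticSiteSpec, classify_pepc
from algc4.records import ProteinRecord, TaxonGroup

# A brown-algal-style PEPC: bacterial-type terminus, C4-type site.
site = DiagnosticSiteSpec()                  # bundled synthetic reference, position 774
seq = list(site.reference.residues)
seq[773] = "S"                               # serine at the diagnostic site
seq[-4:] = list("KNTG")                      # bacterial-type tetrapeptide
rec = ProteinRecord("q1", "Saccharina-like sp.", TaxonGroup.ochrophyta, "".join(seq))
call = classify_pepc(rec, site)
print(call.pepc_type.value, call.terminal_tetrapeptide,
      call.c4_status.value, call.diagnostic_residue, call.diagnostic_query_pos)

# Convergence bookkeeping on two synthetic posterior runs.
from algc4.simulate import TreeSimSpec, default_base_topology, gen_tree_samples
from algc4.trees import asdsf

base = default_base_topology(8)
run_a = gen_tree_samples(TreeSimSpec(base, 5000, 0.05, seed=11))
run_b = gen_tree_samples(TreeSimSpec(base, 5000, 0.05, seed=22))
print(f"ASDSF = {asdsf(run_a, run_b):.6f}")

# Donor-lineage recovery on a simulated gene family.
from algc4.simulate import gen_origin_scenario
from algc4.align import pairwise_distance_matrix
from algc4.trees import assign_origin, neighbor_joining

sc = gen_origin_scenario(donor=TaxonGroup.proteobacteria, divergence=0.2, seed=1)
tree = neighbor_joining(pairwise_distance_matrix(sc.records))
call = assign_origin(tree, {r.id: r.taxon_group for r in sc.records}, sc.eukaryote_group)
print(f"inferred donor: {call.inferred_donor.value} (true: {sc.donor.value})")
```

Output:

```
BTPC KNTG C4_type S 774
ASDSF = 0.001131
inferred donor: proteobacteria (true: proteobacteria)
```

The first line says the sequence is a bacterial-type PEPC (KNTG terminus)
carrying the C4-type serine at the mapped position 774 — the combination
characteristic of brown-algal PEPCs, and a reminder that the type call and
the C4-site call are independent. The ASDSF of 0.0011 between two
independent 5,000-tree runs is well under the 0.01 bound conventionally
taken to indicate that two runs sample the same split distribution. The
last line shows the full align → distance → neighbor-joining → sister-group
pipeline recovering the planted proteobacterial donor.

## Command line

Every stage is exposed as a subcommand over the library:

```bash
algc4 simulate --spec spec.yaml --seed 3 --outdir sim/    # FASTA/FASTQ/Newick with ground truth
algc4 qc       --in sim/reads.fastq --out kept.fastq      # Q20/N read filter
algc4 classify --in sim/proteins.fasta --out calls.tsv    # PEPC + PPDK/PEPS verdicts
algc4 inventory --in sim/proteins.fasta --out inv.tsv     # family assignment + completeness
algc4 trees    --in run1.nwk --in run2.nwk --outdir trees/  # consensus + ASDSF
algc4 origin   --in family.fasta --euk-group rhodophyta --out origin.tsv
algc4 all      --config run.yaml --outdir out/            # full pipeline + markdown report
```

See `docs/methods.md` for the model, parameter defaults, and the design
decisions behind each stage.

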