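# Methods

## Scope and model

`algc4` re-implements, as a tested library, the classification and inference
machinery used in surveys of C4-photosynthesis (Hatch–Slack cycle) genes in
algal transcriptomes and genomes. Its components are:

1. a read-quality filter for the transcriptome QC stage,
2. three rule-based enzyme classifiers (PEPC typing by C-terminal
   tetrapeptide, C4-diagnostic-site calling, PPDK-vs-PEPS discrimination),
3. reference-panel family assignment feeding an organism × enzyme-variant
   inventory and C4-subtype completeness assessment,
4. tree-sample summarization (burn-in, bipartition frequencies,
   majority-rule consensus, ASDSF) plus neighbor joining and a formalized
   sister-group origin-assignment procedure, and
5. seeded synthetic-data generators that produce every input with known
   ground truth.

No MCMC, multiple alignment, assembly, BLAST/nr annotation, or targeting
prediction is performed; those stages are consumed as inputs (labels,
tree-sample files) or replaced by deterministic desk-scale equivalents as
described below.

## Read-quality filter

A read is discarded iff the fraction of bases with Phred score below Q20
strictly exceeds 0.10, or the fraction of N bases strictly exceeds 0.05
(both thresholds configurable). The comparisons are strict — "more than" —
so reads sitting exactly on a bound are kept. Quality encoding is fixed to
Phred+33; there is no autodetection. The filter is idempotent and preserves
input order.

## Pairwise alignment

All homology computations (diagnostic-site mapping, family assignment,
distance matrices) use optimal global pairwise alignment (Needleman–Wunsch
with affine gaps, via Biopython's `PairwiseAligner` in global mode) rather
than multiple alignment. This is a deliberate design choice: pairwise optima
are deterministic, cheap, and oracle-testable by exhaustive enumeration,
and they suffice for locating a single reference column or computing
identity. Default scoring is BLOSUM62 with gap open 11 / extend 1 (a gap run
of length L costs `open + L·extend`); these are community conventions, fully
configurable via `ScoringScheme`. `X` scores 0 against everything. Identity
is computed over columns where both sequences carry a residue, which
automatically excludes terminal gaps from the denominator. Co-optimal
alignments are resolved by taking the aligner's first alignment, which is
deterministic for fixed inputs; the test suite checks scores against an
independent brute-force enumeration on short strings rather than relying on
any particular traceback convention.

## PEPC typing and the C4-diagnostic site

The tetrapeptide rule examines exactly the last four residues after
stripping a terminal stop: RNTG/KNTG → bacterial-type PEPC (BTPC), QNTG →
plant-type PEPC (PTPC), anything else → unclassified (this last class covers
archaeal/cryptophyte-style PEPCs that fit neither motif). There is no
internal scanning.

The diagnostic site is the column homologous to position 774 of a reference
PTPC: serine marks a C4-type enzyme, alanine a non-photosynthetic one, any
other residue is reported as `other`, and a deletion spanning the site as
`undetermined`. The site is located by globally aligning the query to the
reference and reading the mapped column. Because no particular coordinate
reference is canonical, the package ships a *synthetic* reference sequence
(920 residues, serine at 774, QNTG terminus; generated from a fixed seed and
labelled synthetic in its file) and the whole spec — reference, position,
residue sets — is user-configurable. Strict single-column mapping is the
default; an optional ±k window mode returns the nearest mapped in-window
residue for users who prefer a tolerant reading, but it is off (k = 0) so
results are deterministic functions of the alignment.

The type call and the site call are independent; a BTPC can be C4-type
(the brown-algal pattern) or non-C4 (the diatom pattern).

## PPDK vs PEPS

PPDK is distinguished from PEPS (and other PEP-utilizing enzymes) by its
N-terminal nucleotide-binding domain. The classifier represents each class
by named signatures — residue regular expressions that must match starting
within an N-terminal window — and calls PPDK iff at least one PPDK signature
matches and no PEPS signature does; PEPS-like in the mirrored case; and
ambiguous when neither or both classes match. The both-match case is
deliberately conservative: re-annotating a deposited PPDK should require
one-sided evidence. The packaged default signatures are synthetic exact
motifs matched to the sequence generator; real-data users must supply
signatures transcribed from a domain database in the same YAML layout.

## Family assignment, inventory, completeness

A query is assigned the enzyme label of its best reference-panel match by
alignment identity (ties: higher raw score, then lexicographic reference
id), or `unassigned` below a minimum identity of 0.35. The identity
threshold replaces a database E-value cutoff, which has no meaning against a
small curated panel; 0.35 sits above the random-alignment background
(~5–10%) and below the divergence of genuine family members in the
generator's regime, and is configurable.

Inventories count (organism, label) assignments into an organism ×
enzyme-variant matrix (Table-style column order ALT, AST, MDH, ME, PCK,
PEPC, PK, PPDK, plus variant-resolved columns). Cofactor (NAD/NADP) and
compartment (cyt/mit) variants come from input labels; the package does not
infer them, since targeting prediction and tree placement are out of scope.

Subtype completeness uses required-label sets, by default:

* NADP-ME: PEPC, PPDK, MDH-NADP, ME-NADP
* NAD-ME: PEPC, PPDK, AST-cyt, AST-mit, MDH-NAD, ME-NAD, ALT
* PCK: PEPC, PPDK, PCK, AST-cyt

Every set contains the two shared enzymes (PEPC, PPDK); the subtype-specific
members follow standard C4 biochemistry (cytosolic AST doubling as the PCK
aminotransferase). These defaults are a design choice — published tables do
not print explicit sets — and are fully overridable. A subtype is complete
for an organism iff every required label has a nonzero count; completeness
is therefore monotone in gene gain. An inventory that does not resolve
MDH/ME cofactor variants can never report NADP-ME complete.

## Tree-sample summarization

* **Schedule arithmetic:** a run of G generations sampled every s
  generations yields `floor(G/s)` trees plus one if the initial state is
  recorded (5,000,000 / 100 + 1 = 50,001).
* **Burn-in:** the first `floor(fraction · n)` trees are discarded
  (default 0.25), matching the common summarizer convention.
* **Splits:** each unrooted tree contributes its n−3 nontrivial
  bipartitions, keyed canonically by the side not containing the
  lexicographically smallest leaf, so tables are byte-stable.
* **Consensus:** splits with frequency strictly above the threshold
  (default 0.5; thresholds below 0.5 are rejected because compatibility is
  no longer guaranteed) are assembled into a tree with supports; a 50/50
  conflict therefore collapses to a star.
* **ASDSF:** over all splits reaching a minimum frequency (default 0.10,
  the standard convention) in at least one of two runs, the sample standard
  deviation of the two frequencies (`|f₁−f₂|/√2`) is averaged. Identical
  runs give exactly 0.

## Neighbor joining and origin assignment

Neighbor joining is implemented directly (O(n³), exact on additive
matrices) with deterministic tie-breaking on the Q criterion (lowest active
index pair) and negative branch lengths clamped to zero, so output Newick is
reproducible byte-for-byte. The test suite cross-checks topologies against
scikit-bio's independent NJ and against additive-matrix ground truth.

Origin assignment formalizes the visual sister-group reading of a gene
tree: the tree is midpoint-rooted (a deterministic choice; published figures
root implicitly), the smallest clade containing every eukaryotic query leaf
plus at least one prokaryote leaf is located (MRCA, ascending while the
clade holds no prokaryote), and the prokaryotic groups inside that clade
give the donor — a single group, or `mixed` when several are present. Over
a tree sample, the modal donor is reported with support equal to the
fraction of agreeing samples.

## Synthetic-data generators

All generators are pure functions of their arguments, including one integer
seed per call; there is no hidden global RNG state.

* **Protein families** mutate a fixed family-specific ancestral sequence
  (derived from a CRC of the family name, so independently built panels and
  query sets share ancestry) i.i.d. per site at the given rate, never
  touching planted features: a terminal 4-mer, a diagnostic residue at a
  fixed position, a signature motif at a fixed offset. Background
  composition is uniform over the 20 amino acids — the simplest null.
  Default length 300 residues (920 when planting the diagnostic site on the
  bundled reference frame).
* **Reads** carry exactly `round(length · f_lowq)` sub-Q20 bases and
  `round(length · f_N)` Ns at disjoint randomized positions (Ns are written
  with Q30 so the two planted counts stay independent).
* **Tree samples** equal a base topology with probability 1−p and otherwise
  receive one uniformly chosen NNI (the smallest topology move, which keeps
  the expected split frequencies analytically tractable). The study-scale
  convergence twin uses 8 taxa, 5,000 trees per run, p = 0.05; with five
  internal splits each at expected frequency ≈0.99 in both runs and binomial
  noise sd ≈ 0.0014 at n = 5,000, the expected ASDSF is ≈0.001–0.003, far
  below the 0.01 stationarity bound.
* **Origin scenarios** place three prokaryote group ancestors at
  `divergence` substitutions/site from a common root, tips at half that
  within each group, and the eukaryotic ancestor at a quarter of it off the
  donor's ancestor. At divergence 0 the eukaryotic sequences equal the donor
  ancestor; at the default 0.2 the donor signal is strong but non-trivial.
  A warning is raised when expected identity falls below ~10% (saturation).

What the generators do *not* emulate: indels, rate heterogeneity across
sites, codon structure, realistic amino-acid composition, paralogy, and
correlated MCMC samples (the tree generator draws i.i.d. around one
topology). Passing recovery tests therefore demonstrates the correctness of
the rules and procedures, not their power on real, messier data.

## Problem sizes and numerics

Default test-time problem sizes: 5,000 trees per convergence run; 50
replicates per origin-recovery condition (12 sequences of 300 residues
each); 200 random pairs (length ≤ 8) for alignment-oracle equivalence; 100
random additive 5–8 taxon matrices for NJ recovery. Identity ties in family
assignment are broken at 1e-12 tolerance, alignment-score ties at 1e-9.
Degenerate inputs are defined rather than accidental: empty tree files are
valid empty sample sets, all-blank inventory rows are all-zero organisms,
empty assignment lists give empty matrices, and burn-in of an empty sample
set is empty.

## Known limitations

* The diagnostic-site call depends on the configured reference; with the
  synthetic default it is only meaningful for sequences generated on (or
  aligned to) that frame. Real analyses must supply a curated PEPC
  reference in the standard 774 numbering.
* Signature-based PPDK/PEPS discrimination is exact-rule classification,
  not domain detection; a profile-HMM would be the real-data tool.
* Midpoint rooting can mislead origin assignment under strong rate
  heterogeneity, which the generator does not produce.
* Family assignment against a one-sequence-per-label panel has no notion of
  statistical significance; the identity threshold is a pragmatic cutoff.
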