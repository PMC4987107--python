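# Methods

## Architectures, equality, and the calcium-binding registry

A domain architecture is the ordered token list of SCOP superfamily sunids
along a protein, with the literal `_gap_` marking unannotated stretches.
Two architectures are equal iff their token sequences are identical, gaps
included: `47473` and `47473,_gap_` are different architectures. This
string-level identity is what all "distinct architecture" counts use; it is
deliberately conservative — a gap often hides a real, unannotated domain, so
collapsing gapped and ungapped forms would conflate genuinely different
proteins. Parsing is strict: any token that is neither a positive integer
nor `_gap_` is an error naming the token, so dialect drift in input dumps
fails loudly rather than being silently reinterpreted.

The calcium-binding registry is data, not code: a CSV of curated
calcium-binding SCOP superfamilies (EF-hand, C2, annexin, calcium-ATPase
domains, GLA, cadherin-like, ...). The packaged table preserves its curated
source row-for-row, including one repeated row (TSP type-3 repeat, sunid
103647), so it has 31 entries over 30 distinct sunids; membership tests use
the deduplicated id set. Ids are validated only as positive integers — the
package does not check them against a live SCOP release, so user-supplied
registries for other domain collections work unchanged. An architecture is
*calcium-binding* iff at least one of its domains is in the registry.

## Repertoire statistics

Per genome, over annotated proteins only (structural annotation typically
covers ~70% of a eukaryote proteome; unannotated proteins are simply absent
from the tables, and the true gene count can be carried in metadata):

- `diversity_fraction = n_ca_archs / n_archs_total`, in [0, 1];
- `redundancy_ratio = (n_ca_proteins / n_ca_archs) / (n_proteins_total /
  n_archs_total)`, > 0 where defined — 1.0 means calcium-binding
  architectures are duplicated exactly as much as the proteome average;
- the occurrence matrix counts *proteins containing* each registry
  superfamily (a protein with two EF-hands counts once in the EF-hand
  column; a protein with an EF-hand and a C2 domain counts once in each).

Genomes where a ratio is undefined (no architectures; no calcium-binding
architecture) are excluded from cross-genome statistics with a logged
warning, never imputed. The abundance–diversity correlation is the Pearson
product-moment correlation (scipy) across genomes of calcium-binding protein
count vs distinct calcium-binding architecture count, one point per genome;
it requires ≥3 genomes and nonzero variance on both axes.

## Component annotation and the minimal toolkit

Functional components (influx, efflux, decoding, relay, plus finer labels
such as `decoding-CDPK`) are a user-editable catalog with a `binds_calcium`
flag per component. Protein-level labels arrive as
(protein_id, genome_id, component_id) rows; each label is inferred onto the
protein's architecture. A label whose component requires calcium binding is
dropped (with a log note) when the architecture has no registry domain;
unresolvable proteins are skipped. Annotations are global — one annotation
per distinct architecture, the union over all labeled proteins — while
presence is evaluated per genome, so a single architecture seen in many
genomes is annotated once but counted in each genome that has it.

An architecture is *multipurpose* when it enables ≥2 components (the ≥3
subset is reported separately). The minimal toolkit at coverage threshold
*t* contains each component for which the fraction of genomes possessing ≥1
annotated architecture of that component is ≥ *t*; a small epsilon (1e-12)
guards the comparison so that e.g. 9/10 ≥ 0.9 despite binary-float
representation. The set is antitone in *t* by construction.

The packaged example catalog (six components across the four categories) is
an editable stand-in for a full literature/pathway-derived mapping, which is
inherently curatorial and not reproducible from code; any analysis intended
for publication should substitute its own catalog and label table.

## Ancestral reconstruction

Reconstruction uses Dollo parsimony: each architecture is gained exactly
once and may be lost repeatedly. This is the standard content model for
multidomain architectures — independently re-inventing the same ordered
domain combination is improbable — and it makes reconstruction deterministic
and exactly testable. For a possessing leaf set L the gain node is MRCA(L);
a node at or below the gain is present iff its subtree retains a member of
L. Given the single-gain constraint this minimizes the loss count; the test
suite verifies optimality exhaustively against brute-force enumeration of
all single-gain assignments on every bifurcating tree shape with ≤6 leaves
and every nonempty presence pattern.

Assumptions and limits: no horizontal transfer (the model is meaningful for
eukaryote lineages; bacteria-heavy trees violate single-gain and are the
user's responsibility), no branch lengths (pure parsimony, no rates), and a
rooted input tree. Polytomies are handled natively — no arbitrary
binarization. Unnamed internal nodes get deterministic preorder ids
(`N0`, `N1`, ...); named internal nodes (e.g. `LECA`) keep their names and
are addressable. Subtree computations use per-node leaf bitmasks, so
reconstruction is linear in tree size per architecture. All tabular outputs
are sorted (nodes in preorder, architectures and events lexicographically)
for reproducible files.

Branch events are state differences along each branch; the root's virtual
incoming branch carries gains of root-present architectures. Treemap tables
report, per node, the number and percentage of multipurpose architectures
among annotated architectures present, and each component's percentage of
the single-purpose architectures (summing to 100 where any are present);
nodes with no annotated architecture are flagged empty rather than given
0/0 percentages.

## The simulator: what it emulates, and what it does not

The generator plants a full gain/loss history per architecture on a random
rooted bifurcating tree (uniform edge attachment), then materializes leaf
proteomes, copy numbers and component labels, with the complete truth
recorded. Defaults describe a moderately conserved toolkit: 20 leaves, 200
architectures, 30% calcium-binding, gains uniform over internal nodes, loss
probability 0.05 per branch, copy numbers 1 + Poisson(1) per architecture
per genome (mean 2 — modest duplication), and architectures enabling 1/2/3
components with probabilities 0.75/0.18/0.07 (most architectures
single-purpose, a small tail highly multipurpose). Gaps are inserted with
probability 0.1 per token boundary to exercise the string dialect.
Calcium-binding architectures carry ≥1 registry sunid; all other tokens come
from a background range (200000–209999) disjoint from the registry, so
membership is unambiguous. Calcium-requiring components are only planted on
calcium-binding architectures, so every planted label survives annotation
filtering and the recovered annotation map equals the planted map exactly.

Randomness is one seed expanded into an independent substream per
architecture index (numpy `SeedSequence` spawn keys), so outputs are
byte-identical under a fixed seed and independent of iteration order.
Architectures extinct at every leaf are redrawn (bounded retries) so every
emitted architecture is observable at ≥1 leaf. In `terminal_losses_only`
mode, loss draws are additionally rejected unless the history is exactly
recoverable under the single-gain/minimal-loss model (survivors span ≥2
children of the gain node and every internal node below the gain keeps a
surviving leaf); this mode exists to produce histories whose reconstruction
can be asserted node-for-node, and the rejection is what makes that
guarantee unconditional rather than merely high-probability. The
planted-loss-rate recovery test conditions on survival, which biases the
empirical rate slightly downward; it is asserted within four binomial
standard errors plus a small allowance.

What the simulator does **not** emulate: sequence evolution and annotation
error, correlated gains (domain shuffling producing related architectures),
rate variation across lineages, horizontal transfer, and time-calibrated
branch lengths. Passing recovery tests therefore demonstrates algorithmic
correctness on the stated model, not robustness of Dollo parsimony to
violations of its assumptions on real data.

## Pipeline and problem sizes

The pipeline stages (`metrics`, `components`, `ancestral`, `all`) are pure
functions of their input files and configuration; `all` writes a manifest
with a SHA-256 per output so reruns can be hash-verified. Strict parsing is
the default; lenient mode downgrades malformed proteome rows to a
dropped-row report. The leaf set of the species tree must equal the genome
set exactly; mismatches abort with both residual sets named.

The test suite and the results script run entirely on simulated data at
desk scale, the package's chosen survey sizes: a 44-genome, 300-architecture
survey for the cross-genome statistics and toolkit sweep, and 20-leaf,
200-architecture histories for reconstruction validation; exhaustive Dollo
checks cover all tree shapes with ≤6 leaves. The truth JSON schema emitted
alongside datasets: `states` (architecture → present node ids), `gain_node`,
`loss_branches` (architecture → [parent, child] pairs), `component_map`,
`copy_numbers` (`"genome\tarchitecture"` → count) and `ca_flags`.
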