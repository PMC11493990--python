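# Methods

This note documents the models, rules and numerical choices behind
`transnetkit`, the parameters that matter, and what the synthetic test
substrate does and does not establish.

## Data model

A trans-omics network is a directed multigraph. Nodes are molecules keyed
by `(id, layer, compartment)`: layers are TF, miRNA, mRNA, protein,
reaction, metabolite and transporter; compartments are tissue, blood or
none. Keying on the compartment makes the same metabolite measured in
tissue and in blood two distinct nodes, which the exchange network
requires. Measured molecules carry a response direction
(increased/decreased); inferred nodes (TFs, reactions, transporters)
default to unknown.

Edges are typed (`tf_target`, `mirna_target`, `ppi`, `enzyme_mrna`,
`substrate`, `product`, `allosteric_activation`, `allosteric_inhibition`,
`transporter_mrna`, `transport_substrate`) and optionally signed. Parallel
edges between the same node pair are allowed only with distinct types — a
metabolite can be both substrate and allosteric regulator of one reaction
— and exact `(source, target, type)` duplicates collapse to the first
occurrence, so degree counts are per-relation, not per-database-row. PPI
edges are stored once per unordered pair in canonical order, unsigned,
and treated as bidirectional by every analysis.

When networks are merged, an unknown direction is absorbed by a concrete
one; two conflicting concrete directions raise an error rather than
silently overwriting, because inputs are per-condition lists and a true
conflict indicates a user error upstream.

## Knowledge-base ingestion

Six single-header TSV dialects mirror the column semantics of the public
resources they are modelled on (ChIP-experiment target-gene tables,
miRNA–target support pairs, PPI combined scores, reaction/EC/gene/compound
mappings, allosteric activator/inhibitor tables, transporter–substrate
tables). Downloading or converting the real databases is out of scope;
adapters only need to produce these columns.

Filters and their defaults:

| parameter | default | meaning |
|---|---|---|
| `tss_window_kb` | 1 | row attribute matched exactly; tables arrive pre-windowed |
| `tf score_threshold` | 0 | minimum peak-caller binding score, inclusive |
| `ppi score_threshold` | 400 | minimum combined score on a 0–1000 scale, inclusive (the source database's "medium confidence" default) |
| `max_compound_degree` | 50 | substrate compounds linked to ≥ 50 other compounds in the chemical ontology are considered promiscuous and removed |
| membrane filter | on | transporters not flagged membrane-localized are removed |

Thresholds keep rows at exactly the threshold value (score 400 stays, 399
goes; compound degree 49 stays, 50 goes). Allosteric compound names
resolve to canonical compound ids with priority InChIKey → exact name →
synonym table, first hit wins; unresolved rows are dropped and counted. A
compound recorded as both activator and inhibitor of one enzyme keeps
both rows, flagged ambiguous, so downstream consumers can decide. Every
loader reports `input = retained + rejected + unresolved` row
conservation.

## Network construction

**Gene regulatory (A).** For each ChIP experiment the 2×2 table is
a = changed targets, b = changed non-targets, c = unchanged targets,
d = remainder of the background. The one-tailed (enrichment) Fisher exact
p is the hypergeometric tail P(X ≥ a); q-values come from one
Benjamini–Hochberg pass over all experiment × direction tests.
Enrichment runs separately for increased and decreased gene sets by
default (`enrichment_mode=split_by_direction`); a joint mode pools them.
Experiments with q ≤ `fdr_threshold` (default 0.05) contribute a TF node
with edges to their *changed* targets only — figure semantics, not the
full KB target set. miRNAs are not tested: any miRNA with ≥ 1 changed
target enters with edges to those targets. When no background list is
uploaded the default is the union of all target genes in the TF table
(the contingency table must be well defined); uploaded backgrounds must
cover every uploaded mRNA.

**PPI (B).** Nodes are uploaded molecules that appear in the PPI table
(isolated ones kept); edges join uploaded pairs at or above the score
threshold. A flag (`include_ppi_neighbors`) optionally pulls in first KB
neighbours as direction-unknown nodes; it is off by default because the
networks of interest are those among the changed molecules. Proteome
tables are accepted under `layer=protein` and treated as mRNA proxies by
builders B–D; identifier conversion is upstream of this package.

**Metabolic (C) and exchange (D).** A reaction node exists iff a changed
mRNA maps to one of its EC numbers or a changed tissue metabolite is a
substrate, product or allosteric regulator; a transporter node exists iff
its gene changed or one of its substrates changed in tissue or blood.
Edges run molecule → reaction/transporter and carry a sign from the rule
table: *(enzyme mRNA, up)*, *(substrate, up)*, *(product, down)*,
*(allosteric activator, up)*, *(allosteric inhibitor, down)*,
*(transporter mRNA, up)* and *(substrate metabolite, up)* activate; the
seven complements inhibit. Signs require a measured direction — unsigned
molecules never reach these builders. Reactions may carry several EC
numbers, each contributing enzyme edges; reaction nodes keep a
`pathway_id` for layout. The regulation-source summary partitions
reaction/transporter nodes into mRNA-only / metabolite-only / both from
their incident edge types; the three counts always sum to the number of
regulated nodes.

## Network analysis

Global metrics are computed on the **simple undirected projection**
(parallel edges, direction and self-loops dropped): the density and
clustering formulas D = 2E/(N(N−1)) and C_u = 2T(u)/(D(u)(D(u)−1))
presuppose simple undirected counts, and the projection makes the
handshake identity Σk = 2E hold exactly. C_u = 0 by convention when
D(u) < 2. Assortativity is the Pearson correlation of endpoint degrees
over all edges, both orientations included; it is reported as undefined
(an error) for regular graphs. Hub ranking sorts by degree descending
with lexicographic tie-breaks, so output order is deterministic.

The scaling parameter fits log₁₀ N_k on log₁₀ k by ordinary least squares
over degrees with N_k > 0 (no binning; logarithmic binning would change
the estimand), reporting γ = −slope, r² and a t-based 95% CI from the
standard slope-error formula. Least-squares estimation of power-law
exponents is known to be imprecise; the CI should be read as describing
the fit, not as a guarantee about the generating process. Maximum-
likelihood (Clauset-style) fitting is deliberately out of scope.

Motif extraction works on the directed edges with a consensus sign per
ordered pair (disagreeing parallel signs → unsigned). Feedback loops are
simple directed cycles of length 2..`max_len` (default 5 — cycle counts
explode combinatorially, so unbounded enumeration is not offered);
a fully signed cycle is positive iff it contains an even number of
inhibiting edges. Feedforward loops are ordered triples X→Y, Y→Z, X→Z,
coherent iff the direct sign equals the product of the two path signs.
Cycles are reported in canonical rotation (smallest node first) for
determinism.

The SMA slope is sign(corr)·sd(y)/sd(x) with the line through the
centroid (positive branch at exactly zero correlation). The common-slope
test permutes group labels over pooled (x, y) pairs (default B = 999,
seeded) with statistic |slope₁ − slope₂| and p = (1 + #extreme)/(B + 1);
permutation avoids the distributional assumptions of likelihood-ratio
common-slope tests and is verifiable by simulation. Degenerate
permutations (zero variance in a group) count as extreme, keeping the
test conservative. Only slopes are compared; elevation differences are
out of scope.

## Synthetic fixtures

The generators emulate the *structure* of real inputs, not the biology of
any dataset: knowledge-base tables that exercise every filter (PPI scores
straddling 400, compound degrees straddling 50, one unresolvable
allosteric name, a non-membrane transporter), omics tables with exact
planted overlap between the changed-gene set and one TF's targets, and
degree sequences with a planted power-law exponent. Decoy ChIP
experiments are constructed with their overlap pinned to the rounded
chance expectation, so the planted TF is the unique enriched experiment
for every seed. All randomness flows through one seeded generator;
identical specs give byte-identical files.

Planted-γ networks draw each node's degree i.i.d. from P(k) ∝ k^(−γ) on
k = 1..k_max, so seeded replicates carry genuine multinomial sampling
noise and confidence-interval calibration is a meaningful property; the
deterministic expected histogram N_k = round(C·k^(−γ)) is available as
`mode="expected"` (it is identical for every seed, and its rounding
introduces a small bias of order 0.03 in the fitted exponent at
n = 2000). When `k_max` is unset the support is truncated where the
expected count falls below one, avoiding a rounded-to-zero tail plateau.
The degree sequence is realized by configuration-model stub matching;
self-loops and duplicate edges are repaired by random pair swaps that
preserve the degree sequence exactly (an unrepairable pair — not observed
at these sizes — would be dropped and recorded in metadata; an odd stub
total appends one degree-1 node).

Passing tests on these fixtures establish that the pipeline recovers what
was planted under the stated models; they do not establish robustness to
the noise structure of real measurements (coverage differences between
omics platforms, identifier mismatches, database incompleteness), which
the fixtures do not model.

## Verification problem sizes

The test suite checks the Fisher tail against exhaustive hypergeometric
enumeration on all 2×2 tables with total ≤ 12; BH against the brute-force
step-up definition on 1,000 random vectors of length ≤ 20; density and
clustering against direct edge/triangle counting on 200 random graphs of
≤ 15 nodes; cycle and feedforward extraction against DFS/triple
enumeration on 100 random digraphs of ≤ 8 nodes; planted-γ recovery at
2,000 nodes with 50 seeded replicates per γ ∈ {1.5, 2.0, 2.5} (within
0.2 and inside the 95% CI in ≥ 80% of runs); and the SMA permutation
test's type-I error over 200 null simulations at B = 999 (within
[0.02, 0.08] at α = 0.05). These sizes make the full suite run in about
a minute on one CPU while keeping every check exhaustive or
well-powered.

## Layouts and serialization

The layered layout places nodes in fixed horizontal bands (TF/miRNA,
mRNA/protein, reaction/transporter, tissue metabolites, blood
metabolites), ordered by id and evenly spaced — a pure function of the
network. The pathway layout places reaction/metabolite nodes at
user-supplied per-pathway coordinates (a two-table TSV standing in for
pathway-map XML, whose licensing and parsing are out of scope), offsets
enzyme mRNAs from their reaction by a fixed displacement, and flags
fallback placements. Exports (GraphML, node-link JSON, flat TSV with a
node/edge discriminator column so isolated nodes survive) are
deterministically ordered and round-trip the node set, edge multiset and
all attributes.

## Known limitations

- Identifier namespaces are taken at face value; no ortholog or
  cross-database id conversion.
- Enrichment backgrounds default to the TF table's target universe when
  not supplied, which can understate d for sparsely covered genomes.
- The γ fit inherits the well-known biases of least squares on log-log
  histograms, especially for short supports (large γ truncates the
  support early).
- Cycle enumeration is bounded by `max_len`; motifs longer than the bound
  are not reported.
- Reaction stoichiometry, kinetics and flux are out of scope; edges are
  qualitative regulatory claims.
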