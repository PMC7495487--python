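# Methods

## Overview

`netpharm` implements the inference chain used in network pharmacology of
herbal medicines: starting from an ingredient table of a herb (the running
example being indigo naturalis, used orally against ulcerative colitis),
it screens ingredients by ADME scores, assembles drug-target and
disease-target gene sets from heterogeneous sources, intersects them into
composite targets, screens hub ("core") targets on a protein-protein
interaction (PPI) graph by centrality medians, localizes targets to
above-average tissues in an expression atlas, and tests pathway
over-representation of the core set. Every stage consumes and produces
plain-text files (TSV, GMT, GraphML) and has a seeded synthetic generator
so the full chain runs and is tested without any database access.

## Compound screen

A compound is retained when its predicted oral bioavailability OB (percent
scale) and drug-likeness DL (unitless, in [0, 1]) satisfy OB >= 30 and
DL >= 0.18, both inclusive. A name-based whitelist (matched
case-insensitively after trimming) rescues compounds with experimental
support that fail the numeric rule; whitelist rescue also overrides a
missing score. Compounds with missing OB or DL that are not whitelisted
are rejected with an explicit `missing-score` audit reason rather than an
error — ingredient tables scraped from multiple databases routinely have
gaps, and the policy keeps them visible. The filter is monotone in both
thresholds and idempotent.

## Target assembly

The canonical identifier is the uppercase gene symbol: it is what PPI
edge lists, tissue atlases and GMT term maps key on. Canonicalization
trims, applies an optional exact-match alias table (for mixed inputs such
as UniProt accessions or legacy symbols), then uppercases. Merging is a
union with per-source provenance; intersection merges provenance from
both sides. No fuzzy matching is attempted: a silent wrong merge corrupts
every downstream stage, whereas a missed merge is visible in the Venn
counts and provenance columns.

## Differential expression

The joint multi-study analysis is intentionally simple and fully
transparent:

1. **Batch adjustment** — a location-only correction using the known
   batch labels: per gene, each batch's mean is shifted to the gene's
   pooled mean. With batches balanced across groups this leaves the
   case-control expectation untouched; a single-batch study passes
   through unchanged. Surrogate-variable estimation is out of scope.
2. **Testing** — a per-gene Welch two-sample t-test on log2 values
   (`scipy.stats.ttest_ind(equal_var=False)`); log2 fold change is mean
   case minus mean control. Genes with zero variance in both groups get
   p = 1 when the means agree. No empirical-Bayes variance moderation is
   applied; with the default group sizes (about 20 per arm) moderation
   changes little, and the screening thresholds, not the test internals,
   define the stage.
3. **Multiple testing** — Benjamini-Hochberg step-up across all tested
   genes (`statsmodels.multipletests`, `fdr_bh`).
4. **Volcano rule** — a gene is called differentially expressed iff
   adjusted p < 0.05 AND |log2 fold change| > 1, both strict.

Because the test differs from moderated-t pipelines, DEG counts from
published moderated analyses are not exact reproduction targets; what the
stage guarantees — verified on simulations with 1000 genes, 20+20
samples, 50 planted DE genes at log2 fold change 2, noise sd 0.5, two
batches with unit batch effects — is sensitivity >= 0.9 at a realized
false-discovery proportion <= 0.1.

## PPI topology and the core-target screen

The PPI graph is read from a STRING-dialect edge list (node, node,
combined score 0-1000), restricted to the composite targets, filtered at
a confidence cutoff (default 400, STRING's conventional "medium
confidence"; the cutoff is exposed as `--score-min`), stripped of
self-loops and duplicates (max score kept), and finally of unconnected
nodes.

Centralities are topological (confidence scores gate edges, never weight
paths):

* **DC** — degree;
* **BC** — Brandes betweenness, endpoints excluded, normalized by
  2/((n-1)(n-2)) so values live in [0, 1] (for a 182-node network a
  median on the order of 1e-3 is only plausible on this scale);
* **CC** — Wasserman-Faust component-corrected closeness,
  cc(v) = ((r-1)/(n-1)) x ((r-1)/sum of distances), where r is the size
  of v's component; on a connected graph this reduces to (n-1)/sum(d),
  and isolated nodes score 0.

The screen keeps a node iff DC >= 2 x median(DC), BC >= median(BC) and
CC >= median(CC), all inclusive, in a single pass with medians taken once
over the cleaned network (never recomputed on survivors). Inclusivity
matters: in the published reference table bundled with the package the
minimum surviving degree equals exactly twice the full-network median
degree, which forces `>=`. The median of an even count is the midpoint of
the central pair. Centralities are delegated to networkx; the test suite
checks them against a hand-written BFS path-enumeration oracle on 200
random graphs to 1e-9, plus closed-form values for paths, stars, cycles
and cliques.

## Organ localization

Following the tissue-atlas convention, probes are collapsed to genes by
arithmetic mean; a gene is assigned to every tissue whose mean expression
strictly exceeds the gene's overall mean across ALL atlas tissues. Only
afterwards is the display restricted to a curated organ panel (the
bundled default lists 17 immune-related organs and tissues; any panel
file can be substituted). The compute-then-restrict order is deliberate:
the overall mean over the full atlas, not the panel, defines
"above average". The rule is invariant under scaling a gene's whole
profile, and genes absent from the atlas are carried in an explicit
missing set that propagates to the audit. Organs with no assigned gene
are dropped from the bipartite network's node set.

## Enrichment

Over-representation uses the hypergeometric upper tail P(X >= k) for a
universe of N genes, term size K, query size n and overlap k, computed
via scipy's log-space survival function and verified in tests against
exhaustive rational-arithmetic enumeration for all N <= 12. The universe
defaults to all genes annotated in the term map, configurable to a custom
background. BH adjustment runs across all tested terms (those with
overlap >= 1); rows sort by (p_adj, p_raw, term id), the id being the
deterministic tie-break. Selection is strict FDR < 0.05 followed by the
top 20 rows. Term collections are flat GMT sets; ontology DAG structure
is not propagated.

## Display networks

The Herb-Component-Target, Target-Organ and Target-Pathway networks are
undirected multipartite graphs whose edges may only join adjacent roles;
a violation is a hard error, re-validated on every build and export. The
`degree` attribute is computed within each assembled network, not
inherited from the PPI graph, because node prominence in each display
reflects that display alone. Exports are GraphML and Cytoscape-dialect
node/edge TSVs, both verified to round-trip losslessly.

## Synthetic data: what it emulates and what it does not

Each generator owns an independent random stream (a `SeedSequence` spawn
key per generator), so one global seed reproduces every fixture
bit-for-bit and adding a generator never perturbs another. Defaults are
set to the study conditions the pipeline was designed around: a
29-compound table with 9 ADME passes and 1 whitelist rescue (10
retained); 933 drug targets vs 913 disease targets sharing exactly 184
symbols (Venn 749/729/184); 1000-gene expression studies with 50 planted
DE genes at log2 fold change 2, noise sd 0.5, and two batches with
additive per-(gene, batch) N(0, 1) effects; 180-node
preferential-attachment graphs (m = 2) with a 40-node hub module wired at
pairwise density 0.8 internally and density/20 outward — dense enough
that the median screen separates the module, sparse enough that recovery
is non-trivial; 20-tissue atlases with planted genes at 10x their
background mean and a stated fraction of atlas gaps; 100-200-term GMT
maps with one term planted at a fixed query overlap.

What the generators do **not** emulate: real microarray probe chemistry
or normalization artifacts, STRING's empirical score distribution, the
correlation structure of real co-expression, or real GO/KEGG term
overlap. Passing the recovery suites therefore demonstrates that the
screening logic recovers planted structure under its stated model — not
that any particular biological claim reproduces on live databases, whose
snapshots drift.

The bundled `core_target_degrees.tsv` is the published 43-row degree
column of the indigo naturalis / ulcerative colitis core-target network
(full-network median degree 15); it is reference data for checking the
two-fold-median degree rule, not generator output.

## Numerical choices and degenerate inputs

* Even-count medians are midpoints; all screen comparisons inclusive.
* Welch p values that come back non-finite (zero variance in both
  groups) map to 1 for equal means and 0 otherwise, logged.
* Empty edge lists, empty survivor sets, empty enrichment tables and
  empty networks are valid outputs with warnings, never crashes;
  infeasible generator cardinalities and malformed thresholds raise
  `ValueError` before any work happens.
* Duplicate PPI edges collapse to the maximum score; malformed edge-list
  lines are skipped with line-numbered warnings.
* Reports are JSON with sorted keys and no timestamp, so fixed seed and
  fixed inputs give byte-identical reruns.

## Problem sizes in the standard suites

The recovery studies average 20 independent seeds each at the sizes
above; the centrality oracle sweep uses 200 random graphs with up to 25
nodes; the hypergeometric oracle enumerates every configuration with
N <= 12. These sizes make the full test suite and the acceptance script
each run in well under a minute on one CPU while keeping the stochastic
margins wide.

## Known limitations

* The batch adjustment assumes known batch labels and additive location
  shifts only; scale differences between batches are not corrected.
* Cross-study gene matching is the intersection of symbols; no ortholog
  or probe-set harmonization beyond mean-collapse.
* The ADME screen trusts the input scores; nothing is computed from
  structures.
* Live-database headline counts (target-list sizes from specific
  snapshots, atlas-dependent per-organ counts) are inherently
  snapshot-bound and are exercised here at their printed cardinalities
  through the generators rather than by re-downloading.
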