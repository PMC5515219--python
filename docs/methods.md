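# Methods

This note documents the models, conventions and design choices behind
`komnet`, in the spirit of a statistical-software methods appendix.

## Quantification model

Let c_g be the (possibly fractional) mapped-read count of gene g in
one omic layer and L_g its *effective length* — the number of
positions a read start can occupy, accepted as input and defined by
the synthetic generator as max(1, gene_length − read_length + 1).
The normalised abundance of g is c_g / L_g (reads per nucleotide of
effective length). KO abundances are sums over member genes:

    KOGA(k) = Σ_{g ∈ k} c_g^MG / L_g       KOTA(k) = Σ_{g ∈ k} c_g^MT / L_g

and relative gene expression is rel(k) = KOTA(k)/KOGA(k): transcription
normalised to underlying gene copy number, so constitutively encoded
but weakly transcribed functions rank low and rare-but-active
functions rank high.

Conventions:

* **Subsampling** draws exactly `depth` reads *without replacement*
  (multivariate hypergeometric over genes) from integer pre-weighting
  counts. It approximates read-level subsampling at the count-table
  boundary; KO abundances are not rescaled afterwards.
* **Multi-mapping reads** contribute 1/k to each of their k genes,
  accumulated in rational arithmetic so the gene total equals the read
  count exactly.
* **Multi-KO genes** contribute their full abundance to every assigned
  KO by default (`multi_ko="split"` divides instead).
* **MT-only KOs** (KOTA > 0, KOGA = 0) have undefined expression; the
  default policy flags them and excludes them from percentile ranking.
  The alternative substitutes the smallest non-zero KOGA as a
  pseudocount, which fabricates a finite but extreme ratio — use only
  when a complete ranking is required.

## Network reconstruction

A reaction-pair map assigns each KO a pair-set of (substrate, product)
metabolites. Nodes are KOs (or KO groups); metabolites are undirected
edges. Two edge semantics are supported:

* `shared_metabolite` (default): an edge (u, v, m) for every
  metabolite m appearing in any role in both pair-sets — the
  connectivity-centred view of community metabolism. One parallel
  edge is kept per shared metabolite.
* `complementary`: m must be a product of one node and a substrate of
  the other — a stricter, flow-like semantics.

`shared_metabolite` always yields an edge superset of `complementary`.
Self-loops are never created (shortest-path measures ignore them and
degree stays interpretable). KOs with no pair annotation are excluded
(with a logged warning); sample-specific networks keep only KOs with
KOTA > 0. No currency-metabolite filter is applied by default — the
pair-map input is expected to encode reactant-pair specificity — but
callers can pre-filter the map.

**Non-redundant collapsing** merges KOs with identical pair-sets
(typically subunits of one enzyme complex) into a single node named
after its lexicographically smallest member; edges are recomputed
between groups, so any two groups are joined by exactly one edge per
qualifying metabolite. Collapsing is idempotent and conserves the KO
set.

## Topology

Betweenness is computed exactly (Brandes' algorithm) on the simple
underlying graph, summed over unordered pairs with endpoints excluded;
pairs in different components contribute nothing. The load score of
node n is

    load(n) = B(n) / (k_n · E)

Two counting conventions exist for k_n and E: `parallel` (default)
counts one edge per metabolite, `simple` counts connected node pairs
once. The default follows the convention in which reported community
edge counts include non-unique metabolites; the choice is recorded in
the output metadata and `simple` is available for sensitivity
analysis. Isolated nodes get load 0 with an `isolated` flag rather
than a division error. Betweenness is left unnormalised by default;
the (N−1)(N−2)/2 normalisation switch exists but cannot change
load-score ranking within one network.

The **weighted variant** re-runs betweenness with Dijkstra path
lengths in which an edge labelled m costs occurrence(m) — the number
of nodes whose pair-set contains m. Equivalently, each edge has
affinity 1/occurrence(m) and distance is its reciprocal: routes
through ubiquitous (currency-like) metabolites are long and avoided,
so weighted load points concentrate within pathways. Parallel edges
collapse to their rarest metabolite. With uniform occurrences the
ranking provably equals the unweighted one. Because this variant is a
reconstruction of an under-specified published idea, it is reported
separately and never drives default keystone selection.

**Choke points** are KOs whose pair-set contains at least one
metabolite present in no other subset member's pair-set — unique
consumers/producers. They are reported as annotation, not used as a
selection criterion: uniqueness is a fragile claim when most community
metabolism is unannotated.

**Average shortest path length** is the mean over connected unordered
node pairs; disconnected pairs are excluded and counted separately.

## Keystone selection

With selection fractions q_load = q_expr = 0.10, the thresholds are
the ceil(q·N)-th largest load score over all N network nodes and the
ceil(q·N')-th largest relative expression over the N' nodes with a
defined expression value. A node is selected iff it meets both
thresholds. Tie policy `include_ties` (default) admits every entity
tied with the threshold; `strict` returns exactly ceil(q·N) entities,
breaking threshold ties by node id. A collapsed group's expression is
the maximum over member KOs by default (sum and mean are available):
a group is as active as its most active member.

Pathway enrichment of the selected set uses the one-sided
Fisher-exact (hypergeometric) test per pathway over the quantified-KO
background, with Benjamini–Hochberg adjustment across pathways;
pathways devoid of selected members report p = 1. Seasonal betweenness
comparisons pair KOs present in both networks: per pathway the median
of per-KO fold changes (pairs with a zero in either season are
excluded from the median and counted) and a two-sided Wilcoxon
signed-rank p-value on the paired differences (exact for small n
without ties; p = 1 when all differences vanish). Pathways with fewer
than two shared KOs are skipped with a warning.

## Synthetic communities and what they show

`SynthConfig()` defaults describe a small community engineered so that
ground truth exists by construction: 57 KOs in 3 ring modules of 19
plus 3 bridge KOs (60 total). Ring KO i converts metabolite M_i to
M_{i+1}, giving every ring KO degree 2 and flat within-module
betweenness. Bridge t exchanges two pendant metabolites, each shared
with exactly one anchor KO of one module, so each bridge is a degree-2
cut vertex: all inter-module shortest paths traverse it, and among
degree-2 nodes it has strictly maximal betweenness — hence maximal
load score. Bridge pair-sets contain both pair orientations so the
`complementary` edge mode stays connected.

Counts: each KO gets 1–3 genes with lengths uniform on 300–1500 nt
(read length 100 nt); per-KO community abundance is lognormal
(σ = 0.5); gene-level MG means are abundance × effective length,
scaled to a library depth of 2×10⁵ reads; MT means multiply the same
baseline by each KO's expression multiplier (10× for bridges, 1
otherwise) and are scaled to the MT depth. Counts are negative
binomial with dispersion 0.1 (variance = μ + 0.1 μ²), the standard
overdispersed model for sequencing counts. These sizes keep a full
pipeline run under a second while leaving clear statistical margins;
replicate runs (25 seeds) recover all planted keystones with a
false-positive rate under a few percent.

What passing on synthetic data does **not** show: the generator plants
clean modular topology, a single sample per layer and season-free
structure; real communities have hub metabolites, incomplete KO
annotation (most genes unannotated), cross-mapping structure between
related strains and compositional noise none of which are emulated.
Results on real data therefore depend on the quality of the KO and
reaction-pair annotations far more than these tests can probe.

## Numerical and degenerate-input choices

* Conservation of multi-mapper weighting is exact (Fractions); tests
  tolerate 1e-9 after float conversion.
* Betweenness/load agreement with the brute-force oracle is asserted
  at 1e-9 absolute.
* Quantile thresholds use the "k-th largest value" definition, so with
  distinct scores exactly ceil(q·N) entities pass.
* Empty networks, empty profile sets and empty KO subsets raise
  errors; isolated nodes, empty pair-sets and zero-expression KOs are
  handled with flags, exclusion or zeros as documented above.
* All pipeline outputs are deterministic given the configuration and
  seed; provenance records contain no timestamps so reruns are
  byte-identical.

## Known limitations

* Edge semantics treat metabolite sharing as potential metabolic
  adjacency; no stoichiometry, mass balance or flux capacity is
  modelled.
* Protein abundances (normalised spectral index) are ingested and
  carried through profiles but no spectrum-level inference is
  performed.
* The weighted load score is one reasonable formalisation of
  occurrence weighting among several.
* Percentile selection is threshold-based, not probabilistic: no
  uncertainty is attached to the keystone calls.
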