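# Methods

This note records the models, parameter choices, and numerical conventions
behind `nscnet`, and what the synthetic-data tests do and do not establish
about real data.

## The significance-threshold model of connectivity

A whole-brain synapse table assigns every ordered neuron pair a synapse
count.  Counts of one or two synapses are dominated by reconstruction noise,
so a single **significance threshold** defines which pairs count as
*connections* everywhere in the package.  All thresholds are inclusive
(count ≥ t) and applied uniformly:

| parameter        | default | role                                           |
|------------------|---------|------------------------------------------------|
| `significance`   | 5       | a pair is connected when count ≥ 5             |
| `output_relaxed` | 2       | relaxed re-analysis of NSC synaptic output     |
| `strong`         | 50      | "strong" input connections                     |
| `nt_cutoff`      | 0.62    | transmitter label requires score **> 0.62**    |
| `max_hops`       | 3       | default pathway search depth (edges per path)  |

Source phrasings for the significance cutoff vary between "a threshold of
5" and "more than five"; the inclusive convention (≥ 5) was chosen and is
applied consistently — the filtering-monotonicity tests make the convention
observable.  The transmitter cutoff, by contrast, is documented as
*strictly greater*: a score of exactly 0.62 yields `unknown`, as do exact
ties between acetylcholine, glutamate, and GABA (the only transmitters
considered, because electron-microscopy predictions for others are less
reliable).  The transmitter of a hop is a property of the presynaptic
neuron, not of individual synapses.

Neuron ids are opaque strings throughout: FlyWire root ids exceed 2^53 and
would be corrupted by any float64 round-trip.  Duplicate edge rows are
collapsed by summation (order-invariant), self-loops are dropped with a
warning, and edge endpoints missing from the annotation table are an error
in strict mode or auto-created as `unknown` in lenient mode.

## Input-profile clustering

Each NSC is represented by its vector of synapse counts over the union of
all significant presynaptic partners.  Raw counts are used without row
normalization — cosine similarity is scale-invariant per row, so the
"total inputs" reading and any per-row normalization give identical
similarities.  NSC with no significant input have zero norm and are
reported in an `excluded` list rather than silently dropped (in the real
dataset this is the fate of most ITP-expressing lateral NSC).

Clustering is agglomerative on distance 1 − cosine with **average linkage**
by default (the linkage used by the original analysis pipeline is not
documented; the linkage is exposed as a parameter).  The number of clusters
is a user parameter — the original cut criterion is likewise undocumented.
Determinism: rows are ordered lexicographically by id before linkage, which
fixes merge order for tied distances; clustering is invariant to
simultaneous row/column permutation of the similarity matrix up to label
renaming (tested).

Morphology heterogeneity is assessed by PCA of four per-cell features
(cable length, surface area, cell size, nuclei volume — units are those of
the supplied table; they are z-scored per column before decomposition so
units cancel).  Zero-variance columns are dropped with a warning.

## Pathway semantics

A *k-hop* pathway has k edges (so a 3-hop ORN→NSC path traverses four
neurons: ORN → projection neuron → interneuron → NSC).  Shortest paths are
unweighted in hops — synapse counts annotate hops but do not enter the
length — and **all** simple paths of the minimum length are retained,
because parallel projection-neuron routes are biologically meaningful.
Searches deeper than 6 hops are refused unless explicitly overridden: at
four hops most of the brain is reachable from anywhere, so deep enumeration
is both combinatorially explosive and uninformative.

Disynaptic sensory pathways require both hops to pass the significance
threshold independently.  Interneurons presynaptic to NSC are partitioned
into *sensory interneurons* (those on a significant sensory→interneuron→NSC
path) and *non-sensory interneurons* (no significant sensory input).

ORN behavioral grouping (aversive / food / pheromonal / egg-laying / other)
is supplied as a user table mapping glomerulus names to categories; the
bundled default covers the commonly analyzed glomeruli and is a convenience
starting point, not an authoritative classification.  Unmapped types fall
into `other` with a warning.

## Paracrine network inference

Expression lives in an `AnnData`: raw counts in `X`, cluster labels in
`obs`, and a `norm` layer = log(1 + counts-per-10k) (per-cell total-count
scaling to 10,000 then log1p — the standard single-cell normalization).
Cluster gating predicates (e.g. `Crz > 3 & Dh44 == 0`) evaluate on the
normalized layer, where thresholds like 3 are log-scale-typical
magnitudes.

Scoring, per (cluster, gene):

* `pct_expressing` — fraction of the cluster's cells with a nonzero raw
  count;
* `scaled_expr` — cluster-mean normalized expression, min–max scaled to
  [0, 100] **across the clusters being compared** (the scaling transform
  behind the published scores is delegated to a toolkit and not stated;
  min–max of cluster means is the choice here, and the scaler is pluggable —
  a center-scale alternative mapping 50 + 25·z clipped to [0, 100] is
  provided — so the unit of the 2.5-score filter is explicit);
* `score = scaled_expr × pct_expressing`, on a 0–100 scale.

Presence rules (all inclusive): a neuropeptide is present in a cluster when
pct ≥ 0.50 **and** score ≥ 2.5; a receptor when pct ≥ 0.05.  When a hormone
has two receptors and both are present in a target cluster, only the
higher-scoring one is used; exact ties break to the lexicographically
smaller gene name.  The three insulin-like peptides (Ilp2/Ilp3/Ilp5) share
one receptor and are averaged **per cell** on both layers into a single
pseudo-gene before any pct/score computation — the stricter reading of
"average expression", making the group's pct the fraction of cells whose
mean is positive.

Edge weight = ligand score × receptor score / 100 ∈ [0, 100]; zero-weight
edges are never emitted.  A hormone whose receptors are absent from every
target contributes no edges (in the real transcriptomes this is the case
for CAPA and ITP).  Outputs are *putative* paracrine connectivity: no claim
about in vivo signaling is made.

## Synthetic data

The generators provide ground truth at desk scale; defaults run the full
pipeline in well under a minute on one CPU.

**Connectome** (defaults: 8 subtypes × 8 NSC, input pools of 10 per
subtype, 30 ORN + 6 gustatory + 12 projection + 20 interneurons +
6 descending ≈ 220 neurons, ≈ 700 edges):

* every NSC receives a significant edge from every neuron of its subtype's
  private presynaptic pool, with counts 5 + NB(mean 12, dispersion 2) —
  negative-binomial over-dispersion matches real synapse-count and scRNA
  count distributions;
* `cross_block_noise_rate` r adds Binomial(pool_size, r) extra inputs per
  NSC from uniformly chosen foreign-pool neurons, so r is the expected
  ratio of cross-subtype to within-subtype input connections: r = 0 gives
  perfectly block-structured profiles, r = 1 equal parts signal and noise.
  This puts the rate on a pool-size-independent [0, 1] scale;
* sensory chains (6 olfactory 3-hop, 4 gustatory 2-hop by default) are
  node-disjoint in their non-NSC layers, so the planted chains are exactly
  the shortest sensory→NSC pathways and path recovery can be scored
  set-exactly;
* a few strong (≥ 50) inputs and alternating weak/significant NSC output
  edges are planted so the strong-connection and dual-threshold output
  reports have structure to find.

**Expression** (defaults: 8 clusters × 150 cells, 400 genes): planted
ligand and receptor genes are expressed in 80% of their assigned cluster's
cells at magnitude 1 + NB(mean 20, dispersion 2) and nowhere else;
background (filler) genes are expressed in 2% of cells everywhere at low
magnitude.  Six hormone–receptor pairs from the bundled catalog are planted
in a ring (cluster c0 → c1 → ... ) by default.

Both generators draw from a single seeded `numpy` generator and serialize
the planted partition, pathways, and paracrine edges (plus seed and config)
as JSON alongside the emitted CSV/Matrix-Market files, which round-trip
through the package loaders.

**What passing tests show — and do not.**  Recovery at ARI 1.0 and
precision = recall = 1.0 demonstrates the pipeline is correct under the
generator's assumptions: clean block structure, node-disjoint chains,
planted expression confined to its cluster.  Real connectomes have
hub neurons, heavy-tailed degree distributions, and spatially correlated
reconstruction artifacts; real transcriptomes have ambient RNA, doublets,
and cross-cluster leakage of marker genes.  None of these are emulated, so
synthetic recovery bounds correctness, not real-data performance.

## Numerical choices and degenerate inputs

* Cosine similarity is symmetrized, clipped to [0, 1], and its diagonal set
  to exactly 1 to absorb floating-point jitter; symmetry and diagonal are
  asserted to 1e-12 in tests.
* Min–max scaling of a degenerate range (single cluster, or constant
  means): nonzero constants map to 100, an all-zero gene to 0 — no division
  error.
* `fcluster` on an empty linkage (a single observation) is special-cased to
  one cluster.
* Empty inputs produce empty tables, not errors, except where an empty
  argument is a caller mistake (empty NSC id list, empty cluster).
* The acceptance script derives all simulation seeds from `--seed` modulo
  2^31.

## Known limitations

* `assign_subtypes` relies on user-supplied anchors or size rules; with the
  default synthetic data the subtype names are known from ground truth, so
  anchor quality on real data is untested here.
* The paracrine scaler choice changes absolute scores (and hence how the
  2.5 filter bites); only the min–max default is exercised against planted
  ground truth.
* GraphML export stores node annotations but not per-neuron transmitter
  score maps.
* The bundled hormone–receptor catalog is a starting point (including a
  proposed ITP receptor); analyses of real data should supply a curated
  catalog.
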