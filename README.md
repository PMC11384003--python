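# nscnet

Connectome and transcriptome analysis of the *Drosophila melanogaster*
neurosecretory network.

The adult fly brain contains 80 neurosecretory cells (NSC) — the insect
analog of the hypothalamus — grouped into ten subtypes by soma position
(medial, lateral, subesophageal) and the peptide hormone they release
(insulin-like peptides, DH44, DH31, corazonin, CAPA, Hugin, ...).  `nscnet`
implements the computational side of characterizing this network from a
whole-brain synaptic connectome and single-cell transcriptomes:

* **Thresholded synaptic graphs** — load edge-list/annotation exports (such
  as FlyWire "codex"-style CSV tables), collapse duplicate synapse rows, and
  apply a uniform significance threshold (default ≥ 5 synapses; ≥ 2 for the
  relaxed output analysis; ≥ 50 for "strong" connections).
* **Input-profile clustering** — NSC subtypes are recovered from
  connectivity alone: for NSC input-count vectors *x*, *y* over all
  significant presynaptic partners, compute cosine similarity
  S(x, y) = x·y / (‖x‖‖y‖) and cluster on distance 1 − S with average
  linkage.
* **Pathway tracing** — direct and disynaptic sensory→endocrine pathways,
  and all shortest k-hop simple paths (ties kept) from olfactory receptor
  neurons to NSC, with per-hop synapse counts and fast-transmitter labels
  (acetylcholine / glutamate / GABA, assigned only when the prediction score
  exceeds 0.62).
* **Shared-input and output motifs** — histograms of neurons contacting
  multiple NSC subtypes, strong-connection reports, and NSC synaptic output
  at both thresholds.
* **Paracrine network inference** — from a clustered gene × cell count
  matrix, an expression score per (cluster, gene) is
  `score = scaled_expression × pct_expressing` (scaled to 0–100 across the
  clusters compared); a hormone present in a source cluster
  (pct ≥ 50% and score ≥ 2.5) is connected to every target cluster where a
  matching receptor is present (pct ≥ 5%), with edge weight
  `ligand_score × receptor_score / 100`.
* **Synthetic data with ground truth** — generators for block-structured
  connectomes (planted subtypes, layered sensory chains, over-dispersed
  synapse counts, tunable cross-subtype noise) and clustered expression
  matrices (planted ligand–receptor pairs), so every stage is verifiable
  without downloading the real datasets.

## Worked example

```python
from nscnet import (generate_connectome, build_input_profile,
                    cosine_similarity_matrix, cluster_nsc, evaluate_recovery,
                    khop_shortest_pathways, generate_expression, score_table,
                    build_paracrine_network, load_pair_catalog)

net, truth = generate_connectome(seed=1)
print(f"simulated connectome: {len(net.neurons)} neurons, {len(net.edges)} edges")

profile = build_input_profile(net, sorted(truth.partition))
labels, _ = cluster_nsc(cosine_similarity_matrix(profile), k=8)
ari = evaluate_recovery(labels.to_dict(), truth, "ari")
print(f"input-profile clustering: {labels.nunique()} clusters, "
      f"ARI vs planted = {ari:.2f}")

paths = khop_shortest_pathways(net, net.ids_by_super_class("sensory"),
                               sorted(truth.partition), max_hops=3)
print(f"sensory->NSC shortest pathways: {len(paths)}")
print("example:", " -> ".join(paths[0].nodes), "| hops:", paths[0].hop_counts,
      "| nt:", paths[0].hop_nt)

adata, _ = generate_expression(seed=1)
pairs = load_pair_catalog()
clusters = sorted(map(str, adata.obs["cluster"].unique()))
genes = [g for p in pairs for g in (p.ligand, *p.receptors)
         if g in adata.var_names]
pairs = [p for p in pairs if p.ligand in adata.var_names
         and any(r in adata.var_names for r in p.receptors)]
edges = build_paracrine_network(score_table(adata, genes, clusters),
                                pairs, clusters, clusters)
print(edges.round(1).to_string(index=False))
```

prints

```
simulated connectome: 218 neurons, 672 edges
input-profile clustering: 8 clusters, ARI vs planted = 1.00
sensory->NSC shortest pathways: 10
example: grn_000 -> in_006 -> nsc_00_06 | hops: (39, 17) | nt: ('acetylcholine', 'acetylcholine')
source target ligand receptor  weight
    c0     c1    Crz     CrzR    66.7
    c1     c2   Dh44  Dh44-R1    66.1
    c2     c3   Dh31   Dh31-R    62.9
    c3     c4    ITP   Gyc76C    65.6
    c4     c5   sNPF   sNPF-R    60.8
    c5     c6     Ms     MsR1    56.7
```

The Adjusted Rand Index of 1.0 means the connectivity clustering recovered
the eight planted NSC subtypes exactly; the ten pathways are the planted
sensory chains; and the six weighted edges are exactly the planted
hormone→receptor connections, each with weight = ligand score × receptor
score / 100.

A command-line interface wraps the same stages
(`nscnet simulate | cluster | trace | shared-inputs | strong | outputs |
paracrine | run`); `nscnet run --seed 5 --out out/` performs the full
synthetic end-to-end analysis and writes a JSON manifest with thresholds,
recovery metrics, and output checksums.

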