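"""Synthetic connectomes and expression matrices with known ground truth.

The generators emulate the structural features the analyses rely on,
at desk scale:

* **Connectome** — NSC of one planted subtype draw synaptic input from a
  subtype-private pool of presynaptic partners (block-structured input
  profiles, hence high within-subtype cosine similarity), layered sensory
  chains (ORN -> projection neuron -> interneuron -> NSC, and gustatory ->
  interneuron -> NSC) are wired node-disjointly, synapse counts are
  over-dispersed (negative binomial on top of the significance threshold),
  and cross-subtype noise edges contaminate the blocks at a configurable
  rate.
* **Expression** — planted ligand and receptor genes are expressed in a
  configured fraction of their cluster's cells at a configured magnitude;
  all other (background) genes are sparse everywhere.

Everything is drawn from a single seeded generator, and the ground truth
(planted partition, pathways, and paracrine edges) is returned alongside so
recovery can be scored exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .classification import ADULT_SUBTYPES
from .connectome import (
    Connectome,
    Neuron,
    ThresholdConfig,
    build_connectome,
    write_annotations,
    write_edges,
)
from .errors import ConfigError

logger = logging.getLogger(__name__)

_TRANSMITTERS = ("acetylcholine", "glutamate", "gaba")


# ---------------------------------------------------------------------------
# configs

@dataclass(frozen=True)
class ChainSpec:
    """A planted layered pathway: each chain takes one fresh node per layer
    (node-disjoint across chains) ending at an NSC, with per-hop synapse
    counts drawn uniformly from ``count_range`` (above the significance
    threshold, so every hop is a significant edge)."""

    layers: tuple[str, ...] = ("orn", "pn", "interneuron", "nsc")
    n_chains: int = 6
    count_range: tuple[int, int] = (6, 40)


@dataclass(frozen=True)
class ConnectomeSimConfig:
    n_subtypes: int = 8
    cells_per_subtype: int = 8
    shared_input_pool_size: int = 10
    cross_block_noise_rate: float = 0.0
    n_orn: int = 30
    n_grn: int = 6
    n_pn: int = 12
    n_interneurons: int = 20
    n_descending: int = 6
    planted_chain_specs: tuple[ChainSpec, ...] = (
        ChainSpec(("orn", "pn", "interneuron", "nsc"), n_chains=6),
        ChainSpec(("grn", "interneuron", "nsc"), n_chains=4),
    )
    count_mean: float = 12.0
    count_dispersion: float = 2.0
    n_strong_inputs: int = 3
    n_output_edges: int = 6
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.cross_block_noise_rate <= 1.0):
            raise ConfigError("cross_block_noise_rate must lie in [0, 1]")
        for name in ("n_subtypes", "cells_per_subtype", "shared_input_pool_size"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.n_subtypes > len(ADULT_SUBTYPES):
            raise ConfigError(
                f"n_subtypes must be <= {len(ADULT_SUBTYPES)} "
                "(the adult subtype catalog)"
            )


@dataclass(frozen=True)
class PlantedSignal:
    """One planted paracrine connection: a ligand expressed in the source
    cluster and its receptor in the target cluster."""

    ligand: str
    receptor: str
    source_cluster: str
    target_cluster: str
    ligand_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.ligand_genes:
            object.__setattr__(self, "ligand_genes", (self.ligand,))


#: Default planted hormone-receptor assignments, drawn from the bundled
#: catalog; pair i signals from cluster c{i} to cluster c{i+1}.
DEFAULT_PLANTED: tuple[PlantedSignal, ...] = (
    PlantedSignal("Crz", "CrzR", "c0", "c1"),
    PlantedSignal("Dh44", "Dh44-R1", "c1", "c2"),
    PlantedSignal("Dh31", "Dh31-R", "c2", "c3"),
    PlantedSignal("ITP", "Gyc76C", "c3", "c4"),
    PlantedSignal("sNPF", "sNPF-R", "c4", "c5"),
    PlantedSignal("Ms", "MsR1", "c5", "c6"),
)


@dataclass(frozen=True)
class ExpressionSimConfig:
    n_clusters: int = 8
    cells_per_cluster: int = 150
    n_genes: int = 400
    planted: tuple[PlantedSignal, ...] = DEFAULT_PLANTED
    planted_pct: float = 0.8
    planted_mean: float = 20.0
    background_pct: float = 0.02
    background_mean: float = 1.0
    dispersion: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("planted_pct", "background_pct"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1]")
        clusters = {f"c{i}" for i in range(self.n_clusters)}
        for signal in self.planted:
            if not {signal.source_cluster, signal.target_cluster} <= clusters:
                raise ConfigError(
                    f"planted signal {signal.ligand} references a cluster "
                    f"outside c0..c{self.n_clusters - 1}"
                )


@dataclass
class GroundTruth:
    """Planted structure serialized alongside every generated dataset."""

    partition: dict[str, str] = field(default_factory=dict)
    pathways: list[list[str]] = field(default_factory=list)
    paracrine_edges: list[dict] = field(default_factory=list)
    seed: int = 0
    config: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# connectome generation

def _nbinom(rng: np.random.Generator, mean: float, dispersion: float, size=None):
    """Negative binomial with the (mean, dispersion) parametrization:
    variance = mean + mean^2 / dispersion."""
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def _config_dict(config) -> dict:
    d = dataclasses.asdict(config)
    return json.loads(json.dumps(d, default=str))


def generate_connectome(
    config: ConnectomeSimConfig | None = None,
    seed: int | None = None,
) -> tuple[Connectome, GroundTruth]:
    """Simulate an annotated connectome with planted subtype blocks and
    sensory chains.  Deterministic given (config, seed)."""
    config = config or ConnectomeSimConfig()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    thr = config.thresholds

    neurons: dict[str, Neuron] = {}
    edges: dict[tuple[str, str], int] = {}

    def add_edge(pre: str, post: str, count: int) -> None:
        key = (pre, post)
        edges[key] = edges.get(key, 0) + int(count)

    def nt_scores(preferred_idx: int) -> dict[str, float]:
        preferred = _TRANSMITTERS[preferred_idx % len(_TRANSMITTERS)]
        scores = {
            t: round(float(rng.uniform(0.02, 0.30)), 4) for t in _TRANSMITTERS
        }
        scores[preferred] = round(float(rng.uniform(0.66, 0.95)), 4)
        return scores

    subtype_names = ADULT_SUBTYPES[: config.n_subtypes]
    partition: dict[str, str] = {}
    nsc_by_subtype: dict[str, list[str]] = {}
    for s, subtype in enumerate(subtype_names):
        members = []
        for i in range(config.cells_per_subtype):
            nid = f"nsc_{s:02d}_{i:02d}"
            neurons[nid] = Neuron(id=nid, super_class="endocrine",
                                  cell_type=subtype)
            partition[nid] = subtype
            members.append(nid)
        nsc_by_subtype[subtype] = members

    pools: dict[str, list[str]] = {}
    for s, subtype in enumerate(subtype_names):
        pool = []
        for j in range(config.shared_input_pool_size):
            nid = f"pool_{s:02d}_{j:02d}"
            neurons[nid] = Neuron(id=nid, super_class="central",
                                  nt_scores=nt_scores(s + j))
            pool.append(nid)
        pools[subtype] = pool

    glomeruli = ("V", "DL4", "DL5", "DP1l", "VA6", "DL2d", "VL2a", "VM7d",
                 "VA1d", "DA1", "VL2p", "VC4")
    layer_pool: dict[str, list[str]] = {"nsc": sorted(partition)}
    for i in range(config.n_orn):
        nid = f"orn_{i:03d}"
        neurons[nid] = Neuron(
            id=nid, super_class="sensory", sensory_modality="olfactory",
            cell_type=glomeruli[i % len(glomeruli)],
            nt_scores=nt_scores(0),
        )
        layer_pool.setdefault("orn", []).append(nid)
    for i in range(config.n_grn):
        nid = f"grn_{i:03d}"
        neurons[nid] = Neuron(
            id=nid, super_class="sensory", sensory_modality="gustatory",
            nt_scores=nt_scores(0),
        )
        layer_pool.setdefault("grn", []).append(nid)
    for i in range(config.n_pn):
        nid = f"pn_{i:03d}"
        neurons[nid] = Neuron(id=nid, super_class="central", cell_type="ALPN",
                              nt_scores=nt_scores(i))
        layer_pool.setdefault("pn", []).append(nid)
    for i in range(config.n_interneurons):
        nid = f"in_{i:03d}"
        neurons[nid] = Neuron(id=nid, super_class="central",
                              nt_scores=nt_scores(i))
        layer_pool.setdefault("interneuron", []).append(nid)
    for i in range(config.n_descending):
        nid = f"dn_{i:03d}"
        neurons[nid] = Neuron(id=nid, super_class="descending",
                              nt_scores=nt_scores(i))
        layer_pool.setdefault("descending", []).append(nid)

    # Block wiring: every NSC receives from every pool neuron of its subtype.
    for subtype in subtype_names:
        for nsc in nsc_by_subtype[subtype]:
            for pool_neuron in pools[subtype]:
                count = thr.significance + _nbinom(
                    rng, config.count_mean, config.count_dispersion
                )
                add_edge(pool_neuron, nsc, count)

    # Cross-block noise: each NSC gains Binomial(pool_size, rate) extra
    # inputs from uniformly chosen foreign pool neurons, so the rate is the
    # expected ratio of cross-block to within-block input connections
    # (rate 1 means as many noise partners as signal partners).
    if config.cross_block_noise_rate > 0 and len(subtype_names) > 1:
        for subtype in subtype_names:
            foreign = sorted(
                p for other in subtype_names if other != subtype
                for p in pools[other]
            )
            for nsc in nsc_by_subtype[subtype]:
                n_noise = rng.binomial(
                    config.shared_input_pool_size, config.cross_block_noise_rate
                )
                picks = rng.choice(
                    len(foreign), size=min(n_noise, len(foreign)), replace=False
                )
                for idx in picks:
                    count = thr.significance + _nbinom(
                        rng, config.count_mean, config.count_dispersion
                    )
                    add_edge(foreign[idx], nsc, count)

    # Planted layered chains, node-disjoint in the non-NSC layers.
    used: dict[str, int] = {}
    planted_paths: list[list[str]] = []
    nsc_cursor = 0
    all_nsc = layer_pool["nsc"]
    for spec in config.planted_chain_specs:
        if spec.layers[-1] != "nsc":
            raise ConfigError("planted chains must end at the 'nsc' layer")
        for layer in spec.layers[:-1]:
            if layer not in layer_pool:
                raise ConfigError(f"unknown chain layer {layer!r}")
            needed = used.get(layer, 0) + spec.n_chains
            if needed > len(layer_pool[layer]):
                raise ConfigError(
                    f"chain spec needs {needed} '{layer}' neurons, "
                    f"only {len(layer_pool[layer])} available"
                )
        for _ in range(spec.n_chains):
            nodes = []
            for layer in spec.layers[:-1]:
                idx = used.get(layer, 0)
                nodes.append(layer_pool[layer][idx])
                used[layer] = idx + 1
            nodes.append(all_nsc[nsc_cursor % len(all_nsc)])
            nsc_cursor += 1
            lo, hi = spec.count_range
            for pre, post in zip(nodes, nodes[1:]):
                add_edge(pre, post, int(rng.integers(lo, hi + 1)))
            planted_paths.append(nodes)

    # A few strong (>= strong threshold) pool inputs, for the strong-input
    # report to find.
    for s in range(min(config.n_strong_inputs, config.n_subtypes)):
        subtype = subtype_names[s]
        count = thr.strong + _nbinom(rng, config.count_mean,
                                     config.count_dispersion)
        add_edge(pools[subtype][0], nsc_by_subtype[subtype][0], count)

    # Sparse NSC output: alternating weak (relaxed-threshold) and significant
    # edges onto descending neurons, so output reports differ across
    # thresholds 2 and 5.
    descending = layer_pool.get("descending", [])
    for j in range(config.n_output_edges if descending else 0):
        pre = all_nsc[(7 * j) % len(all_nsc)]
        post = descending[j % len(descending)]
        if j % 2 == 0:
            count = int(rng.integers(thr.output_relaxed, thr.significance))
        else:
            count = thr.significance + _nbinom(
                rng, config.count_mean, config.count_dispersion
            )
        add_edge(pre, post, count)

    edge_df = pd.DataFrame(
        [
            {"pre": pre, "post": post, "count": count}
            for (pre, post), count in sorted(edges.items())
        ]
    )
    connectome = build_connectome(neurons, edge_df, thresholds=thr, strict=True)
    truth = GroundTruth(
        partition=partition,
        pathways=planted_paths,
        seed=seed,
        config=_config_dict(config),
    )
    logger.info(
        "simulated connectome: %d neurons, %d edges, %d subtypes, %d chains",
        len(neurons), len(edge_df), config.n_subtypes, len(planted_paths),
    )
    return connectome, truth


def write_connectome_files(
    connectome: Connectome, truth: GroundTruth, outdir: str | Path
) -> dict[str, Path]:
    """Emit the exact CSV formats the loaders consume, plus ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotations": outdir / "annotations.csv",
        "edges": outdir / "edges.csv",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_annotations(connectome.neurons, paths["annotations"])
    write_edges(connectome.edges, paths["edges"])
    truth.save(paths["ground_truth"])
    return paths


# ---------------------------------------------------------------------------
# expression generation

def generate_expression(
    config: ExpressionSimConfig | None = None,
    seed: int | None = None,
):
    """Simulate a clustered single-cell count matrix with planted
    ligand-receptor signals.  Returns (AnnData with raw X, ``norm`` layer and
    ``obs['cluster']``, GroundTruth).  Deterministic given (config, seed)."""
    import anndata as ad

    from .paracrine import normalize_counts

    config = config or ExpressionSimConfig()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    clusters = [f"c{i}" for i in range(config.n_clusters)]
    planted_genes: list[str] = []
    for signal in config.planted:
        for gene in (*signal.ligand_genes, signal.receptor):
            if gene not in planted_genes:
                planted_genes.append(gene)
    n_filler = max(config.n_genes - len(planted_genes), 0)
    genes = planted_genes + [f"g{i:04d}" for i in range(n_filler)]

    n_cells = config.n_clusters * config.cells_per_cluster
    labels = np.repeat(clusters, config.cells_per_cluster)
    counts = np.zeros((n_cells, len(genes)), dtype=float)

    # Background genes: sparse low-magnitude expression everywhere.
    filler_cols = np.arange(len(planted_genes), len(genes))
    if len(filler_cols):
        mask = rng.random((n_cells, len(filler_cols))) < config.background_pct
        values = 1 + _nbinom(
            rng, config.background_mean, config.dispersion,
            size=(n_cells, len(filler_cols)),
        )
        counts[:, filler_cols] = mask * values

    # Planted genes: expressed only in their assigned cluster, in
    # planted_pct of its cells at planted_mean magnitude.
    gene_idx = {g: i for i, g in enumerate(genes)}
    cluster_rows = {
        c: np.flatnonzero(labels == c) for c in clusters
    }

    def plant(gene: str, cluster: str) -> None:
        rows = cluster_rows[cluster]
        expressed = rng.random(len(rows)) < config.planted_pct
        values = 1 + _nbinom(
            rng, config.planted_mean, config.dispersion, size=len(rows)
        )
        counts[rows, gene_idx[gene]] = expressed * values

    truth_edges = []
    for signal in config.planted:
        for gene in signal.ligand_genes:
            plant(gene, signal.source_cluster)
        plant(signal.receptor, signal.target_cluster)
        truth_edges.append(
            {
                "source": signal.source_cluster,
                "target": signal.target_cluster,
                "ligand": signal.ligand,
                "receptor": signal.receptor,
            }
        )

    obs = pd.DataFrame(
        {"cluster": pd.Categorical(labels)},
        index=[f"cell_{i:05d}" for i in range(n_cells)],
    )
    adata = ad.AnnData(
        X=counts, obs=obs, var=pd.DataFrame(index=genes)
    )
    normalize_counts(adata)
    truth = GroundTruth(
        paracrine_edges=truth_edges, seed=seed, config=_config_dict(config)
    )
    return adata, truth


def write_expression_files(adata, truth: GroundTruth, outdir: str | Path):
    """Write the matrix as Matrix Market triplets with gene/cell sidecars
    and the cluster label table."""
    import scipy.io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / "matrix.mtx",
        "genes": outdir / "genes.csv",
        "cells": outdir / "cells.csv",
        "clusters": outdir / "clusters.csv",
        "ground_truth": outdir / "ground_truth.json",
    }
    import scipy.sparse as sp

    scipy.io.mmwrite(str(paths["matrix"]), sp.csr_matrix(adata.X))
    pd.Series(adata.var_names, name="gene").to_csv(paths["genes"], index=False)
    pd.Series(adata.obs_names, name="cell").to_csv(paths["cells"], index=False)
    pd.DataFrame(
        {"cell": adata.obs_names, "cluster": adata.obs["cluster"].astype(str)}
    ).to_csv(paths["clusters"], index=False)
    truth.save(paths["ground_truth"])
    return paths


def load_expression_files(outdir: str | Path):
    """Round-trip loader for :func:`write_expression_files` output."""
    import anndata as ad
    import scipy.io

    from .paracrine import normalize_counts

    outdir = Path(outdir)
    x = scipy.io.mmread(str(outdir / "matrix.mtx")).toarray()
    genes = pd.read_csv(outdir / "genes.csv")["gene"].astype(str)
    cells = pd.read_csv(outdir / "cells.csv")["cell"].astype(str)
    labels = pd.read_csv(outdir / "clusters.csv").set_index("cell")["cluster"]
    obs = pd.DataFrame(
        {"cluster": pd.Categorical(labels.loc[cells])}, index=list(cells)
    )
    adata = ad.AnnData(X=x, obs=obs, var=pd.DataFrame(index=list(genes)))
    return normalize_counts(adata)


# ---------------------------------------------------------------------------
# recovery metrics

def _set_metrics(predicted: set, truth: set) -> dict[str, float]:
    tp = len(predicted & truth)
    precision = tp / len(predicted) if predicted else 0.0
    recall = tp / len(truth) if truth else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return {"precision": precision, "recall": recall, "f1": f1}


def evaluate_recovery(predicted, ground_truth: GroundTruth, metric: str):
    """Score recovered structure against the planted ground truth.

    metric='ari': ``predicted`` maps NSC id -> cluster label; returns the
    Adjusted Rand Index against the planted partition (id universes must
    match).  metric='path_f1': ``predicted`` is an iterable of node
    sequences; returns {precision, recall, f1} against planted pathways.
    metric='edge_precision_recall': ``predicted`` is a DataFrame or iterable
    of (source, target, ligand) records; same report against planted
    paracrine edges.
    """
    if metric == "ari":
        from sklearn.metrics import adjusted_rand_score

        predicted = dict(predicted)
        if set(predicted) != set(ground_truth.partition):
            raise ValueError(
                "predicted partition covers a different id universe than "
                "the ground truth"
            )
        ids = sorted(predicted)
        return float(
            adjusted_rand_score(
                [ground_truth.partition[i] for i in ids],
                [predicted[i] for i in ids],
            )
        )
    if metric == "path_f1":
        pred = {tuple(p) for p in predicted}
        truth = {tuple(p) for p in ground_truth.pathways}
        return _set_metrics(pred, truth)
    if metric == "edge_precision_recall":
        if isinstance(predicted, pd.DataFrame):
            pred = {
                (r["source"], r["target"], r["ligand"])
                for _, r in predicted.iterrows()
            }
        else:
            pred = {tuple(e)[:3] for e in predicted}
        truth = {
            (e["source"], e["target"], e["ligand"])
            for e in ground_truth.paracrine_edges
        }
        return _set_metrics(pred, truth)
    raise ValueError(f"unknown metric {metric!r}")
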