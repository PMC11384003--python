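"""Pathway tracing and connectivity reports on the thresholded connectome.

Covers direct and disynaptic sensory-to-endocrine pathways, k-hop shortest
pathway enumeration (e.g. the canonical ORN -> projection neuron ->
interneuron -> NSC olfactory route), strong-connection reports, shared-input
motifs across NSC subtypes, transmitter annotation of hops, and NSC
synaptic output.  Every operation sees only edges at or above the relevant
synapse-count threshold.
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .connectome import Connectome, significant_edges

logger = logging.getLogger(__name__)

#: Fast-acting transmitters with reliable electron-microscopy predictions.
FAST_TRANSMITTERS = ("acetylcholine", "gaba", "glutamate")

#: Path searches deeper than this are refused unless explicitly overridden:
#: at 4+ hops most of the brain is reachable and enumeration explodes.
MAX_HOPS_GUARD = 6


@dataclass(frozen=True)
class Pathway:
    """A simple directed path with per-hop synapse counts and annotations.

    ``nodes`` runs source..target; ``hop_counts`` and ``hop_nt`` have one
    entry per consecutive node pair; ``layers`` gives one role label per node
    (taken from the annotations, e.g. sensory/central/endocrine).
    """

    nodes: tuple[str, ...]
    hop_counts: tuple[int, ...]
    hop_nt: tuple[str, ...] = ()
    layers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.hop_counts) != len(self.nodes) - 1:
            raise ValueError("hop_counts must have len(nodes) - 1 entries")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("pathway must be a simple path (no repeated node)")

    @property
    def n_hops(self) -> int:
        return len(self.hop_counts)

    def to_dict(self) -> dict:
        return {
            "nodes": list(self.nodes),
            "hop_counts": list(self.hop_counts),
            "hop_nt": list(self.hop_nt),
            "layers": list(self.layers),
        }


@dataclass(frozen=True)
class SharedInputSummary:
    """Neurons presynaptic to NSC, by how many subtypes they contact.

    ``targets_by_neuron`` maps each presynaptic neuron to the set of NSC
    subtype names it significantly contacts; ``histogram`` counts neurons per
    number-of-subtypes.  Only neurons contacting >= 2 subtypes appear in the
    multi-target report.
    """

    targets_by_neuron: Mapping[str, frozenset[str]]
    histogram: Mapping[int, int]

    @property
    def multi_target_neurons(self) -> dict[str, frozenset[str]]:
        return {
            nid: subs
            for nid, subs in self.targets_by_neuron.items()
            if len(subs) >= 2
        }

    @property
    def multi_target_total(self) -> int:
        return multi_target_total(self.histogram)


def multi_target_total(histogram: Mapping[int, int]) -> int:
    """Total neurons contacting two or more NSC subtypes, from a histogram
    of (number of subtypes contacted -> neuron count)."""
    return sum(count for n_subtypes, count in histogram.items() if n_subtypes >= 2)


@dataclass(frozen=True)
class StrongConnectionReport:
    """Per-subtype strong input connections (count >= strong threshold)."""

    connections: pd.DataFrame  # columns: subtype, pre, post, count
    summary: pd.DataFrame = field(default_factory=pd.DataFrame)
    # summary columns: subtype, n_connections, total_synapses


def nt_annotate(
    nt_scores: Mapping[str, float],
    cutoff: float = 0.62,
    transmitters: Iterable[str] = FAST_TRANSMITTERS,
) -> str:
    """Transmitter label of a presynaptic neuron from its prediction scores.

    Only fast-acting transmitters are considered.  The arg-max score wins if
    it is *strictly* greater than the cutoff; a score exactly at the cutoff,
    an exact tie between transmitters, or no scores at all gives 'unknown'.
    """
    candidates = {t: nt_scores[t] for t in transmitters if t in nt_scores}
    if not candidates:
        return "unknown"
    best = max(candidates.values())
    if best <= cutoff:
        return "unknown"
    winners = sorted(t for t, s in candidates.items() if s == best)
    return winners[0] if len(winners) == 1 else "unknown"


def _hop_labels(connectome: Connectome, nodes: tuple[str, ...]) -> tuple[str, ...]:
    cutoff = connectome.thresholds.nt_cutoff
    return tuple(
        nt_annotate(connectome.neuron(pre).nt_scores, cutoff) for pre in nodes[:-1]
    )


def _layers(connectome: Connectome, nodes: tuple[str, ...]) -> tuple[str, ...]:
    return tuple(connectome.super_class(n) for n in nodes)


def direct_sensory_inputs(
    connectome: Connectome,
    nsc_ids: Iterable[str],
    threshold: int | None = None,
) -> pd.DataFrame:
    """Sensory neurons with a significant edge onto any NSC.

    Returns one row per (sensory neuron, NSC) connection with the sensory
    modality annotation.
    """
    nsc = {str(n) for n in nsc_ids}
    sig = significant_edges(connectome, threshold)
    rows = sig.loc[sig["post"].isin(nsc)]
    rows = rows.loc[
        [connectome.super_class(p) == "sensory" for p in rows["pre"]]
    ]
    out = pd.DataFrame(
        {
            "sensory_id": rows["pre"].to_numpy(),
            "modality": [connectome.neuron(p).sensory_modality for p in rows["pre"]],
            "nsc_id": rows["post"].to_numpy(),
            "count": rows["count"].to_numpy(),
        }
    )
    return out.sort_values(["sensory_id", "nsc_id"]).reset_index(drop=True)


def disynaptic_sensory_pathways(
    connectome: Connectome,
    nsc_ids: Iterable[str],
    threshold: int | None = None,
) -> tuple[list[Pathway], set[str], set[str]]:
    """All 2-hop sensory -> interneuron -> NSC pathways.

    Both hops must individually pass the significance threshold.  Returns
    (pathways, sensory interneurons, non-sensory interneurons): an
    interneuron presynaptic to NSC is *sensory* if it sits on such a 2-hop
    path and *non-sensory* if it receives no significant sensory input.
    Sensory neurons and NSC themselves never count as interneurons.
    """
    nsc = {str(n) for n in nsc_ids}
    sig = significant_edges(connectome, threshold)
    sensory = {
        nid for nid in connectome.neurons
        if connectome.super_class(nid) == "sensory"
    }
    onto_nsc = sig.loc[sig["post"].isin(nsc)]
    interneurons = set(onto_nsc["pre"]) - sensory - nsc
    from_sensory = sig.loc[sig["pre"].isin(sensory)]
    sensory_inputs = dict(
        from_sensory.groupby("post").apply(
            lambda g: list(zip(g["pre"], g["count"])), include_groups=False
        )
    )

    pathways: list[Pathway] = []
    sensory_interneurons: set[str] = set()
    for _, edge in onto_nsc.iterrows():
        inter, target, second = edge["pre"], edge["post"], int(edge["count"])
        if inter not in interneurons:
            continue
        for source, first in sensory_inputs.get(inter, []):
            if source == target:
                continue
            nodes = (source, inter, target)
            pathways.append(
                Pathway(
                    nodes=nodes,
                    hop_counts=(int(first), second),
                    hop_nt=_hop_labels(connectome, nodes),
                    layers=_layers(connectome, nodes),
                )
            )
            sensory_interneurons.add(inter)
    non_sensory = {i for i in interneurons if i not in sensory_inputs}
    pathways.sort(key=lambda p: p.nodes)
    return pathways, sensory_interneurons, non_sensory


def khop_shortest_pathways(
    connectome: Connectome,
    sources: Iterable[str],
    targets: Iterable[str],
    max_hops: int | None = None,
    threshold: int | None = None,
    allow_deep: bool = False,
) -> list[Pathway]:
    """All shortest simple pathways from each source to each target.

    For each (source, target) pair with a path of <= max_hops significant
    edges, every simple path of the *minimum* hop length is returned — ties
    are kept, not broken, because parallel routes (e.g. several projection
    neurons relaying one glomerulus) are biologically meaningful.  Hops are
    unweighted: "shortest" counts edges, not synapses.
    """
    if max_hops is None:
        max_hops = connectome.thresholds.max_hops
    if max_hops < 1:
        raise ValueError("max_hops must be >= 1")
    if max_hops > MAX_HOPS_GUARD and not allow_deep:
        raise ValueError(
            f"max_hops={max_hops} exceeds the combinatorial guard "
            f"({MAX_HOPS_GUARD}); pass allow_deep=True to override"
        )
    graph = connectome.graph(threshold)
    weights = {(u, v): d["count"] for u, v, d in graph.edges(data=True)}
    sources = sorted({str(s) for s in sources})
    targets = sorted({str(t) for t in targets})

    pathways: list[Pathway] = []
    for source in sources:
        if source not in graph:
            continue
        lengths = nx.single_source_shortest_path_length(
            graph, source, cutoff=max_hops
        )
        for target in targets:
            if target == source or target not in lengths:
                continue
            min_len = lengths[target]
            for nodes in nx.all_simple_paths(graph, source, target, cutoff=min_len):
                if len(nodes) - 1 != min_len:
                    continue
                nodes = tuple(nodes)
                pathways.append(
                    Pathway(
                        nodes=nodes,
                        hop_counts=tuple(
                            weights[(u, v)] for u, v in zip(nodes, nodes[1:])
                        ),
                        hop_nt=_hop_labels(connectome, nodes),
                        layers=_layers(connectome, nodes),
                    )
                )
    pathways.sort(key=lambda p: p.nodes)
    return pathways


def group_orns(
    connectome: Connectome,
    pathways: Iterable[Pathway],
    category_map: Mapping[str, str],
) -> pd.DataFrame:
    """Group pathway source ORNs by behavioral category.

    ``category_map`` maps ORN cell types (glomeruli) to behavioral
    categories (aversive, food, pheromonal, egg-laying, other); unmapped
    types fall into 'other' with a warning.  Synapse totals sum each unique
    first hop (ORN -> next layer edge) once.
    """
    first_hops: dict[tuple[str, str], int] = {}
    for path in pathways:
        first_hops[(path.nodes[0], path.nodes[1])] = path.hop_counts[0]
    records = []
    unmapped: set[str] = set()
    for (orn, _nxt), count in first_hops.items():
        cell_type = connectome.neuron(orn).cell_type
        category = category_map.get(cell_type)
        if category is None:
            unmapped.add(cell_type)
            category = "other"
        records.append({"orn": orn, "category": category, "count": count})
    if unmapped:
        logger.warning("ORN types without behavioral category -> 'other': %s",
                       sorted(unmapped))
    if not records:
        return pd.DataFrame({"category": [], "n_orns": [], "n_synapses": []})
    table = pd.DataFrame(records)
    grouped = table.groupby("category").agg(
        n_orns=("orn", "nunique"), n_synapses=("count", "sum")
    )
    return grouped.reset_index().sort_values("category").reset_index(drop=True)


def strong_connections(
    connectome: Connectome,
    nsc_labels: Mapping[str, str],
    threshold: int | None = None,
) -> StrongConnectionReport:
    """Input connections at/above the strong threshold, per NSC subtype.

    ``nsc_labels`` maps NSC id -> subtype name.  The summary reports, per
    subtype, the number of strong connections and the total synapses they
    comprise.
    """
    if threshold is None:
        threshold = connectome.thresholds.strong
    sig = significant_edges(connectome, threshold)
    rows = sig.loc[sig["post"].isin(set(nsc_labels))]
    table = pd.DataFrame(
        {
            "subtype": [nsc_labels[p] for p in rows["post"]],
            "pre": rows["pre"].to_numpy(),
            "post": rows["post"].to_numpy(),
            "count": rows["count"].to_numpy(),
        }
    ).sort_values(["subtype", "pre", "post"]).reset_index(drop=True)
    if len(table):
        summary = (
            table.groupby("subtype")
            .agg(n_connections=("count", "size"), total_synapses=("count", "sum"))
            .reset_index()
        )
    else:
        summary = pd.DataFrame(
            {"subtype": [], "n_connections": [], "total_synapses": []}
        )
    return StrongConnectionReport(connections=table, summary=summary)


def shared_input_neurons(
    connectome: Connectome,
    nsc_labels: Mapping[str, str],
    threshold: int | None = None,
) -> SharedInputSummary:
    """Which presynaptic neurons contact how many NSC subtypes.

    Every NSC id must carry a subtype label.  NSC themselves are not counted
    as presynaptic partners of other NSC here; the question is which
    *external* neurons coordinate multiple hormonal systems.
    """
    if not nsc_labels:
        raise ValueError("nsc_labels must be nonempty")
    if any(not v for v in nsc_labels.values()):
        raise ValueError("every NSC id must carry a subtype label")
    sig = significant_edges(connectome, threshold)
    rows = sig.loc[
        sig["post"].isin(set(nsc_labels)) & ~sig["pre"].isin(set(nsc_labels))
    ]
    targets: dict[str, set[str]] = defaultdict(set)
    for _, edge in rows.iterrows():
        targets[edge["pre"]].add(nsc_labels[edge["post"]])
    frozen = {nid: frozenset(subs) for nid, subs in targets.items()}
    histogram: dict[int, int] = defaultdict(int)
    for subs in frozen.values():
        histogram[len(subs)] += 1
    return SharedInputSummary(targets_by_neuron=frozen, histogram=dict(histogram))


def nsc_output_partners(
    connectome: Connectome,
    nsc_ids: Iterable[str],
    threshold: int | None = None,
) -> pd.DataFrame:
    """Significant postsynaptic partners of NSC, with partner super class.

    Re-runnable at the relaxed output threshold (default 2) to probe weak
    output that the standard threshold hides.
    """
    if threshold is None:
        threshold = connectome.thresholds.significance
    nsc = {str(n) for n in nsc_ids}
    sig = significant_edges(connectome, threshold)
    rows = sig.loc[sig["pre"].isin(nsc)]
    out = pd.DataFrame(
        {
            "nsc_id": rows["pre"].to_numpy(),
            "partner_id": rows["post"].to_numpy(),
            "partner_super_class": [
                connectome.super_class(p) for p in rows["post"]
            ],
            "count": rows["count"].to_numpy(),
        }
    )
    return out.sort_values(["nsc_id", "partner_id"]).reset_index(drop=True)


def write_pathways_jsonl(pathways: Iterable[Pathway], path: str | Path) -> None:
    with open(path, "w") as handle:
        for p in pathways:
            handle.write(json.dumps(p.to_dict()) + "\n")


def pathways_to_hop_table(pathways: Iterable[Pathway]) -> pd.DataFrame:
    """Flatten pathways to one row per hop (pathway index, hop index, pre,
    post, count, transmitter)."""
    records = []
    for idx, p in enumerate(pathways):
        nts = p.hop_nt or ("unknown",) * p.n_hops
        for hop, (pre, post) in enumerate(zip(p.nodes, p.nodes[1:])):
            records.append(
                {
                    "pathway": idx,
                    "hop": hop,
                    "pre": pre,
                    "post": post,
                    "count": p.hop_counts[hop],
                    "transmitter": nts[hop],
                }
            )
    return pd.DataFrame(
        records, columns=["pathway", "hop", "pre", "post", "count", "transmitter"]
    )
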