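"""Annotated synaptic connectome: loading, validation, and thresholding.

The connectome is a directed weighted multigraph of annotated neurons.  A
single synapse-count threshold ("significance threshold", default 5) defines
which edges count as *connections* in every downstream analysis; a relaxed
threshold (default 2) is used for output analyses and a "strong" threshold
(default 50) singles out the heaviest inputs.

Neuron ids are kept as opaque strings throughout, even when they look
numeric: FlyWire root ids exceed the exactly-representable float64 integer
range, so round-tripping them through numeric dtypes would corrupt them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .errors import DanglingEndpointError, FormatError, ValidationError

logger = logging.getLogger(__name__)

SUPER_CLASSES = frozenset(
    {
        "sensory",
        "central",
        "ascending",
        "descending",
        "endocrine",
        "visual_projection",
        "visual_centrifugal",
        "optic",
        "motor",
        "glia",
        "unknown",
    }
)

SIDES = frozenset({"left", "right", "center", "na"})

SENSORY_MODALITIES = frozenset(
    {"gustatory", "mechanosensory", "olfactory", "pharyngeal", "unknown", "na"}
)

#: Annotation columns holding neurotransmitter prediction scores are named
#: ``nt_<transmitter>``, e.g. ``nt_acetylcholine``.
NT_PREFIX = "nt_"


@dataclass(frozen=True)
class Neuron:
    """One annotated neuron.

    ``nt_scores`` maps transmitter name to a predicted probability in [0, 1];
    missing transmitters are simply absent from the map.
    """

    id: str
    super_class: str = "unknown"
    cell_type: str = ""
    side: str = "na"
    sensory_modality: str = "na"
    nt_scores: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, score in self.nt_scores.items():
            if not (0.0 <= float(score) <= 1.0):
                raise ValidationError(
                    f"neuron {self.id}: transmitter score {name}={score} "
                    "outside [0, 1]"
                )


@dataclass(frozen=True)
class ThresholdConfig:
    """Synapse-count and transmitter-probability cutoffs.

    significance:   minimum synapse count of a significant connection.
    output_relaxed: relaxed threshold for the NSC output analysis.
    strong:         minimum count of a "strong" connection.
    nt_cutoff:      transmitter label requires a score strictly above this.
    max_hops:       default pathway search depth (edges per path).
    """

    significance: int = 5
    output_relaxed: int = 2
    strong: int = 50
    nt_cutoff: float = 0.62
    max_hops: int = 3

    def __post_init__(self) -> None:
        if not (1 <= self.output_relaxed <= self.significance <= self.strong):
            raise ValidationError(
                "thresholds must satisfy 1 <= output_relaxed <= significance "
                f"<= strong, got {self}"
            )
        if not (0.0 < self.nt_cutoff < 1.0):
            raise ValidationError(f"nt_cutoff must lie in (0, 1), got {self.nt_cutoff}")
        if self.max_hops < 1:
            raise ValidationError("max_hops must be >= 1")


@dataclass(frozen=True)
class Connectome:
    """Immutable annotated connectome.

    ``edges`` is a DataFrame with string columns ``pre``/``post`` and integer
    ``count``, one row per collapsed (pre, post) pair.
    """

    neurons: Mapping[str, Neuron]
    edges: pd.DataFrame
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)

    def neuron(self, neuron_id: str) -> Neuron:
        return self.neurons[neuron_id]

    def super_class(self, neuron_id: str) -> str:
        return self.neurons[neuron_id].super_class

    def ids_by_super_class(self, super_class: str) -> list[str]:
        return sorted(
            nid for nid, n in self.neurons.items() if n.super_class == super_class
        )

    def graph(self, threshold: int | None = None) -> nx.DiGraph:
        """Directed graph of edges at/above ``threshold`` (default: significance)."""
        sig = significant_edges(self, threshold)
        g = nx.DiGraph()
        g.add_nodes_from(self.neurons)
        g.add_weighted_edges_from(
            zip(sig["pre"], sig["post"], sig["count"]), weight="count"
        )
        return g


def _normalize_annotation_row(
    row: pd.Series, nt_cols: list[str], strict: bool
) -> Neuron:
    raw_super = str(row["super_class"]).strip()
    super_class = raw_super.lower()
    cell_type = str(row.get("cell_type", "") or "").strip()
    if super_class not in SUPER_CLASSES:
        if strict:
            raise ValidationError(f"unrecognized super_class {raw_super!r}")
        logger.warning(
            "neuron %s: unrecognized super_class %r mapped to 'unknown'",
            row["id"],
            raw_super,
        )
        if not cell_type:
            cell_type = raw_super  # keep the verbatim label recoverable
        super_class = "unknown"

    side = str(row.get("side", "na") or "na").strip().lower() or "na"
    if side not in SIDES:
        side = "na"

    modality = str(row.get("sensory_modality", "na") or "na").strip().lower() or "na"
    if modality not in SENSORY_MODALITIES:
        modality = "unknown" if super_class == "sensory" else "na"
    if super_class != "sensory" and modality != "na":
        if strict:
            raise ValidationError(
                f"neuron {row['id']}: sensory_modality {modality!r} on "
                f"non-sensory super_class {super_class!r}"
            )
        logger.warning(
            "neuron %s: dropping sensory_modality %r (super_class %s)",
            row["id"],
            modality,
            super_class,
        )
        modality = "na"

    nt_scores: dict[str, float] = {}
    for col in nt_cols:
        value = row[col]
        if pd.isna(value) or value == "":
            continue
        nt_scores[col[len(NT_PREFIX) :]] = float(value)

    return Neuron(
        id=str(row["id"]),
        super_class=super_class,
        cell_type=cell_type,
        side=side,
        sensory_modality=modality,
        nt_scores=nt_scores,
    )


def load_annotations(path: str | Path, strict: bool = False) -> dict[str, Neuron]:
    """Read a neuron annotation table (CSV with header).

    Required columns: ``id``, ``super_class``.  Optional: ``cell_type``,
    ``side``, ``sensory_modality``, and any number of ``nt_<name>`` score
    columns.  Unrecognized super-class labels fold to ``unknown`` with a
    warning (error in strict mode); duplicate ids are always an error.
    """
    table = pd.read_csv(path, dtype=str, keep_default_na=False)
    for required in ("id", "super_class"):
        if required not in table.columns:
            raise FormatError(f"annotation table missing required column {required!r}")
    if table["id"].duplicated().any():
        dupes = table.loc[table["id"].duplicated(), "id"].tolist()
        raise ValidationError(f"duplicate neuron ids: {dupes}")

    nt_cols = [c for c in table.columns if c.startswith(NT_PREFIX)]
    neurons: dict[str, Neuron] = {}
    for _, row in table.iterrows():
        neuron = _normalize_annotation_row(row, nt_cols, strict)
        neurons[neuron.id] = neuron
    logger.info("loaded %d neurons from %s", len(neurons), path)
    return neurons


def load_edges(path: str | Path) -> pd.DataFrame:
    """Read a synapse edge table (CSV with columns pre, post, count).

    Duplicate (pre, post) rows are collapsed by summing their counts, so the
    result is independent of row order.  Counts must be positive integers.
    """
    table = pd.read_csv(path, dtype={"pre": str, "post": str})
    for required in ("pre", "post", "count"):
        if required not in table.columns:
            raise FormatError(f"edge table missing required column {required!r}")
    if len(table) == 0:
        return pd.DataFrame({"pre": [], "post": [], "count": []}).astype(
            {"pre": str, "post": str, "count": int}
        )
    counts = pd.to_numeric(table["count"], errors="coerce")
    if counts.isna().any() or (counts != counts.astype(int)).any():
        raise ValidationError("edge counts must be integers")
    if (counts <= 0).any():
        raise ValidationError("edge counts must be positive")
    table = table.assign(count=counts.astype(int))
    collapsed = (
        table.groupby(["pre", "post"], as_index=False, sort=True)["count"]
        .sum()
        .astype({"count": int})
    )
    logger.info(
        "loaded %d edges (%d raw rows) from %s", len(collapsed), len(table), path
    )
    return collapsed


def build_connectome(
    neurons: Mapping[str, Neuron],
    edges: pd.DataFrame,
    thresholds: ThresholdConfig | None = None,
    strict: bool = True,
) -> Connectome:
    """Assemble a validated Connectome.

    In strict mode an edge endpoint missing from ``neurons`` is an error; in
    lenient mode the endpoint is auto-created with super_class ``unknown``.
    Self-loops carry no meaning at this resolution and are dropped with a
    warning.
    """
    neurons = dict(neurons)
    edges = edges.copy()

    loops = edges["pre"] == edges["post"]
    if loops.any():
        logger.warning("dropping %d self-loop edge(s)", int(loops.sum()))
        edges = edges.loc[~loops]

    endpoints = set(edges["pre"]).union(edges["post"])
    dangling = sorted(endpoints - set(neurons))
    if dangling:
        if strict:
            raise DanglingEndpointError(
                f"{len(dangling)} edge endpoint(s) missing from annotations, "
                f"e.g. {dangling[:5]}"
            )
        logger.warning(
            "auto-creating %d unannotated endpoint(s) as super_class=unknown",
            len(dangling),
        )
        for nid in dangling:
            neurons[nid] = Neuron(id=nid, super_class="unknown")

    edges = edges.sort_values(["pre", "post"], kind="mergesort").reset_index(drop=True)
    connectome = Connectome(
        neurons=neurons, edges=edges, thresholds=thresholds or ThresholdConfig()
    )
    logger.info(
        "built connectome: %d neurons, %d edges", len(neurons), len(edges)
    )
    return connectome


def significant_edges(
    connectome: Connectome, threshold: int | None = None
) -> pd.DataFrame:
    """Edges with count >= threshold (inclusive; default: significance).

    The inclusive convention (count >= t) is applied uniformly everywhere.
    """
    if threshold is None:
        threshold = connectome.thresholds.significance
    if threshold < 1:
        raise ValidationError(f"threshold must be >= 1, got {threshold}")
    return connectome.edges.loc[connectome.edges["count"] >= threshold].reset_index(
        drop=True
    )


def super_class_summary(
    connectome: Connectome,
    target_set: Iterable[str],
    direction: str = "in",
    threshold: int | None = None,
) -> pd.DataFrame:
    """Partner composition of a target neuron set, grouped by super class.

    For ``direction='in'`` the partners are presynaptic to the targets; for
    ``'out'`` postsynaptic.  A partner contacting several targets is counted
    once in ``n_neurons`` but contributes all its synapses to ``n_synapses``.
    Proportions are synapse-weighted and sum to 1 whenever any partner exists.
    """
    targets = {str(t) for t in target_set}
    if not targets:
        raise ValueError("target_set must be nonempty")
    if direction not in ("in", "out"):
        raise ValueError(f"direction must be 'in' or 'out', got {direction!r}")
    sig = significant_edges(connectome, threshold)
    if direction == "in":
        rows = sig.loc[sig["post"].isin(targets)]
        partner_col = "pre"
    else:
        rows = sig.loc[sig["pre"].isin(targets)]
        partner_col = "post"
    if len(rows) == 0:
        return pd.DataFrame(
            {"super_class": [], "n_neurons": [], "n_synapses": [], "proportion": []}
        )
    rows = rows.assign(
        super_class=[connectome.super_class(p) for p in rows[partner_col]]
    )
    grouped = rows.groupby("super_class").agg(
        n_neurons=(partner_col, "nunique"), n_synapses=("count", "sum")
    )
    grouped["proportion"] = grouped["n_synapses"] / grouped["n_synapses"].sum()
    return grouped.reset_index().sort_values("super_class").reset_index(drop=True)


def write_annotations(neurons: Mapping[str, Neuron], path: str | Path) -> None:
    """Write neurons back to the CSV layout ``load_annotations`` reads."""
    nt_names = sorted({name for n in neurons.values() for name in n.nt_scores})
    records = []
    for nid in sorted(neurons):
        n = neurons[nid]
        rec = {
            "id": n.id,
            "super_class": n.super_class,
            "cell_type": n.cell_type,
            "side": n.side,
            "sensory_modality": n.sensory_modality,
        }
        for name in nt_names:
            rec[NT_PREFIX + name] = n.nt_scores.get(name, "")
        records.append(rec)
    columns = ["id", "super_class", "cell_type", "side", "sensory_modality"] + [
        NT_PREFIX + n for n in nt_names
    ]
    pd.DataFrame(records, columns=columns).to_csv(path, index=False)


def write_edges(edges: pd.DataFrame, path: str | Path) -> None:
    edges[["pre", "post", "count"]].to_csv(path, index=False)


def export_graphml(
    connectome: Connectome, path: str | Path, threshold: int | None = None
) -> None:
    """Export the thresholded graph as GraphML with node annotations."""
    g = connectome.graph(threshold)
    for nid in g.nodes:
        n = connectome.neuron(nid)
        g.nodes[nid]["super_class"] = n.super_class
        g.nodes[nid]["cell_type"] = n.cell_type
        g.nodes[nid]["side"] = n.side
    nx.write_graphml(g, str(path))


def write_manifest(connectome: Connectome, path: str | Path, **extra) -> None:
    """JSON run-manifest recording thresholds and basic counts."""
    manifest = {
        "n_neurons": len(connectome.neurons),
        "n_edges": int(len(connectome.edges)),
        "n_significant_edges": int(len(significant_edges(connectome))),
        "thresholds": {
            "significance": connectome.thresholds.significance,
            "output_relaxed": connectome.thresholds.output_relaxed,
            "strong": connectome.thresholds.strong,
            "nt_cutoff": connectome.thresholds.nt_cutoff,
            "max_hops": connectome.thresholds.max_hops,
        },
    }
    manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
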