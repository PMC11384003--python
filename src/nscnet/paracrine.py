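"""Paracrine ligand-receptor network inference from single-cell expression.

NSC signal mostly hormonally, not synaptically, so their interconnectivity
is inferred from transcriptomes: a cluster that expresses a neuropeptide in
enough of its cells can signal to a cluster expressing the matching
receptor.  The strength of a putative connection is the product of the two
expression scores, where an expression score is the scaled cluster-level
expression of a gene multiplied by the fraction of cluster cells expressing
it.

Filtering rules:
  * a ligand is *present* in a cluster when >= 50% of its cells express it
    AND its expression score is >= 2.5 (both inclusive);
  * a receptor is present at >= 5% of cells expressing (inclusive);
  * when a hormone acts through two receptors and both are present in a
    target cluster, only the higher-scoring one is kept (exact ties break
    to the lexicographically smaller gene name);
  * the three insulin-like peptides of m-NSC^DILP (Ilp2/Ilp3/Ilp5) share one
    receptor and are averaged per cell into a single pseudo-gene before any
    scoring.

Expression lives in an :class:`anndata.AnnData`: ``X`` holds raw counts,
``layers['norm']`` the normalized values (counts-per-10k, log1p), and
``obs[cluster_key]`` the cluster labels.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

LIGAND_PCT_MIN = 0.50
LIGAND_SCORE_MIN = 2.5
RECEPTOR_PCT_MIN = 0.05

DILP_GENES = ("Ilp2", "Ilp3", "Ilp5")
DILP_NAME = "DILP"


# ---------------------------------------------------------------------------
# expression container helpers

def _dense(values) -> np.ndarray:
    return values.toarray() if sp.issparse(values) else np.asarray(values)


def normalize_counts(adata: ad.AnnData, target_sum: float = 1e4) -> ad.AnnData:
    """Add a ``norm`` layer: per-cell total-count scaling to ``target_sum``
    followed by log(1 + x).  Cells with zero total stay all-zero."""
    counts = _dense(adata.X).astype(float)
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    adata.layers["norm"] = np.log1p(counts / totals * target_sum)
    return adata


def _gene_vector(adata: ad.AnnData, gene: str, layer: str | None) -> np.ndarray:
    if gene not in adata.var_names:
        raise KeyError(f"gene {gene!r} not found in expression matrix")
    idx = adata.var_names.get_loc(gene)
    values = adata.layers[layer] if layer else adata.X
    return _dense(values[:, idx]).ravel()


def _cluster_mask(adata: ad.AnnData, cluster: str, cluster_key: str) -> np.ndarray:
    mask = (adata.obs[cluster_key] == cluster).to_numpy()
    if not mask.any():
        raise ValueError(f"cluster {cluster!r} is empty or unknown")
    return mask


# ---------------------------------------------------------------------------
# gating

_PREDICATE = re.compile(r"^\s*([\w.:()-]+)\s*(>|==)\s*([0-9.]+)\s*$")


@dataclass(frozen=True)
class GatingCriterion:
    """Conjunction of per-gene predicates, e.g. ``Crz > 3 & Dh44 == 0``.

    Predicates evaluate on the normalized layer; ``>`` is strict and ``==``
    exact (used in practice only as ``== 0``, i.e. not expressed).
    """

    predicates: tuple[tuple[str, str, float], ...]

    @classmethod
    def parse(cls, text: str) -> "GatingCriterion":
        """Parse the textual form, e.g. ``"Crz > 3 & sNPF > 3 & Dh44 == 0"``.
        An empty string yields the empty (always-true) criterion."""
        text = text.strip()
        if not text:
            return cls(predicates=())
        predicates = []
        for clause in text.split("&"):
            match = _PREDICATE.match(clause)
            if not match:
                raise FormatError(f"cannot parse gating clause {clause!r}")
            gene, op, value = match.groups()
            predicates.append((gene, op, float(value)))
        return cls(predicates=tuple(predicates))


def gate_cells(
    adata: ad.AnnData,
    criterion: GatingCriterion | str,
    layer: str = "norm",
) -> list[str]:
    """Cell ids satisfying every predicate of the criterion."""
    if isinstance(criterion, str):
        criterion = GatingCriterion.parse(criterion)
    mask = np.ones(adata.n_obs, dtype=bool)
    for gene, op, value in criterion.predicates:
        if gene not in adata.var_names:
            raise KeyError(f"gating criterion references unknown gene {gene!r}")
        vec = _gene_vector(adata, gene, layer)
        mask &= (vec > value) if op == ">" else (vec == value)
    return list(adata.obs_names[mask])


# ---------------------------------------------------------------------------
# scoring

def percent_expressing(
    adata: ad.AnnData,
    cluster: str,
    gene: str,
    cluster_key: str = "cluster",
) -> float:
    """Fraction of the cluster's cells with a nonzero raw count for gene."""
    mask = _cluster_mask(adata, cluster, cluster_key)
    vec = _gene_vector(adata, gene, None)[mask]
    return float((vec > 0).mean())


def minmax_scale_0_100(means: pd.Series) -> pd.Series:
    """Min-max scale cluster means to [0, 100]; degenerate ranges map a
    nonzero constant to 100 and an all-zero gene to 0."""
    lo, hi = means.min(), means.max()
    if hi == lo:
        return pd.Series(np.where(means > 0, 100.0, 0.0), index=means.index)
    return (means - lo) / (hi - lo) * 100.0


def zscore_scale_0_100(means: pd.Series) -> pd.Series:
    """Alternative scaler: z-score the cluster means, then map 50 + 25z
    clipped to [0, 100] (roughly +/-2 SD spans the scale)."""
    sd = means.std(ddof=0)
    if sd == 0:
        return pd.Series(np.where(means > 0, 100.0, 0.0), index=means.index)
    z = (means - means.mean()) / sd
    return (50.0 + 25.0 * z).clip(0.0, 100.0)


def scaled_expression(
    adata: ad.AnnData,
    gene: str,
    clusters: Sequence[str],
    cluster_key: str = "cluster",
    scaler: Callable[[pd.Series], pd.Series] = minmax_scale_0_100,
) -> pd.Series:
    """Scaled expression of a gene per cluster, on a 0-100 scale.

    The cluster-mean normalized expression is computed for every cluster in
    the comparison set, then rescaled across that set by ``scaler``
    (default: min-max to [0, 100]).
    """
    if not clusters:
        raise ValueError("clusters must be nonempty")
    vec = _gene_vector(adata, gene, "norm")
    means = pd.Series(
        {
            c: float(vec[_cluster_mask(adata, c, cluster_key)].mean())
            for c in clusters
        }
    )
    return scaler(means)


def expression_score(scaled: float, pct: float) -> float:
    """score = scaled expression (0-100) x fraction expressing (0-1)."""
    if not (0.0 <= scaled <= 100.0):
        raise ValidationError(f"scaled expression {scaled} outside [0, 100]")
    if not (0.0 <= pct <= 1.0):
        raise ValidationError(f"percent expressing {pct} outside [0, 1]")
    return scaled * pct


def score_table(
    adata: ad.AnnData,
    genes: Iterable[str],
    clusters: Sequence[str],
    cluster_key: str = "cluster",
    scaler: Callable[[pd.Series], pd.Series] = minmax_scale_0_100,
) -> pd.DataFrame:
    """Long-format (cluster, gene) table of pct expressing, scaled
    expression, and their product (the expression score)."""
    records = []
    for gene in genes:
        scaled = scaled_expression(adata, gene, clusters, cluster_key, scaler)
        for cluster in clusters:
            pct = percent_expressing(adata, cluster, gene, cluster_key)
            records.append(
                {
                    "cluster": cluster,
                    "gene": gene,
                    "pct_expressing": pct,
                    "scaled_expr": float(scaled[cluster]),
                    "score": expression_score(float(scaled[cluster]), pct),
                }
            )
    return pd.DataFrame(records)


def presence_filters(table: pd.DataFrame, role: str) -> pd.Series:
    """Presence of each (cluster, gene) row under the role's thresholds.

    Ligands (neuropeptides) must be expressed in at least 50% of cells and
    score at least 2.5; receptors need at least 5% of cells expressing.
    All thresholds inclusive.
    """
    if role == "ligand":
        return (table["pct_expressing"] >= LIGAND_PCT_MIN) & (
            table["score"] >= LIGAND_SCORE_MIN
        )
    if role == "receptor":
        return table["pct_expressing"] >= RECEPTOR_PCT_MIN
    raise ValueError(f"role must be 'ligand' or 'receptor', got {role!r}")


# ---------------------------------------------------------------------------
# hormone-receptor catalog

@dataclass(frozen=True)
class HormoneReceptorPair:
    """A hormone and its receptor(s).

    ``ligand_genes`` usually holds one gene; for the insulin group it holds
    the three DILP genes, averaged per cell into the pseudo-gene ``ligand``.
    """

    ligand: str
    receptors: tuple[str, ...]
    ligand_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (1 <= len(self.receptors) <= 2):
            raise ValidationError(
                f"pair {self.ligand}: expected 1-2 receptors, "
                f"got {self.receptors}"
            )
        if not self.ligand_genes:
            object.__setattr__(self, "ligand_genes", (self.ligand,))


def load_pair_catalog(path: str | Path | None = None) -> list[HormoneReceptorPair]:
    """Load a hormone-receptor pair catalog from CSV (columns: ligand,
    ligand_genes [';'-separated], receptor1, receptor2).  Without a path the
    bundled default catalog of brain NSC hormones is used."""
    if path is None:
        source = resources.files("nscnet.data").joinpath(
            "hormone_receptor_pairs.csv"
        )
        with resources.as_file(source) as p:
            table = pd.read_csv(p, keep_default_na=False)
    else:
        table = pd.read_csv(path, keep_default_na=False)
    for required in ("ligand", "receptor1"):
        if required not in table.columns:
            raise FormatError(f"pair catalog missing column {required!r}")
    pairs = []
    for _, row in table.iterrows():
        receptors = tuple(
            r for r in (row["receptor1"], row.get("receptor2", "")) if r
        )
        genes = tuple(
            g for g in str(row.get("ligand_genes", "") or "").split(";") if g
        )
        pairs.append(
            HormoneReceptorPair(
                ligand=row["ligand"], receptors=receptors, ligand_genes=genes
            )
        )
    return pairs


def dilp_group_expression(
    adata: ad.AnnData,
    genes: Sequence[str] = DILP_GENES,
    name: str = DILP_NAME,
) -> ad.AnnData:
    """Append a pseudo-gene averaging the insulin-like peptides per cell.

    The mean is taken per cell on both the raw and the normalized layer
    before any scoring, so downstream treats the group exactly like a single
    ligand gene; its percent-expressing is the fraction of cells whose mean
    is positive.  Returns a new AnnData with one extra var.
    """
    for gene in genes:
        if gene not in adata.var_names:
            raise KeyError(f"insulin-group gene {gene!r} missing from matrix")
    if name in adata.var_names:
        return adata
    idx = [adata.var_names.get_loc(g) for g in genes]
    raw_mean = _dense(adata.X)[:, idx].mean(axis=1, keepdims=True)
    new_x = np.hstack([_dense(adata.X), raw_mean])
    var = pd.DataFrame(index=list(adata.var_names) + [name])
    out = ad.AnnData(X=new_x, obs=adata.obs.copy(), var=var)
    for layer, values in adata.layers.items():
        layer_mean = _dense(values)[:, idx].mean(axis=1, keepdims=True)
        out.layers[layer] = np.hstack([_dense(values), layer_mean])
    return out


def resolve_receptor(
    pair: HormoneReceptorPair,
    cluster: str,
    table: pd.DataFrame,
) -> str | None:
    """Pick the receptor that carries the pair's signal in a target cluster.

    Among the pair's receptors that pass the receptor presence filter in the
    cluster, the higher-scoring one wins; exact score ties break to the
    lexicographically smaller gene name.  None when no receptor is present.
    """
    rows = table.loc[
        (table["cluster"] == cluster) & table["gene"].isin(pair.receptors)
    ]
    rows = rows.loc[presence_filters(rows, "receptor")]
    if len(rows) == 0:
        return None
    rows = rows.sort_values(["score", "gene"], ascending=[False, True])
    return str(rows.iloc[0]["gene"])


def build_paracrine_network(
    table: pd.DataFrame,
    pairs: Iterable[HormoneReceptorPair],
    sources: Sequence[str],
    targets: Sequence[str],
) -> pd.DataFrame:
    """Weighted ligand-receptor edges between clusters.

    One edge per (source, target, ligand) where the ligand is present in the
    source and a receptor resolves in the target; the weight is
    ligand score x receptor score / 100, on a 0-100 scale.  Zero-weight
    edges are never emitted, and a ligand whose receptors are absent from
    every target yields no edges at all.
    """
    ligand_rows = table.set_index(["cluster", "gene"])
    edges = []
    for pair in pairs:
        for source in sources:
            key = (source, pair.ligand)
            if key not in ligand_rows.index:
                continue
            row = ligand_rows.loc[key]
            present = (row["pct_expressing"] >= LIGAND_PCT_MIN) and (
                row["score"] >= LIGAND_SCORE_MIN
            )
            if not present:
                continue
            for target in targets:
                receptor = resolve_receptor(pair, target, table)
                if receptor is None:
                    continue
                r_row = ligand_rows.loc[(target, receptor)]
                weight = float(row["score"]) * float(r_row["score"]) / 100.0
                if weight <= 0:
                    continue
                edges.append(
                    {
                        "source": source,
                        "target": target,
                        "ligand": pair.ligand,
                        "receptor": receptor,
                        "weight": weight,
                    }
                )
    return pd.DataFrame(
        edges, columns=["source", "target", "ligand", "receptor", "weight"]
    )


def tissue_receptor_catalog(
    adata: ad.AnnData,
    receptors: Iterable[str],
    tissue_key: str = "tissue",
    scaler: Callable[[pd.Series], pd.Series] = minmax_scale_0_100,
) -> pd.DataFrame:
    """Hormone-receptor expression across tissue/cell-type clusters.

    A long-format dot-plot table (tissue, receptor, pct expressing, scaled
    expression, score) using the same scoring rules as the NSC network;
    cell types spanning several tissues should be pooled by the caller
    under a 'general' label before this call.
    """
    tissues = list(pd.unique(adata.obs[tissue_key]))
    table = score_table(adata, receptors, tissues, cluster_key=tissue_key,
                        scaler=scaler)
    return table.rename(columns={"cluster": "tissue", "gene": "receptor"})


def network_to_graphml(edges: pd.DataFrame, path: str | Path) -> None:
    import networkx as nx

    g = nx.MultiDiGraph()
    for _, e in edges.iterrows():
        g.add_edge(
            e["source"], e["target"],
            ligand=e["ligand"], receptor=e["receptor"], weight=float(e["weight"]),
        )
    nx.write_graphml(g, str(path))
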