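"""NSC subtype catalog, input-profile cosine clustering, and morphology PCA.

Adult *Drosophila* brains contain 80 neurosecretory cells (NSC) falling into
ten subtypes named by soma position (medial, lateral, subesophageal) and the
hormone they produce.  Subtypes are recoverable from connectivity alone:
NSC of one subtype draw synaptic input from a shared pool of presynaptic
partners, so the cosine similarity of their input-count vectors is high
within a subtype and low between subtypes.  Agglomerative clustering on
1 - cosine similarity therefore groups NSC into their subtypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from io import StringIO
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA
from sklearn.metrics.pairwise import cosine_similarity

from .connectome import Connectome, significant_edges
from .errors import AmbiguityError, ValidationError

logger = logging.getLogger(__name__)

# Adult NSC subtype catalog: soma location, hormone gene(s), and cell counts
# in first-instar larvae, expected in adults, and observed in the adult brain
# connectome.  The eclosion-hormone and PTTH populations apoptose shortly
# after adult eclosion, hence zero adults.
_CATALOG_CSV = """\
name,location,peptides,n_larva,n_expected_adult,n_observed_adult
m-NSC^DMS,medial,Ms,4,4,6
m-NSC^DH44,medial,Dh44,6,6,6
m-NSC^DILP,medial,Ilp2;Ilp3;Ilp5,14,14,18
NSC^EH,medial,Eh,2,0,0
l-NSC^CRZ,lateral,Crz;sNPF,6,14,6
l-NSC^ITP,lateral,ITP,8,8,8
l-NSC^DH31,lateral,Dh31;ITP,6,6,6
l-NSC^PTTH,lateral,Ptth,4,0,0
SEZ-NSC^CAPA,subesophageal,Capa,2,2,2
SEZ-NSC^Hugin,subesophageal,Hug,4,4,4
m-NSC^unknown,medial,,0,0,10
l-NSC^unknown,lateral,,0,0,14
"""

SUBTYPE_CATALOG: pd.DataFrame = pd.read_csv(
    StringIO(_CATALOG_CSV), keep_default_na=False
)

#: The ten subtypes present in the adult brain, in catalog order.
ADULT_SUBTYPES: tuple[str, ...] = tuple(
    SUBTYPE_CATALOG.loc[SUBTYPE_CATALOG["n_observed_adult"] > 0, "name"]
)


@dataclass(frozen=True)
class InputProfile:
    """NSC-by-presynaptic-partner synapse count matrix.

    ``matrix`` rows are NSC ids, columns the union of all significant
    presynaptic partners.  NSC with no significant input cannot enter a
    cosine computation (zero norm) and are listed in ``excluded`` instead of
    being silently dropped.
    """

    matrix: pd.DataFrame
    excluded: tuple[str, ...]


def build_input_profile(
    connectome: Connectome,
    nsc_ids: Iterable[str],
    threshold: int | None = None,
) -> InputProfile:
    """Collect each NSC's significant presynaptic partners into a matrix."""
    nsc_ids = [str(n) for n in nsc_ids]
    if not nsc_ids:
        raise ValueError("nsc_ids must be nonempty")
    missing = [n for n in nsc_ids if n not in connectome.neurons]
    if missing:
        raise ValidationError(f"nsc_ids not in connectome: {missing[:5]}")
    sig = significant_edges(connectome, threshold)
    rows = sig.loc[sig["post"].isin(set(nsc_ids))]
    matrix = (
        rows.pivot_table(
            index="post", columns="pre", values="count", fill_value=0, aggfunc="sum"
        )
        .reindex(sorted(nsc_ids), fill_value=0)
        .astype(int)
    )
    matrix = matrix[sorted(matrix.columns)]
    matrix.index.name = "nsc"
    matrix.columns.name = "partner"
    zero = matrix.sum(axis=1) == 0
    excluded = tuple(matrix.index[zero])
    if excluded:
        logger.info("%d NSC with no significant input excluded: %s",
                    len(excluded), list(excluded)[:8])
    return InputProfile(matrix=matrix.loc[~zero], excluded=excluded)


def cosine_similarity_matrix(profile: InputProfile | pd.DataFrame) -> pd.DataFrame:
    """Pairwise cosine similarity of input-count rows.

    S[i, j] = x_i . x_j / (|x_i| |x_j|); symmetric, unit diagonal, and in
    [0, 1] for non-negative counts.  Raw counts are used directly — cosine
    is scale-invariant per row, so no normalization is needed.
    """
    matrix = profile.matrix if isinstance(profile, InputProfile) else profile
    values = matrix.to_numpy(dtype=float)
    if values.shape[0] and (np.linalg.norm(values, axis=1) == 0).any():
        raise ValidationError("all-zero profile row reached similarity computation")
    sim = cosine_similarity(values)
    sim = np.clip((sim + sim.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(sim, 1.0)
    return pd.DataFrame(sim, index=matrix.index, columns=matrix.index)


def cluster_nsc(
    similarity: pd.DataFrame,
    k: int,
    method: str = "average",
) -> tuple[pd.Series, np.ndarray]:
    """Agglomerative clustering on distance 1 - similarity.

    Returns (labels, linkage matrix).  Labels are integers 1..k and are
    deterministic given the similarity matrix: rows are ordered
    lexicographically by id before linkage, which fixes the merge order for
    tied distances.
    """
    n = len(similarity)
    if k > n:
        raise ValueError(f"k={k} exceeds number of observations n={n}")
    if not np.allclose(similarity.to_numpy(), similarity.to_numpy().T, atol=1e-9):
        raise ValidationError("similarity matrix must be symmetric")
    order = sorted(similarity.index)
    sim = similarity.loc[order, order].to_numpy(dtype=float)
    if n == 1:
        return pd.Series([1], index=order, name="cluster"), np.empty((0, 4))
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = linkage(squareform(dist, checks=False), method=method)
    labels = fcluster(z, t=k, criterion="maxclust")
    return pd.Series(labels, index=order, name="cluster"), z


def dendrogram_newick(z: np.ndarray, leaf_names: Iterable[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree string."""
    names = list(leaf_names)
    n = len(names)
    if n == 1:
        return f"{names[0]};"

    def render(node: int) -> tuple[str, float]:
        if node < n:
            return names[node], 0.0
        left, right, height = (
            int(z[node - n, 0]),
            int(z[node - n, 1]),
            float(z[node - n, 2]),
        )
        ltext, lheight = render(left)
        rtext, rheight = render(right)
        return (
            f"({ltext}:{height - lheight:.6g},{rtext}:{height - rheight:.6g})",
            height,
        )

    text, _ = render(2 * n - 2)
    return text + ";"


def morphology_pca(features: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of per-NSC morphology features (cable length, surface area, cell
    size, nuclei volume).

    Columns are z-scored before decomposition so each feature contributes on
    an equal footing regardless of units; zero-variance columns are dropped
    with a warning.  Returns (scores, explained-variance fractions).
    """
    if len(features) < 3:
        raise ValueError("morphology PCA needs at least 3 records")
    numeric = features.astype(float)
    if (numeric <= 0).any().any():
        raise ValidationError("morphology features must be strictly positive")
    std = numeric.std(axis=0, ddof=1)
    degenerate = std[std == 0].index.tolist()
    if degenerate:
        logger.warning("dropping zero-variance feature column(s): %s", degenerate)
        numeric = numeric.drop(columns=degenerate)
        std = std.drop(index=degenerate)
    z = (numeric - numeric.mean(axis=0)) / std
    pca = PCA(n_components=min(z.shape))
    scores = pca.fit_transform(z.to_numpy())
    score_df = pd.DataFrame(
        scores,
        index=features.index,
        columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
    )
    return score_df, pca.explained_variance_ratio_


def assign_subtypes(
    labels: pd.Series,
    anchors: Mapping[str, str] | None = None,
    size_map: Mapping[int, str] | None = None,
    soma_position: Mapping[str, str] | None = None,
) -> dict[int, str]:
    """Map cluster labels to NSC subtype names.

    ``anchors`` maps known NSC ids to subtype names (e.g. from morphology);
    every cluster containing an anchor inherits its subtype, and two anchors
    of different subtypes in one cluster is an ambiguity error.  Clusters
    without anchors fall back to ``size_map`` (cluster size -> subtype, e.g.
    the 18-cell cluster is m-NSC^DILP), then to ``unknown-m`` / ``unknown-l``
    from ``soma_position`` (NSC id -> 'medial' | 'lateral'), then to
    ``unknown``.
    """
    anchors = dict(anchors or {})
    assignment: dict[int, str] = {}
    for cluster in sorted(labels.unique()):
        members = labels.index[labels == cluster]
        hit = sorted({anchors[m] for m in members if m in anchors})
        if len(hit) > 1:
            raise AmbiguityError(
                f"cluster {cluster} contains anchors of multiple subtypes: {hit}"
            )
        if hit:
            assignment[int(cluster)] = hit[0]
            continue
        if size_map and len(members) in size_map:
            assignment[int(cluster)] = size_map[len(members)]
            continue
        if soma_position:
            positions = {soma_position.get(m, "") for m in members}
            if positions == {"medial"}:
                assignment[int(cluster)] = "unknown-m"
                continue
            if positions == {"lateral"}:
                assignment[int(cluster)] = "unknown-l"
                continue
        assignment[int(cluster)] = "unknown"
    return assignment
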