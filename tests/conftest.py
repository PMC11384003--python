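import anndata as ad
import numpy as np
import pandas as pd
import pytest

from nscnet import (
    Neuron,
    ThresholdConfig,
    build_connectome,
    generate_connectome,
    generate_expression,
    normalize_counts,
)


@pytest.fixture
def toy():
    """Factory for small hand-built connectomes.

    ``neurons`` maps id -> super_class or -> dict of Neuron kwargs;
    ``edges`` is a list of (pre, post, count) triples.
    """

    def _toy(neurons, edges, thresholds=None, strict=True):
        neuron_map = {}
        for nid, spec in neurons.items():
            if isinstance(spec, str):
                neuron_map[nid] = Neuron(id=nid, super_class=spec)
            else:
                neuron_map[nid] = Neuron(id=nid, **spec)
        edge_df = pd.DataFrame(edges, columns=["pre", "post", "count"])
        return build_connectome(
            neuron_map, edge_df,
            thresholds=thresholds or ThresholdConfig(), strict=strict,
        )

    return _toy


@pytest.fixture(scope="session")
def sim_connectome():
    """Default synthetic connectome (zero noise) with its ground truth."""
    return generate_connectome()


@pytest.fixture(scope="session")
def sim_expression():
    """Default synthetic expression matrix with planted paracrine signals."""
    return generate_expression()


@pytest.fixture
def expr_from_counts():
    """Factory: dense count matrix + cluster labels -> normalized AnnData."""

    def _make(counts, clusters, genes=None):
        counts = np.asarray(counts, dtype=float)
        genes = list(genes) if genes is not None else [
            f"g{i}" for i in range(counts.shape[1])
        ]
        obs = pd.DataFrame(
            {"cluster": pd.Categorical(clusters)},
            index=[f"cell{i}" for i in range(counts.shape[0])],
        )
        adata = ad.AnnData(X=counts, obs=obs, var=pd.DataFrame(index=genes))
        return normalize_counts(adata)

    return _make
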