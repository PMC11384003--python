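import random
from collections import defaultdict

import pandas as pd
import pytest

from nscnet import (
    Neuron,
    ThresholdConfig,
    build_connectome,
    direct_sensory_inputs,
    disynaptic_sensory_pathways,
    group_orns,
    khop_shortest_pathways,
    multi_target_total,
    nsc_output_partners,
    nt_annotate,
    shared_input_neurons,
    strong_connections,
)


# ---------------------------------------------------------------------------
# independent brute-force oracle for path enumeration

def brute_force_shortest_paths(edges, source, target, max_hops, threshold):
    """All simple paths of minimum hop length from source to target using
    plain recursive DFS over the thresholded edge list."""
    adj = defaultdict(list)
    for (u, v), c in edges.items():
        if c >= threshold:
            adj[u].append(v)
    found = []

    def dfs(node, path):
        if len(path) - 1 > max_hops:
            return
        if node == target:
            found.append(tuple(path))
            return
        for nxt in adj[node]:
            if nxt not in path:
                dfs(nxt, path + [nxt])

    if source != target:
        dfs(source, [source])
    if not found:
        return set()
    shortest = min(len(p) for p in found)
    return {p for p in found if len(p) == shortest}


def random_connectome(rng, max_nodes=30, max_edges=120):
    n = rng.randint(4, max_nodes)
    node_ids = [f"v{i:02d}" for i in range(n)]
    neurons = {}
    for nid in node_ids:
        cls = rng.choice(["sensory", "central", "central", "endocrine"])
        kwargs = {"super_class": cls}
        if cls == "sensory":
            kwargs["sensory_modality"] = rng.choice(["gustatory", "olfactory"])
        neurons[nid] = Neuron(id=nid, **kwargs)
    edges = {}
    for _ in range(rng.randint(0, max_edges)):
        u, v = rng.sample(node_ids, 2)
        edges[(u, v)] = rng.randint(1, 12)
    edge_df = pd.DataFrame(
        [{"pre": u, "post": v, "count": c} for (u, v), c in edges.items()],
        columns=["pre", "post", "count"],
    )
    net = build_connectome(neurons, edge_df, ThresholdConfig(), strict=True)
    return net, edges


class TestKhopShortestPathways:
    def test_planted_chain_found_at_three_hops(self, toy):
        net = toy(
            {
                "orn": {"super_class": "sensory", "sensory_modality": "olfactory"},
                "pn": "central",
                "inn": "central",
                "nsc": "endocrine",
            },
            [("orn", "pn", 8), ("pn", "inn", 9), ("inn", "nsc", 10)],
        )
        paths = khop_shortest_pathways(net, ["orn"], ["nsc"], max_hops=3)
        assert len(paths) == 1
        assert paths[0].nodes == ("orn", "pn", "inn", "nsc")
        assert paths[0].hop_counts == (8, 9, 10)
        assert paths[0].layers == ("sensory", "central", "central", "endocrine")

    def test_direct_edge_shortcuts_longer_routes(self, toy):
        net = toy(
            {"s": "sensory", "i": "central", "n": "endocrine"},
            [("s", "i", 6), ("i", "n", 6), ("s", "n", 7)],
        )
        paths = khop_shortest_pathways(net, ["s"], ["n"], max_hops=3)
        assert [p.nodes for p in paths] == [("s", "n")]

    def test_parallel_shortest_routes_all_kept(self, toy):
        net = toy(
            {"s": "sensory", "i1": "central", "i2": "central", "n": "endocrine"},
            [("s", "i1", 6), ("s", "i2", 6), ("i1", "n", 6), ("i2", "n", 6)],
        )
        paths = khop_shortest_pathways(net, ["s"], ["n"], max_hops=3)
        assert sorted(p.nodes for p in paths) == [
            ("s", "i1", "n"),
            ("s", "i2", "n"),
        ]

    def test_deep_search_refused_without_override(self, toy):
        net = toy({"a": "central", "b": "central"}, [("a", "b", 6)])
        with pytest.raises(ValueError):
            khop_shortest_pathways(net, ["a"], ["b"], max_hops=7)
        paths = khop_shortest_pathways(
            net, ["a"], ["b"], max_hops=7, allow_deep=True
        )
        assert len(paths) == 1

    def test_matches_bruteforce_on_random_graphs(self):
        rng = random.Random(2024)
        for _ in range(40):
            net, edges = random_connectome(rng)
            threshold = rng.choice([1, 2, 5])
            nodes = sorted(net.neurons)
            sources = rng.sample(nodes, min(3, len(nodes)))
            targets = rng.sample(nodes, min(3, len(nodes)))
            max_hops = rng.choice([2, 3, 4])
            paths = khop_shortest_pathways(
                net, sources, targets, max_hops=max_hops, threshold=threshold
            )
            got = defaultdict(set)
            for p in paths:
                got[(p.nodes[0], p.nodes[-1])].add(p.nodes)
            for s in sources:
                for t in targets:
                    if s == t:
                        continue
                    expected = brute_force_shortest_paths(
                        edges, s, t, max_hops, threshold
                    )
                    assert got.get((s, t), set()) == expected

    def test_stable_when_max_hops_raised(self, sim_connectome):
        net, truth = sim_connectome
        orns = [n for n in net.neurons if n.startswith("orn")]
        nsc = sorted(truth.partition)
        three = khop_shortest_pathways(net, orns, nsc, max_hops=3)
        four = khop_shortest_pathways(net, orns, nsc, max_hops=4)
        assert {p.nodes for p in three} <= {p.nodes for p in four}
        # pairs already connected in <= 3 hops keep exactly the same paths
        reached = {(p.nodes[0], p.nodes[-1]) for p in three}
        four_same = {
            p.nodes for p in four if (p.nodes[0], p.nodes[-1]) in reached
        }
        assert four_same == {p.nodes for p in three}


class TestDirectSensoryInputs:
    def test_no_sensory_neurons_empty_table(self, toy):
        net = toy({"a": "central", "n": "endocrine"}, [("a", "n", 9)])
        assert len(direct_sensory_inputs(net, ["n"])) == 0

    def test_planted_gustatory_edge_reported(self, toy):
        net = toy(
            {
                "grn": {"super_class": "sensory", "sensory_modality": "gustatory"},
                "n": "endocrine",
            },
            [("grn", "n", 8)],
        )
        table = direct_sensory_inputs(net, ["n"])
        assert len(table) == 1
        row = table.iloc[0]
        assert (row["sensory_id"], row["modality"], row["count"]) == (
            "grn", "gustatory", 8,
        )

    def test_subthreshold_edge_ignored(self, toy):
        net = toy(
            {"s": {"super_class": "sensory"}, "n": "endocrine"},
            [("s", "n", 4)],
        )
        assert len(direct_sensory_inputs(net, ["n"])) == 0


class TestDisynapticPathways:
    def test_two_hop_chain_found(self, toy):
        net = toy(
            {"s": {"super_class": "sensory"}, "i": "central", "n": "endocrine"},
            [("s", "i", 6), ("i", "n", 7)],
        )
        paths, sensory_in, nonsensory_in = disynaptic_sensory_pathways(net, ["n"])
        assert len(paths) == 1
        assert paths[0].nodes == ("s", "i", "n")
        assert paths[0].hop_counts == (6, 7)
        assert sensory_in == {"i"}
        assert nonsensory_in == set()

    def test_subthreshold_second_hop_blocks_pathway(self, toy):
        net = toy(
            {"s": {"super_class": "sensory"}, "i": "central", "n": "endocrine"},
            [("s", "i", 6), ("i", "n", 4)],
        )
        paths, sensory_in, nonsensory_in = disynaptic_sensory_pathways(net, ["n"])
        assert paths == []
        assert sensory_in == set()
        # i has no significant edge onto NSC, so it is not an interneuron at all
        assert nonsensory_in == set()

    def test_interneuron_partition(self, toy):
        net = toy(
            {
                "s": {"super_class": "sensory"},
                "i1": "central",
                "i2": "central",
                "n": "endocrine",
            },
            [("s", "i1", 6), ("i1", "n", 7), ("i2", "n", 9)],
        )
        _, sensory_in, nonsensory_in = disynaptic_sensory_pathways(net, ["n"])
        assert sensory_in == {"i1"}
        assert nonsensory_in == {"i2"}

    def test_matches_bruteforce_on_random_graphs(self):
        rng = random.Random(7)
        for _ in range(30):
            net, edges = random_connectome(rng, max_nodes=20, max_edges=80)
            nsc = [
                n for n, neuron in net.neurons.items()
                if neuron.super_class == "endocrine"
            ]
            if not nsc:
                continue
            sensory = {
                n for n, neuron in net.neurons.items()
                if neuron.super_class == "sensory"
            }
            paths, _, _ = disynaptic_sensory_pathways(net, nsc)
            got = {p.nodes for p in paths}
            t = net.thresholds.significance
            expected = {
                (s, i, n)
                for (s, i), c1 in edges.items()
                if c1 >= t and s in sensory
                for (i2, n), c2 in edges.items()
                if i2 == i and c2 >= t and n in nsc
                and i not in sensory and i not in nsc and n != s
            }
            assert got == expected


class TestNtAnnotate:
    @pytest.mark.parametrize(
        "scores,expected",
        [
            ({"acetylcholine": 0.63}, "acetylcholine"),
            ({"acetylcholine": 0.62}, "unknown"),  # strictly-greater cutoff
            ({}, "unknown"),
            ({"gaba": 0.8, "glutamate": 0.8}, "unknown"),  # exact tie
            ({"glutamate": 0.7, "acetylcholine": 0.65}, "glutamate"),
            ({"serotonin": 0.99}, "unknown"),  # not fast-acting
        ],
    )
    def test_cutoff_and_tie_rules(self, scores, expected):
        assert nt_annotate(scores, cutoff=0.62) == expected


class TestStrongConnections:
    def test_inclusive_boundary_at_50(self, toy):
        net = toy(
            {"p": "central", "q": "central", "n": "endocrine"},
            [("p", "n", 49), ("q", "n", 50)],
        )
        report = strong_connections(net, {"n": "l-NSC^DH31"})
        assert list(report.connections["pre"]) == ["q"]
        summary = report.summary.iloc[0]
        assert (summary["n_connections"], summary["total_synapses"]) == (1, 50)

    def test_no_strong_edges_empty_report(self, toy):
        net = toy({"p": "central", "n": "endocrine"}, [("p", "n", 30)])
        report = strong_connections(net, {"n": "x"})
        assert len(report.connections) == 0
        assert len(report.summary) == 0


class TestSharedInputs:
    def test_single_subtype_contact_absent_from_multi_report(self, toy):
        net = toy(
            {"p": "central", "n1": "endocrine", "n2": "endocrine"},
            [("p", "n1", 6), ("p", "n2", 7)],
        )
        summary = shared_input_neurons(net, {"n1": "A", "n2": "A"})
        assert summary.histogram == {1: 1}
        assert summary.multi_target_neurons == {}

    def test_two_subtype_contact_lands_in_bin_two(self, toy):
        net = toy(
            {"p": "central", "n1": "endocrine", "n2": "endocrine"},
            [("p", "n1", 6), ("p", "n2", 7)],
        )
        summary = shared_input_neurons(
            net, {"n1": "m-NSC^DH44", "n2": "m-NSC^DILP"}
        )
        assert summary.histogram == {2: 1}
        assert summary.multi_target_total == 1

    def test_histogram_conservation_against_pair_count(self, sim_connectome):
        """sum_k k*bin(k) equals the number of distinct (neuron, subtype)
        significant incidence pairs, counted directly from the edge list."""
        net, truth = sim_connectome
        summary = shared_input_neurons(net, truth.partition)
        lhs = sum(k * v for k, v in summary.histogram.items())
        from nscnet import significant_edges

        sig = significant_edges(net)
        pairs = {
            (row["pre"], truth.partition[row["post"]])
            for _, row in sig.iterrows()
            if row["post"] in truth.partition
            and row["pre"] not in truth.partition
        }
        assert lhs == len(pairs)

    def test_printed_histogram_sums_to_published_total(self):
        assert multi_target_total({2: 53, 3: 22, 4: 1}) == 76

    def test_unlabeled_nsc_rejected(self, toy):
        net = toy({"p": "central", "n": "endocrine"}, [("p", "n", 6)])
        with pytest.raises(ValueError):
            shared_input_neurons(net, {"n": ""})


class TestOutputPartners:
    def test_planted_output_edge(self, toy):
        net = toy(
            {"crz": "endocrine", "dn": "descending"},
            [("crz", "dn", 60)],
        )
        table = nsc_output_partners(net, ["crz"])
        assert len(table) == 1
        assert table.iloc[0]["partner_super_class"] == "descending"

    def test_relaxed_threshold_is_superset(self, sim_connectome):
        net, truth = sim_connectome
        nsc = sorted(truth.partition)
        strict = nsc_output_partners(net, nsc, threshold=5)
        relaxed = nsc_output_partners(net, nsc, threshold=2)
        strict_set = set(zip(strict["nsc_id"], strict["partner_id"]))
        relaxed_set = set(zip(relaxed["nsc_id"], relaxed["partner_id"]))
        assert strict_set <= relaxed_set
        assert len(relaxed_set) > len(strict_set)  # generator plants weak output

    def test_nsc_without_output_yields_no_rows(self, toy):
        net = toy({"n": "endocrine", "d": "descending"}, [("n", "d", 3)])
        assert len(nsc_output_partners(net, ["n"])) == 0


class TestGroupOrns:
    def test_categories_and_synapse_totals(self, toy):
        net = toy(
            {
                "o1": {"super_class": "sensory", "sensory_modality": "olfactory",
                       "cell_type": "DL5"},
                "o2": {"super_class": "sensory", "sensory_modality": "olfactory",
                       "cell_type": "DP1l"},
                "pn": "central",
                "inn": "central",
                "n": "endocrine",
            },
            [("o1", "pn", 30), ("o2", "pn", 10), ("pn", "inn", 9),
             ("inn", "n", 9)],
        )
        paths = khop_shortest_pathways(net, ["o1", "o2"], ["n"], max_hops=3)
        table = group_orns(
            net, paths, {"DL5": "aversive", "DP1l": "food"}
        ).set_index("category")
        assert table.loc["aversive", "n_synapses"] == 30
        assert table.loc["food", "n_synapses"] == 10
        assert table["n_orns"].sum() == 2

    def test_unmapped_type_goes_to_other(self, toy):
        net = toy(
            {
                "o1": {"super_class": "sensory", "cell_type": "XX9"},
                "n": "endocrine",
            },
            [("o1", "n", 8)],
        )
        paths = khop_shortest_pathways(net, ["o1"], ["n"], max_hops=3)
        table = group_orns(net, paths, {})
        assert list(table["category"]) == ["other"]

    def test_empty_pathway_list(self, toy):
        net = toy({"n": "endocrine"}, [])
        assert len(group_orns(net, [], {})) == 0
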