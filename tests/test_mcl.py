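import networkx as nx
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from subnetmark.diffexpr import SeedGeneSet
from subnetmark.mcl import MCLParams, Subnetwork, filter_subnetworks, mcl_cluster
from subnetmark.network import InteractionGraph
from subnetmark.synthetic import SyntheticSpec, gen_ppi

from _oracles import mcl_reference


def _graph(edges, nodes=None):
    g = nx.Graph()
    g.add_edges_from(edges)
    if nodes:
        g.add_nodes_from(nodes)
    return InteractionGraph(g, set())


BRIDGED_TRIANGLES = [
    ("a", "b"), ("b", "c"), ("a", "c"),
    ("d", "e"), ("e", "f"), ("d", "f"),
    ("c", "d"),
]


class TestMCLCluster:
    def test_bridged_triangles_split_into_two(self):
        """Two triangles joined by one bridge dissolve into their triangles."""
        result = mcl_cluster(_graph(BRIDGED_TRIANGLES))
        sizes = sorted(len(c) for c in result.clusters)
        assert sizes == [3, 3]
        assert {"a", "b", "c"} in result.clusters
        assert {"d", "e", "f"} in result.clusters

    def test_single_triangle_one_cluster(self):
        result = mcl_cluster(_graph([("a", "b"), ("b", "c"), ("a", "c")]))
        assert result.clusters == [{"a", "b", "c"}]

    def test_flow_cannot_cross_components(self):
        result = mcl_cluster(
            _graph([("a", "b"), ("b", "c"), ("x", "y"), ("y", "z")])
        )
        for cluster in result.clusters:
            assert cluster <= {"a", "b", "c"} or cluster <= {"x", "y", "z"}

    def test_partition_property(self, synthetic_study):
        graph = _graph(synthetic_study["edges"])
        result = mcl_cluster(graph)
        all_nodes = [n for c in result.clusters for n in c]
        assert len(all_nodes) == len(set(all_nodes)) == len(graph.nodes)

    def test_column_stochastic_every_iteration(self, synthetic_study):
        result = mcl_cluster(_graph(synthetic_study["edges"]))
        assert result.column_sum_errors  # at least one iteration ran
        assert max(result.column_sum_errors) < 1e-9

    def test_idempotent_at_convergence(self, synthetic_study):
        """One more expand-inflate round barely moves the converged matrix."""
        params = MCLParams()
        result = mcl_cluster(_graph(synthetic_study["edges"]), params)
        assert result.converged
        m = result.matrix
        nxt = np.linalg.matrix_power(m, params.expansion_e) ** params.inflation_r
        nxt = nxt / nxt.sum(axis=0)
        assert np.abs(nxt - m).max() < 10 * params.convergence_tol

    def test_oracle_equivalence_on_atlas_graphs(self):
        """Identical clusterings to an independently coded dense MCL on every
        connected graph with <= 7 nodes (one per isomorphism class)."""
        params = MCLParams()
        checked = 0
        for g in nx.graph_atlas_g()[1:]:
            if g.number_of_nodes() == 0 or not nx.is_connected(g):
                continue
            relabeled = nx.relabel_nodes(g, {n: f"n{n:02d}" for n in g.nodes})
            ours = mcl_cluster(InteractionGraph(relabeled, set()), params)
            expected = mcl_reference(relabeled.nodes, relabeled.edges)
            assert frozenset(frozenset(c) for c in ours.clusters) == expected
            checked += 1
        assert checked > 900  # all connected graphs on 1..7 nodes

    def test_planted_partition_recovery(self):
        """5 blocks x 8 nodes at p_in=0.6 / p_out=0.05: ARI >= 0.9 vs truth."""
        spec = SyntheticSpec(rng_seed=7)
        edges, blocks, _ = gen_ppi(spec, {f"G{i:05d}": 0 for i in range(1, 501)})
        members = sorted(set().union(*blocks))
        result = mcl_cluster(_graph(edges, nodes=members))
        truth = {g: i for i, blk in enumerate(blocks) for g in blk}
        found = {g: i for i, c in enumerate(result.clusters) for g in c}
        ari = adjusted_rand_score(
            [truth[g] for g in members], [found[g] for g in members]
        )
        assert ari >= 0.9

    def test_no_planted_structure_gives_low_ari(self):
        spec = SyntheticSpec(rng_seed=8, p_in=0.3, p_out=0.3)
        edges, blocks, _ = gen_ppi(spec, {f"G{i:05d}": 0 for i in range(1, 501)})
        members = sorted(set().union(*blocks))
        result = mcl_cluster(_graph(edges, nodes=members))
        truth = {g: i for i, blk in enumerate(blocks) for g in blk}
        found = {g: i for i, c in enumerate(result.clusters) for g in c}
        ari = adjusted_rand_score(
            [truth[g] for g in members], [found[g] for g in members]
        )
        assert abs(ari) < 0.2

    def test_higher_inflation_more_clusters(self, synthetic_study):
        graph = _graph(synthetic_study["edges"])
        coarse = mcl_cluster(graph, MCLParams(inflation_r=1.5))
        fine = mcl_cluster(graph, MCLParams(inflation_r=4.0))
        assert len(fine.clusters) >= len(coarse.clusters)

    def test_bad_params_rejected(self):
        with pytest.raises(ValueError):
            MCLParams(inflation_r=1.0)
        with pytest.raises(ValueError):
            MCLParams(expansion_e=1)


class TestFilterSubnetworks:
    CLUSTERS = [
        {"a", "b", "c", "d"},       # size 4, 1 seed
        {"p", "q", "r", "s", "t"},  # size 5, no seeds
        {"x", "y"},                 # size 2, 2 seeds
    ]

    def test_selection_rule(self):
        kept = filter_subnetworks(self.CLUSTERS, SeedGeneSet({"a", "x", "y"}))
        assert [sn.members for sn in kept] == [{"a", "b", "c", "d"}]
        assert kept[0].seed_members == {"a"}

    def test_boundary_size_three_kept(self):
        kept = filter_subnetworks([{"a", "b", "c"}], SeedGeneSet({"a"}))
        assert len(kept) == 1 and len(kept[0]) == 3

    def test_all_seedless_is_error(self):
        with pytest.raises(ValueError, match="no subnetwork markers"):
            filter_subnetworks(self.CLUSTERS, SeedGeneSet({"zzz"}))

    def test_ordering_and_ids(self):
        clusters = [{"m", "n", "o"}, {"a", "b", "c"}, {"w", "x", "y", "z"}]
        kept = filter_subnetworks(clusters, SeedGeneSet({"m", "a", "w"}))
        assert [sn.id for sn in kept] == [1, 2, 3]
        assert [len(sn) for sn in kept] == [4, 3, 3]
        assert min(kept[1].members) == "a"  # lexicographic tie-break

    def test_up_down_disjointness_enforced(self):
        with pytest.raises(ValueError, match="disjoint"):
            Subnetwork(1, {"a", "b", "c"}, {"a"}, up_set={"a"}, down_set={"a"})
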