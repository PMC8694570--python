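import itertools

import networkx as nx
import numpy as np
import pytest

from adversome import graph_metrics as gm
from adversome.adversome_net import IsingNetwork


# ---------------------------------------------------------------------------
# Brute-force oracles


def modularity_formula(g: nx.Graph, assignment) -> float:
    """Direct evaluation of Q = (1/2m) Σ_ij (A_ij − k_i k_j / 2m) δ(c_i,c_j)."""
    nodes = list(g.nodes)
    A = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
    two_m = A.sum()
    if two_m == 0:
        return 0.0
    k = A.sum(axis=1)
    q = 0.0
    for i, u in enumerate(nodes):
        for j, v in enumerate(nodes):
            if assignment[u] == assignment[v]:
                q += A[i, j] - k[i] * k[j] / two_m
    return q / two_m


def best_partition_bruteforce(g: nx.Graph):
    """Exhaustive search over all set partitions (feasible for <= 8 nodes)."""
    nodes = list(g.nodes)

    def partitions(seq):
        if not seq:
            yield []
            return
        head, rest = seq[0], seq[1:]
        for smaller in partitions(rest):
            for i, block in enumerate(smaller):
                yield smaller[:i] + [block + [head]] + smaller[i + 1:]
            yield [[head]] + smaller

    best_q, best_p = -np.inf, None
    for part in partitions(nodes):
        assignment = {n: i for i, block in enumerate(part) for n in block}
        q = modularity_formula(g, assignment)
        if q > best_q:
            best_q, best_p = q, part
    return best_q, best_p


def degree_assort_oracle(g: nx.Graph):
    deg = dict(g.degree())
    xs, ys = [], []
    for u, v in g.edges():
        xs += [deg[u], deg[v]]
        ys += [deg[v], deg[u]]
    xs, ys = np.array(xs, float), np.array(ys, float)
    if xs.size == 0 or np.var(xs) == 0:
        return None
    return float(np.corrcoef(xs, ys)[0, 1])


def categorical_assort_oracle(g: nx.Graph, labels):
    cats = sorted({labels[n] for n in g.nodes})
    idx = {c: i for i, c in enumerate(cats)}
    e = np.zeros((len(cats), len(cats)))
    for u, v in g.edges():
        e[idx[labels[u]], idx[labels[v]]] += 1
        e[idx[labels[v]], idx[labels[u]]] += 1
    e /= e.sum()
    a, b = e.sum(axis=1), e.sum(axis=0)
    denom = 1 - (a * b).sum()
    if denom == 0:
        return None
    return float((np.trace(e) - (a * b).sum()) / denom)


def two_cliques():
    g = nx.Graph()
    for off in (0, 4):
        for i, j in itertools.combinations(range(4), 2):
            g.add_edge(off + i, off + j)
    g.add_edge(0, 4)
    return g


class TestLouvain:
    def test_two_cliques_found_as_modularity_optimum(self):
        g = two_cliques()
        part = gm.louvain(g, seed=1)
        assert sorted(map(sorted, part.communities())) == [[0, 1, 2, 3], [4, 5, 6, 7]]
        best_q, _ = best_partition_bruteforce(g)
        assert part.modularity == pytest.approx(best_q, abs=1e-12)

    def test_edgeless_graph_all_singletons(self):
        part = gm.louvain(nx.empty_graph(5), seed=0)
        assert part.n_communities == 5 and part.modularity == 0.0

    def test_no_community_spans_components(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(3))
        part = gm.louvain(g, seed=2)
        comps = list(nx.connected_components(g))
        for comm in part.communities():
            assert any(comm <= comp for comp in comps)

    def test_seed_determinism(self):
        g = nx.planted_partition_graph(4, 8, 0.6, 0.05, seed=7)
        p1 = gm.louvain(g, seed=11)
        p2 = gm.louvain(g, seed=11)
        assert p1.assignment == p2.assignment and p1.modularity == p2.modularity

    def test_negative_weights_rejected(self):
        net = IsingNetwork(["A", "B"], np.zeros(2),
                           np.array([[0, -1.0], [-1.0, 0]]))
        with pytest.raises(ValueError, match="positive_subnetwork"):
            gm.louvain(net)

    def test_planted_partition_recovery(self):
        from sklearn.metrics import adjusted_rand_score

        ok = 0
        for seed in range(20):
            g = nx.planted_partition_graph(4, 8, 0.6, 0.05, seed=seed)
            part = gm.louvain(g, seed=seed)
            truth = [n // 8 for n in range(32)]
            pred = [part.assignment[n] for n in range(32)]
            ok += adjusted_rand_score(truth, pred) >= 0.9
        assert ok >= 18


class TestModularity:
    def test_triangle_hand_values(self):
        tri = nx.cycle_graph(3)
        assert gm.modularity(tri, {0: 0, 1: 0, 2: 0}) == pytest.approx(0.0, abs=1e-12)
        assert gm.modularity(tri, {0: 0, 1: 1, 2: 2}) == pytest.approx(-1 / 3)

    def test_matches_formula_on_random_graphs(self):
        rng = np.random.default_rng(3)
        for seed in range(5):
            g = nx.gnp_random_graph(8, 0.4, seed=seed)
            for u, v in g.edges():
                g[u][v]["weight"] = float(rng.uniform(0.1, 2.0))
            assignment = {n: int(rng.integers(0, 3)) for n in g.nodes}
            assert gm.modularity(g, assignment) == pytest.approx(
                modularity_formula(g, assignment), abs=1e-12
            )

    def test_louvain_beats_singletons(self):
        g = two_cliques()
        part = gm.louvain(g, seed=0)
        singletons = {n: i for i, n in enumerate(g.nodes)}
        assert part.modularity >= gm.modularity(g, singletons)

    def test_uncovered_node_rejected(self):
        with pytest.raises(ValueError):
            gm.modularity(nx.path_graph(3), {0: 0, 1: 0})


class TestAssortativity:
    def test_star_is_perfectly_disassortative(self):
        res = gm.assortativity_degree(nx.star_graph(5))
        assert res.coefficient == pytest.approx(-1.0, abs=1e-12)

    @pytest.mark.parametrize("g", [nx.cycle_graph(6), nx.Graph([(0, 1), (2, 3)])])
    def test_constant_degree_undefined(self, g):
        assert gm.assortativity_degree(g).coefficient is None

    def test_perfect_same_label_mixing(self):
        g = nx.Graph([(0, 1), (2, 3)])
        res = gm.assortativity_categorical(g, {0: "a", 1: "a", 2: "b", 3: "b"})
        assert res.coefficient == pytest.approx(1.0)

    def test_bipartite_k22_fully_disassortative(self):
        g = nx.complete_bipartite_graph(2, 2)
        labels = {n: ("L" if n < 2 else "R") for n in g}
        res = gm.assortativity_categorical(g, labels)
        assert res.coefficient == pytest.approx(
            categorical_assort_oracle(g, labels), abs=1e-12
        )
        assert res.coefficient < 0

    def test_label_renaming_invariance(self):
        g = nx.gnp_random_graph(12, 0.3, seed=5)
        labels = {n: n % 3 for n in g}
        renamed = {n: f"group-{v}" for n, v in labels.items()}
        r1 = gm.assortativity_categorical(g, labels).coefficient
        r2 = gm.assortativity_categorical(g, renamed).coefficient
        assert r1 == pytest.approx(r2, abs=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_naive_oracles_on_random_graphs(self, seed):
        g = nx.gnp_random_graph(50, 0.08, seed=seed)
        rd = gm.assortativity_degree(g).coefficient
        expected = degree_assort_oracle(g)
        assert rd == pytest.approx(expected, abs=1e-12)
        labels = {n: n % 4 for n in g}
        rc = gm.assortativity_categorical(g, labels).coefficient
        assert rc == pytest.approx(categorical_assort_oracle(g, labels), abs=1e-12)

    def test_unlabeled_node_rejected(self):
        with pytest.raises(ValueError):
            gm.assortativity_categorical(nx.path_graph(3), {0: "a", 1: "b"})


class TestAnnotation:
    def test_profiles_and_table(self, hierarchy):
        from adversome.dispro import ContingencyTable, SDRResult

        def sdr(drug, event, flag):
            return SDRResult(drug, event, ContingencyTable(5, 5, 5, 5, drug, event),
                             2.0, 1.5, 3.0, 1e-6, 10, 0.005, True, flag, flag, flag)

        net = IsingNetwork(
            ["Hepatocellular damage", "Diarrhoea symptoms"], np.zeros(2),
            np.array([[0.0, 0.8], [0.8, 0.0]]),
        )
        sdrs = [
            sdr("hydroxychloroquine", "Hepatocellular damage", True),
            sdr("azithromycin", "Hepatocellular damage", True),
            sdr("remdesivir", "Diarrhoea symptoms", False),
        ]
        profiles = gm.sdr_profiles(net.nodes, sdrs)
        assert profiles["Hepatocellular damage"] == ("azithromycin", "hydroxychloroquine")
        assert profiles["Diarrhoea symptoms"] == ()
        part = gm.louvain(net, seed=0)
        table = gm.annotate_nodes(net, sdrs, hierarchy, part).set_index("hlt")
        assert table.loc["Hepatocellular damage", "primary_soc"] == "Hepatobiliary disorders"
        assert table.loc["Hepatocellular damage", "degree"] == 1
        # profiles feed categorical assortativity as the disproportionality attribute
        res = gm.assortativity_categorical(net, profiles, "sdr_profile")
        assert res.coefficient is not None
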