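import numpy as np
import pytest

from adversome import adversome_net as an
from adversome.adversome_net import (
    DegenerateColumnError,
    EventMatrix,
    IsingNetwork,
    binarize,
    fit_ising,
    gibbs_sample,
    positive_subnetwork,
)
from adversome.faers_io import DrugEntry
from adversome import synthetic_data as sd

from conftest import make_report


def chain_model(p=6, w=1.0, tau=-1.0):
    W = np.zeros((p, p))
    for i in range(p - 1):
        W[i, i + 1] = W[i + 1, i] = w
    return np.full(p, tau), W


def edge_set(net: IsingNetwork):
    return {frozenset((a, b)) for a, b, _ in net.edges()}


class TestBinarize:
    def test_min_cases_filter(self, hierarchy):
        cohort = [make_report(str(i), reactions=("Hepatitis", "Diarrhoea")) for i in range(9)]
        cohort += [make_report(f"x{i}", reactions=("Diarrhoea",)) for i in range(3)]
        m = binarize(cohort, hierarchy, min_cases=10)
        assert m.columns == ["Diarrhoea symptoms"]  # Hepatitis HLT has only 9 cases
        assert m.X.sum() == 12

    def test_three_report_fixture_matrix(self, hierarchy):
        cohort = [
            make_report("0", reactions=("Hepatitis", "Diarrhoea")),
            make_report("1", reactions=("Hepatitis",)),
            make_report("2", reactions=("Diarrhoea",)),
        ]
        m = binarize(cohort, hierarchy, min_cases=1)
        # columns sorted by descending count then name
        assert m.columns == ["Diarrhoea symptoms", "Hepatocellular damage"]
        assert m.X.tolist() == [[1, 1], [0, 1], [1, 0]]

    def test_column_sums_match_generator_bookkeeping(self):
        cfg = sd.null_config(n_reports=500, seed=11)
        records, truth = sd.generate_records(cfg)
        import tempfile

        from adversome.meddra import load_hierarchy

        with tempfile.TemporaryDirectory() as td:
            sd.write_dictionary(cfg, f"{td}/d.tsv", f"{td}/s.tsv")
            h = load_hierarchy(f"{td}/d.tsv", f"{td}/s.tsv")
        m = binarize(records, h, min_cases=1)
        expected = truth.event_report_counts()
        assert m.column_counts() == {k: v for k, v in expected.items() if v >= 1}

    def test_no_surviving_column_raises_with_distribution(self, hierarchy):
        cohort = [make_report("0", reactions=("Hepatitis",))]
        with pytest.raises(DegenerateColumnError, match="min_cases"):
            binarize(cohort, hierarchy, min_cases=10)


class TestGibbsSampler:
    def test_independence_limit_matches_logistic_means(self):
        tau = np.array([-1.0, 0.0, 1.0])
        m = gibbs_sample(tau, np.zeros((3, 3)), n=5000, seed=5)
        target = 1 / (1 + np.exp(-tau))
        se = np.sqrt(target * (1 - target) / 5000)
        assert np.all(np.abs(m.X.mean(axis=0) - target) < 3 * se + 1e-9)

    def test_two_node_closed_form(self):
        tau = np.array([-0.5, 0.3])
        W = np.array([[0.0, 1.2], [1.2, 0.0]])
        # exact 4-state normalization
        states = [(0, 0), (0, 1), (1, 0), (1, 1)]
        weights = np.array([
            np.exp(tau[0] * x0 + tau[1] * x1 + W[0, 1] * x0 * x1) for x0, x1 in states
        ])
        probs = weights / weights.sum()
        n = 8000
        m = gibbs_sample(tau, W, n=n, burn_in=500, thin=2, seed=9)
        emp = np.array([
            np.mean((m.X[:, 0] == x0) & (m.X[:, 1] == x1)) for x0, x1 in states
        ])
        se = np.sqrt(probs * (1 - probs) / n)
        # thinned single-site Gibbs still autocorrelates; allow 4 SE
        assert np.all(np.abs(emp - probs) < 4 * se + 1e-9)

    def test_same_seed_reproduces_exactly(self):
        tau, W = chain_model()
        m1 = gibbs_sample(tau, W, 100, seed=42)
        m2 = gibbs_sample(tau, W, 100, seed=42)
        assert np.array_equal(m1.X, m2.X)

    def test_asymmetric_coupling_rejected(self):
        W = np.zeros((2, 2))
        W[0, 1] = 1.0
        with pytest.raises(ValueError):
            gibbs_sample(np.zeros(2), W, 10, seed=0)


class TestFitIsing:
    def test_chain_recovery(self):
        tau, W = chain_model()
        hits = 0
        for seed in range(5):
            m = gibbs_sample(tau, W, 3000, seed=seed)
            net = fit_ising(m)
            true = {frozenset((f"V{i}", f"V{i+1}")) for i in range(5)}
            hits += edge_set(net) == true
        assert hits >= 4

    def test_recovered_weights_positive_on_chain(self):
        tau, W = chain_model()
        m = gibbs_sample(tau, W, 4000, seed=1)
        net = fit_ising(m)
        for _, _, w in net.edges():
            assert w > 0

    def test_and_rule_subset_of_or_rule(self):
        tau, W = chain_model(w=0.6)
        m = gibbs_sample(tau, W, 1500, seed=3)
        net_and = fit_ising(m, rule="AND")
        net_or = fit_ising(m, rule="OR")
        assert edge_set(net_and) <= edge_set(net_or)

    def test_gamma_monotone_sparsity(self):
        tau, W = chain_model(w=0.6)
        m = gibbs_sample(tau, W, 1500, seed=4)
        counts = [fit_ising(m, gamma=g).n_edges() for g in (0.0, 0.25, 0.5)]
        assert counts[0] >= counts[1] >= counts[2]

    def test_row_permutation_invariant_column_equivariant(self):
        tau, W = chain_model(p=4)
        m = gibbs_sample(tau, W, 800, seed=6)
        net = fit_ising(m)
        rng = np.random.default_rng(0)
        rperm = rng.permutation(m.n)
        m_rows = EventMatrix([m.row_ids[i] for i in rperm], m.columns, m.X[rperm])
        assert np.allclose(fit_ising(m_rows).W, net.W, atol=1e-6)
        cperm = rng.permutation(m.p)
        m_cols = EventMatrix(m.row_ids, [m.columns[j] for j in cperm], m.X[:, cperm])
        net_c = fit_ising(m_cols)
        assert np.allclose(net_c.W, net.W[np.ix_(cperm, cperm)], atol=1e-6)

    def test_selected_model_beats_empty_on_pseudolikelihood(self):
        tau, W = chain_model()
        m = gibbs_sample(tau, W, 2000, seed=8)
        net = fit_ising(m)
        X = m.X.astype(float)

        def pseudo_ll(tau_v, W_m):
            eta = tau_v + X @ W_m
            return float(np.sum(X * eta - np.logaddexp(0.0, eta)))

        ybar = X.mean(axis=0)
        tau_empty = np.log(ybar / (1 - ybar))
        assert pseudo_ll(net.tau, net.W) >= pseudo_ll(tau_empty, np.zeros_like(net.W))

    def test_parameter_recovery_planted_sparse_model(self):
        # p = 12, 8 random edges of |w| = 1: sign agreement and Hamming distance
        rng = np.random.default_rng(2024)
        p = 12
        results = []
        for seed in range(5):
            W = np.zeros((p, p))
            pairs = rng.choice([(i, j) for i in range(p) for j in range(i + 1, p)],
                               size=8, replace=False)
            for i, j in pairs:
                w = rng.choice([-1.0, 1.0])
                W[i, j] = W[j, i] = w
            tau = -np.ones(p)
            m = gibbs_sample(tau, W, 4000, seed=seed)
            net = fit_ising(m)
            true_edges = {frozenset((f"V{i}", f"V{j}")) for i, j in pairs}
            est_edges = edge_set(net)
            hamming = len(true_edges ^ est_edges)
            idx = {n: k for k, n in enumerate(net.nodes)}
            signs = [
                np.sign(net.W[idx[f"V{i}"], idx[f"V{j}"]]) == np.sign(W[i, j])
                for i, j in pairs
                if frozenset((f"V{i}", f"V{j}")) in est_edges
            ]
            sign_agree = np.mean(signs) if signs else 0.0
            results.append((hamming, sign_agree))
        assert np.median([h for h, _ in results]) <= 2
        assert np.median([s for _, s in results]) >= 0.95

    def test_constant_column_rejected(self):
        X = np.zeros((50, 3), dtype=np.int8)
        X[:, 0] = np.arange(50) % 2
        X[:, 1] = np.arange(50) // 25
        m = EventMatrix([f"r{i}" for i in range(50)], ["A", "B", "C"], X)
        with pytest.raises(DegenerateColumnError, match="C"):
            fit_ising(m)

    def test_non_binary_input_rejected(self):
        with pytest.raises(TypeError):
            EventMatrix(["r0", "r1"], ["A", "B"], np.array([[0, 2], [1, 0]]))


class TestPositiveSubnetwork:
    def test_negative_edges_zeroed_nodes_kept(self):
        W = np.array([[0.0, 1.5, -0.7], [1.5, 0.0, 0.0], [-0.7, 0.0, 0.0]])
        net = IsingNetwork(["A", "B", "C"], np.zeros(3), W)
        pos = positive_subnetwork(net)
        assert pos.nodes == net.nodes
        assert edge_set(pos) == {frozenset(("A", "B"))}

    def test_all_positive_is_fixpoint(self):
        W = np.array([[0.0, 0.4], [0.4, 0.0]])
        net = IsingNetwork(["A", "B"], np.zeros(2), W)
        assert np.array_equal(positive_subnetwork(net).W, W)

    def test_all_negative_empties_edge_set(self):
        W = np.array([[0.0, -0.4], [-0.4, 0.0]])
        net = IsingNetwork(["A", "B"], np.zeros(2), W)
        assert positive_subnetwork(net).n_edges() == 0


class TestExports:
    def test_matrix_and_network_round_trip_files(self, tmp_path):
        from scipy import io as sio

        tau, W = chain_model(p=3)
        m = gibbs_sample(tau, W, 200, seed=0)
        an.write_event_matrix(m, tmp_path)
        X = np.asarray(sio.mmread(tmp_path / "event_matrix.mtx").todense())
        assert np.array_equal(X, m.X)
        net = IsingNetwork(["A", "B", "C"], np.zeros(3),
                           np.array([[0, 1.0, 0], [1.0, 0, -2.0], [0, -2.0, 0]]))
        an.write_network(net, tmp_path)
        edges = (tmp_path / "adversome_edges.tsv").read_text().splitlines()
        assert len(edges) == 3  # header + 2 edges
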