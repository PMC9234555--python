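"""Cross-correlation matrices, residue networks and centrality measures."""

import itertools

import numpy as np
import pytest

from _oracles import (
    brute_force_dccm,
    exhaustive_betweenness,
    exhaustive_closeness,
    random_weighted_graph,
)
from confdyn.corrnet import (
    DCCMatrix,
    ResidueNetwork,
    betweenness_centrality,
    build_network,
    centrality_difference,
    centrality_pearson,
    centrality_profile,
    closeness_centrality,
    compute_dccm,
    dccm_from_covariance,
    degree_centrality,
    select_central_residues,
)
from confdyn.essential_dynamics import build_covariance
from confdyn.synthetic_data import (
    GaussianTrajectorySpec,
    ca_topology,
    generate_gaussian_trajectory,
    helix_structure,
)
from confdyn.trajectory_core import Trajectory


def traj_from_coords(coords):
    coords = np.asarray(coords, float)
    return Trajectory(
        ca_topology(coords.shape[1]), coords, np.arange(coords.shape[0], dtype=float)
    )


def net_from_edges(nodes, edges) -> ResidueNetwork:
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(nodes)
    for pair, w in edges.items():
        u, v = sorted(pair)
        g.add_edge(u, v, weight=w, corr=np.exp(-w))
    return ResidueNetwork(graph=g, cmin=0.0)


class TestDccm:
    def test_diagonal_is_one(self, small_gaussian_traj):
        traj, _ = small_gaussian_traj
        C = compute_dccm(traj)
        assert np.allclose(np.diag(C.values), 1.0, atol=1e-10)
        assert np.allclose(C.values, C.values.T, atol=1e-12)
        assert C.values.min() >= -1.0 and C.values.max() <= 1.0

    def test_analytic_phase_limits(self):
        """Same-axis in-phase -> C=1; anti-phase -> C=-1; 90 deg -> C=0."""
        t = np.linspace(0, 4 * np.pi, 200)
        osc = np.sin(t)
        base = np.array([[0.0, 0, 0], [10.0, 0, 0]])

        def two_atom(disp_a, disp_b):
            coords = np.repeat(base[None], len(t), axis=0)
            coords[:, 0, :] += disp_a
            coords[:, 1, :] += disp_b
            return compute_dccm(traj_from_coords(coords), fit=False).values[0, 1]

        along_x = np.stack([osc, np.zeros_like(t), np.zeros_like(t)], axis=1)
        along_y = np.stack([np.zeros_like(t), osc, np.zeros_like(t)], axis=1)
        assert two_atom(along_x, along_x) == pytest.approx(1.0, abs=1e-10)
        assert two_atom(along_x, -along_x) == pytest.approx(-1.0, abs=1e-10)
        assert two_atom(along_x, along_y) == pytest.approx(0.0, abs=1e-10)

    def test_matches_brute_force_double_loop(self, rng):
        coords = rng.normal(size=(10, 5, 3)) + helix_structure(5)[None] * 3
        C = compute_dccm(traj_from_coords(coords), fit=False)
        oracle = brute_force_dccm(coords)
        assert np.max(np.abs(C.values - oracle)) < 1e-10

    def test_zero_fluctuation_residue_flagged(self):
        coords = np.zeros((50, 3, 3))
        coords[:, 0, 0] = np.sin(np.linspace(0, 6, 50))
        coords[:, 1, 0] = np.cos(np.linspace(0, 6, 50))
        coords[:, 2] = (5.0, 5.0, 5.0)  # frozen residue
        C = compute_dccm(traj_from_coords(coords), fit=False)
        assert C.undefined is not None and 2 in C.undefined
        assert C.values[2, 0] == 0.0
        assert C.values[2, 2] == 1.0

    def test_block_structure_recovered(self, small_gaussian_traj):
        traj, spec = small_gaussian_traj
        C = compute_dccm(traj, fit=False)
        target = spec.residue_correlation()
        assert np.max(np.abs(C.values - target)) < 0.08  # 2000 frames

    def test_from_covariance_consistent_with_direct(self, small_gaussian_traj):
        traj, _ = small_gaussian_traj
        model = build_covariance(traj, fit=False)
        via_cov = dccm_from_covariance(model)
        direct = compute_dccm(traj, fit=False)
        assert np.max(np.abs(via_cov.values - direct.values)) < 1e-8

    def test_from_identity_and_rank_one_covariance(self, small_gaussian_traj):
        traj, _ = small_gaussian_traj
        model = build_covariance(traj, fit=False)
        n = model.n_atoms
        model.covariance = np.eye(3 * n)
        assert np.allclose(dccm_from_covariance(model).values, np.eye(n))
        v = np.tile([1.0, 0.0, 0.0], n)
        model.covariance = np.outer(v, v)
        assert np.allclose(dccm_from_covariance(model).values, 1.0)


class TestNetworkConstruction:
    def make_dccm(self, values):
        values = np.asarray(values, float)
        return DCCMatrix(values=values, resids=np.arange(1, len(values) + 1))

    def test_edge_weights_are_minus_log_abs_corr(self):
        C = np.eye(3)
        C[0, 1] = C[1, 0] = 0.5
        C[1, 2] = C[2, 1] = -1.0
        net = build_network(self.make_dccm(C), cmin=0.3)
        assert net.graph[1][2]["weight"] == pytest.approx(np.log(2.0))
        assert net.graph[2][3]["weight"] == pytest.approx(0.0)

    def test_threshold_excludes_weak_edges(self):
        C = np.eye(2)
        C[0, 1] = C[1, 0] = 0.2
        net = build_network(self.make_dccm(C), cmin=0.3)
        assert net.graph.number_of_edges() == 0

    def test_weight_monotone_in_correlation(self):
        cs = np.linspace(0.3, 1.0, 10)
        omegas = []
        for c in cs:
            C = np.eye(2)
            C[0, 1] = C[1, 0] = c
            net = build_network(self.make_dccm(C), cmin=0.1)
            omegas.append(net.graph[1][2]["weight"])
        assert np.all(np.diff(omegas) < 0)

    def test_contact_filter(self):
        C = np.ones((3, 3))
        ref = np.array([[0.0, 0, 0], [3.0, 0, 0], [30.0, 0, 0]])
        net = build_network(
            self.make_dccm(C), cmin=0.3, contact_cutoff=10.0, reference_coords=ref
        )
        assert net.graph.has_edge(1, 2)
        assert not net.graph.has_edge(1, 3)
        assert not net.graph.has_edge(2, 3)


class TestCentralities:
    def path_graph(self):
        return net_from_edges(
            [1, 2, 3], {frozenset((1, 2)): 1.0, frozenset((2, 3)): 1.0}
        )

    def test_degree_on_path_and_isolated(self):
        net = net_from_edges(
            [1, 2, 3, 4], {frozenset((1, 2)): 1.0, frozenset((2, 3)): 1.0}
        )
        cd = degree_centrality(net)
        assert list(cd) == [1, 2, 1, 0]

    def test_degree_complete_graph(self):
        edges = {frozenset(p): 0.7 for p in itertools.combinations(range(4), 2)}
        cd = degree_centrality(net_from_edges(range(4), edges))
        assert (cd == 3).all()

    def test_closeness_on_path(self):
        cc = closeness_centrality(self.path_graph())
        assert cc[2] == pytest.approx(1.0)
        assert cc[1] == pytest.approx(2.0 / 3.0)
        assert cc[3] == pytest.approx(2.0 / 3.0)

    def test_closeness_complete_unit_graph(self):
        edges = {frozenset(p): 1.0 for p in itertools.combinations(range(5), 2)}
        cc = closeness_centrality(net_from_edges(range(5), edges))
        assert np.allclose(cc, 1.0)

    def test_betweenness_path_and_cycle(self):
        cb = betweenness_centrality(self.path_graph())
        assert cb[2] == pytest.approx(1.0 / 3.0)
        assert cb[1] == pytest.approx(0.0)
        # 4-cycle with tied alternative paths: each node carries 1/12
        cyc = net_from_edges(
            range(4),
            {
                frozenset((0, 1)): 1.0,
                frozenset((1, 2)): 1.0,
                frozenset((2, 3)): 1.0,
                frozenset((3, 0)): 1.0,
            },
        )
        cb4 = betweenness_centrality(cyc)
        assert np.allclose(cb4, 1.0 / 12.0)

    def test_matches_exhaustive_oracle_on_random_graphs(self):
        """Dijkstra/Brandes vs exhaustive simple-path enumeration."""
        rng = np.random.default_rng(99)
        for _ in range(30):
            nodes, edges = random_weighted_graph(rng)
            net = net_from_edges(nodes, edges)
            cb = betweenness_centrality(net)
            cc = closeness_centrality(net)
            cb_oracle = exhaustive_betweenness(nodes, edges)
            cc_oracle = exhaustive_closeness(nodes, edges)
            for n in nodes:
                assert cb[n] == pytest.approx(cb_oracle[n], abs=1e-10)
                assert cc[n] == pytest.approx(cc_oracle[n], abs=1e-10)
            # sum rule against the oracle's total
            assert sum(cb) == pytest.approx(sum(cb_oracle.values()), abs=1e-10)

    def test_permutation_equivariance(self, rng):
        nodes, edges = random_weighted_graph(rng)
        perm = {n: p for n, p in zip(nodes, rng.permutation(len(nodes)))}
        relabeled = {
            frozenset((perm[u], perm[v])): w
            for (u, v), w in ((tuple(k), v) for k, v in edges.items())
        }
        cb1 = betweenness_centrality(net_from_edges(nodes, edges))
        cb2 = betweenness_centrality(
            net_from_edges([perm[n] for n in nodes], relabeled)
        )
        for n in nodes:
            assert cb1[n] == pytest.approx(cb2[perm[n]], abs=1e-12)


class TestProfilesAndDifferences:
    def make_profile(self, cb):
        from confdyn.corrnet import CentralityProfile

        n = len(cb)
        return CentralityProfile(
            resids=np.arange(1, n + 1),
            degree=np.ones(n, dtype=int),
            closeness=np.linspace(0.1, 1, n),
            betweenness=np.asarray(cb, float),
        )

    def test_identical_profiles_no_differences(self):
        p = self.make_profile([0.1, 0.2, 0.3])
        delta, selected = centrality_difference(p, p, threshold=0.12)
        assert len(selected) == 0
        assert np.allclose(delta, 0.0)

    def test_planted_shift_detected(self):
        a = self.make_profile([0.1, 0.2, 0.3])
        b = self.make_profile([0.1, 0.4, 0.3])
        _, selected = centrality_difference(a, b, threshold=0.12)
        assert list(selected) == [2]
        _, all_sel = centrality_difference(a, b, threshold=0.0)
        assert len(all_sel) == 3

    def test_absolute_selection(self):
        p = self.make_profile([0.05, 0.151, 0.29])
        assert list(select_central_residues(p, threshold=0.15)) == [2, 3]

    def test_mismatched_residue_sets_rejected(self):
        a = self.make_profile([0.1, 0.2])
        b = self.make_profile([0.1, 0.2, 0.3])
        with pytest.raises(ValueError, match="different residue sets"):
            centrality_difference(a, b)

    def test_pearson_matrix(self, rng):
        from confdyn.corrnet import CentralityProfile

        n = 1000
        p = CentralityProfile(
            resids=np.arange(n),
            degree=rng.integers(1, 10, n),
            closeness=rng.random(n),
            betweenness=rng.random(n),
        )
        r = centrality_pearson(p)
        assert np.allclose(np.diag(r), 1.0)
        assert abs(r.loc["C_c", "C_B"]) < 0.1  # independent columns
        # self vs negation through a crafted profile
        q = CentralityProfile(
            resids=np.arange(n),
            degree=p.degree,
            closeness=p.closeness,
            betweenness=-p.closeness,
        )
        assert centrality_pearson(q).loc["C_c", "C_B"] == pytest.approx(-1.0)

    def test_profile_from_planted_block_network(self, small_gaussian_traj):
        traj, spec = small_gaussian_traj
        C = compute_dccm(traj, fit=False)
        net = build_network(C, cmin=0.3)
        profile = centrality_profile(net)
        # block residues (1-5) are densely interconnected; others isolated
        assert profile.degree[:5].min() >= 4
        assert profile.degree[5:].max() == 0
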