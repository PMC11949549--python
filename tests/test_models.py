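"""Maximum-entropy ensembles: fitting, probabilities, sampling, likelihood."""

import numpy as np
import pytest
from scipy.optimize import root

import neuromaxent as nm
from conftest import random_adjacency, net_from_adjacency


def degree_equations_oracle(k_star, mask=None):
    """Solve the degree constraints with a generic nonlinear root finder.

    Independent of the fixed-point path: parametrise by theta_i, solve
    k_i* = sum_j p_ij with scipy.optimize.root, return the p matrix.
    """
    k_star = np.asarray(k_star, dtype=float)
    n = len(k_star)

    def eqs(theta):
        x = np.exp(theta)
        p = 1.0 / (1.0 + np.outer(x, x))
        np.fill_diagonal(p, 0.0)
        if mask is not None:
            p = p * mask
        return p.sum(axis=1) - k_star

    sol = root(eqs, np.zeros(n), tol=1e-13)
    assert sol.success
    x = np.exp(sol.x)
    p = 1.0 / (1.0 + np.outer(x, x))
    np.fill_diagonal(p, 0.0)
    if mask is not None:
        p = p * mask
    return p


class TestDegreeModel:
    def test_regular_sequence_gives_uniform_p(self):
        model = nm.fit_degree_model([2, 2, 2, 2])
        assert np.allclose(model.probabilities(), 2.0 / 3.0)

    def test_zero_degree_node_and_forced_triangle(self):
        model = nm.fit_degree_model([0, 2, 2, 2])
        p = model.probabilities()
        # node 0 isolated; the remaining triangle is forced to p = 1
        assert np.allclose(p, [0, 0, 0, 1, 1, 1])
        assert len(model.boundary_nodes) == 3

    def test_matches_generic_solver_on_five_nodes(self):
        k_star = np.array([1.0, 1.0, 2.0, 2.0, 2.0])
        model = nm.fit_degree_model(k_star)
        p_oracle = degree_equations_oracle(k_star)
        iu, ju = np.triu_indices(5, k=1)
        assert np.abs(model.probabilities() - p_oracle[iu, ju]).max() < 1e-6

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_generic_solver_on_small_graphs(self, seed):
        """Realized degree sequences of random graphs with n <= 8."""
        from conftest import is_interior_sequence

        rng = np.random.default_rng(seed)
        while True:
            n = int(rng.integers(4, 9))
            a = random_adjacency(rng, n, rng.uniform(0.3, 0.7))
            k_star = a.sum(axis=1).astype(float)
            if is_interior_sequence(k_star):
                break
        model = nm.fit_degree_model(k_star, tol=1e-10)
        p_oracle = degree_equations_oracle(k_star)
        iu, ju = np.triu_indices(n, k=1)
        assert np.abs(model.probabilities() - p_oracle[iu, ju]).max() < 1e-6
        assert model.residual <= 1e-6

    def test_target_degrees_reproduced_within_tolerance(self, small_scenario):
        k = small_scenario.connectome.degrees()
        model = nm.fit_degree_model(k, node_ids=small_scenario.nodes.ids)
        err = np.abs(model.expected_degrees() - k) / np.maximum(k, 1)
        assert err.max() <= 1e-6

    def test_infeasible_degree_raises(self):
        with pytest.raises(nm.InfeasibleConstraintsError):
            nm.fit_degree_model([5, 1, 1, 1])


class TestHardContactModel:
    def test_mask_forces_zero_probability(self, small_scenario):
        scen = small_scenario
        k = scen.connectome.degrees()
        mask = scen.contactome.edges.condensed_mask(scen.nodes)
        model = nm.fit_degree_model(k, node_ids=scen.nodes.ids,
                                    hard_mask=mask)
        p = model.probabilities()
        assert np.all(p[~mask] == 0.0)
        err = np.abs(model.expected_degrees() - k) / np.maximum(k, 1)
        assert err.max() <= 1e-6

    def test_degree_above_mask_degree_is_infeasible(self):
        # path a-b-c: node a has a single allowed partner but target 2
        mask = np.array([True, False, True])  # pairs (0,1),(0,2),(1,2)
        with pytest.raises(nm.InfeasibleConstraintsError):
            nm.fit_degree_model([2, 2, 2], hard_mask=mask)

    def test_matches_generic_solver_with_mask(self):
        rng = np.random.default_rng(0)  # draw with an interior solution
        n = 7
        cont = random_adjacency(rng, n, 0.8)
        sub = cont & random_adjacency(rng, n, 0.7)
        k_star = sub.sum(axis=1).astype(float)
        iu, ju = np.triu_indices(n, k=1)
        model = nm.fit_degree_model(k_star, hard_mask=cont[iu, ju],
                                    tol=1e-10)
        assert model.forced_mask is None or not model.forced_mask.any()
        p_oracle = degree_equations_oracle(k_star, mask=cont.astype(float))
        assert np.abs(model.probabilities() - p_oracle[iu, ju]).max() < 1e-6


class TestDegreeWiringModel:
    def test_equal_distances_reduce_to_model_k(self):
        k_star = np.array([1.0, 1.5, 2.0, 1.5])
        # regular tetrahedron: all six pair distances equal
        pos = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                       dtype=float)
        nodes = nm.NodeTable(list("abcd"), pos)
        d = nm.condensed_distances(nodes)
        mk = nm.fit_degree_model(k_star, tol=1e-10)
        L_star = float((mk.probabilities() * d).sum())
        mkl = nm.fit_degree_wiring_model(k_star, L_star, d, tol_k=1e-10,
                                         tol_L=1e-8)
        assert np.allclose(mkl.probabilities(), mk.probabilities(),
                           atol=1e-5)

    def test_large_d0_limit_matches_model_k(self):
        rng = np.random.default_rng(2)
        nodes = nm.generate_positions(30, seed=2)
        d = nm.condensed_distances(nodes)
        k_star = 1.0 + 3.0 * rng.random(30)
        mk = nm.fit_degree_model(k_star, tol=1e-10)
        L_star = float((mk.probabilities() * d).sum())
        mkl = nm.fit_degree_wiring_model(k_star, L_star, d,
                                         d0_bracket=(1.0, 1e6))
        assert np.abs(mkl.probabilities() - mk.probabilities()).max() < 1e-3

    def test_planted_parameter_recovery(self, kl_truth):
        nodes, d, x_true, d0_true, k_star, L_star, _ = kl_truth
        model = nm.fit_degree_wiring_model(k_star, L_star, d,
                                           node_ids=nodes.ids)
        assert abs(model.d0 - d0_true) / d0_true < 0.10
        from scipy.stats import spearmanr
        assert spearmanr(x_true, model.x).statistic > 0.9

    def test_wiring_residual_below_tolerance(self, kl_truth):
        nodes, d, _, _, k_star, L_star, _ = kl_truth
        model = nm.fit_degree_wiring_model(k_star, L_star, d)
        assert abs(model.expected_wiring_length() - L_star) / L_star <= 1e-4

    def test_bad_bracket_raises(self, kl_truth):
        _, d, _, _, k_star, L_star, _ = kl_truth
        with pytest.raises(ValueError, match="bracket"):
            nm.fit_degree_wiring_model(k_star, L_star, d,
                                       d0_bracket=(1e3, 1e5))


class TestDistanceModel:
    def test_single_bin_probability_is_edge_fraction(self):
        nodes = nm.NodeTable(list("abcd"),
                             [[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        edges = nm.EdgeList([("a", "b")])
        model = nm.fit_distance_model(nodes, edges, n_bins=1)
        assert np.allclose(model.probabilities(), 1.0 / 6.0)

    def test_default_is_50_linear_bins(self, small_scenario):
        model = nm.fit_distance_model(small_scenario.nodes,
                                      small_scenario.connectome.edges)
        assert model.bin_table.n_bins == 50
        widths = np.diff(model.bin_table.bin_edges)
        assert np.allclose(widths, widths[0])

    @pytest.mark.parametrize("n_bins", [2, 7, 50])
    def test_expected_edge_total_equals_observed(self, small_scenario,
                                                 n_bins):
        scen = small_scenario
        model = nm.fit_distance_model(scen.nodes, scen.connectome.edges,
                                      n_bins=n_bins)
        assert model.expected_edge_count() == pytest.approx(
            scen.connectome.n_edges, abs=1e-6)

    def test_conditional_variant_respects_mask_and_edge_total(
            self, small_scenario):
        scen = small_scenario
        mask = scen.contactome.edges.condensed_mask(scen.nodes)
        model = nm.fit_distance_model(scen.nodes, scen.connectome.edges,
                                      hard_mask=mask)
        p = model.probabilities()
        assert np.all(p[~mask] == 0.0)
        assert model.expected_edge_count() == pytest.approx(
            scen.connectome.n_edges, abs=1e-6)


class TestUniformContactModel:
    def test_uniform_probability(self):
        mask = np.zeros(45, dtype=bool)
        mask[:40] = True
        model = nm.fit_uniform_contact_model(10, mask,
                                             [f"n{i}" for i in range(10)])
        assert model.uniform_p == pytest.approx(0.25)
        p = model.probabilities()
        assert np.all(p[mask] == 0.25) and np.all(p[~mask] == 0.0)

    def test_zero_edges(self):
        mask = np.ones(3, dtype=bool)
        model = nm.fit_uniform_contact_model(0, mask, list("abc"))
        assert np.all(model.probabilities() == 0.0)

    def test_mouse_table_arithmetic(self):
        # printed edge counts for the mouse: 111,636 synaptic in
        # 1,373,875 contact pairs -> p ~ 0.0813
        assert 111_636 / 1_373_875 == pytest.approx(0.08125, abs=5e-5)

    def test_infeasible_edge_count(self):
        with pytest.raises(nm.InfeasibleConstraintsError):
            nm.fit_uniform_contact_model(5, np.zeros(3, dtype=bool), "abc")


class TestEdgeProbability:
    def test_closed_forms(self):
        m = nm.FittedEnsemble(kind="k", node_ids=("a", "b"),
                              x=np.array([1.0, 1.0]))
        assert m.edge_probability(("a", "b")) == pytest.approx(0.5)
        mkl = nm.FittedEnsemble(kind="k+L", node_ids=("a", "b"),
                                x=np.array([1.0, 1.0]), d0=3.0)
        assert mkl.edge_probability(("a", "b"), distance=3.0) == \
            pytest.approx(1.0 / (1.0 + np.e))

    def test_pair_outside_mask_is_zero(self):
        mask = np.array([True, False, True])
        m = nm.FittedEnsemble(kind="k+c", node_ids=("a", "b", "c"),
                              x=np.ones(3), hard_mask=mask)
        assert m.edge_probability(("a", "c")) == 0.0
        assert m.edge_probability(("c", "a")) == m.edge_probability(("a", "c"))

    def test_unknown_pair_is_an_error(self):
        m = nm.FittedEnsemble(kind="k", node_ids=("a", "b"), x=np.ones(2))
        with pytest.raises(KeyError):
            m.edge_probability(("a", "z"))


class TestSampling:
    def test_forced_pairs_always_present(self):
        mask = np.array([True, True, False])
        m = nm.fit_uniform_contact_model(2, mask, list("abc"))
        assert m.uniform_p == 1.0
        for real in nm.sample_ensemble(m, seed=0, n_realizations=5):
            assert real.pairs == {("a", "b"), ("a", "c")}

    def test_identical_seed_identical_output(self, small_scenario):
        scen = small_scenario
        model = nm.fit_degree_model(scen.connectome.degrees(),
                                    node_ids=scen.nodes.ids)
        s1 = nm.sample_ensemble(model, seed=9, n_realizations=3)
        s2 = nm.sample_ensemble(model, seed=9, n_realizations=3)
        assert all(a.pairs == b.pairs for a, b in zip(s1, s2))

    def test_hard_constraint_never_violated(self, small_scenario):
        scen = small_scenario
        k = scen.connectome.degrees()
        mask = scen.contactome.edges.condensed_mask(scen.nodes)
        model = nm.fit_degree_model(k, node_ids=scen.nodes.ids,
                                    hard_mask=mask)
        for real in nm.sample_ensemble(model, seed=1, n_realizations=20):
            assert real.pairs <= scen.contactome.edges.pairs

    def test_sampled_degrees_match_targets(self):
        """Per-node mean degree over realizations within 3 binomial SE."""
        rng = np.random.default_rng(8)
        k_star = 2.0 + 6.0 * rng.random(50)
        model = nm.fit_degree_model(k_star)
        R = 200
        samples = nm.sample_ensemble(model, seed=4, n_realizations=R)
        nodes = nm.generate_positions(50, seed=0)
        degs = np.array([nm.SpatialNetwork(nodes, e).degrees()
                         for e in samples], dtype=float)
        mean_deg = degs.mean(axis=0)
        p = model.probabilities()
        iu, ju = np.triu_indices(50, k=1)
        var = np.zeros(50)
        np.add.at(var, iu, p * (1 - p))
        np.add.at(var, ju, p * (1 - p))
        se = np.sqrt(var / R)
        frac_ok = np.mean(np.abs(mean_deg - k_star) <= 3 * se)
        assert frac_ok >= 0.95

    def test_pair_frequency_matches_probability(self):
        """Empirical edge frequency of fixed pairs inside binomial CI."""
        model = nm.fit_degree_model([1.2, 1.8, 1.8, 1.2])
        p = model.probabilities()
        R = 1000
        samples = nm.sample_ensemble(model, seed=11, n_realizations=R)
        ids = model.node_ids
        iu, ju = np.triu_indices(4, k=1)
        freq = np.array([np.mean([(ids[i], ids[j]) in e.pairs
                                  for e in samples])
                         for i, j in zip(iu, ju)])
        se = np.sqrt(p * (1 - p) / R)
        assert np.all(np.abs(freq - p) <= 4 * se + 1e-12)


class TestLogLikelihood:
    def test_two_node_edge(self):
        nodes = nm.NodeTable(["a", "b"], [[0, 0, 0], [1, 0, 0]])
        net = nm.SpatialNetwork(nodes, nm.EdgeList([("a", "b")]))
        model = nm.FittedEnsemble(kind="k", node_ids=("a", "b"),
                                  x=np.array([1.0, 1.0]))
        assert nm.log_likelihood(model, net) == pytest.approx(np.log(0.5))

    def test_edge_outside_mask_gives_minus_inf_with_pairs(self):
        nodes = nm.NodeTable(list("abc"), np.eye(3))
        net = nm.SpatialNetwork(nodes, nm.EdgeList([("a", "c")]))
        mask = np.array([True, False, True])
        model = nm.fit_uniform_contact_model(1, mask, list("abc"))
        value, offenders = nm.log_likelihood(model, net,
                                             return_diagnostics=True)
        assert value == float("-inf")
        assert offenders == [("a", "c")]

    def test_ordering_on_planted_degree_wiring_truth(self, kl_truth):
        """Fitted k+L beats fitted k and fitted d on k+L-planted data."""
        nodes, d, _, _, _, _, p_true = kl_truth
        rng = np.random.default_rng(17)
        iu, ju = np.triu_indices(len(nodes), k=1)
        hit = rng.random(len(p_true)) < p_true
        edges = nm.EdgeList((nodes.ids[i], nodes.ids[j])
                            for i, j in zip(iu[hit], ju[hit]))
        obs = nm.SpatialNetwork(nodes, edges)
        k_obs = obs.degrees()
        mk = nm.fit_degree_model(k_obs, node_ids=nodes.ids)
        mkl = nm.fit_degree_wiring_model(k_obs, obs.wiring_length(), d,
                                         node_ids=nodes.ids)
        md = nm.fit_distance_model(nodes, edges)
        ll_k = nm.log_likelihood(mk, obs)
        ll_kl = nm.log_likelihood(mkl, obs, distances=d)
        ll_d = nm.log_likelihood(md, obs)
        assert ll_kl > ll_k
        assert ll_kl > ll_d


class TestPersistence:
    @pytest.mark.parametrize("kind", ["k", "k+c", "k+L", "d", "c"])
    def test_json_roundtrip_preserves_probabilities(self, tmp_path, kind,
                                                    small_scenario):
        scen = small_scenario
        d = nm.condensed_distances(scen.nodes)
        k = scen.connectome.degrees()
        mask = scen.contactome.edges.condensed_mask(scen.nodes)
        if kind == "k":
            model = nm.fit_degree_model(k, node_ids=scen.nodes.ids)
        elif kind == "k+c":
            model = nm.fit_degree_model(k, node_ids=scen.nodes.ids,
                                        hard_mask=mask)
        elif kind == "k+L":
            model = nm.fit_degree_wiring_model(
                k, scen.connectome.wiring_length(), d,
                node_ids=scen.nodes.ids)
        elif kind == "d":
            model = nm.fit_distance_model(scen.nodes, scen.connectome.edges)
        else:
            model = nm.fit_uniform_contact_model(scen.connectome.n_edges,
                                                 mask, scen.nodes.ids)
        path = tmp_path / "model.json"
        model.save(path)
        back = nm.FittedEnsemble.load(path)
        assert back.kind == model.kind
        assert np.allclose(back.probabilities(distances=d),
                           model.probabilities(), atol=1e-12)


class TestInvariants:
    @pytest.mark.parametrize("kind", ["k", "k+L", "d", "c", "d+c", "k+c"])
    def test_probability_bounds_and_edge_total(self, kind, small_scenario):
        """0 <= p <= 1 and sum p = E for every ensemble kind."""
        scen = small_scenario
        d = nm.condensed_distances(scen.nodes)
        k = scen.connectome.degrees()
        E = scen.connectome.n_edges
        mask = scen.contactome.edges.condensed_mask(scen.nodes)
        if kind == "k":
            model = nm.fit_degree_model(k, node_ids=scen.nodes.ids)
        elif kind == "k+L":
            model = nm.fit_degree_wiring_model(
                k, scen.connectome.wiring_length(), d,
                node_ids=scen.nodes.ids)
        elif kind == "d":
            model = nm.fit_distance_model(scen.nodes, scen.connectome.edges)
        elif kind == "c":
            model = nm.fit_uniform_contact_model(E, mask, scen.nodes.ids)
        elif kind == "d+c":
            model = nm.fit_distance_model(scen.nodes, scen.connectome.edges,
                                          hard_mask=mask)
        else:
            model = nm.fit_degree_model(k, node_ids=scen.nodes.ids,
                                        hard_mask=mask)
        p = model.probabilities(distances=d)
        assert np.all((p >= 0) & (p <= 1))
        assert p.sum() == pytest.approx(E, rel=1e-4)
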