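"""Unit and property tests for the LP network model."""

import numpy as np
import pytest

from flowcircuit import (
    ActivationMatrix,
    ModelConfig,
    RegionGraph,
    assemble_lp,
    canonicalize_graph,
    compute_gamma,
    enhanced_capacities,
    extract_circuit,
    solve_flow,
    solve_joint_model,
    validate_solution,
)

from conftest import random_instance
from _oracle import oracle_objective


def three_node_example():
    """Two-edge triangle fragment with a weak alternative link.

    Demand at i (1.0) pushes the strong edge past its capacity; enlarging
    that capacity is cheaper than routing the remainder over the weak edge.
    """
    g = RegionGraph(("i", "j", "k"), ((0, 1), (0, 2)), np.array([0.99, 0.01]))
    R = ActivationMatrix(np.array([[1.0], [0.99], [0.0]]), ("m",))
    cfg = ModelConfig(gamma=1.0, rho=1.0)
    return g, R, cfg


class TestCanonicalizeGraph:
    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="no structural signal"):
            canonicalize_graph(np.zeros((3, 3)))

    def test_max_entry_maps_to_one(self):
        g = canonicalize_graph(np.array([[0.0, 50.0], [50.0, 0.0]]))
        assert g.capacity[0] == pytest.approx(1.0)
        assert g.edges == ((0, 1),)

    def test_normalization_and_floor(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 50.0
        w[0, 2] = w[2, 0] = 5.0
        g = canonicalize_graph(w, ["a", "b", "c"])
        caps = dict(zip(g.edges, g.capacity))
        assert caps[(0, 1)] == pytest.approx(1.0)
        assert caps[(0, 2)] == pytest.approx(0.1)
        assert caps[(1, 2)] == pytest.approx(1e-4)  # floored absent pair

    def test_complete_candidate_set(self):
        w = np.zeros((5, 5))
        w[0, 1] = w[1, 0] = 3.0
        g = canonicalize_graph(w)
        assert g.n_edges == 10

    def test_asymmetric_names_cell(self):
        w = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="asymmetric"):
            canonicalize_graph(w, ["a", "b"])

    def test_negative_rejected(self):
        w = np.array([[0.0, -1.0], [-1.0, 0.0]])
        with pytest.raises(ValueError, match="negative"):
            canonicalize_graph(w, ["a", "b"])


class TestComputeGamma:
    def test_two_nodes(self):
        g = RegionGraph(("a", "b"), ((0, 1),), np.array([1.0]))
        R = ActivationMatrix(np.array([[1.0], [0.5]]), ("m",))
        assert compute_gamma(g, R) == pytest.approx(1.0)

    def test_all_zero_activation(self):
        g = RegionGraph(("a", "b"), ((0, 1),), np.array([1.0]))
        R = ActivationMatrix(np.zeros((2, 1)), ("m",))
        assert compute_gamma(g, R) == 0.0

    def test_three_node_complete(self):
        g = RegionGraph(("a", "b", "c"), ((0, 1), (0, 2), (1, 2)),
                        np.array([0.5, 0.5, 0.5]))
        R = ActivationMatrix(np.array([[2.0], [1.0], [1.0]]), ("m",))
        assert compute_gamma(g, R) == pytest.approx(2.0)


class TestAssembleLP:
    def test_minimal_shape(self):
        g = RegionGraph(("a", "b"), ((0, 1),), np.array([1.0]))
        R = ActivationMatrix(np.array([[1.0], [0.5]]), ("m",))
        lp = assemble_lp(g, R, ModelConfig(gamma=1.0))
        assert lp.n_variables == 2  # one flow + one correction
        assert lp.A_ub.shape[0] == 4  # 1 capacity + 2 demand + 1 feasibility

    def test_phantom_scale_variable_count(self):
        n = 16
        w = np.ones((n, n)) - np.eye(n)
        g = canonicalize_graph(w)
        R = ActivationMatrix(np.ones((n, 5)), tuple("abcde"))
        lp = assemble_lp(g, R, ModelConfig(gamma=1.0))
        assert lp.n_variables == 120 * 5 + 120

    def test_zero_mode_forces_zero_flow(self):
        g = RegionGraph(("a", "b"), ((0, 1),), np.array([1.0]))
        R = ActivationMatrix(np.array([[1.0, 0.0], [0.5, 0.0]]), ("m1", "m2"))
        cfg = ModelConfig(gamma=1.0)
        sol = solve_flow(assemble_lp(g, R, cfg), cfg)
        assert np.all(sol.flows[:, 1] == 0.0)


class TestSolveFlow:
    def test_zero_demand(self):
        g = RegionGraph(("a", "b"), ((0, 1),), np.array([1.0]))
        R = ActivationMatrix(np.zeros((2, 1)), ("m",))
        with pytest.warns(UserWarning, match="all-zero"):
            sol = solve_joint_model(g, R, ModelConfig(gamma=1.0))
        assert sol.objective_value == 0.0
        assert np.all(sol.flows == 0) and np.all(sol.corrections == 0)

    def test_two_node_vertex(self):
        g = RegionGraph(("a", "b"), ((0, 1),), np.array([1.0]))
        R = ActivationMatrix(np.array([[1.0], [0.5]]), ("m",))
        cfg = ModelConfig(gamma=1.0, rho=1.0)
        sol = solve_flow(assemble_lp(g, R, cfg), cfg)
        assert sol.is_optimal
        assert sol.objective_value == pytest.approx(1.0, abs=1e-9)
        assert sol.flows[0, 0] == pytest.approx(1.0, abs=1e-9)
        assert sol.corrections[0] == pytest.approx(0.0, abs=1e-9)

    def test_three_node_correction_vertex(self):
        # frozen from a one-dimensional line search over the correction p,
        # with the strong-edge flow at 0.99 + p and the weak edge covering
        # the remainder of node i's demand
        g, R, cfg = three_node_example()
        sol = solve_flow(assemble_lp(g, R, cfg), cfg)
        assert sol.is_optimal
        expected = 1.0 / 0.99 + (1.0 + 1.0 / 0.99) * 0.01
        assert sol.objective_value == pytest.approx(expected, abs=1e-9)
        assert sol.flows[0, 0] == pytest.approx(1.0, abs=1e-8)
        assert sol.flows[1, 0] == pytest.approx(0.0, abs=1e-8)
        assert sol.corrections[0] == pytest.approx(0.01, abs=1e-8)

    def test_infeasible_reports_worst_demand(self):
        # node a demands flow but has no incident edge: unsatisfiable
        g = RegionGraph(("a", "b", "c"), ((1, 2),), np.array([1.0]))
        R = ActivationMatrix(np.array([[1.0], [0.0], [0.0]]), ("m",))
        cfg = ModelConfig(gamma=1.0, rho=1.0)
        sol = solve_flow(assemble_lp(g, R, cfg), cfg, g, R)
        assert sol.solver_status == "infeasible"
        assert "node a" in sol.message


class TestValidateSolution:
    def test_zero_problem_zero_residuals(self):
        g = RegionGraph(("a", "b"), ((0, 1),), np.array([1.0]))
        R = ActivationMatrix(np.zeros((2, 1)), ("m",))
        cfg = ModelConfig(gamma=1.0)
        with pytest.warns(UserWarning, match="all-zero"):
            sol = solve_joint_model(g, R, cfg)
        assert sol.max_residual == 0.0

    def test_hand_solution_residuals(self):
        g, R, cfg = three_node_example()
        sol = solve_flow(assemble_lp(g, R, cfg), cfg)
        report = validate_solution(g, R, cfg, sol)
        assert max(report.values()) <= 1e-8

    def test_perturbed_solution_flagged(self):
        from dataclasses import replace

        g, R, cfg = three_node_example()
        sol = solve_flow(assemble_lp(g, R, cfg), cfg)
        bad_flows = sol.flows.copy()
        bad_flows[0, 0] += 1.0  # violates capacity and feasibility
        bad = replace(sol, flows=bad_flows)
        with pytest.raises(ValueError, match="constraint violated"):
            validate_solution(g, R, cfg, bad)


class TestCircuitsAndEnhancement:
    def test_empty_circuit(self):
        g = RegionGraph(("a", "b"), ((0, 1),), np.array([1.0]))
        R = ActivationMatrix(np.zeros((2, 1)), ("m",))
        cfg = ModelConfig(gamma=1.0)
        sol = solve_flow(assemble_lp(g, R, cfg), cfg)
        circuit = extract_circuit(sol, g, 0, cfg, ("m",))
        assert circuit.edges == ()

    def test_two_node_circuit(self):
        g = RegionGraph(("a", "b"), ((0, 1),), np.array([1.0]))
        R = ActivationMatrix(np.array([[1.0], [0.5]]), ("m",))
        cfg = ModelConfig(gamma=1.0)
        sol = solve_flow(assemble_lp(g, R, cfg), cfg)
        circuit = extract_circuit(sol, g, "m", cfg, ("m",))
        assert circuit.edges == ((0, 1),)
        assert circuit.weights[0] == pytest.approx(1.0, abs=1e-8)

    def test_unknown_mode_label(self):
        g = RegionGraph(("a", "b"), ((0, 1),), np.array([1.0]))
        R = ActivationMatrix(np.array([[1.0], [0.5]]), ("m",))
        cfg = ModelConfig(gamma=1.0)
        sol = solve_flow(assemble_lp(g, R, cfg), cfg)
        with pytest.raises(KeyError):
            extract_circuit(sol, g, "nope", cfg, ("m",))

    def test_enhanced_capacities(self):
        g, R, cfg = three_node_example()
        sol = solve_flow(assemble_lp(g, R, cfg), cfg)
        enhanced = enhanced_capacities(g, sol)
        assert enhanced.loc[("i", "j")] == pytest.approx(1.0, abs=1e-8)
        assert enhanced.loc[("i", "k")] == pytest.approx(0.01, abs=1e-8)
        assert np.all(enhanced.to_numpy() >= g.capacity - 1e-12)


class TestModelProperties:
    def test_constraints_hold_on_random_instances(self):
        """Auto-gamma keeps every random instance feasible with tiny residuals."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            w, r = random_instance(rng, n_max=20, m_max=5)
            cfg = ModelConfig()
            g = canonicalize_graph(w, config=cfg)
            if not np.any(r > 0):
                continue
            R = ActivationMatrix(r, tuple(f"m{k}" for k in range(r.shape[1])))
            lp = assemble_lp(g, R, cfg)
            sol = solve_flow(lp, cfg, g, R)
            assert sol.is_optimal, "auto-gamma instance must be feasible"
            assert sol.max_residual <= 1e-8
            validate_solution(g, R, cfg, sol)

    def test_objective_matches_independent_oracle(self):
        """Objective equals an independently assembled and solved program."""
        rng = np.random.default_rng(7)
        checked = 0
        for _ in range(100):
            w, r = random_instance(rng, n_max=4, m_max=2)
            cfg = ModelConfig()
            g = canonicalize_graph(w, config=cfg)
            R = ActivationMatrix(r, tuple(f"m{k}" for k in range(r.shape[1])))
            lp = assemble_lp(g, R, cfg)
            sol = solve_flow(lp, cfg, g, R)
            assert sol.is_optimal
            dense = np.zeros_like(w, dtype=float)
            for l, (i, j) in enumerate(g.edges):
                dense[i, j] = dense[j, i] = g.capacity[l]
            ref = oracle_objective(dense, r, lp.gamma, cfg.rho)
            assert ref is not None
            assert sol.objective_value == pytest.approx(
                ref, abs=1e-6 * max(1.0, abs(ref)))
            checked += 1
        assert checked == 100

    def test_total_correction_monotone_in_rho(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            w, r = random_instance(rng, n_max=6, m_max=2)
            if not np.any(r > 0):
                continue
            totals = []
            for rho in (0.1, 1.0, 10.0, 100.0):
                cfg = ModelConfig(rho=rho)
                g = canonicalize_graph(w, config=cfg)
                R = ActivationMatrix(r, tuple(f"m{k}" for k in range(r.shape[1])))
                sol = solve_flow(assemble_lp(g, R, cfg), cfg)
                assert sol.is_optimal
                totals.append(sol.corrections.sum())
            for a, b in zip(totals, totals[1:]):
                assert b <= a + 1e-7

    def test_scaling_at_rho_zero(self):
        """At rho=0 the program is homogeneous: scaling R by c scales the optimum by c."""
        rng = np.random.default_rng(11)
        w, r = random_instance(rng, n_max=5, m_max=2, zero_frac=0.1)
        cfg = ModelConfig(rho=0.0)
        g = canonicalize_graph(w, config=cfg)
        labels = tuple(f"m{k}" for k in range(r.shape[1]))
        base = solve_flow(assemble_lp(g, ActivationMatrix(r, labels), cfg), cfg)
        scaled = solve_flow(
            assemble_lp(g, ActivationMatrix(3.0 * r, labels), cfg), cfg)
        assert base.is_optimal and scaled.is_optimal
        assert scaled.objective_value == pytest.approx(
            3.0 * base.objective_value, rel=1e-8)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(19)
        w, r = random_instance(rng, n_max=5, m_max=2, zero_frac=0.2)
        n = w.shape[0]
        perm = rng.permutation(n)
        cfg = ModelConfig()
        g = canonicalize_graph(w, config=cfg)
        labels = tuple(f"m{k}" for k in range(r.shape[1]))
        sol = solve_flow(assemble_lp(g, ActivationMatrix(r, labels), cfg), cfg)
        gp = canonicalize_graph(w[np.ix_(perm, perm)], config=cfg)
        solp = solve_flow(assemble_lp(gp, ActivationMatrix(r[perm], labels), cfg), cfg)
        assert solp.objective_value == pytest.approx(
            sol.objective_value, rel=1e-8)
        # corrections permute with the nodes (objective-equal optima may
        # reshuffle flows, but total correction mass must agree)
        assert solp.corrections.sum() == pytest.approx(
            sol.corrections.sum(), abs=1e-7)

    def test_mode_isolation_at_rho_zero(self):
        """Zeroing one mode's activations removes exactly that mode's flows."""
        rng = np.random.default_rng(23)
        w, _ = random_instance(rng, n_max=5, m_max=1, zero_frac=0.1)
        n = w.shape[0]
        r = rng.uniform(0.2, 1.0, size=(n, 2))
        cfg = ModelConfig(rho=0.0)
        g = canonicalize_graph(w, config=cfg)
        full = solve_flow(assemble_lp(g, ActivationMatrix(r, ("a", "b")), cfg), cfg)
        r0 = r.copy()
        r0[:, 1] = 0.0
        part = solve_flow(assemble_lp(g, ActivationMatrix(r0, ("a", "b")), cfg), cfg)
        assert part.is_optimal
        assert np.all(part.flows[:, 1] == 0.0)
        # mode a's cost contribution is unchanged
        inv_d = 1.0 / g.capacity
        cost_full_a = float(inv_d @ full.flows[:, 0])
        cost_part_a = float(inv_d @ part.flows[:, 0])
        assert cost_part_a == pytest.approx(cost_full_a, rel=1e-6)

    def test_all_zero_activation_yields_zero_solution(self):
        g = canonicalize_graph(np.array([[0.0, 3.0], [3.0, 0.0]]))
        R = ActivationMatrix(np.zeros((2, 2)), ("a", "b"))
        with pytest.warns(UserWarning, match="all-zero"):
            sol = solve_joint_model(g, R)
        assert sol.is_optimal and sol.objective_value == 0.0
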