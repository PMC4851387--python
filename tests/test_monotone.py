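import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from togglepop.equilibria import find_equilibrium
from togglepop.models import PopulationSpec, mirror_state, state_bounds
from togglepop.monotone import (
    OrthantPartition,
    PartitionFailure,
    SignIndefiniteError,
    _validate_signs,
    brute_force_partition,
    connectivity_path,
    find_orthant_partition,
    graph_to_dot,
    influence_graph,
    is_strongly_connected,
    kamke_order_check,
    order_leq,
    oscillation_probe,
    parametric_monotonicity_check,
    partition_for_spec,
)
from togglepop.experiments import make_population_state


class TestInfluenceGraph:
    def test_s_single_cell_edges(self, reference):
        G = influence_graph("S", reference)
        expected = {
            ("y1", "x1", -1), ("g1", "x1", +1),
            ("x1", "y1", -1), ("r1", "y1", +1),
            ("y1", "g1", -1), ("ge", "g1", +1),
            ("x1", "r1", -1), ("re", "r1", +1),
            ("g1", "ge", +1), ("r1", "re", +1),
        }
        got = {(u, v, d["sign"]) for u, v, d in G.edges(data=True)}
        assert got == expected

    def test_a_single_cell_edges(self, reference):
        # signs derived by differentiating the A right-hand side
        G = influence_graph("A", reference)
        expected = {
            ("y1", "x1", -1), ("r1", "x1", +1),
            ("x1", "y1", -1), ("x1", "r1", -1),
            ("re", "r1", +1), ("r1", "re", +1),
        }
        got = {(u, v, d["sign"]) for u, v, d in G.edges(data=True)}
        assert got == expected

    def test_a3_zero_removes_edge(self, reference):
        G = influence_graph("S", reference.replace(a3=0.0))
        assert not G.has_edge("g1", "x1")

    def test_no_self_edges(self, reference):
        G = influence_graph("S", reference, N=3)
        assert all(u != v for u, v in G.edges)

    def test_sign_validation_catches_wrong_declaration(self, reference):
        spec = PopulationSpec("S", (1,))
        G = influence_graph("S", reference, validate=False)
        G["g1"]["x1"]["sign"] = -1   # deliberately wrong
        with pytest.raises(SignIndefiniteError):
            _validate_signs(G, reference, spec, n_samples=20, seed=0)


class TestPartition:
    @pytest.mark.parametrize("N", [1, 2, 5, 10])
    def test_s_partition(self, reference, N):
        G = influence_graph("S", reference, N=N, validate=(N <= 2))
        part = find_orthant_partition(G)
        assert isinstance(part, OrthantPartition)
        expected = partition_for_spec(PopulationSpec("S", (N,)))
        assert part.S_plus == expected.S_plus
        assert part.S_minus == expected.S_minus

    @pytest.mark.parametrize("N", [1, 2, 5, 10])
    def test_a_unbalanced(self, reference, N):
        G = influence_graph("A", reference, N=N, validate=(N <= 2))
        fail = find_orthant_partition(G)
        assert isinstance(fail, PartitionFailure)
        assert fail.negative_edge_count % 2 == 1
        # witness is a closed walk in the graph
        for u, v, s in fail.cycle:
            edge = G.get_edge_data(u, v) or G.get_edge_data(v, u)
            assert edge is not None and edge["sign"] == s

    def test_single_node(self):
        G = nx.DiGraph()
        G.add_node("x1")
        part = find_orthant_partition(G)
        assert part.S_plus == {"x1"} and part.S_minus == frozenset()
        assert is_strongly_connected(G)

    @given(st.data())
    @settings(max_examples=40, deadline=None)
    def test_agrees_with_brute_force(self, data):
        n = data.draw(st.integers(2, 7))
        G = nx.DiGraph()
        G.add_nodes_from(f"n{i}" for i in range(n))
        n_edges = data.draw(st.integers(0, 12))
        for _ in range(n_edges):
            i = data.draw(st.integers(0, n - 1))
            j = data.draw(st.integers(0, n - 1))
            if i == j:
                continue
            s = data.draw(st.sampled_from([1, -1]))
            if not G.has_edge(f"n{i}", f"n{j}"):
                G.add_edge(f"n{i}", f"n{j}", sign=s)
        fast = find_orthant_partition(G)
        brute = brute_force_partition(G)
        if brute is None:
            assert isinstance(fast, PartitionFailure)
            assert fast.negative_edge_count % 2 == 1
        else:
            assert isinstance(fast, OrthantPartition)
            # validity: + edges within sides, - edges across
            for u, v, d in G.edges(data=True):
                assert fast.side(u) * fast.side(v) == d["sign"]


class TestConnectivity:
    def test_s_strongly_connected(self, reference):
        G = influence_graph("S", reference, N=2, validate=False)
        assert is_strongly_connected(G)
        # certificate of indirect influence between cells
        path = connectivity_path(G, "x1", "x2")
        assert path[0] == "x1" and path[-1] == "x2"
        assert all(G.has_edge(a, b) for a, b in zip(path, path[1:]))

    def test_parameter_nodes_break_connectivity(self, reference):
        G = influence_graph("S", reference, include_params=True)
        assert not is_strongly_connected(G)

    def test_dot_export(self, reference):
        dot = graph_to_dot(influence_graph("S", reference))
        assert "digraph" in dot and 'sign="-"' in dot


def _ordered_pair(rng, params, spec, partition, scale=0.1):
    ub = state_bounds(params, spec)
    lo = rng.uniform(0.05, 0.8, spec.dim) * ub
    sigma = np.array([partition.side(v) for v in spec.var_names()], float)
    hi = lo + sigma * rng.uniform(0, scale, spec.dim) * lo
    hi = np.maximum(hi, 0.0)
    return lo, hi


class TestKamke:
    def test_order_preserved_s(self, reference, rng):
        spec = PopulationSpec("S", (3,))
        part = partition_for_spec(spec)
        for _ in range(5):
            lo, hi = _ordered_pair(rng, reference, spec, part)
            rep = kamke_order_check(lo, hi, reference, spec, part, horizon=30.0)
            assert rep.ok, rep.first_violation

    def test_identical_states(self, reference):
        spec = PopulationSpec("S", (2,))
        part = partition_for_spec(spec)
        z = np.full(spec.dim, 1.0)
        rep = kamke_order_check(z, z, reference, spec, part, horizon=10.0)
        assert rep.ok and rep.max_violation == 0.0

    def test_unordered_inputs_rejected(self, reference):
        spec = PopulationSpec("S", (1,))
        part = partition_for_spec(spec)
        lo = np.ones(6)
        hi = lo.copy()
        hi[1] += 1.0   # y is in S_minus: raising it breaks lo <= hi
        with pytest.raises(ValueError, match="not ordered"):
            kamke_order_check(lo, hi, reference, spec, part)

    def test_a_model_reported_not_asserted(self, reference, rng):
        # the A model carries no monotonicity guarantee; the harness must
        # return a report either way
        spec = PopulationSpec("A", (2,))
        names = spec.var_names()
        part = OrthantPartition(
            frozenset(n for n in names if n.startswith("x")),
            frozenset(n for n in names if not n.startswith("x")))
        lo, hi = _ordered_pair(rng, reference, spec, part, scale=0.3)
        rep = kamke_order_check(lo, hi, reference, spec, part, horizon=30.0)
        assert rep.ok in (True, False)

    def test_perturbing_one_cell_orders_population(self, reference):
        # bump x of one cell upward from a mixed-state neighborhood: the whole
        # population stays ordered componentwise for all sampled times
        spec = PopulationSpec("S", (1, 1))
        res = make_population_state((1, 1), reference.replace(d=0.1), spec)
        lo = res.record.state * 1.0
        hi = lo.copy()
        hi[0] *= 1.1
        part = partition_for_spec(spec)
        rep = kamke_order_check(lo, hi, reference.replace(d=0.1), spec, part,
                                horizon=50.0)
        assert rep.ok, rep.first_violation


class TestParametricShifts:
    def test_a5_increase_from_homogeneous(self, reference):
        params = reference.replace(d=0.1)
        res = make_population_state((1, 0), params, PopulationSpec("S", (2,)))
        rep = parametric_monotonicity_check(res.record, "a5",
                                            0.05 * params.a5)
        assert rep.ok
        assert rep.shifts["x1"] > 0 and rep.shifts["g1"] > 0
        assert rep.shifts["ge"] > 0
        assert rep.shifts["y1"] <= 0 and rep.shifts["re"] <= 0

    def test_zero_increment(self, reference):
        params = reference.replace(d=0.1)
        res = make_population_state((1, 0), params, PopulationSpec("S", (2,)))
        rep = parametric_monotonicity_check(res.record, "delta_g", 0.0)
        assert rep.ok
        assert all(abs(v) < 1e-8 for v in rep.shifts.values())

    def test_delta_g_decrease_at_mixed_state(self, reference):
        params = reference.replace(d=0.1)
        res = make_population_state((1, 1), params, PopulationSpec("S", (1, 1)))
        rep = parametric_monotonicity_check(res.record, "delta_g", -0.05)
        # delta_g sits on the red side: decreasing it is a move up the order
        assert rep.ok

    def test_non_monotone_parameter_rejected(self, reference):
        params = reference.replace(d=0.1)
        res = make_population_state((1, 0), params, PopulationSpec("S", (2,)))
        with pytest.raises(ValueError, match="monotone parameters"):
            parametric_monotonicity_check(res.record, "d", 0.1)


class TestOscillationProbe:
    def test_flags_sustained_oscillation(self):
        t = np.linspace(0, 100, 1001)
        traj = np.sin(t)[None, :]
        assert oscillation_probe(t, traj)

    def test_accepts_damped_oscillation(self):
        t = np.linspace(0, 100, 1001)
        traj = (np.exp(-0.2 * t) * np.sin(t))[None, :]
        assert not oscillation_probe(t, traj)

    def test_accepts_monotone_decay(self):
        t = np.linspace(0, 100, 1001)
        traj = np.exp(-t)[None, :]
        assert not oscillation_probe(t, traj)
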