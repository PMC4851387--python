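"""Signed influence graphs, orthant monotonicity, and order preservation.

The species influence graph has one node per state variable and a signed
edge ``j -> i`` wherever the Jacobian entry ``dF_i/dz_j`` keeps one strict
sign over the whole positive orthant (no self-edges). A system is monotone
with respect to an orthant order exactly when this signed graph is
*balanced*: the nodes 2-color so that positive edges join like colors and
negative edges join unlike colors. Strong connectivity upgrades this to
strong monotonicity, under which generic bounded solutions converge to
steady states and ordered initial conditions stay ordered for all time.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .equilibria import ConvergenceError, EquilibriumRecord, find_equilibrium
from .models import PopulationSpec, jacobian
from .params import ModelParams

__all__ = [
    "SignIndefiniteError",
    "OrthantPartition",
    "influence_graph",
    "find_orthant_partition",
    "brute_force_partition",
    "is_strongly_connected",
    "connectivity_path",
    "partition_for_spec",
    "order_leq",
    "kamke_order_check",
    "parametric_monotonicity_check",
    "oscillation_probe",
    "PARAMETER_SIDE",
    "EquilibriumLostError",
]


class SignIndefiniteError(RuntimeError):
    """A sampled Jacobian entry changed sign across the positive orthant."""


class EquilibriumLostError(RuntimeError):
    """Equilibrium disappeared within a parameter increment (fold crossed)."""

    def __init__(self, message: str, fold_estimate: float):
        super().__init__(message)
        self.fold_estimate = fold_estimate


@dataclass
class OrthantPartition:
    """A balanced 2-coloring of the influence graph's nodes."""

    S_plus: frozenset[str]
    S_minus: frozenset[str]

    def side(self, node: str) -> int:
        if node in self.S_plus:
            return +1
        if node in self.S_minus:
            return -1
        raise KeyError(node)

    def to_dict(self) -> dict:
        return {"S_plus": sorted(self.S_plus), "S_minus": sorted(self.S_minus)}


@dataclass
class PartitionFailure:
    """Witness of unbalancedness: a cycle with an odd number of - edges."""

    cycle: list[tuple[str, str, int]]   # (src, dst, sign) edges

    @property
    def negative_edge_count(self) -> int:
        return sum(1 for _, _, s in self.cycle if s < 0)


# sides of the eight parameters that extend the orthant order when embedded
# as constant state variables (a-rates sit with the variable they drive;
# the degradation rates act against their own arm)
PARAMETER_SIDE = {
    "a1": +1, "a3": +1, "a5": +1, "delta_r": +1,
    "a2": -1, "a4": -1, "a6": -1, "delta_g": -1,
}


def _structural_edges(model_id: str, params: ModelParams, N: int):
    """Signed edges of the per-cell + extracellular influence structure."""
    p = params
    edges = []

    def cell(v, i):
        return f"{v}{i+1}"

    for i in range(N):
        if model_id == "S":
            if p.a1 > 0:
                edges.append((cell("y", i), cell("x", i), -1))
            if p.a3 > 0:
                edges.append((cell("g", i), cell("x", i), +1))
            if p.a2 > 0:
                edges.append((cell("x", i), cell("y", i), -1))
            if p.a4 > 0:
                edges.append((cell("r", i), cell("y", i), +1))
            if p.a5 > 0:
                edges.append((cell("y", i), cell("g", i), -1))
            if p.a6 > 0:
                edges.append((cell("x", i), cell("r", i), -1))
            if p.d > 0:
                edges.append(("ge", cell("g", i), +1))
                edges.append(("re", cell("r", i), +1))
                if p.rho > 0:
                    edges.append((cell("g", i), "ge", +1))
                    edges.append((cell("r", i), "re", +1))
        else:
            if p.a1 > 0:
                edges.append((cell("y", i), cell("x", i), -1))
            if p.a4 > 0:
                edges.append((cell("r", i), cell("x", i), +1))
            if p.a2 > 0:
                edges.append((cell("x", i), cell("y", i), -1))
            if p.a6 > 0:
                edges.append((cell("x", i), cell("r", i), -1))
            if p.d > 0:
                edges.append(("re", cell("r", i), +1))
                if p.rho > 0:
                    edges.append((cell("r", i), "re", +1))
    return edges


def influence_graph(model_id: str, params: ModelParams, N: int = 1,
                    include_params: bool = False, validate: bool = True,
                    n_samples: int = 100, seed: int = 0) -> nx.DiGraph:
    """Signed species-influence graph of the model (no self-edges).

    The sign structure is derived from the monomial-ratio form of the Hill
    terms (each off-diagonal Jacobian entry is a single signed term) and,
    when ``validate`` is set, certified numerically on ``n_samples`` random
    positive states, components log-uniform in [1e-3, 1e2]. A sampled entry
    that changes sign raises :class:`SignIndefiniteError`.

    ``include_params`` adds the eight monotone parameters as constant-state
    nodes with edges into the variables they drive (and no incoming edges),
    which destroys strong connectivity.
    """
    spec = PopulationSpec(model_id, (N,))
    names = spec.var_names()
    G = nx.DiGraph()
    G.add_nodes_from(names)
    for u, v, s in _structural_edges(model_id, params, N):
        G.add_edge(u, v, sign=s)

    if validate:
        _validate_signs(G, params, spec, n_samples, seed)

    if include_params:
        for pname, side in PARAMETER_SIDE.items():
            G.add_node(pname)
        for i in range(N):
            G.add_edge("a1", f"x{i+1}", sign=+1)
            G.add_edge("a2", f"y{i+1}", sign=+1)
            if model_id == "S":
                G.add_edge("a3", f"x{i+1}", sign=+1)
                G.add_edge("a4", f"y{i+1}", sign=+1)
                G.add_edge("a5", f"g{i+1}", sign=+1)
                G.add_edge("a6", f"r{i+1}", sign=+1)
                G.add_edge("delta_g", f"g{i+1}", sign=-1)
                G.add_edge("delta_r", f"r{i+1}", sign=-1)
            else:
                G.add_edge("a4", f"x{i+1}", sign=+1)
                G.add_edge("a6", f"r{i+1}", sign=+1)
                G.add_edge("delta_r", f"r{i+1}", sign=-1)
    return G


def _validate_signs(G: nx.DiGraph, params: ModelParams, spec: PopulationSpec,
                    n_samples: int, seed: int) -> None:
    rng = np.random.default_rng(seed)
    names = spec.var_names()
    index = {v: i for i, v in enumerate(names)}
    states = 10.0 ** rng.uniform(-3, 2, size=(n_samples, spec.dim))
    seen = {}
    for z in states:
        J = jacobian(z, params, spec)
        for i, vi in enumerate(names):
            for j, vj in enumerate(names):
                if i == j:
                    continue
                val = J[i, j]
                key = (vj, vi)
                s = 0 if val == 0 else (1 if val > 0 else -1)
                prev = seen.get(key)
                if prev is None:
                    seen[key] = s
                elif prev != s and 0 not in (prev, s):
                    raise SignIndefiniteError(
                        f"Jacobian entry d{vi}/d{vj} changed sign across "
                        "sampled states")
    for (vj, vi), s in seen.items():
        has_edge = G.has_edge(vj, vi)
        if s != 0:
            if not has_edge:
                raise SignIndefiniteError(
                    f"nonzero sampled entry d{vi}/d{vj} has no declared edge")
            if G[vj][vi]["sign"] != s:
                raise SignIndefiniteError(
                    f"declared sign of edge {vj}->{vi} disagrees with samples")


def find_orthant_partition(G: nx.DiGraph):
    """2-color the signed graph; return a partition or an odd-cycle witness.

    BFS sign propagation: positive edges force equal colors, negative edges
    force opposite colors. On conflict, the BFS-tree path between the two
    endpoints plus the conflicting edge forms a cycle with an odd number of
    negative edges, returned as a :class:`PartitionFailure`.
    """
    # undirected constraint multigraph; keep original edge data for witness
    constraint = {}
    for u, v, data in G.edges(data=True):
        s = data["sign"]
        key = frozenset((u, v)) if u != v else None
        if key is None:
            continue
        if key in constraint and constraint[key][2] != s:
            # same pair constrained both ways: immediate odd 2-cycle
            a, b, s0 = constraint[key]
            return PartitionFailure([(a, b, s0), (u, v, s)])
        constraint[key] = (u, v, s)

    color: dict[str, int] = {}
    parent: dict[str, tuple[str, int] | None] = {}
    adj: dict[str, list[tuple[str, int]]] = {n: [] for n in G.nodes}
    for u, v, s in constraint.values():
        adj[u].append((v, s))
        adj[v].append((u, s))

    def tree_path(node):
        path = []
        while parent[node] is not None:
            prev, s = parent[node]
            path.append((prev, node, s))
            node = prev
        return node, path

    for root in G.nodes:
        if root in color:
            continue
        color[root] = +1
        parent[root] = None
        queue = [root]
        while queue:
            u = queue.pop()
            for v, s in adj[u]:
                want = color[u] * s
                if v not in color:
                    color[v] = want
                    parent[v] = (u, s)
                    queue.append(v)
                elif color[v] != want:
                    # witness cycle: tree paths to common ancestor + (u,v)
                    ru, pu = tree_path(u)
                    rv, pv = tree_path(v)
                    cycle = pu + [(u, v, s)] + pv
                    return PartitionFailure(cycle)

    # orientation convention: larger = greener (x-side is S_plus)
    anchor = next((n for n in G.nodes if n.startswith("x")), None)
    flip = -1 if anchor is not None and color[anchor] < 0 else 1
    plus = frozenset(n for n, c in color.items() if c * flip > 0)
    minus = frozenset(n for n, c in color.items() if c * flip < 0)
    return OrthantPartition(plus, minus)


def brute_force_partition(G: nx.DiGraph):
    """Exhaustive 2-coloring search (oracle for small graphs, <= ~16 nodes)."""
    nodes = list(G.nodes)
    if len(nodes) > 20:
        raise ValueError("brute force limited to small graphs")
    edges = [(u, v, d["sign"]) for u, v, d in G.edges(data=True)]
    for bits in itertools.product((1, -1), repeat=len(nodes) - 1):
        color = dict(zip(nodes, (1,) + bits))
        if all(color[u] * color[v] == s for u, v, s in edges):
            plus = frozenset(n for n in nodes if color[n] > 0)
            minus = frozenset(n for n in nodes if color[n] < 0)
            return OrthantPartition(plus, minus)
    return None


def is_strongly_connected(G: nx.DiGraph) -> bool:
    """Strong connectivity of the directed graph, ignoring signs."""
    if G.number_of_nodes() <= 1:
        return True
    return nx.is_strongly_connected(G)


def connectivity_path(G: nx.DiGraph, src: str, dst: str) -> list[str]:
    """A certificate path of directed influence from src to dst."""
    return nx.shortest_path(G, src, dst)


def partition_for_spec(spec: PopulationSpec) -> OrthantPartition:
    """The canonical orthant partition of an S population (larger = greener)."""
    if spec.model_id != "S":
        raise ValueError("the A model admits no orthant partition")
    plus, minus = [], []
    for i in range(spec.N):
        plus += [f"x{i+1}", f"g{i+1}"]
        minus += [f"y{i+1}", f"r{i+1}"]
    plus.append("ge")
    minus.append("re")
    return OrthantPartition(frozenset(plus), frozenset(minus))


def _signs_vector(partition: OrthantPartition, spec: PopulationSpec) -> np.ndarray:
    return np.array([partition.side(v) for v in spec.var_names()], dtype=float)


def order_leq(state_lo, state_hi, partition: OrthantPartition,
              spec: PopulationSpec, tol: float = 0.0) -> bool:
    """True if state_lo <= state_hi in the orthant order of the partition."""
    sigma = _signs_vector(partition, spec)
    diff = sigma * (np.asarray(state_hi) - np.asarray(state_lo))
    return bool(np.all(diff >= -tol))


@dataclass
class OrderReport:
    ok: bool
    first_violation: tuple[float, str, float] | None  # (time, var, amount)
    times: np.ndarray
    max_violation: float


def kamke_order_check(state_lo, state_hi, params: ModelParams,
                      spec: PopulationSpec, partition: OrthantPartition,
                      horizon: float = 50.0, n_times: int = 51,
                      tol: float = 1e-9) -> OrderReport:
    """Integrate an ordered pair and test order preservation along the flow.

    The two trajectories are integrated as one joint system so that both
    share the solver's step sequence, keeping the numerical error of their
    difference well below ``tol``. A violation is reported (never asserted
    away): for the monotone S model the order must hold; for the A model
    the report simply records what happened.
    """
    lo = np.asarray(state_lo, float)
    hi = np.asarray(state_hi, float)
    if not order_leq(lo, hi, partition, spec):
        raise ValueError("initial states are not ordered (lo <= hi required)")

    from scipy.integrate import solve_ivp
    from .models import rhs as model_rhs, jacobian as model_jac
    import scipy.linalg as sla

    n = spec.dim

    def joint_rhs(t, w):
        return np.concatenate([model_rhs(w[:n], params, spec),
                               model_rhs(w[n:], params, spec)])

    def joint_jac(t, w):
        J = np.zeros((2 * n, 2 * n))
        J[:n, :n] = model_jac(w[:n], params, spec)
        J[n:, n:] = model_jac(w[n:], params, spec)
        return J

    times = np.linspace(0.0, horizon, n_times)
    sol = solve_ivp(joint_rhs, (0.0, horizon), np.concatenate([lo, hi]),
                    method="LSODA", jac=joint_jac, t_eval=times,
                    rtol=1e-10, atol=1e-12)
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")

    sigma = _signs_vector(partition, spec)
    names = spec.var_names()
    diff = sigma[:, None] * (sol.y[n:, :] - sol.y[:n, :])
    worst = float(np.min(diff))
    viol = None
    bad = np.argwhere(diff < -tol)
    if bad.size:
        k = bad[np.argmin(bad[:, 1])]
        viol = (float(sol.t[k[1]]), names[k[0]], float(diff[k[0], k[1]]))
    return OrderReport(ok=viol is None, first_violation=viol,
                       times=times, max_violation=max(0.0, -worst))


@dataclass
class ShiftReport:
    ok: bool
    param_name: str
    increment: float
    shifts: dict[str, float]
    violations: list[tuple[str, float]]
    new_equilibrium: EquilibriumRecord


def parametric_monotonicity_check(eq: EquilibriumRecord, param_name: str,
                                  increment: float,
                                  partition: OrthantPartition | None = None,
                                  tol: float = 1e-8,
                                  n_steps: int = 4) -> ShiftReport:
    """Check the monotone shift of a stable equilibrium under a parameter move.

    The eight monotone parameters embed as constant states on a definite
    side of the orthant partition; increasing one must move every component
    of a stable equilibrium weakly in the direction given by the product of
    the parameter's side and the component's side. The equilibrium at the
    shifted parameter is re-solved by natural continuation in ``n_steps``
    sub-increments; losing it mid-way raises :class:`EquilibriumLostError`
    with the bracketing estimate of the fold.
    """
    if param_name not in PARAMETER_SIDE:
        raise ValueError(
            f"{param_name!r} is not one of the monotone parameters "
            f"{sorted(PARAMETER_SIDE)}")
    if not eq.stable:
        raise ValueError("parametric monotonicity applies to stable equilibria")
    spec = eq.spec
    partition = partition or partition_for_spec(spec)
    p0 = float(getattr(eq.params, param_name))

    state = eq.state
    params = eq.params
    last_good = p0
    for k in range(1, n_steps + 1):
        p_k = p0 + increment * k / n_steps
        params_k = params.replace(**{param_name: p_k})
        try:
            rec = find_equilibrium(state, params_k, spec)
        except ConvergenceError as exc:
            raise EquilibriumLostError(
                f"equilibrium lost between {param_name}={last_good} and {p_k}",
                fold_estimate=0.5 * (last_good + p_k)) from exc
        state, last_good = rec.state, p_k

    sigma = _signs_vector(partition, spec)
    names = spec.var_names()
    expected = PARAMETER_SIDE[param_name] * np.sign(increment) * sigma
    delta = rec.state - eq.state
    shifts = dict(zip(names, delta))
    violations = [(names[i], float(delta[i]))
                  for i in range(len(names))
                  if expected[i] * delta[i] < -tol]
    return ShiftReport(ok=not violations, param_name=param_name,
                       increment=increment, shifts=shifts,
                       violations=violations, new_equilibrium=rec)


def oscillation_probe(times: np.ndarray, traj: np.ndarray,
                      window_frac: float = 0.2, amp_tol: float = 1e-6,
                      max_sign_changes: int = 2) -> bool:
    """True if the trajectory tail looks like a sustained oscillation.

    Inspects the final ``window_frac`` of the trajectory: a component with
    amplitude above ``amp_tol`` whose time-derivative changes sign more
    than ``max_sign_changes`` times flags the trajectory as non-convergent.
    Damped oscillations that have settled below the amplitude floor do not
    trigger.
    """
    times = np.asarray(times)
    traj = np.atleast_2d(np.asarray(traj))  # (dim, n_times)
    k0 = int(len(times) * (1.0 - window_frac))
    w = traj[:, k0:]
    if w.shape[1] < 3:
        return False
    amp = w.max(axis=1) - w.min(axis=1)
    dw = np.diff(w, axis=1)
    for i in range(w.shape[0]):
        if amp[i] <= amp_tol:
            continue
        s = np.sign(dw[i])
        s = s[s != 0]
        changes = int(np.sum(s[1:] != s[:-1]))
        if changes > max_sign_changes:
            return True
    return False


def graph_to_dot(G: nx.DiGraph) -> str:
    """DOT serialization with a ``sign`` edge attribute in {+, -}."""
    lines = ["digraph influence {"]
    for n in G.nodes:
        lines.append(f'  "{n}";')
    for u, v, d in G.edges(data=True):
        s = "+" if d.get("sign", 1) > 0 else "-"
        lines.append(f'  "{u}" -> "{v}" [sign="{s}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"
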