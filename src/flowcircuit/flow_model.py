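"""Joint structural-functional network model solved by linear programming.

The brain (or phantom) is modeled as an undirected network whose nodes are
gray-matter regions and whose edges are candidate white-matter pathways.  Each
edge ``l = (i, j)`` carries a *capacity* ``D_l`` derived from normalized
tractography streamline counts, and each node ``i`` carries a nonnegative
*functional activation* ``R_i^m`` per functional mode ``m`` (a task contrast
or an ICA resting-state component).  The model distributes nonnegative
*information flow* ``f_l^m`` over the edges and may raise a nonnegative
*capacity correction* ``P_l``, by solving

    minimize    sum_l (1/D_l) sum_m f_l^m  +  rho * sum_l (1 + 1/D_l) P_l
    subject to  sum_m f_l^m        <= gamma * (D_l + P_l)      for every edge l
                sum_{l in N(i)} f_l^m >= R_i^m                 for every node i, mode m
                f_l^m              <= max(R_i^m, R_j^m)         for every edge l=(i,j), mode m
                f, P >= 0

where ``N(i)`` is the set of edges incident to node ``i``.  The unit delivery
cost ``1/D_l`` makes anatomically strong pathways cheap to use; the second
term penalizes corrections, more heavily on weak links, so that ``P_l``
becomes positive only where fMRI demand cannot be met through the estimated
anatomy.  The unit-conversion parameter ``gamma`` (capacity -> flow, with flow
stored in activation-equivalent units) is by default set to the largest nodal
ratio of total activation to total incident capacity, which guarantees
feasibility.

Edges with positive flow for a mode define that mode's anatomical circuit;
``D_l + P_l`` is the enhanced structural connectivity estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import linprog

__all__ = [
    "RegionGraph",
    "ActivationMatrix",
    "ModelConfig",
    "LPSpec",
    "FlowSolution",
    "CircuitNetwork",
    "canonicalize_graph",
    "compute_gamma",
    "assemble_lp",
    "solve_flow",
    "validate_solution",
    "extract_circuit",
    "enhanced_capacities",
    "solve_joint_model",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelConfig:
    """Tunable parameters of the joint model.

    gamma:            capacity-to-activation unit conversion, or "auto" to use
                      the feasibility-guaranteeing rule (largest nodal ratio of
                      total activation to total incident capacity).
    rho:              weight of the capacity-correction penalty (> 0); larger
                      values restrict corrections.
    capacity_floor:   floor applied to normalized capacities so every candidate
                      edge has D_l > 0 and finite unit cost 1/D_l.
    flow_epsilon:     threshold above which an edge flow counts toward a
                      mode's circuit.
    solver_tolerance: maximum accepted constraint violation of an optimal
                      solution.
    solver_method:    scipy.optimize.linprog method name (deterministic).
    seed:             recorded for provenance; the LP itself is deterministic.
    """

    gamma: float | str = "auto"
    rho: float = 1.0
    capacity_floor: float = 1e-4
    flow_epsilon: float = 1e-6
    solver_tolerance: float = 1e-8
    solver_method: str = "highs"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rho < 0:
            raise ValueError(f"rho must be >= 0, got {self.rho}")
        if self.capacity_floor <= 0:
            raise ValueError(f"capacity_floor must be > 0, got {self.capacity_floor}")
        if self.solver_tolerance <= 0:
            raise ValueError("solver_tolerance must be > 0")
        if isinstance(self.gamma, str):
            if self.gamma != "auto":
                raise ValueError(f"gamma must be a positive number or 'auto', got {self.gamma!r}")
        elif self.gamma <= 0:
            raise ValueError(f"gamma must be > 0 or 'auto', got {self.gamma}")


@dataclass(frozen=True)
class RegionGraph:
    """Undirected candidate-edge graph with floored, normalized capacities.

    ``edges`` are canonical ``(i, j)`` index pairs with ``i < j``; ``capacity``
    aligns with ``edges``.  The graph need not be complete (unit tests use
    hand-built graphs), but :func:`canonicalize_graph` produces the complete
    candidate set so fully missed pathways can still be recovered via P_l.
    """

    node_labels: tuple[str, ...]
    edges: tuple[tuple[int, int], ...]
    capacity: np.ndarray  # shape (L,)

    def __post_init__(self) -> None:
        cap = np.asarray(self.capacity, dtype=float)
        object.__setattr__(self, "capacity", cap)
        n = len(self.node_labels)
        if len(set(self.node_labels)) != n:
            raise ValueError("duplicate node labels")
        seen = set()
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-loop at node {self.node_labels[i]}")
            if not (0 <= i < j < n):
                raise ValueError(f"edge ({i}, {j}) not in canonical order within node range")
            if (i, j) in seen:
                raise ValueError(f"duplicate edge ({i}, {j})")
            seen.add((i, j))
        if cap.shape != (len(self.edges),):
            raise ValueError("capacity length does not match edge count")
        if not np.all(np.isfinite(cap)) or np.any(cap <= 0):
            raise ValueError("all capacities must be finite and > 0 (apply the floor first)")

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def edge_index(self) -> dict[tuple[int, int], int]:
        return {e: k for k, e in enumerate(self.edges)}

    def incident(self) -> list[list[int]]:
        """Edge indices incident to each node (N(i) in the model)."""
        inc: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for k, (i, j) in enumerate(self.edges):
            inc[i].append(k)
            inc[j].append(k)
        return inc

    def edge_labels(self) -> list[tuple[str, str]]:
        return [(self.node_labels[i], self.node_labels[j]) for i, j in self.edges]


@dataclass(frozen=True)
class ActivationMatrix:
    """Nonnegative region-by-mode functional activations R_i^m."""

    values: np.ndarray  # shape (N, M)
    mode_labels: tuple[str, ...]
    node_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        vals = np.atleast_2d(np.asarray(self.values, dtype=float))
        object.__setattr__(self, "values", vals)
        if vals.shape[1] != len(self.mode_labels):
            raise ValueError("mode_labels length does not match activation columns")
        if not np.all(np.isfinite(vals)):
            raise ValueError("activations contain non-finite entries")
        if np.any(vals < 0):
            i, m = np.argwhere(vals < 0)[0]
            raise ValueError(f"negative activation at region {i}, mode {self.mode_labels[m]}")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_modes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        index = list(self.node_labels) if self.node_labels else list(range(self.n_nodes))
        return pd.DataFrame(self.values, index=index, columns=list(self.mode_labels))


@dataclass(frozen=True)
class LPSpec:
    """Assembled LP in standard inequality form A_ub x <= b_ub, x >= 0.

    Variable layout: x = [f_0^0 ... f_0^{M-1}, f_1^0, ..., f_{L-1}^{M-1},
    P_0, ..., P_{L-1}], i.e. flow variable (l, m) at index l*M + m and
    correction variable l at index L*M + l.
    """

    c: np.ndarray
    A_ub: sp.csr_matrix
    b_ub: np.ndarray
    n_edges: int
    n_nodes: int
    n_modes: int
    gamma: float
    row_families: dict[str, slice] = field(default_factory=dict)

    def flow_index(self, edge: int, mode: int) -> int:
        return edge * self.n_modes + mode

    def correction_index(self, edge: int) -> int:
        return self.n_edges * self.n_modes + edge

    @property
    def n_variables(self) -> int:
        return self.n_edges * (self.n_modes + 1)


@dataclass(frozen=True)
class FlowSolution:
    """Optimal flows, corrections and diagnostics for one model solve."""

    flows: np.ndarray  # shape (L, M), activation-equivalent flow units
    corrections: np.ndarray  # shape (L,), capacity units
    objective_value: float
    solver_status: str  # "optimal" | "infeasible" | "error"
    max_residual: float
    gamma: float
    message: str = ""

    @property
    def is_optimal(self) -> bool:
        return self.solver_status == "optimal"


@dataclass(frozen=True)
class CircuitNetwork:
    """Anatomical circuit of one functional mode: edges with supra-threshold flow."""

    mode_label: str
    edges: tuple[tuple[int, int], ...]
    weights: np.ndarray
    node_labels: tuple[str, ...]

    @property
    def nodes(self) -> tuple[int, ...]:
        touched = sorted({i for e in self.edges for i in e})
        return tuple(touched)

    @property
    def node_label_set(self) -> frozenset[str]:
        return frozenset(self.node_labels[i] for i in self.nodes)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def canonicalize_graph(
    raw_weights: np.ndarray | pd.DataFrame,
    labels: list[str] | None = None,
    config: ModelConfig | None = None,
    symmetry_rtol: float = 1e-8,
) -> RegionGraph:
    """Build the complete floored candidate graph from a raw weight matrix.

    Weights (streamline counts) are max-normalized: divided by the largest
    off-diagonal entry, so capacities lie in (0, 1].  The candidate edge set is
    *all* node pairs; pairs with no observed streamlines receive the capacity
    floor so that fully missed pathways remain recoverable through P_l.
    """
    config = config or ModelConfig()
    if isinstance(raw_weights, pd.DataFrame):
        if labels is None:
            labels = [str(c) for c in raw_weights.columns]
        w = raw_weights.to_numpy(dtype=float)
    else:
        w = np.asarray(raw_weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"weight matrix must be square, got shape {w.shape}")
    n = w.shape[0]
    if labels is None:
        labels = [f"R{i + 1}" for i in range(n)]
    if len(labels) != n:
        raise ValueError("label count does not match matrix size")
    if not np.all(np.isfinite(w)):
        i, j = np.argwhere(~np.isfinite(w))[0]
        raise ValueError(f"non-finite weight at ({labels[i]}, {labels[j]})")
    neg = np.argwhere(w < 0)
    if neg.size:
        i, j = neg[0]
        raise ValueError(f"negative weight at ({labels[i]}, {labels[j]})")
    asym = np.abs(w - w.T)
    tol = symmetry_rtol * max(1.0, float(np.abs(w).max()))
    if asym.max() > tol:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise ValueError(
            f"asymmetric weights at ({labels[i]}, {labels[j]}): {w[i, j]} vs {w[j, i]}"
        )
    off = w.copy()
    np.fill_diagonal(off, 0.0)
    wmax = float(off.max())
    if wmax <= 0:
        raise ValueError("all off-diagonal weights are zero: no structural signal")
    edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
    # symmetrize exactly before normalizing so tiny input asymmetries cancel
    sym = 0.5 * (off + off.T)
    capacity = np.array(
        [max(sym[i, j] / wmax, config.capacity_floor) for i, j in edges], dtype=float
    )
    return RegionGraph(tuple(labels), tuple(edges), capacity)


def compute_gamma(g: RegionGraph, R: ActivationMatrix) -> float:
    """Feasibility-guaranteeing unit conversion.

    Returns the largest ratio, over nodes, of total functional activation
    (summed over modes) to total incident structural capacity.  Zero when all
    activations are zero.
    """
    if R.n_nodes != g.n_nodes:
        raise ValueError(f"activation rows ({R.n_nodes}) != graph nodes ({g.n_nodes})")
    inc = g.incident()
    total_R = R.values.sum(axis=1)
    gamma = 0.0
    for i in range(g.n_nodes):
        cap = float(g.capacity[inc[i]].sum()) if inc[i] else 0.0
        if total_R[i] > 0 and cap <= 0:
            raise ValueError(
                f"node {g.node_labels[i]} has positive activation but no incident capacity"
            )
        if cap > 0:
            gamma = max(gamma, total_R[i] / cap)
    return gamma


def _resolve_gamma(g: RegionGraph, R: ActivationMatrix, config: ModelConfig) -> float:
    if isinstance(config.gamma, str):  # "auto"
        return compute_gamma(g, R)
    return float(config.gamma)


def assemble_lp(g: RegionGraph, R: ActivationMatrix, config: ModelConfig) -> LPSpec:
    """Assemble objective and inequality rows of the full model.

    Row layout: L capacity rows, then N*M node-demand rows (negated to <=
    form), then L*M feasibility rows.
    """
    if R.n_nodes != g.n_nodes:
        raise ValueError("activation/graph node count mismatch")
    gamma = _resolve_gamma(g, R, config)
    if gamma <= 0 and np.any(R.values > 0):
        raise ValueError("gamma <= 0 with positive activations: model is infeasible")
    L, N, M = g.n_edges, g.n_nodes, R.n_modes
    nvar = L * M + L
    inv_d = 1.0 / g.capacity

    c = np.empty(nvar)
    c[: L * M] = np.repeat(inv_d, M)  # flow cost 1/D_l for each mode
    c[L * M :] = config.rho * (1.0 + inv_d)  # correction cost rho*(1 + 1/D_l)

    rows: list[int] = []
    cols: list[int] = []
    data: list[float] = []
    b = np.empty(L + N * M + L * M)

    # capacity: sum_m f_l^m - gamma * P_l <= gamma * D_l
    for l in range(L):
        for m in range(M):
            rows.append(l)
            cols.append(l * M + m)
            data.append(1.0)
        rows.append(l)
        cols.append(L * M + l)
        data.append(-gamma)
        b[l] = gamma * g.capacity[l]

    # demand: -sum_{l in N(i)} f_l^m <= -R_i^m
    inc = g.incident()
    for i in range(N):
        for m in range(M):
            r = L + i * M + m
            for l in inc[i]:
                rows.append(r)
                cols.append(l * M + m)
                data.append(-1.0)
            b[r] = -R.values[i, m]

    # feasibility: f_l^m <= max(R_i^m, R_j^m)
    for l, (i, j) in enumerate(g.edges):
        for m in range(M):
            r = L + N * M + l * M + m
            rows.append(r)
            cols.append(l * M + m)
            data.append(1.0)
            b[r] = max(R.values[i, m], R.values[j, m])

    A = sp.csr_matrix(
        (data, (rows, cols)), shape=(L + N * M + L * M, nvar), dtype=float
    )
    families = {
        "capacity": slice(0, L),
        "demand": slice(L, L + N * M),
        "feasibility": slice(L + N * M, L + N * M + L * M),
    }
    return LPSpec(c=c, A_ub=A, b_ub=b, n_edges=L, n_nodes=N, n_modes=M, gamma=gamma,
                  row_families=families)


def solve_flow(lp: LPSpec, config: ModelConfig, g: RegionGraph | None = None,
               R: ActivationMatrix | None = None) -> FlowSolution:
    """Solve the assembled LP with a deterministic method (HiGHS by default).

    The objective value is the canonical comparator for a solve: optimal flow
    patterns may be non-unique (symmetric capacities create ties), so solution
    vectors should not be compared across solvers.
    """
    L, M = lp.n_edges, lp.n_modes
    if lp.gamma == 0:
        # all-zero activation: the zero solution is optimal by construction
        return FlowSolution(
            flows=np.zeros((L, M)), corrections=np.zeros(L), objective_value=0.0,
            solver_status="optimal", max_residual=0.0, gamma=0.0,
        )
    res = linprog(lp.c, A_ub=lp.A_ub, b_ub=lp.b_ub, bounds=(0, None),
                  method=config.solver_method)
    if res.status == 2:
        msg = "LP infeasible"
        if g is not None and R is not None:
            # diagnostic: demand rows are the only rows that can be unsatisfiable
            inc = g.incident()
            worst, worst_v = None, -np.inf
            for i in range(g.n_nodes):
                cap = lp.gamma * g.capacity[inc[i]].sum()
                for m in range(R.n_modes):
                    v = R.values[i, m] - cap
                    if v > worst_v:
                        worst_v, worst = v, (g.node_labels[i], m)
            msg += f"; most-violated node demand at node {worst[0]}, mode index {worst[1]}"
        return FlowSolution(np.zeros((L, M)), np.zeros(L), np.nan, "infeasible",
                            np.inf, lp.gamma, msg)
    if not res.success:
        return FlowSolution(np.zeros((L, M)), np.zeros(L), np.nan, "error",
                            np.inf, lp.gamma, res.message)
    x = res.x
    flows = x[: L * M].reshape(L, M)
    corrections = x[L * M :]
    residual = float(np.max(lp.A_ub @ x - lp.b_ub, initial=0.0))
    residual = max(residual, float(-min(x.min(), 0.0)))
    # snap solver noise to exact zero / feasible range
    flows = np.where(flows < config.solver_tolerance, 0.0, flows)
    corrections = np.where(corrections < config.solver_tolerance, 0.0, corrections)
    return FlowSolution(flows=flows, corrections=corrections,
                        objective_value=float(res.fun), solver_status="optimal",
                        max_residual=residual, gamma=lp.gamma)


def validate_solution(g: RegionGraph, R: ActivationMatrix, config: ModelConfig,
                      sol: FlowSolution) -> dict[str, float]:
    """Per-constraint-family maximum violation of the optimal solution.

    Raises if any family violates the solver tolerance (with a small margin
    for the zero-snapping applied by :func:`solve_flow`).
    """
    if not sol.is_optimal:
        raise ValueError("validate_solution requires an optimal solution")
    L, N, M = g.n_edges, g.n_nodes, R.n_modes
    gamma = sol.gamma
    cap_viol = float(np.max(
        sol.flows.sum(axis=1) - gamma * (g.capacity + sol.corrections), initial=0.0))
    inc = g.incident()
    demand_viol = 0.0
    for i in range(N):
        gathered = sol.flows[inc[i], :].sum(axis=0) if inc[i] else np.zeros(M)
        demand_viol = max(demand_viol, float(np.max(R.values[i] - gathered, initial=0.0)))
    feas_viol = 0.0
    for l, (i, j) in enumerate(g.edges):
        bound = np.maximum(R.values[i], R.values[j])
        feas_viol = max(feas_viol, float(np.max(sol.flows[l] - bound, initial=0.0)))
    report = {"capacity": cap_viol, "demand": demand_viol, "feasibility": feas_viol}
    # zero-snapping can shift residuals by up to M*tolerance per constraint
    allowed = config.solver_tolerance * (10 + M)
    for family, viol in report.items():
        if viol > allowed:
            raise ValueError(
                f"{family} constraint violated by {viol:.3e} (allowed {allowed:.3e})"
            )
    return report


def extract_circuit(sol: FlowSolution, g: RegionGraph, mode: str | int,
                    config: ModelConfig, mode_labels: tuple[str, ...] | None = None,
                    filter_detours: bool = True) -> CircuitNetwork:
    """Edges whose flow for ``mode`` exceeds the circuit threshold, with weights.

    On a complete floored candidate graph with auto-gamma, every floor edge
    carries a small amount of free capacity (gamma * capacity_floor), so the
    optimum may spread residual demand over arbitrary floor edges at no
    correction cost.  Such detour flows are bounded by gamma * capacity_floor
    per edge; ``filter_detours`` raises the inclusion threshold to 1.5x that
    bound so circuits keep only edges carrying substantive flow.  Set it to
    False to threshold at ``flow_epsilon`` alone.
    """
    if not sol.is_optimal:
        raise ValueError("extract_circuit requires an optimal solution")
    if isinstance(mode, str):
        if mode_labels is None or mode not in mode_labels:
            raise KeyError(f"unknown mode label {mode!r}")
        m = mode_labels.index(mode)
        label = mode
    else:
        if not 0 <= mode < sol.flows.shape[1]:
            raise KeyError(f"mode index {mode} out of range")
        m = mode
        label = mode_labels[m] if mode_labels else f"mode{m}"
    threshold = config.flow_epsilon
    if filter_detours:
        threshold = max(threshold, 1.5 * sol.gamma * config.capacity_floor)
    keep = np.where(sol.flows[:, m] > threshold)[0]
    edges = tuple(g.edges[k] for k in keep)
    weights = sol.flows[keep, m].copy()
    return CircuitNetwork(mode_label=label, edges=edges, weights=weights,
                          node_labels=g.node_labels)


def enhanced_capacities(g: RegionGraph, sol: FlowSolution) -> pd.Series:
    """Corrected structural connectivity ``D_l + P_l`` per edge."""
    if not sol.is_optimal:
        raise ValueError("enhanced_capacities requires an optimal solution")
    idx = pd.MultiIndex.from_tuples(g.edge_labels(), names=["node_i", "node_j"])
    return pd.Series(g.capacity + sol.corrections, index=idx, name="enhanced_capacity")


def solve_joint_model(g: RegionGraph, R: ActivationMatrix,
                      config: ModelConfig | None = None) -> FlowSolution:
    """Assemble, solve and validate in one call; drops all-zero modes first."""
    config = config or ModelConfig()
    active = np.any(R.values > 0, axis=0)
    if not np.all(active):
        dropped = [R.mode_labels[m] for m in np.where(~active)[0]]
        warnings.warn(f"dropping all-zero activation modes: {dropped}", stacklevel=2)
        R = ActivationMatrix(R.values[:, active],
                             tuple(np.array(R.mode_labels)[active]),
                             R.node_labels)
        if R.n_modes == 0:
            return FlowSolution(np.zeros((g.n_edges, 0)), np.zeros(g.n_edges), 0.0,
                                "optimal", 0.0, 0.0)
    lp = assemble_lp(g, R, config)
    sol = solve_flow(lp, config, g, R)
    if sol.is_optimal:
        validate_solution(g, R, config, sol)
    return sol
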