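"""Readers, writers and run manifests.

All tabular artifacts are TSV/CSV with string region labels (never indices),
deterministic row/column order (canonical edge order) and floats at 12
significant digits, so a run is byte-reproducible from its manifest.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .flow_model import CircuitNetwork, FlowSolution, ModelConfig, RegionGraph

__all__ = [
    "read_adjacency",
    "write_adjacency",
    "read_edge_list",
    "read_activation",
    "write_activation",
    "write_flow_tables",
    "export_graphml",
    "write_manifest",
]

FLOAT_FMT = "%.12g"


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_adjacency(path: str | Path) -> pd.DataFrame:
    """Square labeled adjacency table from CSV/TSV (header row and column)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    if df.index.has_duplicates or df.columns.has_duplicates:
        dup = df.index[df.index.duplicated()].tolist() or \
            df.columns[df.columns.duplicated()].tolist()
        raise ValueError(f"duplicate region labels: {dup}")
    if list(df.index) != list(df.columns):
        raise ValueError("adjacency row labels do not match column labels")
    try:
        return df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc


def write_adjacency(table: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    table.to_csv(path, sep=_sep_for(path), float_format=FLOAT_FMT)


def read_edge_list(path: str | Path, nodes: list[str] | None = None) -> pd.DataFrame:
    """Dense adjacency from a 3-column (node_i, node_j, count) edge list."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), header=None,
                     names=["node_i", "node_j", "count"], comment="#", dtype=str)
    try:
        counts = df["count"].astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric count in {path}: {exc}") from exc
    if nodes is None:
        nodes = sorted(set(df["node_i"]) | set(df["node_j"]))
    adj = pd.DataFrame(0.0, index=nodes, columns=nodes)
    for (_, row), c in zip(df.iterrows(), counts):
        a, b = row["node_i"], row["node_j"]
        adj.loc[a, b] = c
        adj.loc[b, a] = c
    return adj


def read_activation(path: str | Path) -> pd.DataFrame:
    """Region x mode activation table (rows = regions, columns = modes)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.map(str)
    return df.astype(float)


def write_activation(table: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    table.to_csv(path, sep=_sep_for(path), float_format=FLOAT_FMT)


def write_flow_tables(g: RegionGraph, sol: FlowSolution,
                      mode_labels: list[str], out_dir: str | Path) -> dict[str, Path]:
    """Tidy flow and correction tables: (edge, mode, flow) and (edge, P_l)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = g.edge_labels()
    rows = [
        (a, b, mode_labels[m], sol.flows[l, m])
        for l, (a, b) in enumerate(labels)
        for m in range(sol.flows.shape[1])
    ]
    flow_path = out_dir / "flows.tsv"
    pd.DataFrame(rows, columns=["node_i", "node_j", "mode", "flow"]).to_csv(
        flow_path, sep="\t", index=False, float_format=FLOAT_FMT)
    corr_path = out_dir / "corrections.tsv"
    pd.DataFrame(
        [(a, b, sol.corrections[l]) for l, (a, b) in enumerate(labels)],
        columns=["node_i", "node_j", "P"],
    ).to_csv(corr_path, sep="\t", index=False, float_format=FLOAT_FMT)
    return {"flows": flow_path, "corrections": corr_path}


def export_graphml(network: CircuitNetwork | nx.Graph, path: str | Path) -> None:
    """GraphML export with node labels and an edge ``weight`` attribute."""
    if isinstance(network, CircuitNetwork):
        graph = nx.Graph(mode=network.mode_label)
        graph.add_nodes_from(network.node_labels)
        for (i, j), w in zip(network.edges, network.weights):
            graph.add_edge(network.node_labels[i], network.node_labels[j],
                           weight=float(w))
    else:
        graph = network
    nx.write_graphml(graph, str(path))


def import_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))


def write_manifest(path: str | Path, *, config: ModelConfig | None = None,
                   **extra) -> None:
    """JSON run manifest: parameters, seed and headline outputs."""
    payload: dict = {}
    if config is not None:
        payload.update(
            gamma=config.gamma if isinstance(config.gamma, str) else float(config.gamma),
            rho=config.rho, capacity_floor=config.capacity_floor,
            flow_epsilon=config.flow_epsilon,
            solver_tolerance=config.solver_tolerance,
            solver_method=config.solver_method, seed=config.seed,
        )
    for key, value in extra.items():
        if isinstance(value, (np.floating, np.integer)):
            value = value.item()
        payload[key] = value
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
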