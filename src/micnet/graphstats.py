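"""Centrality and integration metrics on simple undirected brain graphs.

Vertices are the 22 montage electrodes (1-based indices); edges come either
from thresholding an association matrix or from the FDR-significant pairs
of a condition contrast.  Definitions are the standard ones: degree,
shortest-path betweenness, and Latora-Marchiori global/local efficiency
(mean inverse shortest-path length; the local variant is the global
efficiency of the subgraph induced by a vertex's neighbors).  All values
are computed with networkx.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from micnet.paradigm import Montage, standard_montage

__all__ = [
    "SignificanceGraph",
    "VertexMetrics",
    "degree_centrality",
    "betweenness_centrality",
    "global_efficiency",
    "local_efficiency",
    "vertex_metrics_table",
]


@dataclass(frozen=True)
class SignificanceGraph:
    """Simple undirected unweighted graph over channel indices 1..n."""

    n_vertices: int = 22
    edges: frozenset[tuple[int, int]] = field(default_factory=frozenset)
    vertex_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        canon = set()
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-loop at vertex {i}")
            if not (1 <= i <= self.n_vertices and 1 <= j <= self.n_vertices):
                raise ValueError(f"edge ({i}, {j}) outside 1..{self.n_vertices}")
            canon.add((min(i, j), max(i, j)))
        object.__setattr__(self, "edges", frozenset(canon))
        if self.vertex_names is not None and len(self.vertex_names) != self.n_vertices:
            raise ValueError("vertex_names length must equal n_vertices")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(1, self.n_vertices + 1))
        g.add_edges_from(self.edges)
        return g

    def names(self, montage: Montage | None = None) -> tuple[str, ...]:
        if self.vertex_names is not None:
            return self.vertex_names
        montage = montage or standard_montage()
        return tuple(montage.channels[: self.n_vertices])


@dataclass(frozen=True)
class VertexMetrics:
    """Per-vertex metric vectors aligned with vertex index order."""

    degree: np.ndarray
    betweenness_raw: np.ndarray
    betweenness_norm: np.ndarray
    local_efficiency: np.ndarray


def degree_centrality(
    g: SignificanceGraph, include_isolated: bool = False
) -> dict:
    """Per-vertex degrees with a mean/sd summary and a degree ranking.

    The summary is computed over all vertices when ``include_isolated`` is
    true, otherwise over vertices with degree >= 1 (the default for sparse
    significance graphs, where isolated electrodes carry no information).
    """
    graph = g.to_networkx()
    degrees = np.array([graph.degree(v) for v in range(1, g.n_vertices + 1)])
    active = degrees if include_isolated else degrees[degrees > 0]
    if active.size:
        mean = float(active.mean())
        sd = float(active.std(ddof=1)) if active.size > 1 else 0.0
    else:
        mean = sd = 0.0
    order = np.argsort(-degrees, kind="stable")
    names = g.names()
    ranking = [(names[v], int(degrees[v])) for v in order if degrees[v] > 0]
    return {
        "degree": degrees,
        "mean": mean,
        "sd": sd,
        "ranking": ranking,
    }


def betweenness_centrality(g: SignificanceGraph) -> dict:
    """Raw pair-count betweenness and the (n-1)(n-2)/2-normalized variant.

    Raw BC(v) sums sigma_st(v)/sigma_st over unordered pairs s != t, both
    distinct from v; the normalized value divides by the number of such
    pairs, (n-1)(n-2)/2.
    """
    graph = g.to_networkx()
    raw = nx.betweenness_centrality(graph, normalized=False)
    norm = nx.betweenness_centrality(graph, normalized=True)
    order = range(1, g.n_vertices + 1)
    return {
        "raw": np.array([raw[v] for v in order]),
        "normalized": np.array([norm[v] for v in order]),
    }


def global_efficiency(g: SignificanceGraph) -> float:
    """Mean inverse shortest-path length over unordered vertex pairs.

    Disconnected pairs contribute 0 (1/infinity).  Requires >= 2 vertices.
    """
    if g.n_vertices < 2:
        raise ValueError("global efficiency needs >= 2 vertices")
    return float(nx.global_efficiency(g.to_networkx()))


def local_efficiency(g: SignificanceGraph) -> dict:
    """Per-vertex local efficiency and its mean over all vertices.

    E_loc(v) is the global efficiency of the subgraph induced by the
    neighbors of v, defined as 0 when v has fewer than 2 neighbors.
    """
    graph = g.to_networkx()
    values = np.zeros(g.n_vertices)
    for v in range(1, g.n_vertices + 1):
        neighbors = list(graph.neighbors(v))
        if len(neighbors) < 2:
            continue
        values[v - 1] = nx.global_efficiency(graph.subgraph(neighbors))
    return {"local_efficiency": values, "mean": float(values.mean())}


def vertex_metrics_table(
    g: SignificanceGraph, montage: Montage | None = None
) -> pd.DataFrame:
    """All per-vertex metrics as a tidy table keyed by electrode name."""
    deg = degree_centrality(g, include_isolated=True)
    bc = betweenness_centrality(g)
    loc = local_efficiency(g)
    names = g.names(montage)
    return pd.DataFrame(
        {
            "vertex": names,
            "degree": deg["degree"],
            "betweenness_raw": bc["raw"],
            "betweenness_norm": bc["normalized"],
            "local_efficiency": loc["local_efficiency"],
        }
    )


def graph_summary(g: SignificanceGraph) -> dict:
    """Graph-level metrics for JSON export."""
    loc = local_efficiency(g)
    return {
        "n_vertices": g.n_vertices,
        "n_edges": g.n_edges,
        "global_efficiency": global_efficiency(g),
        "mean_local_efficiency": loc["mean"],
    }


def write_metrics(
    g: SignificanceGraph, prefix: str | Path, montage: Montage | None = None
) -> None:
    prefix = Path(prefix)
    vertex_metrics_table(g, montage).to_csv(
        prefix.with_suffix(".tsv"), sep="\t", index=False, float_format="%.6g"
    )
    prefix.with_suffix(".json").write_text(json.dumps(graph_summary(g), indent=2))
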