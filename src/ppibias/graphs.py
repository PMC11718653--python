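"""Hypothetical ground-truth interactome generators.

The ground truth of an observed PPI network is unknown; to study what
measurement bias does to degree distributions we need controllable stand-ins
with radically different topologies.  Two classical random-graph families are
provided:

* Erdős–Rényi (ER) graphs, whose node degrees are binomially distributed
  (no hubs), in both the fixed-edge-count G(n, m) and the fixed-probability
  G(n, p) flavor;
* Barabási–Albert (BA) preferential-attachment graphs, whose node degrees
  follow a power law (hubs emerge naturally).

Graphs are plain :class:`networkx.Graph` objects: simple, undirected, with
integer nodes ``0..n-1`` for synthetic graphs.
"""

from __future__ import annotations

import math
from typing import Iterable

import networkx as nx
import numpy as np

__all__ = [
    "generate_er",
    "generate_er_p",
    "ba_edges_for_target",
    "generate_ba",
    "degree_sequence",
    "write_edge_tsv",
    "read_edge_tsv",
]


def generate_er(n: int, m_er: int, seed: int) -> nx.Graph:
    """Uniform random simple graph with exactly ``n`` nodes and ``m_er`` edges."""
    if n < 1:
        raise ValueError("n must be positive")
    max_edges = n * (n - 1) // 2
    if not 0 <= m_er <= max_edges:
        raise ValueError(f"m_er must be in [0, {max_edges}] for n={n}")
    g = nx.gnm_random_graph(n, m_er, seed=seed)
    return g


def generate_er_p(n: int, p: float, seed: int) -> nx.Graph:
    """ER graph G(n, p): each possible edge included independently with probability ``p``.

    ``p=0`` returns the empty graph on ``n`` nodes (the empty ground truth).
    """
    if n < 1:
        raise ValueError("n must be positive")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be a probability")
    if p == 0.0:
        g = nx.empty_graph(n)
    elif p == 1.0:
        g = nx.complete_graph(n)
    else:
        g = nx.fast_gnp_random_graph(n, p, seed=seed)
    return g


def ba_edges_for_target(n: int, m_er: int) -> int:
    """Edges-per-step ``m_ba`` so that a star-initialized BA graph on ``n`` nodes
    ends up with approximately ``m_er`` edges.

    A BA graph grown from a star on ``m_ba + 1`` nodes has exactly
    ``m_ba + m_ba * (n - (m_ba + 1))`` edges; solving that quadratic for the
    target count gives ``m_ba = round(n/2 - sqrt(n^2/4 - m_er))``.
    """
    if n < 1 or m_er < 1:
        raise ValueError("n and m_er must be positive")
    disc = n * n / 4.0 - m_er
    if disc < 0:
        raise ValueError(f"m_er={m_er} exceeds n^2/4={n * n / 4.0}; no real solution")
    m_ba = round(n / 2.0 - math.sqrt(disc))
    if m_ba < 1:
        raise ValueError(
            f"target edge count m_er={m_er} is too small relative to n={n}: "
            "the BA sizing rule rounds to zero edges per step"
        )
    return m_ba


def generate_ba(n: int, m_ba: int, seed: int) -> nx.Graph:
    """Barabási–Albert graph initialized with the star on ``m_ba + 1`` nodes.

    Each node added after the initial star attaches ``m_ba`` edges to distinct
    existing nodes with probability proportional to their current degree, so
    the final edge count is exactly ``m_ba + m_ba * (n - (m_ba + 1))``.
    """
    if not 1 <= m_ba < n:
        raise ValueError("require 1 <= m_ba < n")
    return nx.barabasi_albert_graph(n, m_ba, seed=seed)


def ba_edge_count(n: int, m_ba: int) -> int:
    """Closed-form edge count of a star-initialized BA graph."""
    return m_ba + m_ba * (n - (m_ba + 1))


def degree_sequence(g: nx.Graph) -> np.ndarray:
    """Degree of every node, in node-iteration order (one entry per node)."""
    return np.fromiter((d for _, d in g.degree()), dtype=np.int64, count=g.number_of_nodes())


def _canonical(u, v):
    return (u, v) if str(u) <= str(v) else (v, u)


def write_edge_tsv(g: nx.Graph, path, header: bool = False) -> None:
    """Serialize a graph as a 2-column TSV edge list, endpoints ordered per line."""
    edges = sorted(_canonical(u, v) for u, v in g.edges())
    with open(path, "w") as fh:
        if header:
            fh.write("u\tv\n")
        for u, v in edges:
            fh.write(f"{u}\t{v}\n")


def read_edge_tsv(path, header: bool = False, nodes: Iterable | None = None) -> nx.Graph:
    """Read a 2-column TSV edge list; optionally pre-populate isolated nodes."""
    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    with open(path) as fh:
        if header:
            next(fh, None)
        for line in fh:
            line = line.strip()
            if not line:
                continue
            u, v = line.split("\t")[:2]
            if u != v:
                g.add_edge(u, v)
    return g
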