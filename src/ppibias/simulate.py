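"""Simulation of observed aggregated PPI networks under study bias.

The simulator measures a hypothetical ground-truth interactome through a
sequence of experiments.  Each experiment selects a list of baits — with
probability proportional to the protein's current degree in the simulated
observed network plus a small baseline ``delta`` (the study-bias feedback
loop) — and a list of preys (uniformly for AP-MS, degree-biased for Y2H),
then tests every ordered bait x prey pair once.  A test of a true edge is
positive with probability 1 - FNR, a test of a non-edge with probability FPR.
Symmetric counters track, per unordered pair, how often it was tested (``a``)
and how often it tested positive (``b``); after each experiment the observed
edge set is

    E' = { uv : b_uv > 0  and  b_uv / a_uv > gamma },

where ``gamma`` in [0, 1) is the minimum required fraction of positive tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "TestCounts",
    "SimConfig",
    "SimResult",
    "sample_baits",
    "sample_preys",
    "run_experiment",
    "current_edges",
    "simulate",
]

METHODS = ("AP-MS", "Y2H")
_DENSE_LIMIT = 4000  # use dense count matrices for integer-labelled graphs up to this size


def _pair(u, v):
    try:
        return (u, v) if u <= v else (v, u)
    except TypeError:
        return (u, v) if str(u) <= str(v) else (v, u)


class TestCounts:
    """Symmetric sparse per-pair counters: times tested (a) and times positive (b)."""

    def __init__(self):
        self._c: dict[tuple, list[int]] = {}

    def a(self, u, v) -> int:
        return self._c.get(_pair(u, v), (0, 0))[0]

    def b(self, u, v) -> int:
        return self._c.get(_pair(u, v), (0, 0))[1]

    def record(self, u, v, positive: bool) -> None:
        if u == v:
            raise ValueError("self-pairs are not tested")
        e = self._c.setdefault(_pair(u, v), [0, 0])
        e[0] += 1
        e[1] += int(positive)

    def pairs(self):
        """Iterate (u, v, a, b) over all tested pairs."""
        for (u, v), (a, b) in self._c.items():
            yield u, v, a, b

    def __len__(self):
        return len(self._c)

    def to_tsv(self, path) -> None:
        rows = sorted(self._c.items(), key=lambda kv: (str(kv[0][0]), str(kv[0][1])))
        with open(path, "w") as fh:
            fh.write("u\tv\ta\tb\n")
            for (u, v), (a, b) in rows:
                fh.write(f"{u}\t{v}\t{a}\t{b}\n")


@dataclass(frozen=True)
class SimConfig:
    """Hyper-parameters of one simulated measurement campaign."""

    method: str
    fnr: float
    fpr: float
    gamma: float
    n_experiments: int
    study_sizes: Sequence[tuple[int, int]]
    delta: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        for name in ("fnr", "fpr"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a probability")
        if not 0.0 <= self.gamma < 1.0:
            raise ValueError("gamma must lie in [0, 1)")
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if len(self.study_sizes) != self.n_experiments:
            raise ValueError("study_sizes must have one (n_bait, n_prey) pair per experiment")


@dataclass
class SimResult:
    """Outcome of a simulated campaign."""

    network: nx.Graph
    counts: TestCounts
    log: list = field(default_factory=list)  # (baits, preys, n_positive) per experiment


def _weighted_sample(weights: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k distinct indices, sequentially drawn proportional to ``weights``.

    Uses exponential race keys, which is distributionally identical to
    successive draw-and-renormalize weighted sampling without replacement.
    """
    keys = rng.exponential(size=weights.size) / weights
    if k >= weights.size:
        return np.argsort(keys)
    idx = np.argpartition(keys, k)[:k]
    return idx[np.argsort(keys[idx])]


def sample_baits(
    current_degrees: Mapping[Hashable, int], n_bait: int, delta: float, seed
) -> list:
    """Sample ``n_bait`` distinct baits with probability ~ degree + delta."""
    nodes = list(current_degrees.keys())
    if n_bait > len(nodes):
        raise ValueError("n_bait exceeds number of nodes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w = np.array([current_degrees[u] for u in nodes], dtype=np.float64) + delta
    idx = _weighted_sample(w, n_bait, rng)
    return [nodes[i] for i in idx]


def sample_preys(
    current_degrees: Mapping[Hashable, int],
    n_prey: int,
    method: str,
    delta: float,
    seed,
) -> list:
    """Sample ``n_prey`` distinct preys: uniformly (AP-MS) or degree-biased (Y2H)."""
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    nodes = list(current_degrees.keys())
    if n_prey > len(nodes):
        raise ValueError("n_prey exceeds number of nodes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if method == "AP-MS":
        idx = rng.permutation(len(nodes))[:n_prey]
    else:
        w = np.array([current_degrees[u] for u in nodes], dtype=np.float64) + delta
        idx = _weighted_sample(w, n_prey, rng)
    return [nodes[i] for i in idx]


def run_experiment(
    ground_truth: nx.Graph,
    baits: Sequence,
    preys: Sequence,
    fnr: float,
    fpr: float,
    counts: TestCounts,
    seed,
) -> TestCounts:
    """Test every ordered bait x prey pair once (self-pairs skipped), updating ``counts``."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for u in baits:
        for v in preys:
            if u == v:
                continue
            p_pos = 1.0 - fnr if ground_truth.has_edge(u, v) else fpr
            counts.record(u, v, rng.random() < p_pos)
    return counts


def current_edges(counts: TestCounts, gamma: float) -> set:
    """Edge set implied by the counters: pairs with b > 0 and b/a > gamma (strict)."""
    return {
        (u, v) for u, v, a, b in counts.pairs() if b > 0 and b / a > gamma
    }


def _simulate_dense(ground_truth: nx.Graph, config: SimConfig) -> SimResult:
    """Vectorized path for integer-labelled graphs 0..n-1 (desk-scale grids)."""
    n = ground_truth.number_of_nodes()
    rng = np.random.default_rng(config.seed)
    adj = np.zeros((n, n), dtype=bool)
    for u, v in ground_truth.edges():
        adj[u, v] = adj[v, u] = True
    a_mat = np.zeros((n, n), dtype=np.int32)
    b_mat = np.zeros((n, n), dtype=np.int32)
    edge = np.zeros((n, n), dtype=bool)
    deg = np.zeros(n, dtype=np.int64)
    log = []

    for n_bait, n_prey in config.study_sizes:
        if n_bait > n or n_prey > n:
            raise ValueError("study size exceeds number of nodes")
        w = deg + config.delta
        baits = _weighted_sample(w.astype(np.float64), n_bait, rng)
        if config.method == "AP-MS":
            preys = rng.permutation(n)[:n_prey]
        else:
            preys = _weighted_sample(w.astype(np.float64), n_prey, rng)
        iu = np.repeat(baits, n_prey)
        iv = np.tile(preys, n_bait)
        keep = iu != iv
        iu, iv = iu[keep], iv[keep]
        p_pos = np.where(adj[iu, iv], 1.0 - config.fnr, config.fpr)
        pos = rng.random(iu.size) < p_pos
        posi = pos.astype(np.int32)
        np.add.at(a_mat, (iu, iv), 1)
        np.add.at(a_mat, (iv, iu), 1)
        np.add.at(b_mat, (iu, iv), posi)
        np.add.at(b_mat, (iv, iu), posi)
        # re-evaluate the gamma rule only on the touched pairs
        lo, hi = np.minimum(iu, iv), np.maximum(iu, iv)
        codes = np.unique(lo.astype(np.int64) * n + hi)
        tu, tv = codes // n, codes % n
        new_state = (b_mat[tu, tv] > 0) & (b_mat[tu, tv] > config.gamma * a_mat[tu, tv])
        changed = new_state != edge[tu, tv]
        cu, cv, cs = tu[changed], tv[changed], new_state[changed]
        edge[cu, cv] = edge[cv, cu] = cs
        dd = np.where(cs, 1, -1)
        np.add.at(deg, cu, dd)
        np.add.at(deg, cv, dd)
        log.append((baits.tolist(), preys.tolist(), int(pos.sum())))

    counts = TestCounts()
    tu, tv = np.nonzero(np.triu(a_mat, 1))
    for u, v, a, b in zip(tu.tolist(), tv.tolist(), a_mat[tu, tv].tolist(), b_mat[tu, tv].tolist()):
        counts._c[(u, v)] = [a, b]
    net = nx.Graph()
    net.add_nodes_from(range(n))
    eu, ev = np.nonzero(np.triu(edge, 1))
    net.add_edges_from(zip(eu.tolist(), ev.tolist()))
    return SimResult(network=net, counts=counts, log=log)


def _simulate_sparse(ground_truth: nx.Graph, config: SimConfig) -> SimResult:
    nodes = list(ground_truth.nodes())
    rng = np.random.default_rng(config.seed)
    counts = TestCounts()
    deg = dict.fromkeys(nodes, 0)
    edges: set[tuple] = set()
    log = []

    for n_bait, n_prey in config.study_sizes:
        baits = sample_baits(deg, n_bait, config.delta, rng)
        preys = sample_preys(deg, n_prey, config.method, config.delta, rng)
        n_pos = 0
        for u in baits:
            for v in preys:
                if u == v:
                    continue
                p_pos = 1.0 - config.fnr if ground_truth.has_edge(u, v) else config.fpr
                positive = bool(rng.random() < p_pos)
                counts.record(u, v, positive)
                n_pos += positive
                key = _pair(u, v)
                a, b = counts._c[key]
                now = b > 0 and b > config.gamma * a
                if now and key not in edges:
                    edges.add(key)
                    deg[key[0]] += 1
                    deg[key[1]] += 1
                elif not now and key in edges:
                    edges.remove(key)
                    deg[key[0]] -= 1
                    deg[key[1]] -= 1
        log.append((baits, preys, n_pos))

    net = nx.Graph()
    net.add_nodes_from(nodes)
    net.add_edges_from(edges)
    return SimResult(network=net, counts=counts, log=log)


def simulate(ground_truth: nx.Graph, config: SimConfig) -> SimResult:
    """Run a full simulated measurement campaign against ``ground_truth``.

    Baits and preys of experiment i are sampled against the degree map of the
    simulated observed network after experiment i-1 (under the configured
    gamma), closing the study-bias feedback loop.  Fully reproducible from
    ``config.seed``.
    """
    n = ground_truth.number_of_nodes()
    dense = n <= _DENSE_LIMIT and all(
        isinstance(u, (int, np.integer)) for u in ground_truth.nodes()
    ) and set(ground_truth.nodes()) == set(range(n))
    if dense:
        return _simulate_dense(ground_truth, config)
    return _simulate_sparse(ground_truth, config)
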