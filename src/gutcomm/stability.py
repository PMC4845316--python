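"""Markov-stability community detection and plateau-based model selection.

The quality of a partition P of a connected graph at Markov time t is

    R(t, P) = sum over blocks B of sum_{i,j in B} [ (Pi exp(-t L))_ij - pi_i pi_j ]

with pi = degree / 2m, Pi = diag(pi) and L = I - D^{-1} A the random-walk
Laplacian. The exact matrix exponential is used (graphs here are small);
optimization is greedy agglomerative node moving with aggregation
(Louvain-style) over multiple seeded restarts. The number of communities
is chosen as the k > 2 whose plateau on the log-time grid is longest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

UNASSIGNED = -1


@dataclass
class Partition:
    """Node -> community label map with contiguous labels 0..k-1."""

    labels: dict[str, int]

    def __post_init__(self) -> None:
        ks = sorted(set(self.labels.values()))
        if ks != list(range(len(ks))):
            raise ValueError("labels must be contiguous 0..k-1")

    @property
    def k(self) -> int:
        return len(set(self.labels.values()))

    def community(self, label: int) -> list[str]:
        return sorted(n for n, c in self.labels.items() if c == label)

    @staticmethod
    def from_array(nodes: Sequence[str], arr: Sequence[int]) -> "Partition":
        return Partition(dict(zip(nodes, _canonical(np.asarray(arr)).tolist())))


@dataclass
class StabilityCurve:
    t_grid: np.ndarray
    partitions: list[Partition]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.t_grid = np.asarray(self.t_grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.diff(self.t_grid) > 0) or np.any(self.t_grid < 0):
            raise ValueError("t_grid must be strictly increasing and nonnegative")

    @property
    def ks(self) -> np.ndarray:
        return np.array([p.k for p in self.partitions])


def _canonical(arr: np.ndarray) -> np.ndarray:
    """Relabel to contiguous ints by order of first occurrence."""
    mapping: dict[int, int] = {}
    out = np.empty(len(arr), dtype=int)
    for i, v in enumerate(arr):
        if v not in mapping:
            mapping[v] = len(mapping)
        out[i] = mapping[v]
    return out


def _adjacency(net: nx.Graph, nodes: list[str], weighted: bool) -> np.ndarray:
    weight = "rho" if weighted else None
    A = nx.to_numpy_array(net, nodelist=nodes, weight=weight)
    if not weighted:
        A = (A > 0).astype(float)
    return A


def stability_matrix(net: nx.Graph, t: float, weighted: bool = False,
                     linearized: bool = False) -> tuple[list[str], np.ndarray]:
    """Return (node order, B) with R(t,P) = sum of B over within-block pairs."""
    nodes = sorted(net.nodes())
    A = _adjacency(net, nodes, weighted)
    if A.sum() == 0:
        raise ValueError("graph has no edges")
    deg = A.sum(axis=1)
    if np.any(deg == 0):
        raise ValueError("graph must be connected (isolated node found)")
    two_m = deg.sum()
    pi = deg / two_m
    if linearized:
        # first-order expansion: (1-t) * Pi + t * A/2m  minus pi pi^T
        B = (1 - t) * np.diag(pi) + t * A / two_m - np.outer(pi, pi)
        return nodes, B
    if t == 0:
        P = np.eye(len(nodes))
    else:
        # exp(-tL) via the symmetrized generator: L = D^{-1/2}(I - N)D^{1/2}
        d_isqrt = 1.0 / np.sqrt(deg)
        N = A * np.outer(d_isqrt, d_isqrt)
        w, U = np.linalg.eigh(N)
        P = (U * np.exp(-t * (1.0 - w))) @ U.T
        P = P * np.outer(d_isqrt, np.sqrt(deg))  # D^{-1/2} expm D^{1/2}
    B = pi[:, None] * P - np.outer(pi, pi)
    B = 0.5 * (B + B.T)  # reversibility makes Pi P symmetric; enforce numerically
    return nodes, B


def stability(net: nx.Graph, partition: Partition, t: float,
              weighted: bool = False, linearized: bool = False) -> float:
    """Markov stability of ``partition`` at time ``t``."""
    nodes, B = stability_matrix(net, t, weighted=weighted, linearized=linearized)
    missing = [n for n in nodes if n not in partition.labels]
    if missing:
        raise ValueError(f"partition does not cover nodes: {missing}")
    labels = np.array([partition.labels[n] for n in nodes])
    return _partition_value(B, labels)


def _partition_value(B: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for c in np.unique(labels):
        idx = np.nonzero(labels == c)[0]
        total += B[np.ix_(idx, idx)].sum()
    return float(total)


def _louvain_level(B: np.ndarray, order: np.ndarray) -> np.ndarray:
    """One level of greedy node moving on quality matrix B (symmetric)."""
    n = len(B)
    labels = np.arange(n)
    improved = True
    while improved:
        improved = False
        labels = _canonical(labels)
        for v in order:
            c = labels[v]
            # gain of moving v to community d: 2*(S[d] - S[c without v]) for d != c
            link = np.zeros(labels.max() + 2)
            np.add.at(link, labels, B[v])
            link_c_without_v = link[c] - B[v, v]
            candidates = np.unique(labels)
            gains = link[candidates] - link_c_without_v
            gains[candidates == c] = 0.0
            # moving to a fresh singleton community
            singleton_gain = -link_c_without_v
            best_idx = int(np.argmax(gains))
            best_gain = gains[best_idx]
            if singleton_gain > best_gain + 1e-12:
                new_label = int(labels.max()) + 1
                if singleton_gain > 1e-12:
                    labels[v] = new_label
                    improved = True
                continue
            if best_gain > 1e-12:
                labels[v] = candidates[best_idx]
                improved = True
    return _canonical(labels)


def _aggregate(B: np.ndarray, labels: np.ndarray) -> np.ndarray:
    k = labels.max() + 1
    M = np.zeros((k, len(B)))
    for i, c in enumerate(labels):
        M[c, i] = 1.0
    return M @ B @ M.T


def optimize_partition(net: nx.Graph, t: float, seed: Optional[int] = None,
                       n_restarts: int = 20, weighted: bool = False,
                       linearized: bool = False) -> Partition:
    """Best-of-``n_restarts`` Louvain-style maximization of stability at ``t``."""
    nodes, B = stability_matrix(net, t, weighted=weighted, linearized=linearized)
    labels, _ = _optimize_matrix(B, seed=seed, n_restarts=n_restarts)
    return Partition.from_array(nodes, labels)


def _optimize_matrix(B: np.ndarray, seed: Optional[int], n_restarts: int
                     ) -> tuple[np.ndarray, float]:
    rng = np.random.default_rng(seed)
    n = len(B)
    best_labels = np.zeros(n, dtype=int)
    best_value = _partition_value(B, best_labels)
    for _ in range(n_restarts):
        labels = _run_louvain(B, rng.permutation(n), rng)
        value = _partition_value(B, labels)
        if value > best_value + 1e-12:
            best_value, best_labels = value, labels
    return _canonical(best_labels), best_value


def _run_louvain(B: np.ndarray, order: np.ndarray, rng: np.random.Generator
                 ) -> np.ndarray:
    mapping = np.arange(len(B))  # node -> current community in original space
    current = B
    while True:
        labels = _louvain_level(current, order)
        if labels.max() + 1 == len(current):  # no merge happened
            break
        mapping = labels[mapping]
        current = _aggregate(current, labels)
        if len(current) == 1:
            break
        order = rng.permutation(len(current))
    return _canonical(mapping)


def stability_sweep(net: nx.Graph, t_min: float = 0.01, t_max: float = 100.0,
                    n_points: int = 60, seed: Optional[int] = None,
                    n_restarts: int = 20, weighted: bool = False,
                    linearized: bool = False) -> StabilityCurve:
    """Optimize the partition on a log-spaced Markov-time grid."""
    if not nx.is_connected(net):
        raise ValueError("graph must be connected; apply largest_component first")
    t_grid = np.logspace(np.log10(t_min), np.log10(t_max), n_points)
    nodes = sorted(net.nodes())
    partitions, values = [], []
    rng = np.random.default_rng(seed)
    for t in t_grid:
        _, B = stability_matrix(net, t, weighted=weighted, linearized=linearized)
        labels, value = _optimize_matrix(B, seed=int(rng.integers(2 ** 31)),
                                         n_restarts=n_restarts)
        partitions.append(Partition.from_array(nodes, labels))
        values.append(value)
    ks = [p.k for p in partitions]
    if any(b > a for a, b in zip(ks, ks[1:])):
        logger.info("community count not monotone along the sweep: %s", ks)
    return StabilityCurve(t_grid, partitions, np.array(values))


def select_partition(curve: StabilityCurve, min_k_exclusive: int = 2) -> Partition:
    """Pick the k > ``min_k_exclusive`` with the longest contiguous log-t run.

    Returns the partition at the midpoint grid index of that run; span ties
    go to the smaller k. Near-singleton partitions (k >= n/2, i.e. mostly
    singleton communities) are excluded: they are the trivial fine-scale
    regime at small Markov time, and the span of that leftmost run is an
    artifact of where the grid starts.
    """
    ks = curve.ks
    n_nodes = len(curve.partitions[0].labels)
    k_cap = max(min_k_exclusive + 1, (n_nodes + 1) // 2)
    logt = np.log10(np.maximum(curve.t_grid, np.finfo(float).tiny))
    runs = []  # (k, span, start, end)
    start = 0
    for i in range(1, len(ks) + 1):
        if i == len(ks) or ks[i] != ks[start]:
            runs.append((int(ks[start]), logt[i - 1] - logt[start], start, i - 1))
            start = i
    best = None
    for k, span, a, b in runs:
        if k <= min_k_exclusive or k > k_cap:
            continue
        if best is None or span > best[1] + 1e-12 or \
                (abs(span - best[1]) <= 1e-12 and k < best[0]):
            best = (k, span, a, b)
    if best is None:
        raise ValueError(f"no partition with k > {min_k_exclusive} on the grid")
    _, _, a, b = best
    return curve.partitions[(a + b) // 2]


def assign_communities(full_net: nx.Graph, partition: Partition) -> dict[str, int]:
    """Carry community labels over to the full network.

    Nodes outside the partitioned (largest) component or with degree <= 1
    in the full network get :data:`UNASSIGNED`.
    """
    out = {}
    for node in full_net.nodes():
        if node in partition.labels and full_net.degree(node) > 1:
            out[node] = partition.labels[node]
        else:
            out[node] = UNASSIGNED
    return out


def write_curve(curve: StabilityCurve, path) -> None:
    with open(path, "w") as fh:
        fh.write("t\tk\tstability\n")
        for t, p, v in zip(curve.t_grid, curve.partitions, curve.values):
            fh.write(f"{t:.8g}\t{p.k}\t{v:.10g}\n")


def write_assignment(assignment: dict[str, int], net: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("genus\tcommunity\tdegree\n")
        for node in sorted(assignment):
            label = assignment[node]
            text = "UNASSIGNED" if label == UNASSIGNED else str(label)
            deg = net.degree(node) if node in net else 0
            fh.write(f"{node}\t{text}\t{deg}\n")


def read_assignment(path) -> dict[str, int]:
    out = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("genus"):
            raise ValueError(f"{path}: expected assignment header")
        for line in fh:
            genus, label, _ = line.rstrip("\n").split("\t")
            out[genus] = UNASSIGNED if label == "UNASSIGNED" else int(label)
    return out
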