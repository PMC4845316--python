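"""Compositionality-corrected Spearman co-occurrence network (ReBoot scheme).

For a genus pair the null distribution is built by permuting one genus
across samples and renormalizing every sample to unit sum before
recomputing the rank correlation; the alternative distribution is built by
bootstrap resampling of samples. The two distributions are compared with a
two-sided z-test. With ``null_variance="perm"`` (the default) the z
denominator is the permutation standard deviation, which is calibrated
(null p-values approximately uniform); ``"pooled"`` adds the bootstrap
variance and is markedly conservative.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .preprocess import AbundanceTable


@dataclass(frozen=True)
class CorrelationResult:
    genus_i: str
    genus_j: str
    rho: float
    p: float


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("spearman_rho undefined for constant input")
    return float(stats.spearmanr(x, y).statistic)


def permute_and_renormalize(values: np.ndarray, i: int, perm: np.ndarray) -> np.ndarray:
    """Replace row ``i`` by its permutation and renormalize every column to 1.

    Reference implementation of the ReBoot permutation step, used to
    cross-check the O(1)-per-row shortcut in :func:`reboot_pvalue`.
    """
    out = np.array(values, dtype=float, copy=True)
    out[i] = values[i][perm]
    sums = out.sum(axis=0)
    if np.any(sums <= 0):
        raise ValueError("column sum became nonpositive")
    return out / sums


def _rowwise_spearman(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Spearman rho between matching rows of X and Y (average ranks)."""
    rx = stats.rankdata(X, axis=1)
    ry = stats.rankdata(Y, axis=1)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean(axis=1, keepdims=True)
    num = (rx * ry).sum(axis=1)
    den = np.sqrt((rx ** 2).sum(axis=1) * (ry ** 2).sum(axis=1))
    out = np.zeros(len(num))
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def reboot_pvalue(abundance: AbundanceTable, i, j, n_perm: int = 1000,
                  n_boot: int = 1000, seed: Optional[int] = None,
                  rng: Optional[np.random.Generator] = None,
                  null_variance: str = "perm") -> CorrelationResult:
    """Compositionality-corrected p-value for one genus pair.

    ``i``/``j`` may be genus names or row indices. Columns of ``abundance``
    must sum to one: permuting row ``i`` then renormalizing column ``s``
    divides rows i and j by ``1 - x_s + x_perm(s)``, which is all the pair
    correlation needs, so only the two rows are materialized.
    """
    if n_perm < 100 or n_boot < 100:
        raise ValueError("n_perm and n_boot must be >= 100")
    if isinstance(i, str):
        i = abundance.genus_ids.index(i)
    if isinstance(j, str):
        j = abundance.genus_ids.index(j)
    name_i, name_j = abundance.genus_ids[i], abundance.genus_ids[j]
    x = abundance.values[i]
    y = abundance.values[j]
    n = len(x)
    if n < 20:
        warnings.warn(f"reboot_pvalue with only {n} samples", stacklevel=2)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn(f"constant genus in pair ({name_i}, {name_j}); p set to 1",
                      stacklevel=2)
        return CorrelationResult(name_i, name_j, 0.0, 1.0)
    if rng is None:
        rng = np.random.default_rng(seed)

    rho_obs = float(stats.spearmanr(x, y).statistic)

    # permutation null with per-sample renormalization (shortcut, see docstring)
    XP = rng.permuted(np.broadcast_to(x, (n_perm, n)), axis=1)
    S = 1.0 - x + XP
    rho_perm = _rowwise_spearman(XP / S, np.broadcast_to(y, XP.shape) / S)

    # bootstrap over samples
    idx = rng.integers(0, n, size=(n_boot, n))
    rho_boot = _rowwise_spearman(x[idx], y[idx])

    mean_perm, var_perm = rho_perm.mean(), rho_perm.var(ddof=1)
    mean_boot, var_boot = rho_boot.mean(), rho_boot.var(ddof=1)
    if null_variance == "pooled":
        denom = np.sqrt(var_perm + var_boot)
    elif null_variance == "perm":
        denom = np.sqrt(var_perm)
    else:
        raise ValueError(f"unknown null_variance {null_variance!r}")
    if denom == 0:
        return CorrelationResult(name_i, name_j, rho_obs, 1.0)
    z = (mean_boot - mean_perm) / denom
    p = float(2.0 * stats.norm.sf(abs(z)))
    return CorrelationResult(name_i, name_j, rho_obs, p)


def all_pairs(abundance: AbundanceTable, n_perm: int = 1000, n_boot: int = 1000,
              seed: Optional[int] = None,
              null_variance: str = "perm") -> list[CorrelationResult]:
    """ReBoot correlation results for every unordered genus pair."""
    rng = np.random.default_rng(seed)
    results = []
    m = len(abundance.genus_ids)
    for i, j in itertools.combinations(range(m), 2):
        results.append(reboot_pvalue(abundance, i, j, n_perm=n_perm, n_boot=n_boot,
                                     rng=rng, null_variance=null_variance))
    return results


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        running = min(running, p[order[rank]] * m / (rank + 1))
        adj[order[rank]] = running
    return adj


def build_network(results: Iterable[CorrelationResult], rho_min: float = 0.4,
                  alpha: float = 0.05, nodes: Optional[Sequence[str]] = None,
                  bh_correct: bool = False) -> nx.Graph:
    """Edge iff p < alpha and rho > rho_min (positive correlations only).

    ``nodes`` optionally forces the node set (so genera without any
    accepted edge still appear, e.g. for later degree-based exclusion).
    No multiple-testing correction by default; ``bh_correct`` switches the
    threshold to Benjamini-Hochberg adjusted p-values.
    """
    results = sorted(results, key=lambda r: (r.genus_i, r.genus_j))
    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    else:
        for r in results:
            g.add_node(r.genus_i)
            g.add_node(r.genus_j)
    pvals = [r.p for r in results]
    effective = benjamini_hochberg(pvals) if (bh_correct and pvals) else pvals
    for r, p_eff in zip(results, effective):
        if p_eff < alpha and r.rho > rho_min:
            g.add_edge(r.genus_i, r.genus_j, rho=r.rho, p=r.p)
    return g


def largest_component(net: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest connected component.

    Size ties are broken by the lexicographically smallest sorted node list.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty graph")
    components = [sorted(c) for c in nx.connected_components(net)]
    max_size = max(len(c) for c in components)
    best = min(c for c in components if len(c) == max_size)
    return net.subgraph(best).copy()


def write_edge_list(net: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("genus_i\tgenus_j\trho\tp\n")
        for u, v, data in sorted(net.edges(data=True)):
            fh.write(f"{u}\t{v}\t{data.get('rho', '')}\t{data.get('p', '')}\n")


def read_edge_list(path, nodes: Optional[Sequence[str]] = None) -> nx.Graph:
    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("genus_i"):
            raise ValueError(f"{path}: expected edge-list header")
        for line in fh:
            u, v, rho, p = line.rstrip("\n").split("\t")
            g.add_edge(u, v, rho=float(rho), p=float(p))
    return g
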