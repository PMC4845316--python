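"""Per-community subject stratification.

Community-restricted abundance tables are compared between children with
UniFrac distances (weighted-normalized by default), clustered with a
deterministic PAM (BUILD + SWAP), and the number of clusters is selected
by the dissimilarity-based Calinski-Harabasz index. Classical-scaling
coordinates are provided for reporting.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import skbio

from .io import Lineage
from .preprocess import AbundanceTable
from .stability import UNASSIGNED

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("nonzero diagonal")
        if self.values.size and self.values.min() < 0:
            raise ValueError("negative distance")

    @property
    def n(self) -> int:
        return len(self.sample_ids)


@dataclass
class Clustering:
    sample_ids: list[str]
    labels: np.ndarray  # contiguous 0..k-1
    medoids: list[int]  # index into sample_ids, one per cluster label

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        ks = sorted(set(self.labels.tolist()))
        if ks != list(range(len(ks))):
            raise ValueError("cluster labels must be contiguous")
        for c, m in enumerate(self.medoids):
            if self.labels[m] != c:
                raise ValueError("medoid not a member of its cluster")

    @property
    def k(self) -> int:
        return len(self.medoids)

    def members(self, label: int) -> list[str]:
        return [s for s, l in zip(self.sample_ids, self.labels) if l == label]


def community_subtable(abundance: AbundanceTable, assignment: dict[str, int],
                       community: int, renormalize: bool = False) -> AbundanceTable:
    """Restrict rows to genera labeled with ``community``.

    Values stay on the whole-composition scale unless ``renormalize``.
    """
    genera = sorted(g for g, c in assignment.items()
                    if c == community and c != UNASSIGNED and g in abundance.genus_ids)
    if not genera:
        raise ValueError(f"community {community} has no genera in the table")
    sub = abundance.select_genera(genera)
    if renormalize:
        sums = sub.values.sum(axis=0)
        if np.any(sums == 0):
            raise ValueError("cannot renormalize: empty community sample")
        sub = AbundanceTable(sub.genus_ids, sub.sample_ids, sub.values / sums)
    return sub


def _check_leaves(tree: skbio.TreeNode, ids: Sequence[str]) -> None:
    leaves = {tip.name for tip in tree.tips()}
    missing = [g for g in ids if g not in leaves]
    if missing:
        raise ValueError(f"genera absent from tree: {missing}")


def _tree_index(tree: skbio.TreeNode, ids: Sequence[str]
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Branch lengths, branch-by-taxon membership, and root-to-tip distances.

    Branches whose subtree contains none of ``ids`` still appear but can
    never contribute: their membership row is all zero.
    """
    id_pos = {g: k for k, g in enumerate(ids)}
    membership: dict[int, np.ndarray] = {}
    lengths, rows = [], []
    for node in tree.postorder(include_self=True):
        vec = np.zeros(len(ids))
        if node.is_tip():
            if node.name in id_pos:
                vec[id_pos[node.name]] = 1.0
        else:
            for child in node.children:
                vec = vec + membership[id(child)]
        membership[id(node)] = vec
        if node is not tree:
            lengths.append(float(node.length or 0.0))
            rows.append(vec)
    depth = {id(tree): float(tree.length or 0.0)}
    tipdist = np.zeros(len(ids))
    for node in tree.preorder(include_self=False):
        d = depth[id(node.parent)] + float(node.length or 0.0)
        depth[id(node)] = d
        if node.is_tip() and node.name in id_pos:
            tipdist[id_pos[node.name]] = d
    return np.asarray(lengths), np.vstack(rows), tipdist


def _unifrac_from_index(lengths: np.ndarray, member: np.ndarray,
                        tipdist: np.ndarray, x: np.ndarray, y: np.ndarray,
                        mode: str) -> float:
    a = member @ x / x.sum()  # subtree proportion below each branch
    b = member @ y / y.sum()
    if mode == "unweighted":
        pres_a, pres_b = a > 0, b > 0
        denom = (lengths * (pres_a | pres_b)).sum()
        if denom == 0:
            return 0.0
        return float((lengths * (pres_a ^ pres_b)).sum() / denom)
    if mode == "weighted_normalized":
        u = (lengths * np.abs(a - b)).sum()
        c = (tipdist * (x / x.sum() + y / y.sum())).sum()
        if c == 0:
            return 0.0
        return float(u / c)
    raise ValueError(f"unknown unifrac mode {mode!r}")


def unifrac(tree: skbio.TreeNode, x: Sequence[float], y: Sequence[float],
            ids: Sequence[str], mode: str = "weighted_normalized") -> float:
    """UniFrac distance between two abundance vectors indexed by ``ids``.

    Unweighted: shared vs unique branch length of the taxa present in
    either sample. Weighted-normalized (Lozupone): branch lengths weighted
    by the difference of subtree proportions, normalized by the
    abundance-weighted root-to-tip distance so the result lies in [0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.sum() <= 0 or y.sum() <= 0:
        raise ValueError("each vector needs at least one positive entry")
    if x.shape != (len(ids),) or y.shape != (len(ids),):
        raise ValueError("vector length does not match ids")
    _check_leaves(tree, ids)
    lengths, member, tipdist = _tree_index(tree, ids)
    return _unifrac_from_index(lengths, member, tipdist, x, y, mode)


def unifrac_matrix(tree: skbio.TreeNode, table: AbundanceTable,
                   mode: str = "weighted_normalized") -> DistanceMatrix:
    """All-pairs UniFrac distances between the samples of ``table``."""
    _check_leaves(tree, table.genus_ids)
    lengths, member, tipdist = _tree_index(tree, table.genus_ids)
    n = len(table.sample_ids)
    sums = table.values.sum(axis=0)
    if np.any(sums <= 0):
        bad = [s for s, ok in zip(table.sample_ids, sums > 0) if not ok]
        raise ValueError(f"sample(s) with zero total abundance: {bad}")
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = _unifrac_from_index(lengths, member, tipdist,
                                table.values[:, i], table.values[:, j], mode)
        D[i, j] = D[j, i] = d
    return DistanceMatrix(list(table.sample_ids), D)


def bray_curtis_matrix(table: AbundanceTable) -> DistanceMatrix:
    """Tree-free alternative dissimilarity (sensitivity analysis only)."""
    V = table.values
    n = V.shape[1]
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        denom = (V[:, i] + V[:, j]).sum()
        D[i, j] = D[j, i] = 0.0 if denom == 0 else \
            np.abs(V[:, i] - V[:, j]).sum() / denom
    return DistanceMatrix(list(table.sample_ids), D)


def pam(dist: DistanceMatrix, k: int) -> Clustering:
    """Partitioning Around Medoids: BUILD then SWAP, fully deterministic.

    Ties in BUILD and SWAP are broken toward the smallest sample index.
    """
    n = dist.n
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside 1..{n}")
    D = dist.values
    # BUILD: first medoid minimizes total distance; then greedy max reduction
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        nearest = D[:, medoids].min(axis=1)
        best_gain, best_cand = -np.inf, None
        for cand in range(n):
            if cand in medoids:
                continue
            gain = np.maximum(nearest - D[:, cand], 0.0).sum()
            if gain > best_gain + 1e-12:
                best_gain, best_cand = gain, cand
        medoids.append(best_cand)
    medoids = sorted(medoids)

    def objective(meds: list[int]) -> float:
        return float(D[:, meds].min(axis=1).sum())

    # SWAP: best improving (medoid, non-medoid) exchange until none; when
    # single swaps are exhausted, try exchanging two medoids at once (the
    # single-swap neighborhood alone can strand PAM in a local optimum)
    current = objective(medoids)
    improved = True
    while improved:
        improved = False
        best = (0.0, None)
        for mi, m in enumerate(medoids):
            for cand in range(n):
                if cand in medoids:
                    continue
                trial = medoids[:mi] + medoids[mi + 1:] + [cand]
                delta = current - objective(sorted(trial))
                if delta > best[0] + 1e-12:
                    best = (delta, [(mi, cand)])
        if best[1] is None and k >= 2:
            non_medoids = [c for c in range(n) if c not in medoids]
            for mi, mj in itertools.combinations(range(k), 2):
                kept = [m for idx, m in enumerate(medoids)
                        if idx not in (mi, mj)]
                for ci, cj in itertools.combinations(non_medoids, 2):
                    delta = current - objective(sorted(kept + [ci, cj]))
                    if delta > best[0] + 1e-12:
                        best = (delta, [(mi, ci), (mj, cj)])
        if best[1] is not None:
            for mi, cand in best[1]:
                medoids[mi] = cand
            medoids = sorted(medoids)
            current = objective(medoids)
            improved = True

    assign = np.argmin(D[:, medoids], axis=1)
    # make labels contiguous in medoid order; force each medoid into its own cluster
    for c, m in enumerate(medoids):
        assign[m] = c
    return Clustering(list(dist.sample_ids), assign, medoids)


def pam_brute_force(dist: DistanceMatrix, k: int) -> tuple[float, tuple[int, ...]]:
    """Exhaustive optimum over all medoid subsets (test oracle; tiny n only)."""
    D = dist.values
    best = (np.inf, None)
    for meds in itertools.combinations(range(dist.n), k):
        obj = D[:, meds].min(axis=1).sum()
        if obj < best[0] - 1e-12:
            best = (obj, meds)
    return best


def calinski_harabasz(dist: DistanceMatrix, clustering: Clustering) -> float:
    """Dissimilarity-based CH index: ((T - W)/(k-1)) / (W/(n-k))."""
    n, k = dist.n, clustering.k
    if not 2 <= k <= n - 1:
        raise ValueError(f"k={k} outside 2..{n - 1}")
    D2 = dist.values ** 2
    T = D2.sum() / (2 * n)
    W = 0.0
    for c in range(k):
        idx = np.nonzero(clustering.labels == c)[0]
        W += D2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    if W == 0:
        warnings.warn("zero within-cluster dispersion; CH set to +inf", stacklevel=2)
        return np.inf
    B = T - W
    return float((B / (k - 1)) / (W / (n - k)))


def choose_k(dist: DistanceMatrix, k_range: Sequence[int] = range(2, 7)
             ) -> Clustering:
    """PAM at each k in range; return the clustering maximizing CH (tie: smaller k)."""
    ks = [k for k in k_range if 2 <= k <= dist.n - 1]
    if not ks:
        raise ValueError("no feasible k in range")
    best: tuple[float, int, Optional[Clustering]] = (-np.inf, 0, None)
    for k in sorted(ks):
        clustering = pam(dist, k)
        ch = calinski_harabasz(dist, clustering)
        logger.info("choose_k: k=%d CH=%.4f", k, ch)
        if ch > best[0] + 1e-12:
            best = (ch, k, clustering)
    return best[2]


def pcoa_coordinates(dist: DistanceMatrix, n_axes: int = 2) -> np.ndarray:
    """Classical scaling coordinates (n_samples x n_axes).

    Axes are ordered by eigenvalue; each axis's first nonzero loading is
    made positive; negative eigenvalues are truncated to zero (logged).
    """
    D2 = dist.values ** 2
    n = dist.n
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ D2 @ J
    w, V = np.linalg.eigh(G)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    neg = w < -1e-10 * max(1.0, abs(w[0]))
    if neg.any():
        logger.info("pcoa: truncating %d negative eigenvalues (min %.3g)",
                    int(neg.sum()), float(w.min()))
    w = np.maximum(w, 0.0)
    w[w < 1e-12 * max(1.0, w[0])] = 0.0  # degenerate axes give exact zeros
    coords = V[:, :n_axes] * np.sqrt(w[:n_axes])
    for a in range(coords.shape[1]):
        col = coords[:, a]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if nz.size and col[nz[0]] < 0:
            coords[:, a] = -col
    return coords


def taxonomy_cladogram(lineages: dict[str, Lineage]) -> skbio.TreeNode:
    """Build a unit-branch-length cladogram from kingdom->genus paths.

    Fallback when no genus tree is supplied; this substitutes taxonomy
    for phylogeny and is logged loudly.
    """
    logger.warning("no genus tree supplied: building taxonomy cladogram "
                   "with unit branch lengths from lineages")
    root = skbio.TreeNode(name="root", length=0.0)
    index: dict[tuple, skbio.TreeNode] = {(): root}
    for genus in sorted(lineages):
        lin = lineages[genus]
        path = [lin.kingdom, lin.phylum, lin.class_, lin.order, lin.family]
        node = root
        key: tuple = ()
        for name in path:
            key = key + (name,)
            if key not in index:
                child = skbio.TreeNode(name=None, length=1.0)
                node.append(child)
                index[key] = child
            node = index[key]
        leaf = skbio.TreeNode(name=genus, length=1.0)
        node.append(leaf)
    return root
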