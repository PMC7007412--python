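"""Identity-by-state relatedness: VIF pruning, 1-IBS distances, dendrograms.

Replicates the PLINK-style workflow: LD pruning by variance inflation factor
(sliding windows of 50 SNPs, step 5, recursively removing the SNP with the
highest VIF until all VIFs <= 2), the ``1 - IBS`` pairwise distance
(heterozygote pairs count as IBS state 2 via ``2 - |g_i - g_j|``), and a
deterministic dendrogram (average-linkage by default, neighbor joining by
flag) serialized as Newick with 6-decimal branch lengths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .trio_mendel import MISSING, GenotypeMatrix


# ---------------------------------------------------------------------------
# VIF pruning


_RANK_TOL = 1e-8


def window_vifs(X: np.ndarray) -> np.ndarray:
    """VIF of each column of X (samples x sites), missing already imputed.

    VIF_i = 1/(1 - R^2_i) of site i regressed on the other sites, computed
    as the diagonal of the inverted window correlation matrix. Columns that
    are part of an exact linear dependency (singular window) get VIF = inf;
    zero-variance columns get VIF 1 (they cannot be inflated).
    """
    vifs, _ = _vifs_or_redundancy(X)
    if vifs is None:
        n, w = X.shape
        out = np.full(w, np.inf)
        out[X.std(axis=0) == 0] = 1.0
        return out
    return vifs


def _vifs_or_redundancy(X: np.ndarray):
    """Return (vifs, None) for a full-rank window, (None, redundancy) otherwise.

    ``redundancy`` scores each column by its summed squared correlation with
    the others; the top-scoring column is the best removal candidate when the
    window is exactly collinear and individual VIFs are all infinite.
    """
    n, w = X.shape
    sd = X.std(axis=0)
    informative = sd > 0
    vifs = np.ones(w)
    if informative.sum() < 2:
        return vifs, None
    Z = (X[:, informative] - X[:, informative].mean(axis=0)) / sd[informative]
    C = (Z.T @ Z) / n
    eigvals = np.linalg.eigvalsh(C)
    idx = np.flatnonzero(informative)
    if eigvals[0] < _RANK_TOL:
        redundancy = np.zeros(w)
        sq = C**2
        np.fill_diagonal(sq, 0.0)
        redundancy[idx] = sq.sum(axis=1)
        return None, redundancy
    vifs[idx] = np.diag(np.linalg.inv(C))
    return vifs, None


def vif_prune(
    matrix: GenotypeMatrix,
    window: int = 50,
    step: int = 5,
    vif_threshold: float = 2.0,
) -> np.ndarray:
    """Indices of sites retained after recursive windowed VIF pruning.

    Windows of ``window`` retained sites slide by ``step``; within a window
    the highest-VIF site is removed (for exactly collinear windows, where
    every VIF is infinite, the most redundant site) until all VIFs <= the
    threshold. A site removed in any window stays removed, and the sliding
    pass repeats until no window removes anything, so the retained set is a
    fixed point: re-pruning it removes nothing.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    g = matrix.genotypes.astype(float).T.copy()  # samples x sites
    miss = matrix.genotypes.T == MISSING
    if miss.any():  # mean-impute missing genotypes for the regressions
        col_means = np.where(
            miss.all(axis=0), 0.0, np.nanmean(np.where(miss, np.nan, g), axis=0)
        )
        g[miss] = np.take(col_means, np.nonzero(miss)[1])
    removed: Set[int] = set()
    n_sites = matrix.n_sites
    changed = True
    while changed:
        changed = False
        start = 0
        while True:
            # up to `window` retained sites starting at `start`
            live = _collect(start, window, removed, n_sites)
            while len(live) >= 2:
                vifs, redundancy = _vifs_or_redundancy(g[:, live])
                if vifs is not None:
                    worst = int(np.argmax(vifs))
                    if vifs[worst] <= vif_threshold:
                        break
                else:
                    worst = int(np.argmax(redundancy))
                removed.add(live[worst])
                live.pop(worst)
                changed = True
            if start + window >= n_sites:
                break
            start += step
    return np.array([i for i in range(n_sites) if i not in removed], dtype=int)


def _collect(start: int, window: int, removed: Set[int], n_sites: int) -> List[int]:
    live = []
    i = start
    while i < n_sites and len(live) < window:
        if i not in removed:
            live.append(i)
        i += 1
    return live


# ---------------------------------------------------------------------------
# 1 - IBS distance


@dataclass
class DistanceMatrix:
    ids: List[str]
    values: np.ndarray  # symmetric, zero diagonal, entries in [0, 1] (or NaN)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape inconsistent with ids")
        if not np.allclose(np.nan_to_num(v), np.nan_to_num(v.T)):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix diagonal must be zero")
        self.values = v

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t"
        )


def ibs_distance(matrix: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise 1 - IBS over sites non-missing in both samples.

    IBS similarity for a pair is sum(2 - |g_i - g_j|) / (2 * M) with M the
    number of co-called sites.
    """
    if matrix.n_samples < 2:
        raise ValueError("need at least two samples")
    g = matrix.genotypes
    n = matrix.n_samples
    called = g != MISSING
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = called[:, i] & called[:, j]
            m = int(both.sum())
            if m == 0:
                warnings.warn(
                    f"samples {matrix.samples[i]} and {matrix.samples[j]} share no "
                    "co-called sites; distance is NA",
                    stacklevel=2,
                )
                D[i, j] = D[j, i] = np.nan
                continue
            ibs = (2 - np.abs(g[both, i].astype(int) - g[both, j].astype(int))).sum()
            D[i, j] = D[j, i] = 1.0 - ibs / (2.0 * m)
    return DistanceMatrix(ids=list(matrix.samples), values=D)


# ---------------------------------------------------------------------------
# dendrogram


@dataclass
class TreeNode:
    name: Optional[str] = None
    length: float = 0.0
    children: List["TreeNode"] = field(default_factory=list)

    def leaves(self) -> List[str]:
        if not self.children:
            return [self.name]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class Dendrogram:
    root: TreeNode
    method: str

    def leaf_names(self) -> List[str]:
        return self.root.leaves()

    def clades(self) -> List[frozenset]:
        """All leaf sets of internal nodes (for topology checks)."""
        out: List[frozenset] = []

        def walk(node: TreeNode):
            if node.children:
                out.append(frozenset(node.leaves()))
                for c in node.children:
                    walk(c)

        walk(self.root)
        return out

    def to_newick(self) -> str:
        def fmt(node: TreeNode, top: bool = False) -> str:
            if node.children:
                inner = ",".join(fmt(c) for c in node.children)
                core = f"({inner})"
            else:
                core = node.name
            if top:
                return core
            return f"{core}:{node.length:.6f}"

        return fmt(self.root, top=True) + ";"


def _scipy_to_tree(Z: np.ndarray, ids: List[str]) -> TreeNode:
    root, nodes = hierarchy.to_tree(Z, rd=True)

    def convert(node, parent_height: float) -> TreeNode:
        if node.is_leaf():
            return TreeNode(name=ids[node.id], length=parent_height)
        t = TreeNode(length=parent_height - node.dist)
        t.children = [convert(node.left, node.dist), convert(node.right, node.dist)]
        return t

    return convert(root, root.dist)


def build_dendrogram(D: DistanceMatrix, method: str = "average_linkage") -> Dendrogram:
    """Deterministic tree from a complete distance matrix.

    Ties are broken by pre-sorting samples lexicographically by id. Raises on
    NA distances (impute or drop samples first).
    """
    if D.has_missing:
        raise ValueError(
            "distance matrix contains NA entries; impute or drop those samples"
        )
    order = sorted(range(len(D.ids)), key=lambda i: D.ids[i])
    ids = [D.ids[i] for i in order]
    values = D.values[np.ix_(order, order)]
    if method == "average_linkage":
        Z = hierarchy.linkage(squareform(values, checks=False), method="average")
        root = _scipy_to_tree(Z, ids)
    elif method == "neighbor_joining":
        import skbio

        dm = skbio.DistanceMatrix(values, ids=ids)
        sk_tree = skbio.tree.nj(dm)

        def convert(sk_node) -> TreeNode:
            t = TreeNode(
                name=str(sk_node.name) if sk_node.name else None,
                length=float(sk_node.length or 0.0),
            )
            t.children = [convert(c) for c in sk_node.children]
            return t

        root = convert(sk_tree.root())
    else:
        raise ValueError(f"unknown method {method!r}")
    return Dendrogram(root=root, method=method)
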