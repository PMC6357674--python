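"""Population-structure analysis: genomic relationships, PCA, NJ clustering.

The relationship matrix is the centered-crossproduct (VanRaden-style)
genomic relationship: with ``p_k`` the panel alternate-allele frequency at
polymorphic site k and ``W`` the matrix of ``dosage - 2 p_k`` (missing
imputed at the mean, i.e. 0 after centering),

    A = W W' / (2 sum_k p_k (1 - p_k)).

PCA is the eigendecomposition of A; principal-component scores are
eigenvectors scaled by the square root of their eigenvalue.  Clustering
uses pairwise-complete Euclidean distances (rescaled for missingness) and
Saitou-Nei neighbor joining with deterministic tie-breaking.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, SampleRecord

logger = logging.getLogger(__name__)


@dataclass
class RelationshipMatrix:
    matrix: np.ndarray
    samples: list[str]


@dataclass
class PcaResult:
    eigenvalues: np.ndarray  # descending, full spectrum
    scores: pd.DataFrame  # samples x PC1..PCn, eigenvector * sqrt(eigenvalue)
    eigenvectors: pd.DataFrame  # raw eigenvectors for the same components
    variance_explained: np.ndarray  # lambda_i / sum(max(lambda, 0))


@dataclass
class DistanceMatrix:
    matrix: np.ndarray
    samples: list[str]
    method: str = "euclidean"


@dataclass
class Tree:
    """Unrooted binary tree from neighbor joining.

    Stored rooted at the final join for serialization; ``children`` maps a
    node id to (child id, branch length) pairs and leaves carry labels.
    """

    root: int
    children: dict[int, list[tuple[int, float]]]
    leaf_labels: dict[int, str]
    n_negative_clamped: int = 0

    @property
    def leaves(self) -> list[str]:
        return sorted(self.leaf_labels.values())

    def to_newick(self) -> str:
        def render(node: int) -> str:
            if node in self.leaf_labels:
                return self.leaf_labels[node]
            inner = ",".join(
                f"{render(c)}:{length:.10g}" for c, length in self.children[node]
            )
            return f"({inner})"

        return render(self.root) + ";"

    def splits(self) -> set[frozenset]:
        """Non-trivial bipartitions (as the smaller-side leaf sets' frozensets)."""
        all_leaves = frozenset(self.leaf_labels.values())
        out: set[frozenset] = set()

        def leafset(node: int) -> frozenset:
            if node in self.leaf_labels:
                return frozenset([self.leaf_labels[node]])
            acc: set[str] = set()
            for c, _ in self.children[node]:
                sub = leafset(c)
                if 1 < len(sub) < len(all_leaves) - 1:
                    out.add(min(sub, all_leaves - sub, key=lambda s: (len(s), sorted(s))))
                acc |= sub
            return frozenset(acc)

        leafset(self.root)
        return out

    def leaf_distance_matrix(self) -> pd.DataFrame:
        """Patristic distances between leaves (sum of branch lengths)."""
        adj: dict[int, list[tuple[int, float]]] = {}
        for parent, kids in self.children.items():
            for child, length in kids:
                adj.setdefault(parent, []).append((child, length))
                adj.setdefault(child, []).append((parent, length))
        labels = self.leaves
        label_to_node = {v: k for k, v in self.leaf_labels.items()}
        n = len(labels)
        out = np.zeros((n, n))
        for i, lab in enumerate(labels):
            # BFS accumulating path lengths
            start = label_to_node[lab]
            dist = {start: 0.0}
            stack = [start]
            while stack:
                node = stack.pop()
                for nxt, length in adj.get(node, []):
                    if nxt not in dist:
                        dist[nxt] = dist[node] + length
                        stack.append(nxt)
            for j, lab2 in enumerate(labels):
                out[i, j] = dist[label_to_node[lab2]]
        return pd.DataFrame(out, index=labels, columns=labels)


def relationship_matrix(gm: GenotypeMatrix) -> RelationshipMatrix:
    """Centered-score genomic relationship matrix over polymorphic sites."""
    if gm.n_samples < 2:
        raise ValueError("need at least 2 samples")
    p = gm.alt_freq()
    poly = np.isfinite(p) & (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic sites")
    calls = gm.calls[:, poly].astype(float)
    pk = p[poly]
    w = np.where(calls == MISSING, 0.0, calls - 2 * pk)
    denom = 2 * float((pk * (1 - pk)).sum())
    a = w @ w.T / denom
    return RelationshipMatrix(matrix=a, samples=list(gm.samples))


def pca(a: RelationshipMatrix, n_components: int = 3) -> PcaResult:
    """Eigendecomposition of the relationship matrix, eigenvalues descending."""
    m = a.matrix
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("relationship matrix is not symmetric")
    eigval, eigvec = np.linalg.eigh(m)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    # deterministic sign: largest-magnitude entry of each eigenvector positive
    for j in range(eigvec.shape[1]):
        k = int(np.argmax(np.abs(eigvec[:, j])))
        if eigvec[k, j] < 0:
            eigvec[:, j] *= -1
    k = min(n_components, len(eigval))
    cols = [f"PC{i + 1}" for i in range(k)]
    scale = np.sqrt(np.maximum(eigval[:k], 0.0))
    scores = pd.DataFrame(eigvec[:, :k] * scale, index=a.samples, columns=cols)
    vectors = pd.DataFrame(eigvec[:, :k], index=a.samples, columns=cols)
    total = float(np.maximum(eigval, 0.0).sum())
    var_exp = eigval[:k] / total if total > 0 else np.zeros(k)
    return PcaResult(
        eigenvalues=eigval, scores=scores, eigenvectors=vectors,
        variance_explained=var_exp,
    )


def euclidean_distance(gm: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise-complete Euclidean distances with missing-data rescaling.

    d(i,j) = sqrt((m / m_obs) * sum over co-observed sites (x_i - x_j)^2),
    where m is the total site count and m_obs the co-observed count for the
    pair — the conventional behavior of R's ``dist``.
    """
    if gm.n_samples < 2:
        raise ValueError("need at least 2 samples")
    x = gm.calls.astype(float)
    x[gm.calls == MISSING] = np.nan
    obs = np.isfinite(x)
    x0 = np.where(obs, x, 0.0)
    # sum of squared diffs over co-observed sites, via expansion
    sq = x0**2
    cross = x0 @ x0.T
    s_i = sq @ obs.T.astype(float)
    ss = s_i + s_i.T - 2 * cross
    m_obs = obs.astype(float) @ obs.T.astype(float)
    if (m_obs[~np.eye(gm.n_samples, dtype=bool)] == 0).any():
        ii, jj = np.where((m_obs == 0) & ~np.eye(gm.n_samples, dtype=bool))
        pair = (gm.samples[ii[0]], gm.samples[jj[0]])
        raise ValueError(f"samples {pair} share no co-observed sites")
    d = np.sqrt(np.maximum(gm.n_sites / m_obs * ss, 0.0))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(matrix=d, samples=list(gm.samples), method="euclidean")


def nj_tree(d: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Ties on the Q criterion are broken by the smallest (i, j) pair in the
    current active-node order; negative branch lengths are clamped to zero
    (count recorded on the tree).
    """
    n = len(d.samples)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    dist = d.matrix.astype(float).copy()
    active = list(range(n))
    leaf_labels = {i: s for i, s in enumerate(d.samples)}
    children: dict[int, list[tuple[int, float]]] = {}
    next_id = n
    clamped = 0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    # dist indexed by node id; grow as nodes are created
    while len(active) > 3:
        m = len(active)
        sub = dist[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        # consider the upper triangle only (q is symmetric up to rounding)
        q[np.tril_indices(m)] = np.inf
        minval = q.min()
        ties = np.argwhere(q == minval)
        # deterministic tie-break: smallest (i, j) among exact minima
        ai, aj = min((int(i), int(j)) for i, j in ties)
        i, j = active[ai], active[aj]
        dij = dist[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        u = next_id
        next_id += 1
        children[u] = [(i, clamp(li)), (j, clamp(lj))]
        new_row = np.zeros(dist.shape[0] + 1)
        for ak, k in enumerate(active):
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (dist[i, k] + dist[j, k] - dij)
        dist = np.pad(dist, ((0, 1), (0, 1)))
        dist[u, : u] = new_row[:u]
        dist[: u, u] = new_row[:u]
        active = [k for k in active if k not in (i, j)] + [u]

    a, b, c = active
    la = 0.5 * (dist[a, b] + dist[a, c] - dist[b, c])
    lb = 0.5 * (dist[a, b] + dist[b, c] - dist[a, c])
    lc = 0.5 * (dist[a, c] + dist[b, c] - dist[a, b])
    root = next_id
    children[root] = [(a, clamp(la)), (b, clamp(lb)), (c, clamp(lc))]
    return Tree(root=root, children=children, leaf_labels=leaf_labels,
                n_negative_clamped=clamped)


def random_additive_tree(
    rng: np.random.Generator, n_leaves: int
) -> tuple[pd.DataFrame, set[frozenset]]:
    """Random binary unrooted tree with uniform branch lengths.

    Returns the additive (patristic) leaf-distance matrix and the set of
    non-trivial bipartitions (each as the canonical smaller-side leafset).
    A neighbor-joining implementation must recover both exactly from the
    distances; used for validation.
    """
    if n_leaves < 3:
        raise ValueError("need at least 3 leaves")
    labels = [f"T{i}" for i in range(n_leaves)]
    next_node = n_leaves
    edges: dict[tuple[int, int], float] = {}

    center = next_node
    next_node += 1
    for leaf in range(3):
        edges[(center, leaf)] = float(rng.uniform(0.5, 2.0))
    for leaf in range(3, n_leaves):
        u, v = list(edges)[rng.integers(len(edges))]
        length = edges.pop((u, v))
        mid = next_node
        next_node += 1
        split = float(rng.uniform(0.25, 0.75))
        edges[(u, mid)] = length * split
        edges[(mid, v)] = length * (1 - split)
        edges[(mid, leaf)] = float(rng.uniform(0.5, 2.0))
    adj: dict[int, list[tuple[int, float]]] = {}
    for (u, v), w in edges.items():
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))
    dist = np.zeros((n_leaves, n_leaves))
    for i in range(n_leaves):
        seen = {i: 0.0}
        stack = [i]
        while stack:
            node = stack.pop()
            for nxt, w in adj[node]:
                if nxt not in seen:
                    seen[nxt] = seen[node] + w
                    stack.append(nxt)
        for j in range(n_leaves):
            dist[i, j] = seen[j]
    splits: set[frozenset] = set()
    for (u, v) in edges:
        side: set[str] = set()
        seen_nodes = {u}
        stack = [u]
        while stack:
            node = stack.pop()
            if node < n_leaves:
                side.add(labels[node])
            for nxt, _ in adj[node]:
                if nxt not in seen_nodes and not (node == u and nxt == v):
                    seen_nodes.add(nxt)
                    stack.append(nxt)
        if 1 < len(side) < n_leaves - 1:
            other = set(labels) - side
            splits.add(min(frozenset(side), frozenset(other),
                           key=lambda s: (len(s), sorted(s))))
    return pd.DataFrame(dist, index=labels, columns=labels), splits


def pc_geo_correlation(
    result: PcaResult,
    passports: Sequence[SampleRecord],
    components: Sequence[int] = (2, 3),
) -> pd.DataFrame:
    """Pearson correlations of PC scores vs longitude/latitude/altitude.

    Pairwise-complete over samples with both a score and the geographic
    variable; cells with fewer than 3 complete pairs are NaN (warned).
    """
    geo = pd.DataFrame(
        {
            "longitude": {r.id: r.longitude for r in passports},
            "latitude": {r.id: r.latitude for r in passports},
            "altitude": {r.id: r.altitude for r in passports},
        }
    )
    rows = []
    for comp in components:
        col = f"PC{comp}"
        if col not in result.scores.columns:
            raise ValueError(f"{col} not in PCA result")
        scores = result.scores[col]
        for var in ("longitude", "latitude", "altitude"):
            joined = pd.concat([scores, geo[var]], axis=1, join="inner").dropna()
            n = len(joined)
            if n < 3:
                warnings.warn(f"fewer than 3 complete pairs for {col} vs {var}")
                r = np.nan
            else:
                r = float(np.corrcoef(joined.iloc[:, 0], joined.iloc[:, 1])[0, 1])
            rows.append({"component": col, "variable": var, "r": r, "n": n})
    return pd.DataFrame(rows)
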