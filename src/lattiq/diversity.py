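"""Genetic-distance and cluster analysis of accession means.

Accession-by-trait means are z-scored per trait (sample standard
deviation, n - 1 denominator) and pairwise Euclidean distances computed
on the standardized profiles.  Clustering is UPGMA (unweighted pair-group
method with arithmetic means): at each step the pair of clusters with the
smallest size-weighted average inter-cluster distance is merged, with the
Lance-Williams update

    d(A+B, C) = (|A| d(A,C) + |B| d(B,C)) / (|A| + |B|)

Ties are broken by the lexicographically smallest pair of smallest member
indices so dendrograms are reproducible across platforms.  Merge heights
are the raw merging distances (ultrametric, non-decreasing); newick
branch lengths are half the height differences so leaf-to-root depths
equal half the final merge height.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import LattiqError, StandardizationError

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "ClusterAssignment",
    "standardize",
    "standardize_and_distance",
    "distance_summary",
    "upgma_cluster",
    "cluster_means",
]


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple
    values: np.ndarray  # g x g symmetric, zero diagonal

    @property
    def g(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


@dataclass(frozen=True)
class Dendrogram:
    """UPGMA merge tree.

    ``merges`` rows are (cluster_a, cluster_b, height, size): leaf ids are
    0..g-1, internal nodes g, g+1, ... in merge order (the scipy linkage
    convention).
    """

    merges: np.ndarray  # (g-1, 4)
    labels: tuple

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


@dataclass(frozen=True)
class ClusterAssignment:
    labels: pd.Series  # accession id -> cluster 1..K
    K: int

    @property
    def members(self) -> dict[int, list]:
        out: dict[int, list] = {}
        for acc, c in self.labels.items():
            out.setdefault(int(c), []).append(acc)
        return out


def standardize(means: pd.DataFrame) -> pd.DataFrame:
    """Z-score each trait column with the sample (n-1) standard deviation."""
    sd = means.std(ddof=1)
    flat = sd[~(sd > 0)]
    if len(flat):
        raise StandardizationError(
            f"trait(s) with zero spread cannot be standardized: {list(flat.index)}"
        )
    return (means - means.mean()) / sd


def standardize_and_distance(
    means: pd.DataFrame,
) -> tuple[pd.DataFrame, DistanceMatrix]:
    """Z-matrix and Euclidean distance matrix of accession mean profiles."""
    if len(means) < 2:
        raise LattiqError("need at least two accessions for distances")
    if means.isna().any().any():
        raise LattiqError("accession-mean matrix contains missing cells")
    z = standardize(means)
    d = squareform(pdist(z.to_numpy(), metric="euclidean"))
    return z, DistanceMatrix(ids=tuple(means.index), values=d)


def distance_summary(D: DistanceMatrix) -> pd.DataFrame:
    """Per-accession and overall distance statistics.

    Each accession row summarizes its g-1 distances to the others; the
    ``overall`` row summarizes the g(g-1)/2 unique pairs.  cv_percent is
    100 * sd / mean (sample sd).
    """
    g = D.g
    if g < 3:
        raise LattiqError(f"distance summary needs >= 3 accessions, got {g}")
    rows = []
    vals = D.values
    for i, acc in enumerate(D.ids):
        d = np.delete(vals[i], i)
        rows.append((acc, d.min(), d.max(), d.mean(), d.std(ddof=1)))
    iu = np.triu_indices(g, k=1)
    pairs = vals[iu]
    rows.append(("overall", pairs.min(), pairs.max(), pairs.mean(), pairs.std(ddof=1)))
    out = pd.DataFrame(rows, columns=["accession", "min", "max", "mean", "sd"])
    out["cv_percent"] = 100.0 * out["sd"] / out["mean"]
    return out.set_index("accession")


def _upgma_merges(D: np.ndarray) -> np.ndarray:
    """UPGMA agglomeration with deterministic lexicographic tie-breaking.

    Active clusters carry (node id, size, smallest member index); on a tie
    in merge distance the pair with the smallest (min leaf, min leaf)
    index pair wins.
    """
    g = D.shape[0]
    dist = D.astype(float).copy()
    node = list(range(g))
    size = [1] * g
    smallest = list(range(g))
    active = list(range(g))
    merges = np.zeros((g - 1, 4))
    next_id = g
    for m in range(g - 1):
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                d = dist[a, b]
                lo, hi = sorted((smallest[a], smallest[b]))
                key = (d, lo, hi)
                if best is None or key < best[0]:
                    best = (key, a, b)
        a, b = best[1], best[2]
        h = dist[a, b]
        na, nb = size[a], size[b]
        for c in active:
            if c not in (a, b):
                dist[a, c] = dist[c, a] = (na * dist[a, c] + nb * dist[b, c]) / (
                    na + nb
                )
        merges[m] = (min(node[a], node[b]), max(node[a], node[b]), h, na + nb)
        node[a] = next_id
        size[a] = na + nb
        smallest[a] = min(smallest[a], smallest[b])
        active.remove(b)
        next_id += 1
    return merges


def _cut(merges: np.ndarray, g: int, K: int) -> np.ndarray:
    """Cluster index per leaf after g - K merges (0-based compact labels)."""
    parent = {}
    for m, (a, b, _, _) in enumerate(merges[: g - K]):
        parent[int(a)] = g + m
        parent[int(b)] = g + m
    labels = np.zeros(g, dtype=int)
    roots: dict[int, int] = {}
    for leaf in range(g):
        x = leaf
        while x in parent:
            x = parent[x]
        labels[leaf] = roots.setdefault(x, len(roots))
    return labels


def _newick(merges: np.ndarray, labels: tuple) -> str:
    g = len(labels)
    height = {i: 0.0 for i in range(g)}
    text = {i: str(labels[i]) for i in range(g)}
    for m, (a, b, h, _) in enumerate(merges):
        a, b = int(a), int(b)
        # branch lengths: half the merge-height difference (ultrametric tree)
        la = (h - height[a]) / 2.0
        lb = (h - height[b]) / 2.0
        nid = g + m
        text[nid] = f"({text[a]}:{la:.6g},{text[b]}:{lb:.6g})"
        height[nid] = h
    return text[g + len(merges) - 1] + ";"


def upgma_cluster(
    D: DistanceMatrix, K: int
) -> tuple[Dendrogram, ClusterAssignment, str]:
    """UPGMA dendrogram, a K-cluster cut, and the newick string.

    Clusters are labelled 1..K in order of each cluster's first accession
    position in the input.
    """
    g = D.g
    if not 1 <= K <= g:
        raise ValueError(f"K must lie in [1, {g}], got {K}")
    merges = _upgma_merges(D.values)
    dendro = Dendrogram(merges=merges, labels=D.ids)
    compact = _cut(merges, g, K)
    # relabel so cluster 1 contains the first accession, etc.
    order: dict[int, int] = {}
    final = np.zeros(g, dtype=int)
    for i, c in enumerate(compact):
        order.setdefault(int(c), len(order) + 1)
        final[i] = order[int(c)]
    assignment = ClusterAssignment(
        labels=pd.Series(final, index=list(D.ids), name="cluster"), K=K
    )
    return dendro, assignment, _newick(merges, D.ids)


def cluster_means(
    means: pd.DataFrame, clusters: ClusterAssignment
) -> pd.DataFrame:
    """Per-cluster arithmetic means of the raw accession means, plus overall.

    Rows are clusters (plus an ``overall`` row over all accessions);
    columns are traits.
    """
    unknown = set(clusters.labels.index) - set(means.index)
    if unknown:
        raise KeyError(f"cluster assignment references unknown accession(s): {sorted(unknown)!r}")
    out = means.groupby(clusters.labels).mean()
    out.index = [int(c) for c in out.index]
    out.loc["overall"] = means.mean()
    return out
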