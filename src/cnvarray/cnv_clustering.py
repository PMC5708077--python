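"""Co-occurring CNV blocks via complete-linkage clustering on Hamming distance.

Rows of the carrier matrix (CNV regions x samples, entries 0/1) are
agglomerated with complete linkage on pairwise Hamming distance, both
implemented here so the merge order and tie-breaks are fully specified:
at each step the minimum-distance cluster pair is merged, ties resolved
in favour of the lowest cluster indices. Cutting the dendrogram at
height 0 (the default) groups exactly the regions with identical carrier
patterns; each reported block carries its supporting samples — the
samples that carry *every* member region.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import CnvRegion

__all__ = [
    "ClusterBlock",
    "carrier_matrix",
    "hamming",
    "pairwise_hamming",
    "complete_linkage",
    "cut_dendrogram",
    "extract_blocks",
    "to_newick",
]


@dataclass(frozen=True)
class ClusterBlock:
    """A block of co-occurring CNV regions."""

    regions: tuple[str, ...]
    supporting_samples: tuple[str, ...]
    max_hamming: int

    @property
    def n_regions(self) -> int:
        return len(self.regions)


def carrier_matrix(
    regions: Sequence[CnvRegion], sample_ids: Sequence[str]
) -> pd.DataFrame:
    """Binary regions x samples carrier matrix (rows in given region order)."""
    ids = [r.region_id for r in regions]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate region ids")
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids")
    data = np.zeros((len(regions), len(sample_ids)), dtype=np.int8)
    col = {s: k for k, s in enumerate(sample_ids)}
    for i, region in enumerate(regions):
        for s in region.all_carriers():
            if s in col:
                data[i, col[s]] = 1
    return pd.DataFrame(data, index=ids, columns=list(sample_ids))


def hamming(u: Sequence[int], v: Sequence[int]) -> int:
    """Number of positions where two equal-length binary vectors disagree."""
    u = np.asarray(u)
    v = np.asarray(v)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError("vectors must share one dimension")
    return int(np.count_nonzero(u != v))


def pairwise_hamming(matrix: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Dense symmetric matrix of row-wise Hamming distances."""
    x = np.asarray(matrix, dtype=np.int64)
    # (x_i - x_j)^2 summed == Hamming for 0/1 entries
    g = x @ x.T
    sq = np.diag(g)
    d = sq[:, None] + sq[None, :] - 2 * g
    return d.astype(np.int64)


def complete_linkage(matrix: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Agglomerative complete-linkage merge sequence on Hamming distance.

    Returns a linkage array of shape (n-1, 4) in the usual encoding:
    each row (a, b, height, size) merges clusters ``a`` and ``b`` (original
    rows are 0..n-1, merged clusters n, n+1, ...) at ``height`` = the
    maximum pairwise Hamming distance between their members. Ties are
    broken toward the lowest (a, b) pair, making the sequence
    deterministic. Heights are non-decreasing (complete-linkage
    guarantee).
    """
    x = np.asarray(matrix, dtype=np.int64)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 rows to cluster")
    d = pairwise_hamming(x).astype(float)
    np.fill_diagonal(d, np.inf)
    active = {i: (i, 1) for i in range(n)}  # slot -> (cluster id, size)
    z = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        slots = sorted(active)
        sub = d[np.ix_(slots, slots)]
        best = sub.min()
        # lowest-index pair among ties, by cluster id order
        pairs = [
            (active[slots[i]][0], active[slots[j]][0], slots[i], slots[j])
            for i, j in zip(*np.nonzero(sub == best))
            if i < j
        ]
        a_id, b_id, si, sj = min(pairs)
        size = active[si][1] + active[sj][1]
        z[step] = (min(a_id, b_id), max(a_id, b_id), best, size)
        # complete linkage: distance to merged cluster is the max
        for k in active:
            if k not in (si, sj):
                d[si, k] = d[k, si] = max(d[si, k], d[sj, k])
        d[sj, :] = np.inf
        d[:, sj] = np.inf
        active[si] = (next_id, size)
        del active[sj]
        next_id += 1
    return z


def cut_dendrogram(z: np.ndarray, n: int, max_height: float) -> list[list[int]]:
    """Flat clusters after applying all merges with height <= max_height.

    Returns the partition of row indices, each cluster sorted, the list
    ordered by smallest member.
    """
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    cluster_of: dict[int, int] = {i: i for i in range(n)}  # linkage id -> root
    next_id = n
    for a, b, height, _ in z:
        if height <= max_height:
            ra, rb = find(cluster_of[int(a)]), find(cluster_of[int(b)])
            parent[max(ra, rb)] = min(ra, rb)
            cluster_of[next_id] = min(ra, rb)
        else:
            cluster_of[next_id] = -1  # never referenced below threshold afterwards
        next_id += 1
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted((sorted(g) for g in groups.values()), key=lambda g: g[0])


def extract_blocks(
    z: np.ndarray,
    matrix: pd.DataFrame,
    max_height: float = 0.0,
    min_regions: int = 2,
) -> list[ClusterBlock]:
    """Report co-occurrence blocks from a dendrogram cut.

    Clusters with at least ``min_regions`` rows become blocks; a block's
    supporting samples are the columns where every member row is 1, and
    ``max_hamming`` the largest pairwise distance inside the block.
    Blocks are sorted by size descending, ties by leftmost (first) region
    row.
    """
    x = matrix.to_numpy()
    n = x.shape[0]
    blocks: list[ClusterBlock] = []
    for cluster in cut_dendrogram(z, n, max_height):
        if len(cluster) < min_regions:
            continue
        sub = x[cluster]
        support = np.nonzero(sub.min(axis=0) == 1)[0]
        dist = pairwise_hamming(sub)
        blocks.append(
            ClusterBlock(
                regions=tuple(matrix.index[i] for i in cluster),
                supporting_samples=tuple(matrix.columns[j] for j in support),
                max_hamming=int(dist.max()) if len(cluster) > 1 else 0,
            )
        )
    order = {rid: i for i, rid in enumerate(matrix.index)}
    blocks.sort(key=lambda b: (-b.n_regions, order[b.regions[0]]))
    return blocks


def to_newick(z: np.ndarray, labels: Sequence[str]) -> str:
    """Newick string of the dendrogram with merge heights as branch lengths."""
    n = len(labels)
    nodes: dict[int, tuple[str, float]] = {i: (str(labels[i]), 0.0) for i in range(n)}
    for step, (a, b, height, _) in enumerate(z):
        sa, ha = nodes[int(a)]
        sb, hb = nodes[int(b)]
        nodes[n + step] = (
            f"({sa}:{height - ha:g},{sb}:{height - hb:g})",
            float(height),
        )
    return nodes[n + len(z) - 1][0] + ";"
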