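"""Hierarchical clustering of tumors on their ternary aberration profiles.

Samples are compared with the Hamming distance over a filtered probe set
(probes altered in at least ``min_altered`` samples, which suppresses
noise-only probes), then agglomerated with complete linkage and the tree
is cut into ``k`` disjoint groups.

The agglomeration is written out here rather than delegated so the tie
rule is explicit and order-independent: when several cluster pairs sit at
the minimal complete-linkage distance, the pair merged is the one whose
lexicographically smallest member sample id is smallest (then the smaller
partner id).  On tie-free distance matrices the merge heights coincide
with any textbook complete-linkage implementation; tests cross-check
against :func:`scipy.cluster.hierarchy.linkage`.

Outliers — samples so distant that they form tiny clusters of their own —
are detected by iteratively cutting at ``k``, dropping clusters of size at
most ``max_outlier_cluster_size``, and re-clustering the remainder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ClusterResult",
    "cluster_samples",
    "detect_outliers",
    "filter_informative_probes",
    "hamming_distance",
    "pairwise_hamming",
]


@dataclass
class ClusterResult:
    """Complete-linkage clustering of one cohort's ternary profiles."""

    sample_ids: list[str]
    filtered_probes: np.ndarray  # global probe indices used for distances
    distances: np.ndarray  # condensed Hamming counts, scipy ordering
    merges: np.ndarray  # scipy-style linkage matrix (n-1, 4)
    k: int
    labels: dict[str, int]  # sample id -> cluster id in 1..k
    outliers: set[str] = field(default_factory=set)
    min_altered: int = 3

    @property
    def cluster_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for c in self.labels.values():
            sizes[c] = sizes.get(c, 0) + 1
        return sizes

    def to_newick(self) -> str:
        """Merge tree as a Newick string (branch lengths from merge heights)."""
        n = len(self.sample_ids)
        names = {i: (self.sample_ids[i], 0.0) for i in range(n)}
        for step, (a, b, h, _size) in enumerate(self.merges):
            na, ha = names.pop(int(a))
            nb, hb = names.pop(int(b))
            node = f"({na}:{h - ha:g},{nb}:{h - hb:g})"
            names[n + step] = (node, float(h))
        (tree, _h), = names.values()
        return tree + ";"


def filter_informative_probes(calls: pd.DataFrame, min_altered: int = 3) -> np.ndarray:
    """Indices of probes with a nonzero call in >= ``min_altered`` samples."""
    altered = (calls.to_numpy() != 0).sum(axis=1)
    return np.flatnonzero(altered >= min_altered)


def hamming_distance(x, y) -> int:
    """Number of positions at which two ternary vectors disagree."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    return int(np.sum(x != y))


def pairwise_hamming(profiles: np.ndarray) -> np.ndarray:
    """Condensed pairwise Hamming counts for rows of ``profiles``."""
    n = len(profiles)
    out = np.empty(n * (n - 1) // 2, dtype=float)
    k = 0
    for i in range(n):
        diff = (profiles[i + 1 :] != profiles[i]).sum(axis=1)
        out[k : k + len(diff)] = diff
        k += len(diff)
    return out


def _complete_linkage(dist: np.ndarray, ids: list[str]) -> np.ndarray:
    """Scipy-format linkage matrix under the smallest-member-id tie rule."""
    n = len(ids)
    d = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    d[iu] = dist
    d = d + d.T
    active: dict[int, dict] = {
        i: {"members": [i], "min_id": ids[i], "size": 1} for i in range(n)
    }
    rows = []
    next_idx = n
    for _ in range(n - 1):
        best = None
        keys = sorted(active.keys())
        for ai in range(len(keys)):
            for bi in range(ai + 1, len(keys)):
                a, b = keys[ai], keys[bi]
                da = max(
                    d[x, y]
                    for x in active[a]["members"]
                    for y in active[b]["members"]
                )
                ids_pair = sorted([active[a]["min_id"], active[b]["min_id"]])
                key = (da, ids_pair[0], ids_pair[1])
                if best is None or key < best[0]:
                    best = (key, a, b)
        (height, _m0, _m1), a, b = best
        merged = {
            "members": active[a]["members"] + active[b]["members"],
            "min_id": min(active[a]["min_id"], active[b]["min_id"]),
            "size": active[a]["size"] + active[b]["size"],
        }
        rows.append([a, b, height, merged["size"]])
        del active[a], active[b]
        active[next_idx] = merged
        next_idx += 1
    return np.array(rows, dtype=float)


def _cut(merges: np.ndarray, n: int, k: int, ids: list[str]) -> dict[str, int]:
    """Partition into k clusters by undoing the last k-1 merges.

    Cluster ids are 1..k, numbered by each cluster's lexicographically
    smallest member so labelling is sample-order invariant.
    """
    parent = list(range(n + len(merges)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step in range(n - k):
        a, b, _h, _s = merges[step]
        node = n + step
        parent[find(int(a))] = node
        parent[find(int(b))] = node
    groups: dict[int, list[str]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(ids[i])
    ordered = sorted(groups.values(), key=lambda m: min(m))
    labels = {}
    for c, members in enumerate(ordered, start=1):
        for m in members:
            labels[m] = c
    return labels


def cluster_samples(
    calls: pd.DataFrame, min_altered: int = 3, k: int = 4,
    samples: list[str] | None = None,
) -> ClusterResult:
    """Complete-linkage Hamming clustering of (a subset of) the cohort.

    The informative-probe filter is applied over the clustered samples
    only, so re-clustering after outlier removal re-filters.
    """
    ids = sorted(samples if samples is not None else calls.columns)
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(ids) < k:
        raise ValueError(f"cannot form {k} clusters from {len(ids)} samples")
    sub = calls[ids]
    probes = filter_informative_probes(sub, min_altered)
    profiles = sub.to_numpy()[probes].T  # samples x filtered probes
    dist = pairwise_hamming(profiles)
    merges = _complete_linkage(dist, ids)
    labels = _cut(merges, len(ids), k, ids)
    return ClusterResult(
        sample_ids=ids,
        filtered_probes=probes,
        distances=dist,
        merges=merges,
        k=k,
        labels=labels,
        min_altered=min_altered,
    )


def detect_outliers(
    calls: pd.DataFrame,
    min_altered: int = 3,
    k: int = 4,
    max_outlier_cluster_size: int = 1,
) -> ClusterResult:
    """Cluster with iterative removal of tiny clusters as outliers.

    Repeatedly cut at ``k``; samples in clusters of size at most
    ``max_outlier_cluster_size`` are flagged and the remaining samples are
    re-clustered, until every cluster is larger than the cap.
    """
    outliers: set[str] = set()
    remaining = sorted(calls.columns)
    while True:
        result = cluster_samples(calls, min_altered=min_altered, k=k, samples=remaining)
        if max_outlier_cluster_size < 1:
            break
        sizes = result.cluster_sizes
        small = {c for c, s in sizes.items() if s <= max_outlier_cluster_size}
        if not small:
            break
        dropped = {s for s, c in result.labels.items() if c in small}
        if len(remaining) - len(dropped) < k:
            break  # cannot drop further and still form k clusters
        outliers |= dropped
        remaining = sorted(set(remaining) - dropped)
    result.outliers = outliers
    return result
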