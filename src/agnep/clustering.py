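"""Phenotype clustering: distances, agglomerative nesting, silhouettes.

The agglomerative step is written out explicitly (not delegated to a
library) because its merge rule, tie-breaking and singleton-silhouette
conventions are the behaviour under test; a reference implementation is
used as an oracle in the test suite only.
"""

from __future__ import annotations

import warnings

import numpy as np

from .datatypes import (
    ClusterPartition,
    DistanceMatrix,
    PhenotypeMatrix,
    SilhouetteResult,
)

LINKAGES = ("single", "complete", "average")


def standardize_rows(values: np.ndarray, labels: list[str] | None = None) -> np.ndarray:
    """Center each row to mean 0 and scale to SD 1 (population SD)."""
    values = np.asarray(values, dtype=float)
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    zero = np.flatnonzero(sd.ravel() == 0)
    if zero.size:
        name = labels[zero[0]] if labels else f"row {zero[0]}"
        raise ValueError(f"phenotype {name} has zero variance and cannot be scaled")
    return (values - mu) / sd


def phenotype_distance_matrix(
    Y: PhenotypeMatrix, standardize: bool = True
) -> DistanceMatrix:
    """Pairwise Euclidean distances between phenotype rows.

    Rows are standardized (mean 0, SD 1 across individuals) by default so
    measurement units do not dominate the clustering; pass
    ``standardize=False`` for raw-scale distances.
    """
    if Y.n_phenotypes < 2:
        raise ValueError("need at least 2 phenotypes")
    bad = np.flatnonzero(~np.isfinite(Y.values).all(axis=1))
    if bad.size:
        raise ValueError(
            f"phenotype {Y.phenotype_ids[bad[0]]} contains missing/non-finite values"
        )
    vals = standardize_rows(Y.values, Y.phenotype_ids) if standardize else Y.values
    sq = np.sum(vals**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (vals @ vals.T)
    np.fill_diagonal(d2, 0.0)
    D = np.sqrt(np.maximum(d2, 0.0))
    D = (D + D.T) / 2.0
    return DistanceMatrix(D, list(Y.phenotype_ids))


def _cluster_distance(
    D: np.ndarray, a: list[int], b: list[int], linkage: str
) -> float:
    block = D[np.ix_(a, b)]
    if linkage == "single":
        return float(block.min())
    if linkage == "complete":
        return float(block.max())
    if linkage == "average":
        return float(block.mean())
    raise ValueError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")


def linkage_merge_sequence(
    D: DistanceMatrix, linkage: str = "single"
) -> list[tuple[int, int, float]]:
    """Full bottom-up merge sequence (d - 1 merges).

    Clusters are named by their smallest member index.  Ties in merge
    distance are broken by the lexicographically smallest
    (min name, max name) pair, making the hierarchy deterministic.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    d = D.size
    clusters: dict[int, list[int]] = {i: [i] for i in range(d)}
    merges: list[tuple[int, int, float]] = []
    while len(clusters) > 1:
        names = sorted(clusters)
        best: tuple[float, int, int] | None = None
        for ai in range(len(names)):
            for bi in range(ai + 1, len(names)):
                a, b = names[ai], names[bi]
                dist = _cluster_distance(D.values, clusters[a], clusters[b], linkage)
                if best is None or dist < best[0]:
                    best = (dist, a, b)
        assert best is not None
        dist, a, b = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
        merges.append((a, b, dist))
    return merges


def _partition_from_merges(
    d: int, merges: list[tuple[int, int, float]], K: int
) -> ClusterPartition:
    parent = list(range(d))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    used = merges[: d - K]
    for a, b, _ in used:
        ra, rb = find(a), find(b)
        parent[max(ra, rb)] = min(ra, rb)
    roots = [find(i) for i in range(d)]
    order = {r: k + 1 for k, r in enumerate(sorted(set(roots)))}
    assignment = np.array([order[r] for r in roots])
    return ClusterPartition(assignment, K, [tuple(m) for m in used])


def agnes(D: DistanceMatrix, K: int, linkage: str = "single") -> ClusterPartition:
    """Cut the agglomerative-nesting hierarchy of ``D`` at ``K`` clusters."""
    d = D.size
    if not 1 <= K <= d:
        raise ValueError(f"K must lie in 1..{d}, got {K}")
    merges = linkage_merge_sequence(D, linkage)
    return _partition_from_merges(d, merges, K)


def silhouette(
    D: DistanceMatrix,
    partition: ClusterPartition,
    singleton_zero: bool = True,
) -> SilhouetteResult:
    """Silhouette coefficients for a partition of the distance matrix.

    a(i) is the mean distance to the other members of i's cluster, defined
    as 0 for singletons; b(i) is the smallest mean distance to another
    cluster; s(i) = (b - a) / max(a, b).  Singletons score s = 0 by
    default (Rousseeuw's convention, required for K selection to prefer
    real structure over near-singleton partitions); pass
    ``singleton_zero=False`` to take the a = 0 definition literally, which
    gives singletons s = 1 whenever b > 0.  When both a and b are 0
    (degenerate all-zero distances) s is defined as 0.
    """
    d = D.size
    if len(partition.assignment) != d:
        raise ValueError("partition size does not match distance matrix")
    if partition.K < 2:
        raise ValueError("silhouette requires K >= 2 (b(i) undefined for K = 1)")
    a = np.zeros(d)
    b = np.zeros(d)
    s = np.zeros(d)
    members = {k: partition.members(k) for k in range(1, partition.K + 1)}
    for i in range(d):
        k = partition.assignment[i]
        own = members[k]
        if len(own) > 1:
            a[i] = D.values[i, own[own != i]].mean()
        b[i] = min(
            D.values[i, members[other]].mean()
            for other in members
            if other != k
        )
        denom = max(a[i], b[i])
        if denom == 0:
            s[i] = 0.0
        elif len(own) == 1 and singleton_zero:
            s[i] = 0.0
        else:
            s[i] = (b[i] - a[i]) / denom
    return SilhouetteResult(s, float(s.mean()), a, b)


def select_k(
    D: DistanceMatrix,
    k_min: int | None = None,
    k_max: int | None = None,
    linkage: str = "single",
    singleton_zero: bool = True,
) -> tuple[int, ClusterPartition, dict[int, float]]:
    """Pick the cluster count maximizing the mean silhouette.

    The hierarchy is built once and cut at every K in [k_min, k_max]
    (defaults 2 and d - 1).  Exact ties in mean silhouette go to the
    smaller K.
    """
    d = D.size
    if d < 3:
        raise ValueError("need at least 3 phenotypes to search K in 2..d-1")
    k_min = 2 if k_min is None else k_min
    k_max = d - 1 if k_max is None else k_max
    if not 2 <= k_min <= k_max <= d - 1:
        raise ValueError(f"require 2 <= k_min <= k_max <= {d - 1}")
    if np.all(D.values == 0):
        warnings.warn("all distances are zero; no cluster structure to select")
        raise ValueError("cannot select K: all phenotypes are identical")
    merges = linkage_merge_sequence(D, linkage)
    s_by_k: dict[int, float] = {}
    best_k = None
    best_partition = None
    for K in range(k_min, k_max + 1):
        part = _partition_from_merges(d, merges, K)
        s_by_k[K] = silhouette(D, part, singleton_zero=singleton_zero).mean_s
        if best_k is None or s_by_k[K] > s_by_k[best_k]:
            best_k, best_partition = K, part
    assert best_k is not None and best_partition is not None
    return best_k, best_partition, s_by_k
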