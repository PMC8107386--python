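"""Per-cluster representative phenotypes: mean, median, or top PCs.

Each cluster's member phenotypes are standardized first; the PCA route
keeps the smallest number of component score vectors whose cumulative
explained-variance fraction strictly exceeds the threshold (default
0.85).  Component signs are fixed by flipping so the loading of largest
magnitude is positive, making output deterministic.
"""

from __future__ import annotations

import numpy as np

from .clustering import standardize_rows
from .datatypes import ClusterPartition, PhenotypeMatrix, RepresentativeSet

METHODS = ("mean", "median", "pca")


def standardize_cluster(Y: PhenotypeMatrix, members: np.ndarray) -> np.ndarray:
    """Standardized (mean 0, SD 1) block of the member phenotype rows."""
    members = np.asarray(members, dtype=int)
    if members.size == 0:
        raise ValueError("members must be nonempty")
    labels = [Y.phenotype_ids[i] for i in members]
    return standardize_rows(Y.values[members], labels)


def mean_representative(Yk: np.ndarray) -> np.ndarray:
    """Elementwise mean over member phenotype rows."""
    Yk = np.atleast_2d(np.asarray(Yk, dtype=float))
    if Yk.shape[0] == 0:
        raise ValueError("empty cluster has no mean representative")
    return Yk.mean(axis=0)


def median_representative(Yk: np.ndarray) -> np.ndarray:
    """Elementwise median over member phenotype rows."""
    Yk = np.atleast_2d(np.asarray(Yk, dtype=float))
    if Yk.shape[0] == 0:
        raise ValueError("empty cluster has no median representative")
    return np.median(Yk, axis=0)


def pca_representatives(
    Yk: np.ndarray, cum_threshold: float = 0.85
) -> tuple[np.ndarray, np.ndarray]:
    """Top principal-component score vectors of a standardized cluster block.

    Returns the minimal set of score vectors whose cumulative explained
    fraction strictly exceeds ``cum_threshold``, and the per-component
    fractions (non-increasing).
    """
    if not 0 < cum_threshold < 1:
        raise ValueError("cum_threshold must lie in (0, 1)")
    Yk = np.atleast_2d(np.asarray(Yk, dtype=float))
    dk, n = Yk.shape
    if dk == 0:
        raise ValueError("empty cluster")
    centered = Yk - Yk.mean(axis=1, keepdims=True)
    cov = centered @ centered.T / n
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.maximum(eigvals[order], 0.0)
    eigvecs = eigvecs[:, order]
    total = eigvals.sum()
    if total == 0:
        raise ValueError("cluster has zero total variance")
    fractions = eigvals / total
    cum = np.cumsum(fractions)
    n_keep = int(np.searchsorted(cum, cum_threshold, side="right")) + 1
    n_keep = min(n_keep, dk)
    # deterministic sign: largest-magnitude loading positive
    for j in range(n_keep):
        v = eigvecs[:, j]
        if v[np.argmax(np.abs(v))] < 0:
            eigvecs[:, j] = -v
    scores = eigvecs[:, :n_keep].T @ centered
    return scores, fractions[:n_keep]


def build_representatives(
    Y: PhenotypeMatrix,
    partition: ClusterPartition,
    method: str = "pca",
    cum_threshold: float = 0.85,
) -> RepresentativeSet:
    """Standardize each cluster and stack its representative row(s)."""
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    if len(partition.assignment) != Y.n_phenotypes:
        raise ValueError("partition does not match phenotype matrix")
    rows: list[np.ndarray] = []
    source: list[int] = []
    row_ids: list[str] = []
    explained: list[float] = []
    for k in range(1, partition.K + 1):
        members = partition.members(k)
        block = standardize_cluster(Y, members)
        if method == "mean":
            rows.append(mean_representative(block))
            source.append(k)
            row_ids.append(f"c{k}_mean")
        elif method == "median":
            rows.append(median_representative(block))
            source.append(k)
            row_ids.append(f"c{k}_median")
        else:
            scores, fracs = pca_representatives(block, cum_threshold)
            for j in range(scores.shape[0]):
                rows.append(scores[j])
                source.append(k)
                row_ids.append(f"c{k}_PC{j + 1}")
                explained.append(float(fracs[j]))
    return RepresentativeSet(
        values=np.vstack(rows),
        source_cluster=np.array(source),
        method=method,
        row_ids=row_ids,
        individual_ids=list(Y.individual_ids),
        explained_fraction=np.array(explained) if method == "pca" else None,
        cum_threshold=cum_threshold,
    )
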