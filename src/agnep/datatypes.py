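"""Core data containers shared across the agnep pipeline.

All containers are thin, validated wrappers around numpy arrays with
identifier bookkeeping.  Phenotype matrices are stored phenotypes-by-
individuals (d x n); genotype matrices individuals-by-variants (n x m).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class PhenotypeMatrix:
    """d x n real matrix of phenotype values (rows = phenotypes)."""

    values: np.ndarray
    phenotype_ids: list[str]
    individual_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("phenotype values must be a 2-D matrix")
        d, n = self.values.shape
        if len(self.phenotype_ids) != d:
            raise ValueError(
                f"phenotype_ids length {len(self.phenotype_ids)} != row count {d}"
            )
        if len(self.individual_ids) != n:
            raise ValueError(
                f"individual_ids length {len(self.individual_ids)} != column count {n}"
            )

    @property
    def n_phenotypes(self) -> int:
        return self.values.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.values.shape[1]


@dataclass
class GenotypeMatrix:
    """n x m matrix of minor-allele counts in {0, 1, 2}."""

    values: np.ndarray
    maf: np.ndarray
    variant_ids: list[str]
    individual_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.maf = np.asarray(self.maf, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be a 2-D matrix")
        n, m = self.values.shape
        if not np.isin(self.values, (0, 1, 2)).all():
            raise ValueError("genotype entries must be 0, 1 or 2")
        if len(self.maf) != m:
            raise ValueError(f"maf length {len(self.maf)} != variant count {m}")
        if np.any(self.maf <= 0) or np.any(self.maf > 0.5):
            raise ValueError("every maf entry must lie in (0, 0.5]")
        if len(self.variant_ids) != m:
            raise ValueError("variant_ids length mismatch")
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length mismatch")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_variants(self) -> int:
        return self.values.shape[1]


@dataclass
class DistanceMatrix:
    """Symmetric d x d Euclidean distance matrix between phenotype rows."""

    values: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        d = self.values.shape[0]
        if self.values.shape != (d, d):
            raise ValueError("distance matrix must be square")
        if len(self.labels) != d:
            raise ValueError("labels length mismatch")
        if np.any(self.values < 0):
            raise ValueError("distances must be nonnegative")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal must be zero")

    @property
    def size(self) -> int:
        return self.values.shape[0]


@dataclass
class ClusterPartition:
    """Assignment of d phenotypes to K clusters plus the merge history.

    ``assignment`` holds labels in 1..K.  ``merge_history`` is the ordered
    list of (cluster-a, cluster-b, merge-distance) triples that produced
    the partition, with exactly d - K entries; clusters are named by their
    smallest member index (0-based).
    """

    assignment: np.ndarray
    K: int
    merge_history: list[tuple[int, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)
        labels = np.unique(self.assignment)
        if not np.array_equal(labels, np.arange(1, self.K + 1)):
            raise ValueError("every label in 1..K must occur at least once")
        d = len(self.assignment)
        if len(self.merge_history) != d - self.K:
            raise ValueError(
                f"merge_history must have d - K = {d - self.K} entries, "
                f"got {len(self.merge_history)}"
            )

    def members(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == label)


@dataclass
class SilhouetteResult:
    per_sample: np.ndarray
    mean_s: float
    a_values: np.ndarray
    b_values: np.ndarray


@dataclass
class RepresentativeSet:
    """r x n matrix of representative phenotypes with cluster provenance."""

    values: np.ndarray
    source_cluster: np.ndarray
    method: str
    row_ids: list[str]
    individual_ids: list[str]
    explained_fraction: np.ndarray | None = None
    cum_threshold: float = 0.85

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.source_cluster = np.asarray(self.source_cluster, dtype=int)
        if self.values.shape[0] != len(self.source_cluster):
            raise ValueError("source_cluster length must match row count")
        if self.method not in ("mean", "median", "pca"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.explained_fraction is not None:
            self.explained_fraction = np.asarray(self.explained_fraction, dtype=float)

    @property
    def n_representatives(self) -> int:
        return self.values.shape[0]


@dataclass
class AssociationResult:
    """Per-variant scan result for one test (MANOVA or one-phenotype ANOVA)."""

    variant_ids: list[str]
    statistic: np.ndarray
    p_value: np.ndarray
    neg_log10_p: np.ndarray
    scan_kind: str
    phenotype_label: str | None = None
    degenerate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.statistic = np.asarray(self.statistic, dtype=float)
        self.p_value = np.asarray(self.p_value, dtype=float)
        self.neg_log10_p = np.asarray(self.neg_log10_p, dtype=float)
        if self.degenerate is None:
            self.degenerate = np.zeros(len(self.p_value), dtype=bool)
        if np.any(self.p_value <= 0) or np.any(self.p_value > 1):
            raise ValueError("p-values must lie in (0, 1]")
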