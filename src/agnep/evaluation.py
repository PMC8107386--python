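"""Power/FDR evaluation against simulated truth and permutation thresholds."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .association import anova_scan, manova_scan
from .clustering import phenotype_distance_matrix, select_k
from .datatypes import AssociationResult, GenotypeMatrix, RepresentativeSet
from .representatives import build_representatives
from .synthetic import SimulationTruth, make_design, simulate_genotypes, simulate_phenotypes

METHOD_LABELS = ("AGNEP", "AGNEm", "AGNEmed", "MANOVA", "ANOVA")


@dataclass
class PowerCurve:
    """Power attainable at each empirical-FDR bound, averaged over replicates."""

    fdr_grid: np.ndarray
    power: np.ndarray
    n_replicates: int
    method_label: str

    def __post_init__(self) -> None:
        self.fdr_grid = np.asarray(self.fdr_grid, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(np.diff(self.fdr_grid) < 0):
            raise ValueError("fdr_grid must be increasing")
        if np.any((self.power < 0) | (self.power > 1)):
            raise ValueError("power must lie in [0, 1]")
        if np.any(np.diff(self.power) < -1e-12):
            raise ValueError("power must be non-decreasing along the grid")


def _single_curve(
    p_values: np.ndarray, is_qtn: np.ndarray, fdr_grid: np.ndarray
) -> np.ndarray:
    """Max power with empirical FDR <= each grid value, for one replicate."""
    order = np.argsort(p_values, kind="stable")
    hits = is_qtn[order]
    n_qtn = int(is_qtn.sum())
    tp = np.cumsum(hits)
    t = np.arange(1, len(p_values) + 1)
    fdr = (t - tp) / t
    power_at_cut = tp / n_qtn
    out = np.zeros(len(fdr_grid))
    for gi, f in enumerate(fdr_grid):
        ok = fdr <= f
        out[gi] = power_at_cut[ok].max() if ok.any() else 0.0
    return out


def power_fdr_curve(
    results: AssociationResult | list[AssociationResult],
    truth: SimulationTruth | list[SimulationTruth],
    fdr_grid: np.ndarray,
    method_label: str = "",
) -> PowerCurve:
    """Rank-based empirical power/FDR curve; averaged when given replicates.

    Variants are ranked by ascending p; at each cut rank t the empirical
    FDR is (false positives in top t)/t and the power is (true QTNs in
    top t)/(all QTNs); each grid value reports the best power attainable
    with FDR at or below it (0 when no cut qualifies).
    """
    fdr_grid = np.asarray(fdr_grid, dtype=float)
    if np.any(np.diff(fdr_grid) < 0):
        raise ValueError("fdr_grid must be increasing")
    if isinstance(results, AssociationResult):
        results = [results]
        truth = [truth]  # type: ignore[list-item]
    curves = []
    for res, tr in zip(results, truth, strict=True):
        if len(tr.qtn_indices) == 0:
            raise ValueError("truth has no QTNs; power is undefined")
        qtn_ids = set(
            tr.qtn_variant_ids
            if tr.qtn_variant_ids
            else [str(j) for j in tr.qtn_indices]
        )
        is_qtn = np.array([v in qtn_ids for v in res.variant_ids])
        if not is_qtn.any():
            raise ValueError("no truth QTN found among the scanned variants")
        curves.append(_single_curve(res.p_value, is_qtn, fdr_grid))
    return PowerCurve(
        fdr_grid, np.mean(curves, axis=0), len(curves), method_label
    )


def min_p_quantile(minima: np.ndarray, alpha: float, n_perm: int) -> float:
    """Empirical alpha-quantile (order statistic) of permuted genome-wide minima."""
    minima = np.sort(np.asarray(minima, dtype=float))
    k = int(np.floor(alpha * n_perm + 1e-12))
    if k < 1:
        warnings.warn(
            f"alpha = {alpha} below the 1/{n_perm} resolution of {n_perm} "
            "permutations; returning the most extreme permuted minimum"
        )
        return float(minima[0])
    return float(minima[k - 1])


def permutation_threshold(
    reps: RepresentativeSet,
    genotypes: GenotypeMatrix,
    n_perm: int = 10,
    alpha: float = 0.05,
    seed: int = 0,
    statistic: str = "wilks",
) -> float:
    """Genome-wide significance threshold from permuted minimum p-values.

    Individuals' representative-phenotype columns are shuffled jointly
    (genotypes fixed), the scan rerun, and the minimum p recorded per
    permutation; the returned value is the -log10 of the empirical
    alpha-quantile of those minima.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    rng = np.random.default_rng(seed)
    n = reps.values.shape[1]
    minima = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n)
        shuffled = RepresentativeSet(
            values=reps.values[:, perm],
            source_cluster=reps.source_cluster,
            method=reps.method,
            row_ids=list(reps.row_ids),
            individual_ids=list(reps.individual_ids),
            explained_fraction=reps.explained_fraction,
            cum_threshold=reps.cum_threshold,
        )
        minima[b] = manova_scan(shuffled, genotypes, statistic).p_value.min()
    return float(-np.log10(min_p_quantile(minima, alpha, n_perm)))


def count_qtns(results: AssociationResult, threshold: float) -> int:
    """Number of variants at or above a -log10 p threshold."""
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    return int(np.sum(results.neg_log10_p >= threshold))


def _scan_for_method(method, pheno, genotypes, cum_threshold):
    if method == "ANOVA":
        return anova_scan(pheno, genotypes).combined
    if method == "MANOVA":
        reps = RepresentativeSet(
            values=pheno.values,
            source_cluster=np.ones(pheno.n_phenotypes, dtype=int),
            method="mean",
            row_ids=list(pheno.phenotype_ids),
            individual_ids=list(pheno.individual_ids),
        )
        return manova_scan(reps, genotypes)
    rep_method = {"AGNEP": "pca", "AGNEm": "mean", "AGNEmed": "median"}[method]
    D = phenotype_distance_matrix(pheno)
    _, partition, _ = select_k(D)
    reps = build_representatives(pheno, partition, rep_method, cum_threshold)
    return manova_scan(reps, genotypes)


def run_benchmark(
    preset: str = "simI",
    methods: tuple[str, ...] = METHOD_LABELS,
    n_replicates: int = 20,
    seed: int = 0,
    *,
    n_qtn: int = 10,
    n_individuals: int = 500,
    n_variants: int = 1000,
    qtn_variance_fraction: float = 0.005,
    fdr_grid: np.ndarray | None = None,
    cum_threshold: float = 0.85,
    mixed_sign: bool = False,
) -> dict[str, PowerCurve]:
    """Simulate -> cluster -> represent -> scan -> power, per method.

    "MANOVA" scans all phenotypes jointly without clustering; "ANOVA" is
    the univariate min-p baseline; the AGNE* methods cluster first and
    differ only in the representative (PC scores / mean / median).
    """
    for method in methods:
        if method not in METHOD_LABELS:
            raise ValueError(
                f"unknown method {method!r}; choose from {METHOD_LABELS}"
            )
    if fdr_grid is None:
        fdr_grid = np.linspace(0.0, 0.3, 31)
    rng = np.random.default_rng(seed)
    per_method: dict[str, list[AssociationResult]] = {m: [] for m in methods}
    truths: list[SimulationTruth] = []
    for _ in range(n_replicates):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        design = make_design(
            preset,
            n_qtn,
            seed=rep_seed,
            n_individuals=n_individuals,
            n_variants=n_variants,
            qtn_variance_fraction=qtn_variance_fraction,
            mixed_sign=mixed_sign,
        )
        genotypes = simulate_genotypes(
            n_individuals, n_variants, design.maf_range, rep_seed
        )
        pheno, truth = simulate_phenotypes(genotypes, design, rep_seed + 1)
        truths.append(truth)
        for method in methods:
            per_method[method].append(
                _scan_for_method(method, pheno, genotypes, cum_threshold)
            )
    return {
        m: power_fdr_curve(per_method[m], truths, fdr_grid, method_label=m)
        for m in methods
    }
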