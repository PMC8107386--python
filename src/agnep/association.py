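"""Per-variant association scans.

The multivariate scan regresses the r representative phenotypes on an
intercept plus allele count and tests the genotype term with Wilks'
lambda.  With a single regressor the hypothesis matrix has rank one, so
lambda reduces to a rank-one determinant update and the Rao F
transformation F = (1 - L)/L * (n - r - 1)/r with (r, n - r - 1) degrees
of freedom is exact; this also makes the whole scan a handful of matrix
products.  Pillai's trace is offered as an option (identical p-values in
the rank-one case).
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy import stats

from .datatypes import (
    AssociationResult,
    GenotypeMatrix,
    PhenotypeMatrix,
    RepresentativeSet,
)

_P_FLOOR = 1e-300  # keep p in (0, 1] on the -log10 scale


def _finish(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.clip(p, _P_FLOOR, 1.0)
    return p, -np.log10(p)


def manova_scan(
    reps: RepresentativeSet,
    genotypes: GenotypeMatrix,
    statistic: str = "wilks",
) -> AssociationResult:
    """MANOVA scan of every variant against the representative phenotypes."""
    if statistic not in ("wilks", "pillai"):
        raise ValueError("statistic must be 'wilks' or 'pillai'")
    Y = np.atleast_2d(reps.values)
    r, n = Y.shape
    if genotypes.n_individuals != n:
        raise ValueError(
            f"individual axis mismatch: representatives have {n}, "
            f"genotypes have {genotypes.n_individuals}"
        )
    if n <= r + 2:
        raise ValueError("need n > r + 2 individuals for the MANOVA scan")
    Yc = Y - Y.mean(axis=1, keepdims=True)
    E_full = Yc @ Yc.T
    rank = np.linalg.matrix_rank(E_full, tol=1e-8 * max(1.0, np.trace(E_full)))
    if rank < r:
        corr = np.corrcoef(Yc)
        ii, jj = np.triu_indices(r, k=1)
        worst = np.argmax(np.abs(corr[ii, jj]))
        raise ValueError(
            "representative phenotypes are rank-deficient (collinear rows "
            f"{reps.row_ids[ii[worst]]} and {reps.row_ids[jj[worst]]})"
        )
    E_inv = np.linalg.inv(E_full)

    X = genotypes.values.astype(float)
    Xc = X - X.mean(axis=0, keepdims=True)
    ss_x = np.einsum("ij,ij->j", Xc, Xc)
    degenerate = ss_x == 0

    U = Yc @ Xc  # r x m cross-products
    quad = np.einsum("ij,ik,kj->j", U, E_inv, U)
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = 1.0 - quad / ss_x
    lam = np.where(degenerate, 1.0, np.clip(lam, 1e-300, 1.0))

    df2 = n - r - 1
    with np.errstate(divide="ignore"):
        F = (1.0 - lam) / lam * df2 / r
    p = stats.f.sf(F, r, df2)
    p = np.where(degenerate, 1.0, p)
    p, nlp = _finish(p)
    stat = 1.0 - lam if statistic == "pillai" else lam
    return AssociationResult(
        variant_ids=list(genotypes.variant_ids),
        statistic=stat,
        p_value=p,
        neg_log10_p=nlp,
        scan_kind="manova",
        degenerate=degenerate,
    )


@dataclass
class AnovaScanResult:
    """Per-phenotype scans plus the min-p ranking summary."""

    per_phenotype: list[AssociationResult]
    combined: AssociationResult


def anova_scan(Y: PhenotypeMatrix, genotypes: GenotypeMatrix) -> AnovaScanResult:
    """Univariate F-test of the additive genotype term, one phenotype at a time.

    The combined result takes the minimum p across phenotypes per variant;
    it is a ranking device for power comparisons, not a calibrated test.
    """
    n = Y.n_individuals
    if genotypes.n_individuals != n:
        raise ValueError("individual axis mismatch between phenotypes and genotypes")
    X = genotypes.values.astype(float)
    Xc = X - X.mean(axis=0, keepdims=True)
    ss_x = np.einsum("ij,ij->j", Xc, Xc)
    degenerate = ss_x == 0
    df2 = n - 2

    results: list[AssociationResult] = []
    for i, label in enumerate(Y.phenotype_ids):
        y = Y.values[i]
        yc = y - y.mean()
        ss_y = yc @ yc
        if ss_y == 0:
            warnings.warn(f"phenotype {label} has zero variance; scan skipped")
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = (yc @ Xc) ** 2 / (ss_x * ss_y)
        r2 = np.where(degenerate, 0.0, np.clip(r2, 0.0, 1.0 - 1e-15))
        F = r2 / (1.0 - r2) * df2
        p = stats.f.sf(F, 1, df2)
        p = np.where(degenerate, 1.0, p)
        p, nlp = _finish(p)
        results.append(
            AssociationResult(
                variant_ids=list(genotypes.variant_ids),
                statistic=F,
                p_value=p,
                neg_log10_p=nlp,
                scan_kind="anova",
                phenotype_label=label,
                degenerate=degenerate,
            )
        )
    if not results:
        raise ValueError("no phenotype with nonzero variance to scan")
    min_p = np.min([res.p_value for res in results], axis=0)
    min_p, nlp = _finish(min_p)
    combined = AssociationResult(
        variant_ids=list(genotypes.variant_ids),
        statistic=np.max([res.statistic for res in results], axis=0),
        p_value=min_p,
        neg_log10_p=nlp,
        scan_kind="anova",
        phenotype_label="min_p",
        degenerate=degenerate,
    )
    return AnovaScanResult(results, combined)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """-log10 of the Bonferroni-corrected per-test threshold alpha/n_tests."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")
    return float(-np.log10(alpha / n_tests))
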