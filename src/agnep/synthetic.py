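"""Synthetic genotype and factor-model phenotype generation.

Genotypes are independent biallelic variants drawn under Hardy-Weinberg
equilibrium with per-variant minor-allele frequencies sampled uniformly
from a configurable interval.  Phenotypes follow a group factor model:
each phenotype loads on the latent factor of every group containing it,
causal variants (QTNs) are assigned to groups and add an additive
allele-count effect to every member phenotype (independent random signs
by default), and residuals are i.i.d. normal (or matrix-normal with a
supplied row covariance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import GenotypeMatrix, PhenotypeMatrix

#: group index sets (1-based, inclusive ranges) for the three built-in designs
PRESET_GROUPS: dict[str, list[tuple[int, int]]] = {
    "simI": [(1, 4), (5, 8), (9, 12), (13, 16), (17, 20)],
    "simII": [(1, 5), (4, 8), (9, 12), (13, 18), (16, 20)],
    "simIII": [
        (1, 15),
        (10, 30),
        (31, 40),
        (41, 60),
        (61, 75),
        (70, 90),
        (85, 95),
        (90, 100),
    ],
}

DEFAULT_LOADING = 0.8
DEFAULT_RESIDUAL_SD = 0.6  # with loading 0.8 a one-group phenotype has unit variance


@dataclass
class SyntheticDesign:
    """Full specification of one simulated dataset."""

    n_individuals: int
    n_variants: int
    n_phenotypes: int
    maf_range: tuple[float, float]
    groups: list[list[int]]  # 0-based phenotype indices per group
    qtn_indices: np.ndarray  # 0-based variant indices
    qtn_group_map: np.ndarray  # group index per QTN
    effect_sizes: np.ndarray | None = None  # per-QTN beta; derived if None
    qtn_variance_fraction: float = 0.005
    loadings: np.ndarray | None = None  # d x G loading matrix; derived if None
    residual_sd: float = DEFAULT_RESIDUAL_SD
    residual_cov: np.ndarray | None = None
    seed: int = 0
    mixed_sign: bool = False
    # "random": each affected phenotype receives the QTN effect with an
    # independent random sign, so the signal is not collinear with the
    # group factor; "positive": identical (aligned) effects throughout
    effect_sign: str = "random"

    def __post_init__(self) -> None:
        self.qtn_indices = np.asarray(self.qtn_indices, dtype=int)
        self.qtn_group_map = np.asarray(self.qtn_group_map, dtype=int)
        d = self.n_phenotypes
        for g, members in enumerate(self.groups):
            if len(members) == 0:
                raise ValueError(f"group {g} is empty")
            if min(members) < 0 or max(members) >= d:
                raise ValueError(f"group {g} indexes phenotypes outside 1..{d}")
        if len(np.unique(self.qtn_indices)) != len(self.qtn_indices):
            raise ValueError("qtn_indices must be distinct")
        if len(self.qtn_indices) and (
            self.qtn_indices.min() < 0 or self.qtn_indices.max() >= self.n_variants
        ):
            raise ValueError("qtn_indices out of variant range")
        if len(self.qtn_group_map) != len(self.qtn_indices):
            raise ValueError("qtn_group_map must pair with qtn_indices")
        if self.effect_sign not in ("random", "positive"):
            raise ValueError("effect_sign must be 'random' or 'positive'")
        if self.residual_cov is not None:
            V = np.asarray(self.residual_cov, dtype=float)
            if V.shape != (d, d):
                raise ValueError("residual_cov must be d x d")
            if not np.allclose(V, V.T):
                raise ValueError("residual_cov must be symmetric")
            eigvals = np.linalg.eigvalsh(V)
            if eigvals.min() < -1e-10 * max(1.0, abs(eigvals.max())):
                raise ValueError("residual_cov must be positive semi-definite")
            self.residual_cov = V
        if self.loadings is None:
            self.loadings = self._default_loadings()
        else:
            self.loadings = np.asarray(self.loadings, dtype=float)
            if self.loadings.shape != (d, len(self.groups)):
                raise ValueError("loadings must be d x n_groups")

    def _default_loadings(self) -> np.ndarray:
        lam = np.zeros((self.n_phenotypes, len(self.groups)))
        for g, members in enumerate(self.groups):
            for j, i in enumerate(sorted(members)):
                sign = -1.0 if (self.mixed_sign and j % 2 == 1) else 1.0
                lam[i, g] = sign * DEFAULT_LOADING
        return lam

    @property
    def group_sets(self) -> list[set[int]]:
        return [set(g) for g in self.groups]


@dataclass
class SimulationTruth:
    """Ground truth paired with a simulated phenotype matrix."""

    qtn_indices: np.ndarray
    qtn_effects: np.ndarray  # n_qtn x d realized per-phenotype effect vectors
    group_structure: list[list[int]] = field(default_factory=list)
    qtn_variant_ids: list[str] = field(default_factory=list)
    qtn_group_map: np.ndarray | None = None


def simulate_genotypes(
    n: int, m: int, maf_range: tuple[float, float], seed: int
) -> GenotypeMatrix:
    """Draw an n x m HWE genotype matrix with uniform MAF in ``maf_range``."""
    if n < 2:
        raise ValueError("n must be at least 2")
    if m < 1:
        raise ValueError("m must be at least 1")
    lo, hi = maf_range
    if not (0 < lo <= hi):
        raise ValueError(f"maf_range lower bound {lo} must be > 0 and <= upper bound")
    if hi > 0.5:
        raise ValueError(f"maf_range upper bound {hi} exceeds 0.5")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(lo, hi, size=m)
    # genotype ~ Binomial(2, p) is exactly the HWE draw ((1-p)^2, 2p(1-p), p^2)
    values = rng.binomial(2, maf[None, :], size=(n, m)).astype(np.int8)
    variant_ids = [f"snp{j + 1}" for j in range(m)]
    individual_ids = [f"ind{i + 1}" for i in range(n)]
    return GenotypeMatrix(values, maf, variant_ids, individual_ids)


def make_design(
    preset: str,
    n_qtn: int = 10,
    seed: int = 0,
    *,
    n_individuals: int = 5000,
    n_variants: int = 10000,
    maf_range: tuple[float, float] = (0.1, 0.5),
    qtn_variance_fraction: float = 0.005,
    mixed_sign: bool = False,
    residual_sd: float = DEFAULT_RESIDUAL_SD,
    effect_sign: str = "random",
) -> SyntheticDesign:
    """Build a :class:`SyntheticDesign` for one of the built-in presets.

    QTNs are spread evenly over the variant index range and assigned
    round-robin to groups so every group carries causal signal.
    """
    if preset not in PRESET_GROUPS:
        raise ValueError(
            f"unknown preset {preset!r}; valid presets: {sorted(PRESET_GROUPS)}"
        )
    if n_qtn < 0:
        raise ValueError("n_qtn must be nonnegative")
    ranges = PRESET_GROUPS[preset]
    groups = [list(range(lo - 1, hi)) for lo, hi in ranges]
    d = max(hi for _, hi in ranges)
    if n_qtn > n_variants:
        raise ValueError("n_qtn exceeds n_variants")
    qtn_indices = np.linspace(0, n_variants - 1, num=n_qtn, dtype=int) if n_qtn else (
        np.empty(0, dtype=int)
    )
    qtn_group_map = np.arange(n_qtn) % len(groups)
    return SyntheticDesign(
        n_individuals=n_individuals,
        n_variants=n_variants,
        n_phenotypes=d,
        maf_range=maf_range,
        groups=groups,
        qtn_indices=qtn_indices,
        qtn_group_map=qtn_group_map,
        qtn_variance_fraction=qtn_variance_fraction,
        mixed_sign=mixed_sign,
        residual_sd=residual_sd,
        effect_sign=effect_sign,
        seed=seed,
    )


def _effect_betas(design: SyntheticDesign, maf: np.ndarray) -> np.ndarray:
    """Per-QTN allele-count effect sizes.

    When not given explicitly, each beta is sized so the QTN explains a
    fraction f of the variance of a phenotype whose non-genetic variance
    is loading^2 + sigma^2 (one group): beta^2 * 2p(1-p) = f/(1-f) * base.
    """
    if design.effect_sizes is not None:
        return np.asarray(design.effect_sizes, dtype=float)
    f = design.qtn_variance_fraction
    if not (0 <= f < 1):
        raise ValueError("qtn_variance_fraction must lie in [0, 1)")
    base = DEFAULT_LOADING**2 + design.residual_sd**2
    p = maf[design.qtn_indices]
    geno_var = 2.0 * p * (1.0 - p)
    return np.sqrt(f / (1.0 - f) * base / geno_var)


def simulate_phenotypes(
    genotypes: GenotypeMatrix, design: SyntheticDesign, seed: int
) -> tuple[PhenotypeMatrix, SimulationTruth]:
    """Generate factor-model phenotypes from ``genotypes`` under ``design``.

    Phenotype i of individual j is the sum of (a) additive allele-count
    effects of every QTN assigned to a group containing i, (b) the loaded
    latent group factors, and (c) residual noise.
    """
    n, m = genotypes.values.shape
    if n != design.n_individuals:
        raise ValueError(
            f"individual axis mismatch: genotypes have {n}, design expects "
            f"{design.n_individuals}"
        )
    if m != design.n_variants:
        raise ValueError(
            f"variant axis mismatch: genotypes have {m}, design expects "
            f"{design.n_variants}"
        )
    d = design.n_phenotypes
    G = len(design.groups)
    rng = np.random.default_rng(seed)

    betas = _effect_betas(design, genotypes.maf)
    # genetic component: effects placed on all phenotypes of the QTN's group,
    # with independent random signs by default (keeps the causal signal from
    # being collinear with the shared group factor)
    effects = np.zeros((len(design.qtn_indices), d))
    for q, (g, beta) in enumerate(zip(design.qtn_group_map, betas)):
        members = design.groups[g]
        signs = (
            rng.choice([-1.0, 1.0], size=len(members))
            if design.effect_sign == "random"
            else np.ones(len(members))
        )
        effects[q, members] = beta * signs
    Y = np.zeros((d, n))
    if len(design.qtn_indices):
        X = genotypes.values[:, design.qtn_indices].astype(float)  # n x q
        Y += effects.T @ X.T

    factors = rng.standard_normal((G, n))
    Y += design.loadings @ factors

    if design.residual_cov is not None:
        L = np.linalg.cholesky(
            design.residual_cov + 1e-12 * np.eye(d) * np.trace(design.residual_cov)
        )
        Y += L @ rng.standard_normal((d, n))
    else:
        Y += design.residual_sd * rng.standard_normal((d, n))

    pheno = PhenotypeMatrix(
        Y,
        phenotype_ids=[f"pheno{i + 1}" for i in range(d)],
        individual_ids=list(genotypes.individual_ids),
    )
    truth = SimulationTruth(
        qtn_indices=design.qtn_indices.copy(),
        qtn_effects=effects,
        group_structure=[list(g) for g in design.groups],
        qtn_variant_ids=[genotypes.variant_ids[j] for j in design.qtn_indices],
        qtn_group_map=design.qtn_group_map.copy(),
    )
    return pheno, truth
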