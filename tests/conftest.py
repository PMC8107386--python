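import numpy as np
import pytest

from agnep import (
    PhenotypeMatrix,
    make_design,
    simulate_genotypes,
    simulate_phenotypes,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210426)


@pytest.fixture(scope="session")
def simI_small():
    """Scaled-down simI dataset: n=600, m=300, 10 QTNs, stronger effects."""
    design = make_design(
        "simI", 10, seed=7, n_individuals=600, n_variants=300,
        qtn_variance_fraction=0.03,
    )
    geno = simulate_genotypes(600, 300, design.maf_range, 7)
    pheno, truth = simulate_phenotypes(geno, design, 8)
    return design, geno, pheno, truth


@pytest.fixture()
def toy_phenotypes():
    rng = np.random.default_rng(5)
    vals = rng.standard_normal((6, 50))
    return PhenotypeMatrix(
        vals,
        [f"p{i}" for i in range(6)],
        [f"ind{j}" for j in range(50)],
    )
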