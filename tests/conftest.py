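import numpy as np
import pytest

from epibn import GenotypeDataset


def make_random_dataset(
    rng: np.random.Generator,
    n_samples: int = 60,
    n_snps: int = 5,
    maf_range: tuple[float, float] = (0.1, 0.5),
) -> GenotypeDataset:
    """Null dataset: HWE genotypes, phenotype independent of everything."""
    while True:
        mafs = rng.uniform(*maf_range, size=n_snps)
        geno = rng.binomial(2, mafs[None, :], size=(n_samples, n_snps))
        pheno = rng.integers(0, 2, size=n_samples)
        if 0 < pheno.sum() < n_samples:
            return GenotypeDataset(
                geno, pheno, [f"s{i}" for i in range(n_snps)]
            )


def make_degenerate_dataset(n_samples: int = 40, n_snps: int = 3, case: bool = False):
    """Constant-phenotype dataset, built without invariant validation.

    Used only to exercise degenerate-limit behaviour of scoring functions;
    such data cannot pass :meth:`GenotypeDataset.validate`.
    """
    rng = np.random.default_rng(7)
    ds = object.__new__(GenotypeDataset)
    ds.genotypes = rng.integers(0, 3, size=(n_samples, n_snps)).astype(np.int8)
    ds.phenotype = np.full(n_samples, int(case), dtype=np.int8)
    ds.snp_ids = [f"s{i}" for i in range(n_snps)]
    ds.sample_ids = None
    return ds


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
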