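import numpy as np
import pytest

from ancestrx import (
    AdmixtureDesign,
    GenotypePanel,
    compute_ibs,
    mds_from_similarity,
    simulate_admixed_genotypes,
    snp_loadings,
)


def make_panel(rng: np.random.Generator, n_subjects: int, n_snps: int,
               missing_rate: float = 0.0) -> GenotypePanel:
    """Random canonical (minor-oriented) panel for round-trip style tests."""
    calls = rng.binomial(2, rng.uniform(0.05, 0.5, size=n_snps),
                         size=(n_subjects, n_snps)).astype(np.int8)
    if missing_rate > 0:
        calls[rng.random(calls.shape) < missing_rate] = -1
    panel = GenotypePanel(
        subject_ids=[f"S{i}" for i in range(n_subjects)],
        snp_ids=[f"rs{j}" for j in range(n_snps)],
        chrom=np.array(["1"] * n_snps, dtype=object),
        pos=np.arange(1, n_snps + 1) * 1000,
        alleles=[("A", "C")] * n_snps,
        calls=calls,
    )
    return panel.canonicalized()


@pytest.fixture
def rng():
    return np.random.default_rng(20230911)


@pytest.fixture(scope="session")
def admixed():
    """Moderate K=3 admixture shared across ancestry/proxy tests."""
    design = AdmixtureDesign(n_subjects=300, n_snps=5000, n_pops=3,
                             fst=0.1, seed=42)
    panel, q = simulate_admixed_genotypes(design)
    return panel, q


@pytest.fixture(scope="session")
def admixed_model(admixed):
    panel, q = admixed
    model = mds_from_similarity(compute_ibs(panel), d=5)
    snp_loadings(panel, model)
    return model
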