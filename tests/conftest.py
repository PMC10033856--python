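import numpy as np
import pytest

from genetne.io import GenotypeMatrix, LocusSpec


def make_matrix(genotypes, marker_type="SSR", repeat_length=2, populations=None):
    """Build a GenotypeMatrix from a nested list [sample][locus] = (a, b)."""
    arr = np.asarray(genotypes, dtype=np.int64)
    n, L, _ = arr.shape
    loci = [
        LocusSpec(name=f"L{j}", marker_type=marker_type,
                  repeat_length=repeat_length if marker_type == "SSR" else None)
        for j in range(L)
    ]
    return GenotypeMatrix(
        samples=[f"s{i}" for i in range(n)],
        loci=loci,
        alleles=arr,
        populations=populations or ["pop1"] * n,
    )


@pytest.fixture(scope="session")
def wf_sample():
    """One Wright-Fisher sample of known Ne for estimator checks."""
    from genetne.simulate import SimParams, simulate_wf

    params = SimParams(true_ne=50, n_generations=15, n_loci_snp=200,
                       sample_size=50, seed=42)
    g, truth = simulate_wf(params)
    return g, truth


@pytest.fixture(scope="session")
def clonal_sample():
    """Partially clonal population (~200 ramets, 10 SSR loci) with truth."""
    from genetne.simulate import SimParams, simulate_clonal_population

    params = SimParams(true_ne=50, n_loci_ssr=10, n_loci_snp=0, founder_size=20,
                       clonality_rate=0.9, growth_rate=0.5, n_years=20,
                       ancestral_ne=200, selfing_rate=0.02, seed=5, name="clonal")
    return simulate_clonal_population(params)
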