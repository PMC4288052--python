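import numpy as np
import pytest

from locusfine.types import GenotypeMatrix, SampleRecord, VariantRecord


def make_gm(calls, status=None, positions=None, ids=None, **sample_kw):
    """Small hand-built genotype matrix for unit tests."""
    calls = np.asarray(calls, dtype=np.int8)
    n, v = calls.shape
    sts = status if status is not None else [0] * n
    pos = positions if positions is not None else [j + 1 for j in range(v)]
    vids = ids if ids is not None else [f"v{j}" for j in range(v)]
    variants = [VariantRecord(id=vids[j], chrom="3", pos=int(pos[j])) for j in range(v)]
    samples = [
        SampleRecord(id=f"s{i:04d}", status=int(sts[i]), **sample_kw) for i in range(n)
    ]
    return GenotypeMatrix(calls, variants, samples)


@pytest.fixture(scope="session")
def study_pools():
    """Shared ancestral haplotype pools: 60 variants in 3 LD blocks."""
    from locusfine.synthetic_cohort import build_study_pools

    return build_study_pools(n_variants=60, block_sizes=(20, 20, 20), seed=5)


@pytest.fixture(scope="session")
def ea_cohort(study_pools):
    """One seeded case-control cohort (n=2000) with a protective causal variant."""
    from locusfine.synthetic_cohort import SimulationConfig, simulate_cohort

    cfg = SimulationConfig(
        n_cases=1000, n_controls=1000, causal_index=30, causal_or=0.7,
        causal_raf=0.30, rare_variant_count=0, seed=20260920,
    )
    gm, table = simulate_cohort(study_pools, cfg)
    return gm, table, cfg
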