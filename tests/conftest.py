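import numpy as np
import pytest

from sweepkit import GenotypeMatrix, SimConfig, VariantSite, simulate_cohort
from sweepkit.variant_io import MISSING


def make_gm(calls, positions=None, chrom="1", pops=None, depth=None, groups=None):
    """Build a GenotypeMatrix from a (samples x variants) nested list."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if positions is None:
        positions = [1000 * (j + 1) for j in range(m)]
    sample_ids = [f"s{i + 1}" for i in range(n)]
    if pops is None:
        pop_of = {s: "pop1" for s in sample_ids}
    else:
        pop_of = {s: p for s, p in zip(sample_ids, pops)}
    variants = [VariantSite(chrom, p, "A", "G") for p in positions]
    return GenotypeMatrix(
        sample_ids=sample_ids,
        pop_of=pop_of,
        group_of=None if groups is None else {s: g for s, g in zip(sample_ids, groups)},
        variants=variants,
        calls=calls,
        depth=None if depth is None else np.asarray(depth),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """4 pops x 5 samples x 100 SNPs, seed 1 — the round-trip fixture."""
    cfg = SimConfig(
        n_pops=4, n_per_pop=5, n_snps=100, chrom_lengths={"1": 500_000},
        sweep_regions=[], seed=1,
    )
    gm, truth = simulate_cohort(cfg)
    return gm, truth, cfg


@pytest.fixture()
def toy_filter_gm():
    """Hand-built 10-site matrix with known per-rule filter failures:
    2 depth, 3 missing, 1 MAF (the exact-boundary MAF=0.05 site), 4 pass.

    10 samples in two populations of 5; 20 alleles per site.
    """
    M = MISSING
    # one row per SITE (transposed below); samples s1-s5 = pop p1, s6-s10 = p2
    site_calls = [
        # 2 depth failures: raw calls complete, but one genotype sits at
        # depth 3 (<= min_depth) so masking pushes a population to 1/5 missing
        [0, 1, 1, 0, 1, 0, 1, 0, 1, 0],
        [0, 1, 1, 0, 1, 0, 1, 0, 1, 0],
        # 3 missingness failures: one raw ./. (1/5 = 0.2, not < 0.2)
        [0, M, 1, 0, 1, 0, 1, 0, 1, 0],
        [1, 0, 1, 0, 1, M, 0, 1, 0, 1],
        [0, 1, 0, 1, 0, 1, 0, 1, 0, M],
        # 1 MAF failure at the exact 5% boundary: 1 ALT allele out of 20
        [0, 0, 1, 0, 0, 0, 0, 0, 0, 0],
        # 4 passing sites, MAF 0.10 / 0.20 / 0.50 / 0.40
        [1, 0, 0, 0, 0, 1, 0, 0, 0, 0],
        [1, 1, 0, 0, 0, 1, 1, 0, 0, 0],
        [1, 1, 1, 1, 1, 1, 1, 1, 1, 1],
        [2, 2, 0, 0, 0, 2, 2, 0, 0, 0],
    ]
    calls = np.array(site_calls, dtype=np.int8).T  # samples x sites
    depth = np.full(calls.shape, 10, dtype=np.int32)
    depth[0, 0] = 3  # site 1: s1 (pop p1) masked
    depth[5, 1] = 3  # site 2: s6 (pop p2) masked
    pops = ["p1"] * 5 + ["p2"] * 5
    return make_gm(calls, pops=pops, depth=depth)
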