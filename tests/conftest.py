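import numpy as np
import pytest

import sowselect as ss


@pytest.fixture(scope="session")
def small_panel() -> ss.GenotypePanel:
    """50 accessions x 2,000 SNPs, 4 groups — cheap shared panel."""
    cfg = ss.SimConfig(n_accessions=50, n_snps=2000, rng_seed=1)
    return ss.simulate_panel(cfg)


@pytest.fixture(scope="session")
def study_panel() -> ss.GenotypePanel:
    """200 accessions x 20,000 SNPs, 4 groups — study-scale panel."""
    cfg = ss.SimConfig(n_accessions=200, n_snps=20_000, rng_seed=11)
    return ss.simulate_panel(cfg)


def naive_mismatch(sample: np.ndarray, accession: np.ndarray) -> float:
    """Loop-based mismatch oracle: discordant homozygous / informative."""
    n_inf = n_disc = 0
    for s, g in zip(sample, accession):
        if s in (0, 1) and g in (0, 1):
            n_inf += 1
            if s != g:
                n_disc += 1
    return float("nan") if n_inf == 0 else n_disc / n_inf


def hudson_fst(g1: np.ndarray, g2: np.ndarray) -> float:
    """Hudson's Fst estimator (ratio of averages) for haploid 0/1 matrices."""
    n1, n2 = g1.shape[0], g2.shape[0]
    p1, p2 = g1.mean(axis=0), g2.mean(axis=0)
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    keep = den > 0
    return float(num[keep].sum() / den[keep].sum())
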