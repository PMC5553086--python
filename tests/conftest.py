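import numpy as np
import pytest

from wpair import simulate as sim
from wpair.tables import PairTable


def pearson_oracle(counts):
    """Brute-force double-loop Pearson X^2 = sum (O-E)^2 / E."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    x2 = 0.0
    for j in range(counts.shape[0]):
        for i in range(counts.shape[1]):
            e = counts[j].sum() * counts[:, i].sum() / n
            x2 += (counts[j, i] - e) ** 2 / e
    return x2


def null_common_table(seed, n_cases=500, n_controls=500):
    """One replicate table from the common-MAF null scenario."""
    from wpair.tables import build_table

    sc = sim.scenario_null_common(replicates=1, seed=seed).with_(
        n_cases=n_cases, n_controls=n_controls
    )
    g1, g2, ph = sim.sample_replicate(sc, 0)
    return build_table(g1, g2, ph)


def random_full_table(rng, n=400):
    """A 2 x 9 table with every cell positive (counts >= 1)."""
    base = np.ones((2, 9), dtype=np.int64)
    extra0 = rng.multinomial(n - 9, rng.dirichlet(np.ones(9)))
    extra1 = rng.multinomial(n - 9, rng.dirichlet(np.ones(9)))
    return PairTable(base + np.vstack([extra0, extra1]))


@pytest.fixture(scope="session")
def null_panel():
    """50 independent common-MAF SNPs, 500 cases + 500 controls, null."""
    from wpair.io import GenotypePanel

    rng = np.random.default_rng(424242)
    dosages = rng.binomial(2, 0.4, size=(1000, 50)).astype(float)
    phenotype = np.concatenate([np.ones(500), np.zeros(500)])
    return GenotypePanel(
        dosages=dosages,
        snp_ids=[f"snp{i:02d}" for i in range(50)],
        sample_ids=[f"id{i:04d}" for i in range(1000)],
        phenotype=phenotype,
    )
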