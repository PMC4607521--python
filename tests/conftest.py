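import numpy as np
import pandas as pd
import pytest

from afrostruct import simdata
from afrostruct.genio import GenotypeMatrix


@pytest.fixture(scope="session")
def default_sim():
    """Genotypes from the default six-component scenario (shared, read-only)."""
    scenario = simdata.default_scenario()
    freqs = simdata.draw_component_frequencies(scenario)
    G = simdata.simulate_genotypes(scenario, freqs)
    return scenario, freqs, G


def make_matrix(dosages, populations=None, chrom="1", seed_ids=0) -> GenotypeMatrix:
    """Small GenotypeMatrix around a raw dosage array."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    if populations is None:
        populations = ["pop1"] * n
    samples = pd.DataFrame(
        {
            "sample_id": [f"s{seed_ids}_{i}" for i in range(n)],
            "population": populations,
        }
    )
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "id": [f"v{j}" for j in range(m)],
            "pos": np.arange(1, m + 1) * 100,
            "allele1": "A",
            "allele2": "G",
        }
    )
    return GenotypeMatrix(dosages, samples, variants)


def two_pop_bn_sim(
    drift_a, drift_b, n_per_pop=50, n_snps=1747, seed=0, labels=("popA", "popB")
):
    """Two independent Balding-Nichols populations over shared ancestral freqs."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.05, 0.95, n_snps)
    dosa = []
    for drift in (drift_a, drift_b):
        pk = rng.beta(p * (1 - drift) / drift, (1 - p) * (1 - drift) / drift)
        dosa.append(rng.binomial(2, np.tile(pk, (n_per_pop, 1))))
    G = np.vstack(dosa)
    pops = [labels[0]] * n_per_pop + [labels[1]] * n_per_pop
    return make_matrix(G, pops, seed_ids=seed)
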