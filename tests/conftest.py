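import numpy as np
import pandas as pd
import pytest

from breedscan import GenotypePanel, SimConfig, simulate_panel


def build_panel(breed_genotypes, chrom="1", positions=None, start_pos=1000, spacing=1000):
    """Toy panel from {breed: genotype matrix (samples x snps)} mappings.

    Genotype entries are 0/1/2 or -1 (missing).  Positions default to an
    evenly spaced ladder on one chromosome.
    """
    blocks, sample_ids, breeds = [], [], []
    for breed, geno in breed_genotypes.items():
        geno = np.asarray(geno, dtype=np.int8)
        blocks.append(geno)
        sample_ids.extend(f"{breed}_{i + 1}" for i in range(geno.shape[0]))
        breeds.extend([breed] * geno.shape[0])
    matrix = np.vstack(blocks)
    n_snps = matrix.shape[1]
    if positions is None:
        positions = [start_pos + spacing * j for j in range(n_snps)]
    snp_map = pd.DataFrame(
        {
            "snp_id": [f"s{j + 1}" for j in range(n_snps)],
            "chrom": [chrom] * n_snps,
            "pos": positions,
            "allele_a": ["A"] * n_snps,
            "allele_b": ["C"] * n_snps,
        }
    )
    return GenotypePanel(matrix, sample_ids, breeds, snp_map)


@pytest.fixture(scope="session")
def default_sim():
    """One desk-scale simulated panel shared across tests (fixed seed)."""
    panel, truth = simulate_panel(SimConfig(seed=0))
    return panel, truth
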