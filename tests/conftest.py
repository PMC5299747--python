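import numpy as np
import pandas as pd
import pytest

from caniglobin.panel import GenotypePanel


def build_panel(genotypes, breeds, positions=None, chrom="chr1", haplotypes=None):
    """Panel from a (markers x samples) dosage array and per-sample breeds."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n_markers, n_samples = genotypes.shape
    if positions is None:
        positions = np.arange(1, n_markers + 1) * 1000
    markers = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "id": [f"snp{i}" for i in range(n_markers)],
            "allele_a": "A",
            "allele_b": "B",
        }
    )
    samples = pd.DataFrame(
        {"id": [f"s{j}" for j in range(n_samples)], "breed": breeds}
    )
    return GenotypePanel(markers, samples, genotypes, haplotypes=haplotypes)


@pytest.fixture
def two_breed_panel():
    """4 markers, 2 breeds x 4 dogs; marker 0 is a fixed difference."""
    geno = np.array(
        [
            [0, 0, 0, 0, 2, 2, 2, 2],  # fixed difference
            [0, 1, 1, 2, 0, 1, 1, 2],  # p = 0.5 in both breeds
            [0, 0, 0, 0, 0, 0, 0, 0],  # monomorphic (undefined F_ST)
            [1, 1, 0, 0, 2, 2, 1, 1],
        ],
        dtype=np.int8,
    )
    return build_panel(geno, ["x"] * 4 + ["y"] * 4)
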