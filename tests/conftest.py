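import numpy as np
import pytest

from vgrscan.genotype_io import GenotypeDataset, Marker, Sample


def make_dataset(geno, chroms=None, positions=None, pops=None):
    """Build a small GenotypeDataset from a dosage matrix (-1 = missing)."""
    geno = np.asarray(geno, dtype=np.int8)
    n, m = geno.shape
    chroms = chroms or ["1"] * m
    positions = positions or list(range(1000, 1000 + 1000 * m, 1000))
    pops = pops or ["A"] * (n // 2) + ["B"] * (n - n // 2)
    markers = [Marker(f"m{j}", str(chroms[j]), int(positions[j]), "A", "G")
               for j in range(m)]
    samples = [Sample(f"s{i}", pops[i]) for i in range(n)]
    return GenotypeDataset(markers=markers, samples=samples, genotypes=geno)


@pytest.fixture
def toy_dataset():
    rng = np.random.default_rng(5)
    geno = rng.integers(0, 3, size=(12, 8)).astype(np.int8)
    geno[0, 0] = -1
    return make_dataset(geno)
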