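import numpy as np
import pytest

from svepop.genio import GenotypeMatrix


def make_genotypes(dosage, pos_bp=None, chrom=None, sample_ids=None, locus_ids=None):
    """Build a GenotypeMatrix around a plain dosage array."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, L = dosage.shape
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    if locus_ids is None:
        locus_ids = [f"l{j}" for j in range(L)]
    if pos_bp is None:
        pos_bp = np.arange(1, L + 1) * 1000
    if chrom is None:
        chrom = ["1"] * L
    return GenotypeMatrix(
        sample_ids=np.array(sample_ids, dtype=object),
        locus_ids=np.array(locus_ids, dtype=object),
        chrom=np.array(chrom, dtype=object),
        pos_bp=np.asarray(pos_bp),
        alleles=np.array([("A", "B")] * L, dtype=object),
        dosage=dosage,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
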