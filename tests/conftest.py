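import numpy as np
import pytest

from methmediate.datasets import (
    GenotypeDataset,
    MethylationDataset,
    Phenotype,
    ProbeRecord,
    SNPRecord,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_genotypes(dosages, chrom="chr1", start_pos=1000):
    """Wrap a samples x SNPs array into a GenotypeDataset."""
    dosages = np.asarray(dosages, dtype=float)
    n, s = dosages.shape
    return GenotypeDataset(
        [f"S{i}" for i in range(n)],
        [SNPRecord(f"rs{j}", chrom, start_pos + j, "A", "G") for j in range(s)],
        dosages,
    )


def make_methylation(betas, chrom="chr2", start_pos=5000, contexts=None):
    betas = np.asarray(betas, dtype=float)
    n, p = betas.shape
    contexts = contexts or ["IGR"] * p
    return MethylationDataset(
        [f"S{i}" for i in range(n)],
        [
            ProbeRecord(f"cg{j}", chrom, start_pos + j, "", contexts[j])
            for j in range(p)
        ],
        betas,
    )


def make_phenotype(status):
    status = np.asarray(status, dtype=int)
    return Phenotype([f"S{i}" for i in range(status.size)], status)


@pytest.fixture
def balanced_88():
    """44 cases + 44 controls, genotype at HWE, null methylation."""
    gen = np.random.default_rng(7)
    dos = gen.binomial(2, 0.3, size=(88, 4)).astype(float)
    bet = np.clip(gen.normal(0.5, 0.05, size=(88, 3)), 0, 1)
    status = np.array([1] * 44 + [0] * 44)
    return make_genotypes(dos), make_methylation(bet), make_phenotype(status)
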