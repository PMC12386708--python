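import numpy as np
import pytest

from sraselect import GenotypeDataset, SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_sim():
    """Small breed-structured panel with planted signal, shared across tests."""
    cfg = SimConfig(
        n_per_class=[40, 40, 40], p_snps=300, n_signal=12,
        fst_signal=0.3, fst_background=0.01, block_size=10,
        haplotypes_per_block=100, seed=11,
    )
    return simulate_dataset(cfg)


def make_dataset(dosages, labels=None, pos=None, chrom=None, **kw):
    """Hand-rolled GenotypeDataset from a plain dosage matrix."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, p = dosages.shape
    return GenotypeDataset(
        dosages=dosages,
        snp_ids=np.array([f"s{j}" for j in range(p)]),
        chrom=np.full(p, "1") if chrom is None else np.asarray(chrom),
        pos=np.arange(1, p + 1) * 100 if pos is None else np.asarray(pos),
        sample_ids=np.array([f"i{i}" for i in range(n)]),
        labels=None if labels is None else np.asarray(labels),
        **kw,
    )
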