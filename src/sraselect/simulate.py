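"""Breed-structured genotype simulation with planted discriminative SNPs.

Population differentiation follows the Balding-Nichols model: per SNP an
ancestral frequency p is drawn, and each class (breed) draws its own
frequency from Beta(p(1-F)/F, (1-p)(1-F)/F). F is the fixation index Fst and
controls how far class frequencies wander from the ancestral value — the
variance of the class frequency is p(1-p)F. A small set of "signal" SNPs is
planted with a larger F, making them class-discriminative; everything else is
near-exchangeable background. Linkage disequilibrium is induced by drawing
each individual's two haplotypes per block from a finite per-class haplotype
pool: the smaller the pool, the stronger the within-block r².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import GenotypeDataset

__all__ = ["SimConfig", "SimTruth", "simulate_frequencies", "simulate_genotypes", "simulate_dataset"]


@dataclass
class SimConfig:
    """Configuration for the genotype simulator.

    Parameters
    ----------
    n_per_class : list of int
        Individuals per class; length B sets the number of classes.
    p_snps : int
        Total SNP count P.
    fst_background, fst_signal : float in (0, 1)
        Balding-Nichols differentiation for background and planted SNPs.
    n_signal : int
        Number of planted class-discriminative SNPs.
    block_size : int
        SNPs per LD block.
    haplotypes_per_block : int
        Per-class haplotype pool size per block; small pools give high r².
    """

    n_per_class: list[int] = field(default_factory=lambda: [100, 100, 100])
    p_snps: int = 3000
    fst_background: float = 0.01
    fst_signal: float = 0.25
    n_signal: int = 30
    block_size: int = 10
    haplotypes_per_block: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.fst_background < 1.0 or not 0.0 < self.fst_signal < 1.0:
            raise ValueError("Fst parameters must lie in (0, 1)")
        if self.fst_signal < self.fst_background:
            raise ValueError("fst_signal must be >= fst_background")
        if self.n_signal > self.p_snps:
            raise ValueError("n_signal cannot exceed p_snps")
        if self.block_size < 1 or self.haplotypes_per_block < 1:
            raise ValueError("block_size and haplotypes_per_block must be >= 1")

    @property
    def n_classes(self) -> int:
        return len(self.n_per_class)


@dataclass
class SimTruth:
    """Ground truth of a simulation: planted SNP ids and class frequencies."""

    signal_snp_ids: np.ndarray  # ids of planted discriminative SNPs
    signal_index: np.ndarray  # column indices of the planted SNPs
    class_freqs: np.ndarray  # B x P allele-frequency matrix
    ancestral_freqs: np.ndarray  # length-P ancestral frequencies


def _snp_ids(p: int) -> np.ndarray:
    return np.array([f"snp{j:06d}" for j in range(p)])


def simulate_frequencies(cfg: SimConfig) -> SimTruth:
    """Draw ancestral and per-class allele frequencies.

    Ancestral frequencies are uniform on [0.1, 0.9]; class frequencies follow
    Balding-Nichols with F = ``fst_background`` except at the ``n_signal``
    planted SNPs, which use ``fst_signal``. Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    p = cfg.p_snps
    b = cfg.n_classes
    ancestral = rng.uniform(0.1, 0.9, size=p)
    signal_index = np.sort(rng.choice(p, size=cfg.n_signal, replace=False))
    fst = np.full(p, cfg.fst_background)
    fst[signal_index] = cfg.fst_signal
    shape_a = ancestral * (1.0 - fst) / fst
    shape_b = (1.0 - ancestral) * (1.0 - fst) / fst
    class_freqs = rng.beta(shape_a, shape_b, size=(b, p))
    return SimTruth(
        signal_snp_ids=_snp_ids(p)[signal_index],
        signal_index=signal_index,
        class_freqs=class_freqs,
        ancestral_freqs=ancestral,
    )


def simulate_genotypes(truth: SimTruth, cfg: SimConfig) -> tuple[GenotypeDataset, SimTruth]:
    """Sample genotypes from class frequencies through per-block haplotype pools.

    For every class and LD block, ``haplotypes_per_block`` haplotypes are
    drawn site-wise Bernoulli(class frequency); each individual then draws two
    pool haplotypes (with replacement) per block and sums them into dosages.
    Blocks sit on one chromosome at 1 SNP / 100 bp with 10 kbp gaps, so each
    block spans well under 100 kbp.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    p, b = cfg.p_snps, cfg.n_classes
    n = int(np.sum(cfg.n_per_class))
    labels = np.concatenate(
        [np.full(m, f"class{c}") for c, m in enumerate(cfg.n_per_class)]
    )
    dosages = np.zeros((n, p), dtype=np.int8)
    block_starts = list(range(0, p, cfg.block_size))
    row0 = 0
    for c, m in enumerate(cfg.n_per_class):
        rows = slice(row0, row0 + m)
        for start in block_starts:
            stop = min(start + cfg.block_size, p)
            freqs = truth.class_freqs[c, start:stop]
            pool = (
                rng.random((cfg.haplotypes_per_block, stop - start)) < freqs
            ).astype(np.int8)
            draws = rng.integers(0, cfg.haplotypes_per_block, size=(m, 2))
            dosages[rows, start:stop] = pool[draws[:, 0]] + pool[draws[:, 1]]
        row0 += m
    # positions: 100 bp between SNPs inside a block, 10 kbp gap between blocks
    pos = np.empty(p, dtype=np.int64)
    cursor = 1
    for start in block_starts:
        stop = min(start + cfg.block_size, p)
        pos[start:stop] = cursor + 100 * np.arange(stop - start)
        cursor = pos[stop - 1] + 10_000
    ds = GenotypeDataset(
        dosages=dosages,
        snp_ids=_snp_ids(p),
        chrom=np.full(p, "1"),
        pos=pos,
        sample_ids=np.array([f"ind{i:05d}" for i in range(n)]),
        labels=labels,
    )
    return ds, truth


def simulate_dataset(cfg: SimConfig) -> tuple[GenotypeDataset, SimTruth]:
    """Convenience: frequencies + genotypes in one call."""
    truth = simulate_frequencies(cfg)
    return simulate_genotypes(truth, cfg)
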