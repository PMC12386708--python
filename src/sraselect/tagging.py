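"""LD-based tagSNP selection: pairwise genotype R² with greedy pruning.

LD between two SNPs is the squared Pearson correlation of their dosage
vectors (composite LD, so unphased genotypes work). Scanning each chromosome
in position order, a SNP becomes a tag unless it exceeds the R² threshold
with an already-retained tag within the comparison window upstream — one
representative per LD neighbourhood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster import FeatureSelectionResult
from .dataset import GenotypeDataset

__all__ = ["TagConfig", "genotype_r2", "select_tag_snps"]


@dataclass
class TagConfig:
    window_bp: int = 100_000
    step_bp: int = 1_000
    r2_max: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2_max <= 1.0:
            raise ValueError("r2_max must be in [0, 1]")
        if self.step_bp > self.window_bp:
            raise ValueError("step_bp must not exceed window_bp")


def genotype_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors; 0 if either is constant."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape:
        raise ValueError(f"length mismatch: {g1.shape} vs {g2.shape}")
    if len(g1) < 2:
        raise ValueError("need at least 2 individuals")
    d1 = g1 - g1.mean()
    d2 = g2 - g2.mean()
    v1 = d1 @ d1
    v2 = d2 @ d2
    if v1 == 0.0 or v2 == 0.0:
        return 0.0
    return float((d1 @ d2) ** 2 / (v1 * v2))


def select_tag_snps(
    ds: GenotypeDataset, cfg: TagConfig | None = None
) -> tuple[FeatureSelectionResult, pd.DataFrame]:
    """Greedy position-order tag selection per chromosome.

    A SNP is retained iff its r² with every already-retained tag within
    ``window_bp`` upstream is <= ``r2_max``. Returns the selection and a
    pruning manifest (pruned_id, tag_id, r2) certifying each removal.
    """
    cfg = cfg or TagConfig()
    if not ds.positions_sorted():
        raise ValueError("positions must be strictly increasing within chromosomes")
    dos = ds.dosages.astype(float)
    centered = dos - dos.mean(axis=0)
    ss = np.einsum("ij,ij->j", centered, centered)

    keep = np.zeros(ds.n_snps, dtype=bool)
    manifest_rows: list[tuple[str, str, float]] = []
    for c in pd.unique(ds.chrom):
        idx = np.flatnonzero(ds.chrom == c)
        tags: list[int] = []  # retained indices on this chromosome, ordered
        for j in idx:
            lo = ds.pos[j] - cfg.window_bp
            pruned_by = -1
            r2_hit = 0.0
            for t in reversed(tags):
                if ds.pos[t] < lo:
                    break
                if ss[j] == 0.0 or ss[t] == 0.0:
                    continue  # monomorphic: r2 defined as 0, never prunes
                r2 = (centered[:, j] @ centered[:, t]) ** 2 / (ss[j] * ss[t])
                if r2 > cfg.r2_max:
                    pruned_by = t
                    r2_hit = r2
                    break
            if pruned_by >= 0:
                manifest_rows.append(
                    (str(ds.snp_ids[j]), str(ds.snp_ids[pruned_by]), float(r2_hit))
                )
            else:
                keep[j] = True
                tags.append(j)
    manifest = pd.DataFrame(manifest_rows, columns=["pruned_id", "tag_id", "r2"])
    result = FeatureSelectionResult(
        relevant_ids=ds.snp_ids[keep],
        relevant_mask=keep,
        centroids=np.empty((0, 0)),
        method="tagging",
    )
    return result, manifest
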