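"""Two-cluster K-means thresholding of feature scores.

Both SRA variants avoid an arbitrary relevance cutoff by running 2-means on
the per-SNP scores and calling "relevant" the cluster whose centroid is
farther from the origin — absolute value in one dimension, Euclidean norm in
W dimensions. Ties on centroid norm go to the smaller cluster.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from sklearn.cluster import KMeans

__all__ = ["FeatureSelectionResult", "two_cluster_select"]


@dataclass
class FeatureSelectionResult:
    """Partition of SNPs into relevant / irrelevant with diagnostics."""

    relevant_ids: np.ndarray
    relevant_mask: np.ndarray  # boolean, length = number of scored SNPs
    centroids: np.ndarray  # 2 x D cluster centres
    method: str  # {"tagging", "1d_sra", "md_sra"}

    @property
    def n_relevant(self) -> int:
        return int(self.relevant_mask.sum())


def two_cluster_select(
    scores: np.ndarray,
    seed: int = 0,
    snp_ids: np.ndarray | None = None,
    method: str = "1d_sra",
) -> FeatureSelectionResult:
    """2-means on score vectors; relevant = larger-norm centroid.

    ``scores`` is (P,) for one-dimensional selection or (P, W) for
    multidimensional selection. Deterministic given ``seed`` (n_init=10).
    """
    v = np.asarray(scores, dtype=float)
    if v.ndim == 1:
        v = v[:, None]
    if not np.isfinite(v).all():
        raise ValueError("scores must be finite")
    if np.ptp(v, axis=0).max() == 0.0:
        raise ValueError("no separation: all score vectors identical")
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(v)
    norms = np.linalg.norm(km.cluster_centers_, axis=1)
    if np.isclose(norms[0], norms[1]):
        sizes = np.bincount(km.labels_, minlength=2)
        relevant_cluster = int(np.argmin(sizes))
        warnings.warn("centroid-norm tie: taking the smaller cluster as relevant")
    else:
        relevant_cluster = int(np.argmax(norms))
    mask = km.labels_ == relevant_cluster
    if snp_ids is None:
        snp_ids = np.arange(len(mask))
    return FeatureSelectionResult(
        relevant_ids=np.asarray(snp_ids)[mask],
        relevant_mask=mask,
        centroids=km.cluster_centers_,
        method=method,
    )
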