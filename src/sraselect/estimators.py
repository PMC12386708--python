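"""Scikit-learn estimator interfaces to the three feature-selection methods.

All three selectors implement fit(X, y) / transform(X) / get_support() and
compose with sklearn pipelines; the fitted relevance partition is exposed as
``support_`` plus method-specific diagnostics.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

from . import lmm as _lmm
from .cluster import FeatureSelectionResult, two_cluster_select
from .dataset import GenotypeDataset
from .reduced import fit_all_blocks, partition_features
from .tagging import TagConfig, select_tag_snps

__all__ = ["SRA1DSelector", "MDSRASelector", "LDTagger", "build_score_matrix"]


def _repeat_seed(master_seed: int, repeat: int) -> int:
    """Deterministic per-repeat seed below 2**31."""
    return int(np.random.SeedSequence([master_seed, repeat]).generate_state(1)[0] % (2**31))


class SRA1DSelector(SelectorMixin, BaseEstimator):
    """One-dimensional supervised rank aggregation (mixed-model BLUP route).

    Fits one reduced multinomial model per random SNP block, regresses the
    reciprocal training cross-entropies on the sparse feature-performance
    design with the ridge-like mixed model (known variances; shrinkage
    lambda = var_e / var_a), solves by Jacobi-PCG, and thresholds the SNP
    effect solutions by 1D 2-means.

    Attributes
    ----------
    support_ : bool array (P,)
        Relevant-SNP mask.
    a_hat_ : ndarray (P,)
        Mixed-model SNP effect solutions (0 for never-scored SNPs).
    mu_hat_, iterations_, final_residual_ : solver diagnostics.
    """

    def __init__(
        self,
        s: int = 250,
        ridge: float = 1e-2,
        var_a: float = _lmm.DEFAULT_VAR_A,
        var_e: float = _lmm.DEFAULT_VAR_E,
        tol: float = 1e-10,
        max_iter: int = 10_000,
        drop_remainder: bool = False,
        fp_mode: str = "abs_max",
        gtol: float = 1e-8,
        fit_max_iter: int = 1000,
        random_state: int = 0,
    ):
        self.s = s
        self.ridge = ridge
        self.var_a = var_a
        self.var_e = var_e
        self.tol = tol
        self.max_iter = max_iter
        self.drop_remainder = drop_remainder
        self.fp_mode = fp_mode
        self.gtol = gtol
        self.fit_max_iter = fit_max_iter
        self.random_state = random_state

    def fit(self, X, y):
        ds = _as_dataset(X, y)
        part = partition_features(
            ds.n_snps, self.s, seed=_repeat_seed(self.random_state, 0),
            drop_remainder=self.drop_remainder,
        )
        self.performance_matrix_ = fit_all_blocks(
            ds, part, ridge=self.ridge, fp_mode=self.fp_mode,
            gtol=self.gtol, max_iter=self.fit_max_iter,
        )
        system = _lmm.assemble_lmm(self.performance_matrix_, self.var_a, self.var_e)
        sol = _lmm.solve_pcg(system, tol=self.tol, max_iter=self.max_iter)
        self.a_hat_ = sol.a_hat
        self.mu_hat_ = sol.mu_hat
        self.iterations_ = sol.iterations
        self.final_residual_ = sol.final_residual
        result = two_cluster_select(
            self.a_hat_, seed=self.random_state, snp_ids=ds.snp_ids, method="1d_sra"
        )
        self.result_ = result
        self.support_ = result.relevant_mask
        self.centroids_ = result.centroids
        self.n_features_in_ = ds.n_snps
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.target_tags.required = True
        return tags


def build_score_matrix(
    ds: GenotypeDataset,
    w_repeats: int = 5,
    s: int = 250,
    master_seed: int = 0,
    ridge: float = 1e-2,
    drop_remainder: bool = False,
    fp_mode: str = "abs_max",
    gtol: float = 1e-8,
    fit_max_iter: int = 1000,
) -> np.ndarray:
    """P x W dense score matrix V from W independent block partitions.

    Column w collapses repeat w's sparse performance matrix: each SNP's FP
    from its unique reduced model, weighted by the reciprocal of that model's
    cross-entropy. SNPs never sampled in a repeat (remainder-dropping) score 0.
    """
    if w_repeats < 1:
        raise ValueError("w_repeats must be >= 1")
    cols = []
    for w in range(w_repeats):
        part = partition_features(
            ds.n_snps, s, seed=_repeat_seed(master_seed, w + 1),
            drop_remainder=drop_remainder,
        )
        c = fit_all_blocks(
            ds, part, ridge=ridge, fp_mode=fp_mode, gtol=gtol, max_iter=fit_max_iter
        )
        cols.append(c.collapse(weight_by_inverse_ce=True))
    return np.column_stack(cols)


class MDSRASelector(SelectorMixin, BaseEstimator):
    """Multidimensional supervised rank aggregation (weighted W-D 2-means).

    Replaces the 1D route's mixed-model solve with direct clustering: W
    independent repeats of the reduced-model stage give a P x W score matrix
    (FPs weighted by reciprocal cross-entropy), and 2-means on its rows with
    the centroid L2-norm rule yields the relevant cluster.
    """

    def __init__(
        self,
        w: int = 5,
        s: int = 250,
        ridge: float = 1e-2,
        drop_remainder: bool = False,
        standardize: bool = False,
        fp_mode: str = "abs_max",
        gtol: float = 1e-8,
        fit_max_iter: int = 1000,
        random_state: int = 0,
    ):
        self.w = w
        self.s = s
        self.ridge = ridge
        self.drop_remainder = drop_remainder
        self.standardize = standardize
        self.fp_mode = fp_mode
        self.gtol = gtol
        self.fit_max_iter = fit_max_iter
        self.random_state = random_state

    def fit(self, X, y):
        ds = _as_dataset(X, y)
        v = build_score_matrix(
            ds, w_repeats=self.w, s=self.s, master_seed=self.random_state,
            ridge=self.ridge, drop_remainder=self.drop_remainder,
            fp_mode=self.fp_mode, gtol=self.gtol, fit_max_iter=self.fit_max_iter,
        )
        self.score_matrix_ = v
        if self.standardize:
            sd = v.std(axis=0)
            v = v / np.where(sd > 0, sd, 1.0)
        result = two_cluster_select(
            v, seed=self.random_state, snp_ids=ds.snp_ids, method="md_sra"
        )
        self.result_ = result
        self.support_ = result.relevant_mask
        self.centroids_ = result.centroids
        self.n_features_in_ = ds.n_snps
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.target_tags.required = True
        return tags


class LDTagger(SelectorMixin, BaseEstimator):
    """Greedy tagSNP pruning on pairwise genotype R² within genomic windows.

    Unsupervised: ``y`` is ignored. Chromosome labels and positions may be
    passed to ``fit``; absent coordinates default to one chromosome with SNPs
    100 bp apart.
    """

    def __init__(self, window_bp: int = 100_000, step_bp: int = 1_000, r2_max: float = 0.5):
        self.window_bp = window_bp
        self.step_bp = step_bp
        self.r2_max = r2_max

    def fit(self, X, y=None, chrom=None, pos=None):
        ds = _as_dataset(X, y, chrom=chrom, pos=pos, require_labels=False)
        cfg = TagConfig(window_bp=self.window_bp, step_bp=self.step_bp, r2_max=self.r2_max)
        result, manifest = select_tag_snps(ds, cfg)
        self.result_ = result
        self.support_ = result.relevant_mask
        self.manifest_ = manifest
        self.n_features_in_ = ds.n_snps
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


def _as_dataset(X, y, chrom=None, pos=None, require_labels=True) -> GenotypeDataset:
    """Accept either a GenotypeDataset or a plain (X, y) dosage matrix."""
    if isinstance(X, GenotypeDataset):
        if y is not None:
            import dataclasses

            X = dataclasses.replace(X, labels=np.asarray(y))
        if require_labels and X.labels is None:
            raise ValueError("labels are required")
        return X
    X = np.asarray(X)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional (individuals x SNPs)")
    n, p = X.shape
    if require_labels and y is None:
        raise ValueError("y is required")
    return GenotypeDataset(
        dosages=X.astype(np.int8),
        snp_ids=np.array([f"snp{j:06d}" for j in range(p)]),
        chrom=np.full(p, "1") if chrom is None else np.asarray(chrom),
        pos=(np.arange(p, dtype=np.int64) * 100 + 1) if pos is None else np.asarray(pos),
        sample_ids=np.array([f"ind{i:05d}" for i in range(n)]),
        labels=None if y is None else np.asarray(y),
    )
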