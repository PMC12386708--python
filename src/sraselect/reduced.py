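"""Reduced multinomial models and the sparse model-performance matrix.

The supervised-rank-aggregation pipeline scores every SNP by fitting many
small ("reduced") multinomial logistic regressions: the P SNPs are shuffled
and cut into K blocks of S, one model is fitted per block, and each SNP's
feature performance (FP) is taken from its coefficients in the one model that
contains it. Each model's fit quality is its training cross-entropy. The K
rows of (block indices, FPs, cross-entropy) form the sparse performance
matrix C with O(K*S) storage — never O(K*P).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize
import scipy.sparse as sp

from .dataset import GenotypeDataset
from .metrics import cross_entropy

__all__ = [
    "BlockPartition",
    "partition_features",
    "MultinomialLogit",
    "ReducedModelFit",
    "fit_block_model",
    "PerformanceMatrix",
    "build_performance_matrix",
    "fit_all_blocks",
]


class ConvergenceError(RuntimeError):
    pass


@dataclass
class BlockPartition:
    """Disjoint SNP-index blocks from one shuffled pass over 1..P."""

    blocks: list[np.ndarray]
    p_total: int
    seed: int

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)


def partition_features(
    p_total: int, s: int, seed: int, drop_remainder: bool = False
) -> BlockPartition:
    """Shuffle feature indices and cut them into consecutive blocks of size s.

    With ``drop_remainder`` the incomplete tail block is discarded, giving
    K = floor(p_total / s) blocks; otherwise the tail forms a final smaller
    block so every feature is scored.
    """
    if not 1 <= s <= p_total:
        raise ValueError(f"block size s={s} must satisfy 1 <= s <= P={p_total}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(p_total)
    k_full = p_total // s
    blocks = [order[i * s : (i + 1) * s] for i in range(k_full)]
    if not drop_remainder and p_total % s:
        blocks.append(order[k_full * s :])
    return BlockPartition(blocks=blocks, p_total=p_total, seed=seed)


class MultinomialLogit:
    """Reference-class multinomial logistic regression.

    Models log(P_b / P_ref) = alpha_b + beta_b . x for each non-reference
    class b, with the reference class fixed to the lexicographically last
    label. A small ridge penalty on the slopes keeps the fit identifiable
    under separation; the reported cross-entropy excludes the penalty.
    """

    def __init__(self, ridge: float = 1e-2, gtol: float = 1e-8, max_iter: int = 1000):
        self.ridge = ridge
        self.gtol = gtol
        self.max_iter = max_iter

    def fit(self, x: np.ndarray, y: np.ndarray) -> "MultinomialLogit":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y)
        n, s = x.shape
        self.classes_ = np.unique(y)
        b = len(self.classes_)
        if b < 2:
            raise ValueError("need at least 2 classes")
        # reference = last class in sorted order; one-hot over non-ref classes
        y_idx = np.searchsorted(self.classes_, y)
        y_onehot = np.zeros((n, b - 1))
        nonref = y_idx < b - 1
        y_onehot[np.flatnonzero(nonref), y_idx[nonref]] = 1.0

        xa = np.hstack([np.ones((n, 1)), x])  # intercept column first
        ridge_mask = np.ones((b - 1, s + 1))
        ridge_mask[:, 0] = 0.0  # no penalty on intercepts

        def probs_nonref(theta: np.ndarray) -> np.ndarray:
            z = xa @ theta.T  # (n, b-1) non-reference logits; ref logit = 0
            m = np.maximum(z.max(axis=1, keepdims=True), 0.0)
            ez = np.exp(z - m)
            denom = np.exp(-m) + ez.sum(axis=1, keepdims=True)
            return ez / denom

        def objective(flat: np.ndarray):
            theta = flat.reshape(b - 1, s + 1)
            p = probs_nonref(theta)
            p_ref = np.clip(1.0 - p.sum(axis=1), 1e-15, None)
            p_true = np.where(nonref, p[np.arange(n), np.minimum(y_idx, b - 2)], p_ref)
            nll = -np.mean(np.log(np.clip(p_true, 1e-15, None)))
            pen = 0.5 * self.ridge * np.sum((theta * ridge_mask) ** 2)
            grad = (p - y_onehot).T @ xa / n + self.ridge * theta * ridge_mask
            return nll + pen, grad.ravel()

        theta0 = np.zeros((b - 1) * (s + 1))
        res = scipy.optimize.minimize(
            objective,
            theta0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": self.max_iter, "gtol": self.gtol,
                     "ftol": 1e-14, "maxfun": 10 * self.max_iter},
        )
        # Near-separable blocks under the tiny ridge flatten the objective and
        # stall L-BFGS slightly above gtol; such solutions are numerically at
        # the optimum for ranking purposes, so only a genuinely large final
        # gradient is treated as failure.
        grad_norm = float(np.max(np.abs(res.jac)))
        if grad_norm > max(self.gtol, 1e-4):
            raise ConvergenceError(
                f"multinomial fit did not converge: |grad|={grad_norm:.2e} "
                f"after {res.nit} iterations"
            )
        theta = res.x.reshape(b - 1, s + 1)
        self.alpha_ = theta[:, 0].copy()
        self.beta_ = theta[:, 1:].copy()
        self.n_iter_ = res.nit
        return self

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        z = x @ self.beta_.T + self.alpha_  # non-reference logits
        z_full = np.hstack([z, np.zeros((x.shape[0], 1))])
        z_full -= z_full.max(axis=1, keepdims=True)
        ez = np.exp(z_full)
        return ez / ez.sum(axis=1, keepdims=True)


@dataclass
class ReducedModelFit:
    """One fitted block: coefficients, training cross-entropy, FP per SNP."""

    block_index: int
    snp_index: np.ndarray  # global column indices of this block's SNPs
    alpha_hat: np.ndarray  # (B-1,) intercepts vs the reference class
    beta_hat: np.ndarray  # (B-1, S) slopes
    ce_loss: float
    feature_performance: np.ndarray  # (S,) FP per SNP


def feature_performance_from_beta(beta: np.ndarray, mode: str = "signed_max") -> np.ndarray:
    """Collapse the (B-1) x S coefficient matrix to one FP per SNP.

    ``signed_max`` takes the plain maximum over class rows; ``abs_max`` takes
    the magnitude of the largest-|.| coefficient, so strong negative effects
    are not discarded.
    """
    if mode == "signed_max":
        return beta.max(axis=0)
    if mode == "abs_max":
        return np.abs(beta).max(axis=0)
    raise ValueError(f"unknown feature-performance mode {mode!r}")


def fit_block_model(
    ds: GenotypeDataset,
    block: np.ndarray,
    ridge: float = 1e-2,
    block_index: int = 0,
    fp_mode: str = "abs_max",
    gtol: float = 1e-8,
    max_iter: int = 1000,
) -> ReducedModelFit:
    """Fit the reduced multinomial model for one SNP block.

    The cross-entropy is evaluated on the same training individuals (model
    fit, not prediction quality — by design) and excludes the ridge penalty.
    """
    if ds.labels is None:
        raise ValueError("labels are required to fit reduced models")
    block = np.asarray(block)
    x = ds.dosages[:, block].astype(float)
    try:
        model = MultinomialLogit(ridge=ridge, gtol=gtol, max_iter=max_iter).fit(
            x, ds.labels
        )
    except ConvergenceError as err:
        raise ConvergenceError(f"block {block_index}: {err}") from err
    probs = model.predict_proba(x)
    ce = cross_entropy(ds.labels, probs, classes=model.classes_)
    fp = feature_performance_from_beta(model.beta_, mode=fp_mode)
    return ReducedModelFit(
        block_index=block_index,
        snp_index=block,
        alpha_hat=model.alpha_,
        beta_hat=model.beta_,
        ce_loss=ce,
        feature_performance=fp,
    )


@dataclass
class PerformanceMatrix:
    """Sparse K x (P+1) model-performance matrix C.

    Row k stores the SNP indices of block k, their feature performances, and
    the block model's cross-entropy (conceptually column P+1). FPs of SNPs
    outside a row's block are implicitly zero. Storage is O(K*S).
    """

    row_snp_indices: list[np.ndarray]
    row_fp_values: list[np.ndarray]
    ce_loss: np.ndarray
    p_total: int

    @property
    def n_rows(self) -> int:
        return len(self.row_snp_indices)

    def z_matrix(self) -> sp.csr_matrix:
        """First P columns of C as a sparse CSR matrix (the LMM design Z)."""
        indptr = np.cumsum([0] + [len(ix) for ix in self.row_snp_indices])
        indices = (
            np.concatenate(self.row_snp_indices)
            if self.row_snp_indices
            else np.empty(0, dtype=int)
        )
        data = (
            np.concatenate(self.row_fp_values)
            if self.row_fp_values
            else np.empty(0)
        )
        return sp.csr_matrix(
            (data, indices, indptr), shape=(self.n_rows, self.p_total)
        )

    def to_dense(self) -> np.ndarray:
        """Densified K x (P+1) matrix — only for small test instances."""
        c = np.zeros((self.n_rows, self.p_total + 1))
        c[:, : self.p_total] = self.z_matrix().toarray()
        c[:, self.p_total] = self.ce_loss
        return c

    def collapse(self, weight_by_inverse_ce: bool = True) -> np.ndarray:
        """Collapse K rows into one dense length-P vector.

        Each SNP occurs in at most one row, so the collapse is a plain
        scatter; with weighting, each FP is multiplied by 1/cross-entropy of
        its model. Never-scored SNPs stay 0.
        """
        v = np.zeros(self.p_total)
        for ix, fp, ce in zip(self.row_snp_indices, self.row_fp_values, self.ce_loss):
            v[ix] = fp / ce if weight_by_inverse_ce else fp
        return v

    def save(self, path: str) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.attrs["p_total"] = self.p_total
            fh.create_dataset("ce_loss", data=self.ce_loss)
            lengths = np.array([len(ix) for ix in self.row_snp_indices])
            fh.create_dataset("row_lengths", data=lengths)
            fh.create_dataset(
                "snp_indices",
                data=np.concatenate(self.row_snp_indices)
                if self.row_snp_indices
                else np.empty(0, dtype=int),
            )
            fh.create_dataset(
                "fp_values",
                data=np.concatenate(self.row_fp_values)
                if self.row_fp_values
                else np.empty(0),
            )

    @classmethod
    def load(cls, path: str) -> "PerformanceMatrix":
        import h5py

        with h5py.File(path, "r") as fh:
            p_total = int(fh.attrs["p_total"])
            ce = fh["ce_loss"][:]
            lengths = fh["row_lengths"][:]
            splits = np.cumsum(lengths)[:-1]
            snp_indices = np.split(fh["snp_indices"][:], splits)
            fp_values = np.split(fh["fp_values"][:], splits)
        return cls(
            row_snp_indices=list(snp_indices),
            row_fp_values=list(fp_values),
            ce_loss=ce,
            p_total=p_total,
        )


def build_performance_matrix(
    fits: list[ReducedModelFit], partition: BlockPartition
) -> PerformanceMatrix:
    """Assemble fitted blocks into the sparse performance matrix C."""
    seen = set()
    for fit in fits:
        if fit.block_index in seen:
            raise ValueError(f"duplicate block index {fit.block_index}")
        seen.add(fit.block_index)
    order = sorted(fits, key=lambda f: f.block_index)
    return PerformanceMatrix(
        row_snp_indices=[f.snp_index for f in order],
        row_fp_values=[f.feature_performance for f in order],
        ce_loss=np.array([f.ce_loss for f in order]),
        p_total=partition.p_total,
    )


def fit_all_blocks(
    ds: GenotypeDataset,
    partition: BlockPartition,
    ridge: float = 1e-2,
    fp_mode: str = "abs_max",
    gtol: float = 1e-8,
    max_iter: int = 1000,
) -> PerformanceMatrix:
    """Fit every block of a partition and assemble C."""
    fits = [
        fit_block_model(
            ds, block, ridge=ridge, block_index=k, fp_mode=fp_mode,
            gtol=gtol, max_iter=max_iter,
        )
        for k, block in enumerate(partition.blocks)
    ]
    return build_performance_matrix(fits, partition)
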