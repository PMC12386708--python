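"""Reproducible synthetic benchmarks for the selection and classification stack.

These routines define the package's standard evaluation conditions on
simulated breed-structured data: a planted-SNP recovery benchmark for the two
supervised-rank-aggregation selectors (with a size-matched random panel as
baseline), and an easy, clearly separable classification task for the CNN.

The problem sizes (N = 300 individuals in 3 classes, P = 3,000 SNPs, 30
planted signal SNPs at Fst 0.25 over a 0.01 background, reduced-model size
S = 50, W = 5 repeats) keep a full multi-seed run on one CPU in minutes while
leaving the planted signal recoverable. The CNN uses the scaled-down profile
(one conv block, kernel 21, Adam at 1e-3) appropriate for panels of a few
hundred SNPs; see the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import apply_qc
from .estimators import MDSRASelector, SRA1DSelector
from .evaluate import train_cv
from .nn import FocalCNNClassifier
from .simulate import SimConfig, simulate_dataset

__all__ = [
    "RECOVERY_SIM",
    "scaled_cnn",
    "recovery_run",
    "recovery_benchmark",
    "easy_task_benchmark",
]

# Study conditions of the planted-SNP recovery benchmark.
RECOVERY_SIM = dict(
    n_per_class=[100, 100, 100],
    p_snps=3000,
    n_signal=30,
    fst_signal=0.25,
    fst_background=0.01,
)
RECOVERY_S = 50
RECOVERY_W = 5


def scaled_cnn(seed: int, epochs: int = 40) -> FocalCNNClassifier:
    """CNN profile for few-hundred-SNP synthetic panels."""
    return FocalCNNClassifier(
        n_conv_blocks=1,
        kernel_size=21,
        learning_rate=1e-3,
        epochs=epochs,
        random_state=seed,
    )


@dataclass
class RecoveryRun:
    """Per-seed result of the recovery benchmark."""

    seed: int
    n_snps: int
    n_signal_present: int
    recall_1d: float
    recall_md: float
    n_relevant_1d: int
    n_relevant_md: int
    f1_1d: float | None = None
    f1_md: float | None = None
    f1_random: float | None = None


def _recall(mask: np.ndarray, sig: np.ndarray) -> float:
    return float(mask[sig].sum() / sig.sum())


def recovery_run(
    seed: int,
    downstream: bool = True,
    n_folds: int = 3,
    epochs: int = 40,
) -> RecoveryRun:
    """One seed of the recovery benchmark.

    Simulates, applies QC, runs both SRA selectors (S=50, W=5), and — when
    ``downstream`` — cross-validates the scaled CNN on each selected panel
    and on a size-matched random SNP panel.
    """
    cfg = SimConfig(seed=seed, **RECOVERY_SIM)
    ds, truth = simulate_dataset(cfg)
    ds = apply_qc(ds)
    sig = np.isin(ds.snp_ids, truth.signal_snp_ids)

    sel1 = SRA1DSelector(s=RECOVERY_S, random_state=seed).fit(ds, ds.labels)
    selm = MDSRASelector(w=RECOVERY_W, s=RECOVERY_S, random_state=seed).fit(
        ds, ds.labels
    )
    run = RecoveryRun(
        seed=seed,
        n_snps=ds.n_snps,
        n_signal_present=int(sig.sum()),
        recall_1d=_recall(sel1.support_, sig),
        recall_md=_recall(selm.support_, sig),
        n_relevant_1d=int(sel1.support_.sum()),
        n_relevant_md=int(selm.support_.sum()),
    )
    if downstream:
        X = ds.dosages.astype(float)
        y = ds.labels
        rng = np.random.default_rng(seed)
        random_panel = rng.choice(ds.n_snps, size=int(sel1.support_.sum()), replace=False)
        for name, cols in (
            ("f1_1d", np.flatnonzero(sel1.support_)),
            ("f1_md", np.flatnonzero(selm.support_)),
            ("f1_random", random_panel),
        ):
            rep = train_cv(
                X[:, cols], y, classifier=scaled_cnn(seed, epochs=epochs),
                n_folds=n_folds, seed=seed,
            )
            setattr(run, name, rep.macro_f1)
    return run


def recovery_benchmark(
    seeds, downstream: bool = True, n_folds: int = 3, epochs: int = 40
) -> list[RecoveryRun]:
    """Run the recovery benchmark over several simulation seeds."""
    return [
        recovery_run(s, downstream=downstream, n_folds=n_folds, epochs=epochs)
        for s in seeds
    ]


def easy_task_benchmark(
    seed: int, permuted: bool = False, n_folds: int = 5, epochs: int = 60
):
    """Clearly separable task: CNN on the 60 planted SNPs of an Fst-0.3 panel.

    With ``permuted`` the labels are shuffled, which should drop macro F1 to
    the 100/B % chance level.
    """
    cfg = SimConfig(
        n_per_class=[100, 100, 100], p_snps=500, n_signal=60,
        fst_signal=0.30, fst_background=0.01, seed=seed,
    )
    ds, truth = simulate_dataset(cfg)
    ds = apply_qc(ds)
    sig = np.isin(ds.snp_ids, truth.signal_snp_ids)
    X = ds.dosages[:, sig].astype(float)
    y = ds.labels
    if permuted:
        y = np.random.default_rng(seed).permutation(y)
    return train_cv(
        X, y, classifier=scaled_cnn(seed, epochs=epochs), n_folds=n_folds, seed=seed
    )
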