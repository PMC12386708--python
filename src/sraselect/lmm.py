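"""Mixed-linear-model aggregation of reduced-model scores, solved by PCG.

The aggregation model is  y = mu*1 + Z a + e,  where y holds the reciprocal
training cross-entropy of each reduced model, Z is the sparse K x P matrix of
feature performances, a ~ N(0, I*var_a) are random SNP effects and
e ~ N(0, I*var_e). With both variances treated as known, the BLUP solutions
come from the mixed model equations

    [ 1'1   1'Z        ] [mu]   [1'y]
    [ Z'1   Z'Z + λI   ] [a ] = [Z'y],        λ = var_e / var_a.

The system is solved matrix-free by preconditioned conjugate gradients with a
Jacobi (diagonal) preconditioner; Z'Z is never materialised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .reduced import PerformanceMatrix

__all__ = ["LmmSystem", "LmmSolution", "assemble_lmm", "solve_pcg"]

# Variances used in the source analysis, treated as known (never estimated):
# var_a = 6.5e-5, var_e = 1.5e-4, hence lambda ~ 2.3077.
DEFAULT_VAR_A = 6.5e-5
DEFAULT_VAR_E = 1.5e-4


@dataclass
class LmmSystem:
    y: np.ndarray  # K reciprocal cross-entropies
    z: sp.csr_matrix  # K x P sparse feature-performance design
    var_a: float
    var_e: float

    @property
    def lam(self) -> float:
        return self.var_e / self.var_a


@dataclass
class LmmSolution:
    mu_hat: float
    a_hat: np.ndarray
    iterations: int
    final_residual: float  # relative residual ||r|| / ||rhs||


def assemble_lmm(
    c: PerformanceMatrix,
    var_a: float = DEFAULT_VAR_A,
    var_e: float = DEFAULT_VAR_E,
) -> LmmSystem:
    """Build the LMM system: y_k = 1 / cross-entropy_k, Z from C's FP entries."""
    if (c.ce_loss <= 1e-12).any():
        raise ValueError("degenerate model fit: cross-entropy <= 1e-12")
    if var_a <= 0 or var_e <= 0:
        raise ValueError("variances must be positive")
    return LmmSystem(y=1.0 / c.ce_loss, z=c.z_matrix(), var_a=var_a, var_e=var_e)


def solve_pcg(
    system: LmmSystem,
    tol: float = 1e-10,
    max_iter: int = 10_000,
    fit_intercept: bool = True,
) -> LmmSolution:
    """Solve the mixed model equations by Jacobi-preconditioned CG.

    Stops when the relative residual ||r|| / ||rhs|| drops to ``tol``; raises
    if ``max_iter`` sweeps do not get there. Only matrix-vector products with
    the sparse Z (and its transpose) are used.
    """
    lam = system.lam
    if lam <= 0:
        raise ValueError("lambda = var_e / var_a must be positive")
    z = system.z
    y = np.asarray(system.y, dtype=float)
    k, p = z.shape
    zt = z.T.tocsr()
    col_sq = np.asarray(z.multiply(z).sum(axis=0)).ravel()  # diag of Z'Z

    if fit_intercept:
        rhs = np.concatenate([[y.sum()], zt @ y])
        diag = np.concatenate([[float(k)], col_sq + lam])

        def matvec(v: np.ndarray) -> np.ndarray:
            mu, a = v[0], v[1:]
            u = z @ a
            return np.concatenate(
                [[k * mu + u.sum()], zt @ (u + mu) + lam * a]
            )

    else:
        rhs = zt @ y
        diag = col_sq + lam

        def matvec(a: np.ndarray) -> np.ndarray:
            return zt @ (z @ a) + lam * a

    rhs_norm = np.linalg.norm(rhs)
    if rhs_norm == 0.0:
        sol = np.zeros_like(rhs)
        return _pack(sol, 0, 0.0, fit_intercept)
    diag = np.where(diag > 0, diag, 1.0)

    x = np.zeros_like(rhs)
    r = rhs.copy()
    s = r / diag
    d = s.copy()
    rs = r @ s
    for it in range(1, max_iter + 1):
        ad = matvec(d)
        alpha = rs / (d @ ad)
        x += alpha * d
        r -= alpha * ad
        rel = np.linalg.norm(r) / rhs_norm
        if rel <= tol:
            return _pack(x, it, rel, fit_intercept)
        s = r / diag
        rs_new = r @ s
        d = s + (rs_new / rs) * d
        rs = rs_new
    raise RuntimeError(
        f"PCG did not converge in {max_iter} iterations "
        f"(relative residual {rel:.3e})"
    )


def _pack(x: np.ndarray, iterations: int, residual: float, fit_intercept: bool):
    if fit_intercept:
        return LmmSolution(
            mu_hat=float(x[0]), a_hat=x[1:], iterations=iterations,
            final_residual=residual,
        )
    return LmmSolution(
        mu_hat=0.0, a_hat=x, iterations=iterations, final_residual=residual
    )
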