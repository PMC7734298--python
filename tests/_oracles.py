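"""Independent reference implementations used only as test oracles.

Everything here is deliberately written from the definitions (explicit loops,
normal equations, textbook coordinate descent) and shares no code with the
package's implementation paths.
"""

from __future__ import annotations

import numpy as np


def unfold_by_fibers(t: np.ndarray, mode: int) -> np.ndarray:
    """Mode-``mode`` unfolding built fiber by fiber with explicit loops.

    Column ordering: the remaining modes keep their original order with the
    last one varying fastest (the package's documented convention).
    """
    I = t.shape
    others = [m for m in (0, 1, 2) if m != mode - 1]
    cols = []
    for a in range(I[others[0]]):
        for b in range(I[others[1]]):
            index = [0, 0, 0]
            index[others[0]], index[others[1]] = a, b
            fiber = np.empty(I[mode - 1])
            for i in range(I[mode - 1]):
                index[mode - 1] = i
                fiber[i] = t[tuple(index)]
            cols.append(fiber)
    return np.column_stack(cols)


def mode_product_by_sum(t: np.ndarray, X: np.ndarray, mode: int) -> np.ndarray:
    """Mode product computed entry-wise from the defining sum."""
    shape = list(t.shape)
    shape[mode - 1] = X.shape[0]
    out = np.zeros(shape)
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                idx = (i, j, k)
                acc = 0.0
                for l in range(t.shape[mode - 1]):
                    src = list(idx)
                    src[mode - 1] = l
                    acc += X[idx[mode - 1], l] * t[tuple(src)]
                out[idx] = acc
    return out


def hosvd_by_unfoldings(t: np.ndarray):
    """HOSVD assembled from dense SVDs of explicitly constructed unfoldings.

    Applies the same deterministic sign convention as the package (largest-
    magnitude entry of each singular vector positive) so factors are directly
    comparable away from degeneracies.  Returns (factors, singular_values,
    core).
    """
    factors, svals = [], []
    for mode in (1, 2, 3):
        M = unfold_by_fibers(t, mode)
        U, s, _ = np.linalg.svd(M, full_matrices=True)
        for j in range(U.shape[1]):
            i_star = int(np.argmax(np.abs(U[:, j])))
            if U[i_star, j] < 0:
                U[:, j] = -U[:, j]
        factors.append(U)
        padded = np.zeros(t.shape[mode - 1])
        padded[: s.size] = s
        svals.append(padded)
    core = np.einsum("abc,ai,bj,ck->ijk", t, factors[0], factors[1], factors[2])
    return factors, svals, core


def least_squares_by_normal_equations(slices: np.ndarray, Z: np.ndarray):
    """Solve min ||Z - sum_k lam_k slices[:,:,k]|| via explicit normal equations.

    Returns (residual_norm, lam).  Uses a pseudo-inverse so rank-deficient
    designs give the minimum-norm solution.
    """
    k3 = slices.shape[2]
    D = np.column_stack([slices[:, :, k].ravel() for k in range(k3)])
    lam = np.linalg.pinv(D.T @ D) @ (D.T @ Z.ravel())
    r = np.linalg.norm(Z.ravel() - D @ lam)
    return r, lam


def glasso_coordinate_descent(
    S: np.ndarray, lam: float, tol: float = 1e-12, max_iter: int = 5000
) -> np.ndarray:
    """Textbook block coordinate-descent graphical lasso (no diagonal penalty).

    Maximizes log det(Theta) - tr(S Theta) - lam * sum_{i!=j} |Theta_ij|.
    Intended for small p only; iterates to a much tighter tolerance than
    production solvers need.
    """
    p = S.shape[0]
    W = S.copy()
    beta_all = np.zeros((p, p))
    for _ in range(max_iter):
        W_old = W.copy()
        for j in range(p):
            idx = [i for i in range(p) if i != j]
            W11 = W[np.ix_(idx, idx)]
            s12 = S[idx, j]
            beta = beta_all[idx, j].copy()
            for _ in range(500):
                b_old = beta.copy()
                for k in range(p - 1):
                    r = s12[k] - W11[k] @ beta + W11[k, k] * beta[k]
                    beta[k] = np.sign(r) * max(abs(r) - lam, 0.0) / W11[k, k]
                if np.max(np.abs(beta - b_old)) < 1e-13:
                    break
            W[idx, j] = W[j, idx] = W11 @ beta
            beta_all[idx, j] = beta
        if np.max(np.abs(W - W_old)) < tol:
            break
    Theta = np.zeros((p, p))
    for j in range(p):
        idx = [i for i in range(p) if i != j]
        beta = beta_all[idx, j]
        theta_jj = 1.0 / (W[j, j] - W[idx, j] @ beta)
        Theta[j, j] = theta_jj
        Theta[idx, j] = -beta * theta_jj
    return (Theta + Theta.T) / 2


def glasso_objective(Theta: np.ndarray, S: np.ndarray, lam: float) -> float:
    """Penalized log-likelihood objective of the graphical lasso."""
    sign, logdet = np.linalg.slogdet(Theta)
    if sign <= 0:
        return -np.inf
    off = np.abs(Theta).sum() - np.trace(np.abs(Theta))
    return logdet - np.trace(S @ Theta) - lam * off
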