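"""Per-snapshot low-rank + sparse + dense decomposition.

Solves, independently for each snapshot,

    min  ||L||_* + gamma ||S||_1 + alpha ||E||_F^2
    s.t. A = L + S + E

with an alternating splitting augmented Lagrangian method (ASALM): a
closed-form dense-noise update, an elementwise soft-thresholding update for
the sparse part, a singular-value-thresholding update for the low-rank part,
and a multiplier ascent step.  All iterates are re-symmetrized after every
sweep so adjacency semantics are preserved under floating point.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.linalg
import scipy.sparse.linalg

from netphase.types import (
    Decomposition,
    DegenerateInputError,
    InvalidInputError,
    SolverConfig,
    TemporalNetwork,
    WeightedNetwork,
)

__all__ = [
    "default_beta",
    "soft_threshold",
    "svt",
    "asalm_decompose",
    "stopping_metric",
    "decompose_sequence",
]

# Below this size a full eigendecomposition is cheaper than Lanczos.
_FULL_SVD_MAX_N = 200


def default_beta(A) -> float:
    """Penalty parameter beta = 0.15 N^2 / ||A||_1 (elementwise l1 norm)."""
    M = A.matrix if isinstance(A, WeightedNetwork) else np.asarray(A, dtype=float)
    l1 = float(np.abs(M).sum())
    if l1 == 0:
        raise DegenerateInputError("all-zero matrix: beta = 0.15 N^2/||A||_1 undefined")
    n = M.shape[0]
    return 0.15 * n * n / l1


def soft_threshold(x, theta):
    """Elementwise shrinkage sign(x) * max(|x| - theta, 0)."""
    if theta < 0:
        raise InvalidInputError("soft threshold must be nonnegative")
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.maximum(np.abs(x) - theta, 0.0)


def _sym_svt(M: np.ndarray, theta: float, rank_hint: int):
    """SVT specialized to symmetric M via eigendecomposition.

    For symmetric M = V diag(lam) V^T the singular values are |lam| with the
    same eigenvectors, so soft-thresholding singular values is equivalent to
    shrinking |lam| toward zero while keeping signs.  Uses a partial Lanczos
    eigendecomposition for large matrices, growing the computed rank
    geometrically until the smallest retrieved |lam| falls below theta.

    Returns (X, kept_singular_values, next_rank_hint).
    """
    n = M.shape[0]
    # Lanczos only pays off while the retained rank is a small fraction of n
    if n <= _FULL_SVD_MAX_N or rank_hint > n // 4:
        lam, V = scipy.linalg.eigh(M)
    else:
        k = min(max(rank_hint, 10), n // 4)
        while True:
            try:
                lam, V = scipy.sparse.linalg.eigsh(M, k=k, which="LM")
            except Exception:  # Lanczos failure: fall back to dense
                lam, V = scipy.linalg.eigh(M)
                break
            if np.min(np.abs(lam)) < theta:
                break
            if k >= n // 4:  # spectrum too flat for a partial solve
                lam, V = scipy.linalg.eigh(M)
                break
            k = min(2 * k, n // 4)
    shrunk = np.sign(lam) * np.maximum(np.abs(lam) - theta, 0.0)
    keep = shrunk != 0.0
    if not np.any(keep):
        return np.zeros_like(M), np.zeros(0), 10
    Vk = V[:, keep]
    X = (Vk * shrunk[keep]) @ Vk.T
    sigma = np.sort(np.abs(shrunk[keep]))[::-1]
    return X, sigma, max(10, int(np.sum(keep)) + 5)


def svt(M, theta):
    """Singular value thresholding: U soft(Sigma, theta) V^T of M = U Sigma V^T."""
    if theta < 0:
        raise InvalidInputError("svt threshold must be nonnegative")
    M = np.asarray(M, dtype=float)
    if not np.all(np.isfinite(M)):
        raise InvalidInputError("svt input must be finite")
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    s = np.maximum(s - theta, 0.0)
    return (U * s) @ Vt


def stopping_metric(L_prev, S_prev, L_curr, S_curr) -> float:
    """(||dL||_F^2 + ||dS||_F^2) / (||L_prev||_F^2 + ||S_prev||_F^2 + 1)."""
    num = np.linalg.norm(L_curr - L_prev) ** 2 + np.linalg.norm(S_curr - S_prev) ** 2
    den = np.linalg.norm(L_prev) ** 2 + np.linalg.norm(S_prev) ** 2 + 1.0
    return float(num / den)


def _symmetrize(X: np.ndarray) -> np.ndarray:
    return (X + X.T) / 2.0


def asalm_decompose(A, cfg: SolverConfig, warn: bool = True) -> Decomposition:
    """Run ASALM on a single symmetric snapshot.

    Per sweep: E (closed form) -> S (soft threshold at gamma/beta) -> L
    (SVT at 1/beta) -> multiplier ascent; then re-symmetrization of all four
    iterates.  Starts from L = S = E = Lambda = 0 and stops when the
    relative change of (L, S) drops below ``cfg.eps`` or at ``max_iter``.

    Non-convergence yields ``converged=False`` with a warning rather than an
    exception: the scanning pipeline must tolerate occasional hard snapshots.
    """
    M = A.matrix if isinstance(A, WeightedNetwork) else np.asarray(A, dtype=float)
    if not np.all(np.isfinite(M)):
        raise InvalidInputError("asalm_decompose requires finite entries")
    if not np.array_equal(M, M.T):
        raise InvalidInputError("asalm_decompose requires a symmetric matrix")
    n = M.shape[0]
    alpha = cfg.alpha
    gamma = cfg.gamma if cfg.gamma is not None else 1.0 / np.sqrt(n)
    if np.all(M == 0):
        Z = np.zeros_like(M)
        return Decomposition(Z, Z.copy(), Z.copy(), Z.copy(), 1, True, 0.0)
    beta = cfg.beta if cfg.beta is not None else default_beta(M)

    L = np.zeros_like(M)
    S = np.zeros_like(M)
    E = np.zeros_like(M)
    Lam = np.zeros_like(M)
    sigma = np.zeros(0)
    rank_hint = 10
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        L_prev, S_prev = L, S
        G = M + Lam / beta
        E = (beta / (2.0 * alpha + beta)) * (G - L - S)
        S = soft_threshold(G - L - E, gamma / beta)
        L, sigma, rank_hint = _sym_svt(_symmetrize(G - S - E), 1.0 / beta, rank_hint)
        Lam = Lam + beta * (M - L - S - E)
        L = _symmetrize(L)
        S = _symmetrize(S)
        E = _symmetrize(E)
        Lam = _symmetrize(Lam)
        if stopping_metric(L_prev, S_prev, L, S) <= cfg.eps:
            converged = True
            break
    if not converged and warn:
        warnings.warn(
            f"ASALM did not converge in {cfg.max_iter} iterations", RuntimeWarning
        )
    residual = float(np.linalg.norm(M - L - S - E))
    return Decomposition(L, S, E, Lam, it, converged, residual, sigma)


def decompose_sequence(net, cfg: SolverConfig, warn: bool = True):
    """Decompose every snapshot of a (padded) temporal network independently.

    Snapshots are independent problems; results do not depend on evaluation
    order.  Per-snapshot failures are re-raised with the offending 1-based
    time index attached.
    """
    if isinstance(net, TemporalNetwork):
        mats = net.matrices()
    else:
        mats = [m.matrix if isinstance(m, WeightedNetwork) else np.asarray(m) for m in net]
    sizes = {m.shape for m in mats}
    if len(sizes) > 1:
        raise InvalidInputError(
            "snapshots must share a common size; run pad_to_union first"
        )
    out = []
    for t, M in enumerate(mats, start=1):
        try:
            out.append(asalm_decompose(M, cfg, warn=warn))
        except Exception as exc:
            raise type(exc)(f"snapshot t={t}: {exc}") from exc
    return out
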