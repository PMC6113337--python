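"""Selection of the dense-noise weight alpha.

Scans a grid of alpha values over the prescribed interval
(0.5/sqrt(N + sqrt(8N)), 10/sqrt(N + sqrt(8N))), decomposing a few sampled
snapshots per alpha, and picks an alpha from the widest plateau of
time-consistent ranks that minimizes inconsistency between neighboring
grid values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from netphase.decompose import asalm_decompose
from netphase.types import InvalidInputError, SolverConfig

__all__ = ["alpha_grid", "inconsistency", "select_alpha", "scan_alphas", "AlphaScan"]


class SelectionFailureError(RuntimeError):
    """No rank-consistent plateau found; advise a finer grid."""


@dataclass
class AlphaScan:
    """Rank / inconsistency tables over (sampled time) x (alpha grid)."""

    alphas: np.ndarray  # (n_alpha,), strictly increasing
    sample_times: list  # 1-based time indices probed
    ranks: np.ndarray  # (n_times, n_alpha) int
    inconsistencies: np.ndarray  # (n_times, n_alpha - 1)

    def __post_init__(self):
        self.alphas = np.asarray(self.alphas, dtype=float)
        self.ranks = np.asarray(self.ranks, dtype=int)
        self.inconsistencies = np.asarray(self.inconsistencies, dtype=float)
        if not np.all(np.diff(self.alphas) > 0):
            raise InvalidInputError("alpha grid must be strictly increasing")
        if np.any(self.ranks < 0):
            raise InvalidInputError("ranks must be nonnegative")


def alpha_interval(n: int):
    """The prescribed open search interval for alpha given network size N."""
    root = np.sqrt(n + np.sqrt(8.0 * n))
    return 0.5 / root, 10.0 / root


def alpha_grid(n: int, step: float = 0.015) -> np.ndarray:
    """Evenly spaced alpha values covering the prescribed interval."""
    if n < 2:
        raise InvalidInputError("need N >= 2")
    if step <= 0:
        raise InvalidInputError("step must be positive")
    lo, hi = alpha_interval(n)
    if step > hi - lo:
        raise InvalidInputError(
            f"step {step} exceeds interval width {hi - lo:.4g} for N={n}"
        )
    grid = np.arange(lo, hi + 1e-12, step)
    return grid


def inconsistency(L_a: np.ndarray, L_b: np.ndarray) -> float:
    """||L_a - L_b||_F / (||L_a||_F + 1).

    The "+1" is read as a scalar added outside the norm, paralleling the
    solver's stopping condition; this guards division by zero.  The reading
    is isolated here so it can be flipped if needed.
    """
    L_a = np.asarray(L_a, dtype=float)
    L_b = np.asarray(L_b, dtype=float)
    if L_a.shape != L_b.shape:
        raise InvalidInputError("inconsistency requires matching shapes")
    return float(np.linalg.norm(L_a - L_b) / (np.linalg.norm(L_a) + 1.0))


def scan_alphas(
    mats,
    alphas=None,
    n_times: int = 20,
    gamma: float = None,
    eps: float = 1e-6,
    max_iter: int = 500,
) -> AlphaScan:
    """Decompose sampled snapshots across an alpha grid.

    ``mats`` is the full list of (padded) adjacency matrices for t = 1..T;
    ``n_times`` evenly spaced time points are probed.
    """
    T = len(mats)
    n = mats[0].shape[0]
    if alphas is None:
        alphas = alpha_grid(n)
    alphas = np.asarray(alphas, dtype=float)
    n_times = min(n_times, T)
    times = np.unique(np.linspace(1, T, n_times).round().astype(int))
    ranks = np.zeros((len(times), len(alphas)), dtype=int)
    incons = np.zeros((len(times), len(alphas) - 1))
    for ti, t in enumerate(times):
        prev_L = None
        for ai, a in enumerate(alphas):
            cfg = SolverConfig(alpha=float(a), gamma=gamma, eps=eps, max_iter=max_iter)
            dec = asalm_decompose(mats[t - 1], cfg, warn=False)
            ranks[ti, ai] = dec.rank
            if prev_L is not None:
                incons[ti, ai - 1] = inconsistency(prev_L, dec.L)
            prev_L = dec.L
    return AlphaScan(alphas, [int(t) for t in times], ranks, incons)


def _constant_runs(ranks: np.ndarray):
    """Maximal index runs [i, j] on which every row of ``ranks`` is constant."""
    n_alpha = ranks.shape[1]
    ok = np.all(ranks[:, 1:] == ranks[:, :-1], axis=0)  # adjacent-pair consistency
    runs = []
    start = 0
    for j in range(n_alpha - 1):
        if not ok[j]:
            if j > start:
                runs.append((start, j))
            start = j + 1
    if n_alpha - 1 > start:
        runs.append((start, n_alpha - 1))
    return runs


def select_alpha(scan: AlphaScan) -> float:
    """Pick alpha from the widest rank-consistent plateau.

    Within the widest contiguous alpha-interval on which every sampled
    time's rank is constant, returns the alpha minimizing the mean
    inconsistency to its grid neighbors; ties break toward larger alpha
    (both for plateaus of equal width and within a plateau).
    """
    if len(scan.alphas) < 3 or len(scan.sample_times) < 2:
        raise InvalidInputError("scan must cover >= 3 alphas and >= 2 sample times")
    runs = _constant_runs(scan.ranks)
    if not runs:
        raise SelectionFailureError(
            "no alpha-interval of >= 2 grid points with time-consistent ranks; "
            "try a finer grid"
        )
    width = lambda r: r[1] - r[0]
    best = max(runs, key=lambda r: (width(r), r[1]))
    i0, i1 = best
    mean_inc = scan.inconsistencies.mean(axis=0)
    best_alpha, best_score = None, np.inf
    for i in range(i0, i1 + 1):
        cols = [c for c in (i - 1, i) if i0 <= c < i1]  # neighbor pairs inside plateau
        if not cols:
            cols = [c for c in (i - 1, i) if 0 <= c < len(mean_inc)]
        score = float(np.mean(mean_inc[cols]))
        if score < best_score or (score == best_score):
            best_score, best_alpha = score, float(scan.alphas[i])
    return best_alpha
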