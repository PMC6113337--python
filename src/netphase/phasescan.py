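"""Phase-transition detection by thresholded-rank window scanning.

The T snapshots are split into ~sqrt(T) windows of length ~sqrt(T); within
each window the low-rank components are averaged and the *thresholded rank*
(number of singular values exceeding a threshold h) is computed.  A single h
is chosen from the widest plateau over which the per-window rank profile is
invariant.  Windows where the thresholded rank changes relative to their
predecessor flag candidate transition regions, which are then re-scanned
recursively with smaller windows (zoom-in) down to the finest level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from netphase.types import InvalidInputError

__all__ = [
    "RankTrace",
    "TransitionReport",
    "window_partition",
    "window_average",
    "thresholded_rank",
    "select_h",
    "detect_transitions",
    "scan",
    "default_levels",
]


class SelectionFailureError(RuntimeError):
    """No h-plateau with a stable per-window rank profile."""


@dataclass
class RankTrace:
    """Thresholded-rank table over (window) x (h grid).

    ``windows`` are half-open 1-based [start, end) intervals partitioning the
    scanned range; ``tr[w, j]`` is the thresholded rank of window w at
    threshold ``h_grid[j]`` (nonincreasing in j for fixed w).
    """

    windows: list
    h_grid: np.ndarray
    tr: np.ndarray
    singular_values: list = field(default_factory=list)  # per-window sigma of the average

    def ranks_at(self, h: float) -> np.ndarray:
        """Thresholded rank of each window average at threshold h."""
        if self.singular_values:
            return np.array([int(np.sum(s > h)) for s in self.singular_values])
        j = int(np.argmin(np.abs(self.h_grid - h)))
        return self.tr[:, j].copy()


@dataclass
class TransitionReport:
    """Detected phase-transition epochs and the stable segments between them.

    Epochs and segments are closed 1-based intervals in snapshot indices.
    """

    epochs: list
    segments: list
    h_selected: float
    window_lengths: list
    traces: list = field(default_factory=list)  # one RankTrace per level (coarsest first)


def window_partition(T: int, w: int):
    """Consecutive half-open [start, end) windows of length w covering 1..T.

    A shorter remainder window is kept (dropping it would blind the scanner
    to changes near T).
    """
    if w <= 0:
        raise InvalidInputError("window length must be positive")
    if w > T:
        raise InvalidInputError("window length exceeds horizon")
    return [(s, min(s + w, T + 1)) for s in range(1, T + 1, w)]


def window_average(Ls, window) -> np.ndarray:
    """Elementwise mean of L(t) for t in the half-open window [start, end)."""
    start, end = window
    if end <= start:
        raise InvalidInputError("empty window")
    if start < 1 or end > len(Ls) + 1:
        raise InvalidInputError("window outside 1..T")
    return np.mean([np.asarray(Ls[t - 1], dtype=float) for t in range(start, end)], axis=0)


def thresholded_rank(M, h: float) -> int:
    """Number of singular values of M strictly exceeding h."""
    if h < 0:
        raise InvalidInputError("threshold must be nonnegative")
    s = np.linalg.svd(np.asarray(M, dtype=float), compute_uv=False)
    return int(np.sum(s > h))


def default_h_grid(Ls, n_points: int = 60) -> np.ndarray:
    """Log-spaced thresholds between 0.1 and sigma_2 of the global mean L.

    The grid is capped at the second singular value: above it every window
    counts only the dominant (Perron) component, producing a spuriously wide
    constant-rank plateau that would starve the transition detector.
    """
    global_mean = np.mean([np.asarray(L, dtype=float) for L in Ls], axis=0)
    s = np.linalg.svd(global_mean, compute_uv=False)
    hi = float(s[1]) if len(s) > 1 and s[1] > 0.3 else float(s[0])
    hi = max(hi, 0.2)
    return np.geomspace(0.1, hi, n_points)


def build_trace(Ls, windows, h_grid) -> RankTrace:
    """Singular spectra of window averages, tabulated over the h grid."""
    h_grid = np.asarray(h_grid, dtype=float)
    sigmas = []
    for win in windows:
        M = window_average(Ls, win)
        sigmas.append(np.linalg.svd(M, compute_uv=False))
    tr = np.array([[int(np.sum(s > h)) for h in h_grid] for s in sigmas])
    return RankTrace(list(windows), h_grid, tr, sigmas)


def select_h(trace: RankTrace, tol: float = 0.1) -> float:
    """Midpoint of the widest h-interval with a stable rank profile.

    An interval counts as stable when at most ``floor(tol * W)`` *distinct*
    windows change rank anywhere inside it: windows straddling a transition
    carry scattered intermediate singular values and flicker at any
    threshold, so demanding exact profile invariance would reject every
    informative interval — but counting distinct windows (rather than
    per-step changes) still rejects intervals where the profile drifts
    gradually across many windows.  Maximal stable intervals are ranked by
    linear h width (the fine-level rows of a stacked trace already reject
    the spuriously calm stretches near the top of the grid); remaining ties
    break toward the lower interval.
    """
    runs = _stable_runs(trace.tr, tol)
    if not runs:
        raise SelectionFailureError("no h-interval of >= 2 grid points with a stable rank profile")
    best = max(
        runs,
        key=lambda r: (trace.h_grid[r[1]] - trace.h_grid[r[0]], -r[0]),
    )
    i0, i1 = best
    return float((trace.h_grid[i0] + trace.h_grid[i1]) / 2.0)


def _stable_runs(tr, tol):
    """Maximal h-index intervals within which at most floor(tol * W)
    distinct windows change rank."""
    n_h = tr.shape[1]
    allowed = int(np.floor(tol * tr.shape[0]))
    step_changes = [
        np.flatnonzero(tr[:, j] != tr[:, j + 1]) for j in range(n_h - 1)
    ]
    runs = []
    for i in range(n_h - 1):
        changed = set()
        j = i
        while j < n_h - 1:
            new = changed | set(step_changes[j].tolist())
            if len(new) > allowed:
                break
            changed = new
            j += 1
        if j > i and (not runs or runs[-1][1] < j):  # drop dominated intervals
            runs.append((i, j))
    return runs


def _select_h_stacked(coarse: RankTrace, fine: RankTrace, tol: float = 0.1) -> float:
    """Threshold selection from coarse + finest-level profiles jointly.

    Stability (distinct-window tolerance) is required on the stacked
    profile.  Among stable intervals, those where coarse and fine windows
    agree on rank at the interval midpoint are preferred — fine windows
    average fewer snapshots, so below the fine noise floor they count more
    spurious components than coarse ones and the two resolutions disagree.
    Consistent intervals are then ranked by total coarse rank (a too-high
    threshold is stable and consistent but counts only the few dominant
    components), then by linear width; ties break toward the lower one.
    """
    h_grid = coarse.h_grid
    tr = np.vstack([coarse.tr, fine.tr])
    runs = _stable_runs(tr, tol)
    if not runs:
        raise SelectionFailureError("no h-interval of >= 2 grid points with a stable rank profile")

    def key(run):
        i0, i1 = run
        mid = (i0 + i1) // 2
        c_mean = float(coarse.tr[:, mid].mean())
        f_mean = float(fine.tr[:, mid].mean())
        consistent = abs(c_mean - f_mean) <= max(1.0, 0.1 * c_mean)
        return (
            consistent,
            int(coarse.tr[:, mid].sum()),
            float(h_grid[i1] - h_grid[i0]),
            -i0,
        )

    i0, i1 = max(runs, key=key)
    return float((h_grid[i0] + h_grid[i1]) / 2.0)


def detect_transitions(trace: RankTrace, h: float):
    """Candidate regions: runs of consecutive windows whose thresholded rank
    differs from the preceding window's."""
    ranks = trace.ranks_at(h)
    flagged = [i for i in range(1, len(ranks)) if ranks[i] != ranks[i - 1]]
    regions = []
    for i in flagged:
        if regions and i == regions[-1][-1] + 1:
            regions[-1].append(i)
        else:
            regions.append([i])
    return [(r[0], r[-1]) for r in regions]  # window-index (0-based) spans


def default_levels(T: int):
    """Window lengths (floor(sqrt(T)), max(2, floor(T**0.25)), 2), deduplicated."""
    levels = [int(np.sqrt(T)), max(2, int(T**0.25)), 2]
    out = []
    for w in levels:
        w = max(1, min(w, T))
        if not out or w < out[-1]:
            out.append(w)
    return out


def _windows_merged_tail(lo, hi, w):
    """Half-open w-windows over [lo, hi]; a remainder shorter than w is
    merged into the last full window rather than kept standalone (a short
    window averages fewer snapshots, so its noise floor is higher and it
    would flag spurious transitions at the finest level)."""
    windows = [(s, min(s + w, hi + 1)) for s in range(lo, hi + 1, w)]
    if len(windows) > 1 and windows[-1][1] - windows[-1][0] < w:
        windows[-2] = (windows[-2][0], windows[-1][1])
        windows.pop()
    return windows


def _refine(Ls, lo, hi, h, levels, level_idx):
    """Recursively zoom into [lo, hi] with ever smaller windows.

    Returns the refined closed epoch interval(s) found inside [lo, hi] at
    the finest level, plus the traces built along the way.  Falls back to
    [lo, hi] itself if this level's windows see no rank change or cannot
    subdivide the range.
    """
    w = levels[level_idx]
    finest = level_idx == len(levels) - 1
    if w >= hi - lo + 1:
        return [(lo, hi)], []
    windows = _windows_merged_tail(lo, hi, w)
    trace = build_trace(Ls, windows, np.array([h]))
    regions = detect_transitions(trace, h)
    traces = [trace]
    if not regions:
        return [(lo, hi)], traces
    epochs = []
    for w0, w1 in regions:
        if finest:
            epochs.append((windows[w0][0], windows[w1][1] - 1))
        else:
            r_lo = windows[max(0, w0 - 1)][0]
            r_hi = windows[min(len(windows) - 1, w1 + 1)][1] - 1
            sub_epochs, sub_traces = _refine(Ls, r_lo, r_hi, h, levels, level_idx + 1)
            epochs.extend(sub_epochs)
            traces.extend(sub_traces)
    return epochs, traces


def scan(Ls, levels=None, h=None, h_grid=None) -> TransitionReport:
    """Full multi-level scan of a sequence of low-rank components.

    The threshold h is selected once at the coarsest level (unless given)
    and reused at finer levels.  Candidate regions found at each level are
    re-scanned over a neighborhood extending one coarse window on each side
    with the next smaller window length.
    """
    T = len(Ls)
    if levels is None:
        levels = default_levels(T)
    levels = list(levels)
    if any(b >= a for a, b in zip(levels, levels[1:])):
        raise InvalidInputError("levels must be strictly decreasing")
    w0 = levels[0]
    windows = window_partition(T, w0)
    if h_grid is None:
        h_grid = default_h_grid(Ls)
    trace = build_trace(Ls, windows, h_grid)
    if h is None:
        # select h on the stacked coarse + finest-level profiles: zoom-in
        # windows average fewer snapshots and so carry a higher noise floor,
        # and a threshold chosen from the coarse trace alone can sit below
        # it, making the finest level flicker everywhere
        try:
            w_fin = levels[-1]
            if w_fin < w0:
                fin_trace = build_trace(Ls, _windows_merged_tail(1, T, w_fin), h_grid)
                h = _select_h_stacked(trace, fin_trace)
            else:
                h = select_h(trace)
        except SelectionFailureError as exc:
            raise SelectionFailureError(f"level w={w0}: {exc}") from exc
    regions = detect_transitions(trace, h)
    traces = [trace]
    epochs = []
    for reg_lo, reg_hi in regions:
        lo = windows[max(0, reg_lo - 1)][0]
        hi = windows[min(len(windows) - 1, reg_hi + 1)][1] - 1
        if len(levels) == 1:
            epochs.append((windows[reg_lo][0], windows[reg_hi][1] - 1))
            continue
        sub_epochs, sub_traces = _refine(Ls, lo, hi, h, levels, 1)
        epochs.extend(sub_epochs)
        traces.extend(sub_traces)
    epochs = _merge_intervals(epochs)
    segments = _complement(epochs, T)
    return TransitionReport(epochs, segments, float(h), levels, traces)


def _merge_intervals(intervals):
    out = []
    for lo, hi in sorted(intervals):
        if out and lo <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], hi))
        else:
            out.append((lo, hi))
    return out


def _complement(epochs, T):
    """Maximal closed intervals of 1..T not covered by any epoch."""
    segments = []
    cur = 1
    for lo, hi in epochs:
        if lo > cur:
            segments.append((cur, lo - 1))
        cur = max(cur, hi + 1)
    if cur <= T:
        segments.append((cur, T))
    return segments
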