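"""Segment-level community extraction and scoring against planted truth.

Communities are read off the segment-averaged low-rank matrix by spectral
clustering: entries are clipped below at zero to form a similarity, the
symmetric-normalized Laplacian embedding into the k leading eigenvectors is
row-normalized, and k-means (fixed seed, multiple restarts) assigns labels.
Nodes with all-zero similarity rows (absent or fully disconnected) receive
the noise label -1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from netphase.phasescan import window_average
from netphase.types import InvalidInputError

__all__ = [
    "segment_average",
    "spectral_communities",
    "match_labels",
    "misclassification_rate",
    "evaluate_detection",
    "SegmentCommunities",
    "EvaluationResult",
]

NOISE_LABEL = -1


@dataclass
class SegmentCommunities:
    """Clustering of one stable segment."""

    segment: tuple  # closed (lo, hi) 1-based interval
    L_bar: np.ndarray
    k: int
    labels: np.ndarray  # -1 for noise/absent nodes


@dataclass
class EvaluationResult:
    recovery_rate: float
    error_rate: float
    per_community_accuracy: dict
    n_recovered: int = 0
    n_planted: int = 0


def segment_average(Ls, segment) -> np.ndarray:
    """Elementwise mean of L(t) over a closed 1-based segment (lo, hi)."""
    lo, hi = segment
    if hi < lo:
        raise InvalidInputError("empty segment")
    return window_average(Ls, (lo, hi + 1))


def spectral_communities(L_bar, k: int, seed: int = 0) -> np.ndarray:
    """Spectral clustering of a (segment-averaged) low-rank matrix.

    Entries are clipped below at 0 to form a similarity W; rows of W that
    are entirely zero are excluded and labeled -1.  Clustering uses the k
    leading eigenvectors of D^{-1/2} W D^{-1/2} with unit-normalized rows
    and k-means with 20 restarts.
    """
    L_bar = np.asarray(L_bar, dtype=float)
    n = L_bar.shape[0]
    if k < 1:
        raise InvalidInputError("k must be >= 1")
    if k > n:
        raise InvalidInputError("k exceeds matrix size")
    W = np.clip(L_bar, 0.0, None)
    active = ~np.all(W == 0.0, axis=1)
    labels = np.full(n, NOISE_LABEL, dtype=int)
    idx = np.flatnonzero(active)
    if idx.size == 0:
        return labels
    if k > idx.size:
        raise InvalidInputError("k exceeds number of active nodes")
    Wa = W[np.ix_(idx, idx)]
    deg = Wa.sum(axis=1)
    deg[deg == 0] = 1.0
    d = 1.0 / np.sqrt(deg)
    M = Wa * np.outer(d, d)
    if k == 1:
        labels[idx] = 0
        return labels
    # top-k eigenvectors of the normalized similarity
    vals, vecs = scipy.linalg.eigh(M, subset_by_index=[idx.size - k, idx.size - 1])
    emb = vecs[:, ::-1]
    norms = np.linalg.norm(emb, axis=1)
    norms[norms == 0] = 1.0
    emb = emb / norms[:, None]
    km = KMeans(n_clusters=k, n_init=20, random_state=seed)
    labels[idx] = km.fit_predict(emb)
    return labels


def _contingency(pred, truth):
    """Overlap counts between predicted and truth classes (incl. -1)."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    p_classes = np.unique(pred)
    t_classes = np.unique(truth)
    C = np.zeros((len(p_classes), len(t_classes)), dtype=int)
    for i, p in enumerate(p_classes):
        mp = pred == p
        for j, t in enumerate(t_classes):
            C[i, j] = int(np.sum(mp & (truth == t)))
    return C, p_classes, t_classes


def match_labels(pred, truth) -> dict:
    """Optimal one-to-one mapping predicted label -> truth label.

    Solved exactly as a rectangular assignment problem maximizing total
    overlap; predicted labels left unmatched map to None.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise InvalidInputError("pred and truth must cover the same node set")
    C, p_classes, t_classes = _contingency(pred, truth)
    rows, cols = linear_sum_assignment(C, maximize=True)
    mapping = {int(p): None for p in p_classes}
    for r, c in zip(rows, cols):
        mapping[int(p_classes[r])] = int(t_classes[c])
    return mapping


def misclassification_rate(pred, truth) -> float:
    """1 - (matched overlap)/N under the optimal label mapping.

    The noise label -1 participates in matching as an ordinary class.
    Invariant under any relabeling permutation of either argument.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise InvalidInputError("pred and truth must cover the same node set")
    C, _, _ = _contingency(pred, truth)
    rows, cols = linear_sum_assignment(C, maximize=True)
    overlap = C[rows, cols].sum()
    return float(1.0 - overlap / pred.size)


def _jaccard(a: np.ndarray, b: np.ndarray) -> float:
    union = np.sum(a | b)
    return float(np.sum(a & b) / union) if union else 0.0


def evaluate_detection(preds, truths) -> EvaluationResult:
    """Score per-time predicted labels against planted per-time membership.

    ``preds`` and ``truths`` are parallel lists of label arrays (one pair
    per evaluated time point; a per-segment clustering is passed by
    repeating its labels for each t of the segment).

    A planted community (label >= 0) counts as recovered when its
    best-matched predicted cluster reaches Jaccard overlap >= 0.5 on
    average over time.  ``error_rate`` is the time-averaged
    misclassification restricted to nodes of recovered communities;
    ``per_community_accuracy`` the time-averaged fraction of a community's
    nodes carrying the matched label.
    """
    if len(preds) != len(truths) or not preds:
        raise InvalidInputError("need parallel, non-empty pred/truth lists")
    planted = sorted(
        {int(c) for tr in truths for c in np.unique(tr) if c >= 0}
    )
    jac = {c: [] for c in planted}
    acc = {c: [] for c in planted}
    matched_per_t = []
    for pred, truth in zip(preds, truths):
        pred = np.asarray(pred)
        truth = np.asarray(truth)
        mapping = match_labels(pred, truth)
        inv = {t: p for p, t in mapping.items() if t is not None}
        matched_per_t.append((pred, truth, inv))
        for c in planted:
            t_mask = truth == c
            if not np.any(t_mask):
                continue
            # the noise cluster can win the assignment but never counts as
            # recovering a planted community
            if c in inv and inv[c] != NOISE_LABEL:
                p_mask = pred == inv[c]
                jac[c].append(_jaccard(p_mask, t_mask))
                acc[c].append(float(np.sum(p_mask & t_mask) / np.sum(t_mask)))
            else:
                jac[c].append(0.0)
                acc[c].append(0.0)
    recovered = {c for c in planted if jac[c] and float(np.mean(jac[c])) >= 0.5}
    errors = []
    for pred, truth, inv in matched_per_t:
        mask = np.isin(truth, sorted(recovered)) if recovered else np.zeros(truth.shape, bool)
        n_nodes = int(np.sum(mask))
        if n_nodes == 0:
            continue
        wrong = 0
        for c in recovered:
            c_mask = truth == c
            if c in inv:
                wrong += int(np.sum(c_mask & (pred != inv[c])))
            else:
                wrong += int(np.sum(c_mask))
        errors.append(wrong / n_nodes)
    return EvaluationResult(
        recovery_rate=(len(recovered) / len(planted)) if planted else 1.0,
        error_rate=float(np.mean(errors)) if errors else 0.0,
        per_community_accuracy={c: float(np.mean(acc[c])) for c in planted if acc[c]},
        n_recovered=len(recovered),
        n_planted=len(planted),
    )
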