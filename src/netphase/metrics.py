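"""Scalar network diagnostics: modularity, relative polarization, variation."""

from __future__ import annotations

import numpy as np

from netphase.types import DegenerateInputError, InvalidInputError, WeightedNetwork

__all__ = ["modularity", "relative_polarization", "variation"]


def _as_matrix(net) -> np.ndarray:
    if isinstance(net, WeightedNetwork):
        return net.matrix
    return np.asarray(net, dtype=float)


def modularity(net, labels) -> float:
    """Q = (1/2m) sum_ij (A_ij - k_i k_j / 2m) delta(g_i, g_j).

    k_i is the weighted degree and 2m the total weight (diagonal included,
    since the sums run over all ij).  Nodes labeled -1 belong to no
    community and never satisfy delta, but still contribute degree mass.
    """
    A = _as_matrix(net)
    labels = np.asarray(labels)
    if labels.shape[0] != A.shape[0]:
        raise InvalidInputError("labels must cover all nodes")
    two_m = float(A.sum())
    if two_m <= 0:
        raise DegenerateInputError("zero total weight")
    k = A.sum(axis=1)
    delta = (labels[:, None] == labels[None, :]) & (labels[:, None] >= 0)
    Q = float(np.sum((A - np.outer(k, k) / two_m) * delta) / two_m)
    return Q


def relative_polarization(net, labels, k: int) -> float:
    """Relative polarization P_k of community k.

    Ratio of the mean within-community-k weight to the mean weight outside
    all communities:

        P_k = (sum_{ij in k} A_ij) / (N_k^2 * P_out),
        P_out = (sum_ij A_ij - sum_c sum_{ij in c} A_ij)
                / (N^2 - sum_c N_c^2).

    Nodes labeled -1 belong to no community; all their pairs count toward
    the outside mean.
    """
    A = _as_matrix(net)
    labels = np.asarray(labels)
    if labels.shape[0] != A.shape[0]:
        raise InvalidInputError("labels must cover all nodes")
    if not np.any(labels == k):
        raise InvalidInputError(f"community {k} has no members")
    n = A.shape[0]
    comms = [c for c in np.unique(labels) if c >= 0]
    sizes = {c: int(np.sum(labels == c)) for c in comms}
    sum_sq = sum(s**2 for s in sizes.values())
    if n * n <= sum_sq:
        raise DegenerateInputError("no node pairs outside communities")
    internal_total = 0.0
    for c in comms:
        m = labels == c
        internal_total += float(A[np.ix_(m, m)].sum())
    p_out = (float(A.sum()) - internal_total) / (n * n - sum_sq)
    if p_out <= 0:
        raise DegenerateInputError("outside-community mean weight is zero")
    mk = labels == k
    within = float(A[np.ix_(mk, mk)].sum())
    return within / (sizes[k] ** 2 * p_out)


def variation(net, i: int, consistent: bool = False) -> float:
    """Sample standard deviation of node i's connection weights.

    Implemented exactly as defined: the mean divides by N while the sum of
    squared deviations divides by N-1 (the usual unbiased-variance form).
    ``consistent=True`` switches the variance divisor to N as well.
    Invariant under adding a constant to the row.
    """
    A = _as_matrix(net)
    n = A.shape[0]
    if n < 2:
        raise InvalidInputError("need N >= 2")
    row = A[i, :]
    mean = row.sum() / n
    ss = np.sum((row - mean) ** 2)
    return float(np.sqrt(ss / (n if consistent else n - 1)))
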